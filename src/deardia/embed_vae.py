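"""Triplet-loss variational autoencoder for XIC embedding.

A 4-branch fully connected encoder maps a length-20 XIC (min-max scaled to
[0,1]) to two 16-dimensional vectors, the latent mean mu and the
log-variance. The mean vector is the embedding used downstream. The decoder
mirrors the encoder; its four branch outputs concatenate to a
384+192+48+128 = 752 vector before the final 20-dimensional layer.

Training minimizes, per triplet (anchor, positive, negative):

    L_total = (L_VAE(a) + L_VAE(p) + L_VAE(n)) / 3 + L_triplet(mu_a, mu_p, mu_n)

with L_VAE = L_KL + L_recon (KL of the diagonal Gaussian posterior against
the standard normal plus mean-squared reconstruction error) and the hinge
triplet loss with margin alpha = 1. A `literal_eq2` mode flipping the KL
sign, and a `literal_sampling` mode using Z = mu + eps * sigma^2 instead of
Z = mu + eps * sigma, are available for comparison; both defaults follow
the standard formulations.

Optimization uses an Adam implementation written here (eta=0.001,
beta1=0.9, beta2=0.999, eps=1e-8) with bias-corrected moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _nn
from ._nn import Tensor

__all__ = [
    "VaeArch", "TripletExample", "EncoderOutput", "AdamState",
    "init_vae_params", "normalize_xic", "encode", "decode", "sample_latent",
    "vae_loss", "triplet_loss", "total_loss", "adam_step", "train_vae",
    "embed_xics", "save_params", "load_params",
]


@dataclass(frozen=True)
class VaeArch:
    """Branch widths of encoder/decoder; defaults follow the 4-branch design."""
    input_dim: int = 20
    latent_dim: int = 16
    enc_branches: tuple = ((384,), (192, 384), (48, 128), (128,))
    dec_branches: tuple = ((384,), (384, 192), (128, 48), (128,))
    dropout: float = 0.2

    @property
    def enc_concat(self) -> int:
        return sum(b[-1] for b in self.enc_branches)

    @property
    def dec_concat(self) -> int:
        return sum(b[-1] for b in self.dec_branches)


@dataclass
class TripletExample:
    anchor: np.ndarray
    positive: np.ndarray
    negative: np.ndarray


@dataclass
class EncoderOutput:
    mu: np.ndarray
    log_var: np.ndarray


@dataclass
class AdamState:
    """First/second moment accumulators and the step counter."""
    m: Dict[str, np.ndarray]
    v: Dict[str, np.ndarray]
    t: int = 0
    eta: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    @classmethod
    def init(cls, params: Dict[str, np.ndarray], **kw) -> "AdamState":
        return cls(m={k: np.zeros_like(p) for k, p in params.items()},
                   v={k: np.zeros_like(p) for k, p in params.items()}, **kw)


# ---------------------------------------------------------------------------
# parameters


def _init_linear(params, name, n_in, n_out, rng):
    bound = 1.0 / math.sqrt(n_in)
    params[f"{name}.W"] = rng.uniform(-bound, bound, size=(n_in, n_out))
    params[f"{name}.b"] = np.zeros(n_out)


def init_vae_params(arch: VaeArch = VaeArch(),
                    seed: int = 0) -> Dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    params: Dict[str, np.ndarray] = {}
    for bi, widths in enumerate(arch.enc_branches):
        n_in = arch.input_dim
        for li, w in enumerate(widths):
            _init_linear(params, f"enc.{bi}.{li}", n_in, w, rng)
            n_in = w
    _init_linear(params, "enc.mu", arch.enc_concat, arch.latent_dim, rng)
    _init_linear(params, "enc.logvar", arch.enc_concat, arch.latent_dim, rng)
    for bi, widths in enumerate(arch.dec_branches):
        n_in = arch.latent_dim
        for li, w in enumerate(widths):
            _init_linear(params, f"dec.{bi}.{li}", n_in, w, rng)
            n_in = w
    _init_linear(params, "dec.out", arch.dec_concat, arch.input_dim, rng)
    return params


def _as_tensors(params) -> Dict[str, Tensor]:
    return {k: (v if isinstance(v, Tensor) else Tensor(v, requires_grad=True))
            for k, v in params.items()}


# ---------------------------------------------------------------------------
# forward passes (tensor graph; numpy wrappers below)


def _branch_stack(x: Tensor, pt, prefix, branches, training, dropout, rng):
    outs = []
    for bi, widths in enumerate(branches):
        h = x
        for li in range(len(widths)):
            h = _nn.relu(h @ pt[f"{prefix}.{bi}.{li}.W"] + pt[f"{prefix}.{bi}.{li}.b"])
        if training and rng is not None:
            h = _nn.dropout(h, dropout, rng)
        outs.append(h)
    return _nn.concat(outs, axis=-1)


def _encode_t(x: Tensor, pt, arch, training=False, rng=None):
    h = _branch_stack(x, pt, "enc", arch.enc_branches, training, arch.dropout, rng)
    mu = h @ pt["enc.mu.W"] + pt["enc.mu.b"]
    logvar = h @ pt["enc.logvar.W"] + pt["enc.logvar.b"]
    return mu, logvar


def _decode_t(z: Tensor, pt, arch, training=False, rng=None):
    h = _branch_stack(z, pt, "dec", arch.dec_branches, training, arch.dropout, rng)
    assert h.shape[-1] == arch.dec_concat
    return h @ pt["dec.out.W"] + pt["dec.out.b"]


def normalize_xic(x: np.ndarray) -> np.ndarray:
    """Min-max scale an XIC to [0,1]; a constant trace maps to zeros."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(axis=-1, keepdims=True), x.max(axis=-1, keepdims=True)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    return np.where(span > 0, (x - lo) / safe, 0.0)


def _check_dim(x, dim, what):
    if x.shape[-1] != dim:
        raise ValueError(f"{what} must have length {dim}, got {x.shape[-1]}")


def encode(x: np.ndarray, params, arch: VaeArch = VaeArch(),
           training: bool = False,
           rng: Optional[np.random.Generator] = None) -> EncoderOutput:
    """Encode one XIC (or a batch); deterministic when training is False."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    _check_dim(x, arch.input_dim, "encoder input")
    mu, logvar = _encode_t(Tensor(x), _as_tensors(params), arch,
                           training=training, rng=rng)
    squeeze = (np.asarray(x).ndim == 2 and x.shape[0] == 1)
    m, lv = mu.data, logvar.data
    return EncoderOutput(mu=m[0] if squeeze else m,
                         log_var=lv[0] if squeeze else lv)


def decode(z: np.ndarray, params, arch: VaeArch = VaeArch(),
           training: bool = False,
           rng: Optional[np.random.Generator] = None) -> np.ndarray:
    z = np.atleast_2d(np.asarray(z, dtype=float))
    _check_dim(z, arch.latent_dim, "decoder input")
    out = _decode_t(Tensor(z), _as_tensors(params), arch,
                    training=training, rng=rng).data
    return out[0] if out.shape[0] == 1 else out


def sample_latent(out: EncoderOutput, epsilon: np.ndarray,
                  literal: bool = False) -> np.ndarray:
    """Reparameterized latent sample.

    Default: Z = mu + eps * sigma with sigma = exp(log_var / 2).
    Literal mode: Z = mu + eps * sigma^2 (the variance-scaled variant).
    """
    sigma2 = np.exp(np.asarray(out.log_var, dtype=float))
    scale = sigma2 if literal else np.sqrt(sigma2)
    return np.asarray(out.mu, dtype=float) + np.asarray(epsilon) * scale


def vae_loss(x, x_hat, mu, log_var,
             literal_eq2: bool = False) -> Tuple[float, float, float]:
    """(loss_kl, loss_recon, loss_vae) averaged over the batch.

    loss_kl = -1/2 sum_d (log sigma^2_d - mu_d^2 - sigma^2_d + 1) >= 0;
    loss_recon is the MSE over the 20 points. The default combination is
    loss_kl + loss_recon; literal_eq2 flips the KL sign.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=float))
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    log_var = np.atleast_2d(np.asarray(log_var, dtype=float))
    if not (np.isfinite(x).all() and np.isfinite(x_hat).all()
            and np.isfinite(mu).all() and np.isfinite(log_var).all()):
        raise FloatingPointError("nonfinite input to vae_loss")
    kl = float(np.mean(
        -0.5 * np.sum(log_var - mu ** 2 - np.exp(log_var) + 1.0, axis=-1)))
    recon = float(np.mean(np.mean((x - x_hat) ** 2, axis=-1)))
    total = (-kl if literal_eq2 else kl) + recon
    return kl, recon, total


def triplet_loss(mu_a, mu_p, mu_n, alpha: float = 1.0) -> float:
    """Hinge triplet loss, mean over the batch:
    [ ||mu_a-mu_p||^2 - ||mu_a-mu_n||^2 + alpha ]_+"""
    mu_a = np.atleast_2d(np.asarray(mu_a, dtype=float))
    mu_p = np.atleast_2d(np.asarray(mu_p, dtype=float))
    mu_n = np.atleast_2d(np.asarray(mu_n, dtype=float))
    if mu_a.shape != mu_p.shape or mu_a.shape != mu_n.shape:
        raise ValueError("triplet embeddings must share a shape")
    d_ap = np.sum((mu_a - mu_p) ** 2, axis=-1)
    d_an = np.sum((mu_a - mu_n) ** 2, axis=-1)
    return float(np.mean(np.maximum(d_ap - d_an + alpha, 0.0)))


def total_loss(triplet: TripletExample, params, arch: VaeArch = VaeArch(),
               epsilons=None, alpha: float = 1.0,
               literal_eq2: bool = False,
               literal_sampling: bool = False) -> float:
    """Combined objective of one (normalized) triplet at inference settings."""
    xs = [normalize_xic(np.asarray(v, dtype=float))
          for v in (triplet.anchor, triplet.positive, triplet.negative)]
    if epsilons is None:
        epsilons = [np.zeros(arch.latent_dim)] * 3
    vae_terms, mus = [], []
    for x, eps in zip(xs, epsilons):
        out = encode(x, params, arch)
        z = sample_latent(out, eps, literal=literal_sampling)
        x_hat = decode(z, params, arch)
        vae_terms.append(vae_loss(x, x_hat, out.mu, out.log_var,
                                  literal_eq2=literal_eq2)[2])
        mus.append(out.mu)
    return float(sum(vae_terms) / 3.0 + triplet_loss(*mus, alpha=alpha))


# ---------------------------------------------------------------------------
# Adam (from scratch)


def adam_step(params: Dict[str, np.ndarray],
              grads: Dict[str, np.ndarray],
              state: AdamState) -> Dict[str, np.ndarray]:
    """One Adam update, in place on `params`; returns `params`.

    m_t = b1 m + (1-b1) g;  v_t = b2 v + (1-b2) g^2;
    m^ = m_t/(1-b1^t);  v^ = v_t/(1-b2^t);  theta -= eta m^/(sqrt(v^)+eps).
    """
    state.t += 1
    b1, b2, t = state.beta1, state.beta2, state.t
    for k, g in grads.items():
        state.m[k] = b1 * state.m[k] + (1.0 - b1) * g
        state.v[k] = b2 * state.v[k] + (1.0 - b2) * g * g
        m_hat = state.m[k] / (1.0 - b1 ** t)
        v_hat = state.v[k] / (1.0 - b2 ** t)
        params[k] -= state.eta * m_hat / (np.sqrt(v_hat) + state.eps)
    return params


# ---------------------------------------------------------------------------
# training


def _triplet_batch_graph(xa, xp, xn, pt, arch, rng, alpha,
                         literal_eq2, literal_sampling, training=True):
    """Build the loss graph for one batch of normalized triplets."""
    terms, mus = [], []
    n = xa.shape[0]
    for x in (xa, xp, xn):
        xt = Tensor(x)
        mu, logvar = _encode_t(xt, pt, arch, training=training, rng=rng)
        eps = rng.standard_normal((n, arch.latent_dim))
        sig2 = _nn.exp(logvar)
        scale = sig2 if literal_sampling else _nn.exp(logvar * 0.5)
        z = mu + Tensor(eps) * scale
        x_hat = _decode_t(z, pt, arch, training=training, rng=rng)
        kl_per = (logvar - mu.square() - sig2 + 1.0).sum(axis=-1) * (-0.5)
        kl = kl_per.mean()
        recon = (xt - x_hat).square().mean(axis=-1).mean()
        terms.append((kl * (-1.0 if literal_eq2 else 1.0)) + recon)
        mus.append(mu)
    mu_a, mu_p, mu_n = mus
    d_ap = (mu_a - mu_p).square().sum(axis=-1)
    d_an = (mu_a - mu_n).square().sum(axis=-1)
    hinge = _nn.relu(d_ap - d_an + alpha)
    return (terms[0] + terms[1] + terms[2]) / 3.0 + hinge.mean()


def train_vae(triplets: Sequence[TripletExample],
              epochs: int = 10, batch_size: int = 256, seed: int = 0,
              arch: VaeArch = VaeArch(), alpha: float = 1.0,
              eta: float = 0.001,
              literal_eq2: bool = False,
              literal_sampling: bool = False,
              params: Optional[Dict[str, np.ndarray]] = None
              ) -> Tuple[Dict[str, np.ndarray], List[float]]:
    """Train the VAE on a triplet set; returns (params, per-epoch mean loss).

    Fully seeded: initialization, shuffling, dropout masks and latent
    epsilons all derive from `seed`, so identical calls are reproducible.
    """
    triplets = list(triplets)
    if not triplets:
        raise ValueError("empty triplet stream")
    rng = np.random.default_rng(seed)
    if params is None:
        params = init_vae_params(arch, seed=seed)
    state = AdamState.init(params, eta=eta)

    xa = normalize_xic(np.stack([t.anchor for t in triplets]).astype(float))
    xp = normalize_xic(np.stack([t.positive for t in triplets]).astype(float))
    xn = normalize_xic(np.stack([t.negative for t in triplets]).astype(float))

    history: List[float] = []
    n = len(triplets)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            pt = _as_tensors(params)
            loss = _triplet_batch_graph(
                xa[idx], xp[idx], xn[idx], pt, arch, rng, alpha,
                literal_eq2, literal_sampling)
            loss.backward()
            grads = {k: t.grad for k, t in pt.items() if t.grad is not None}
            adam_step(params, grads, state)
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return params, history


def embed_xics(xics, params, arch: VaeArch = VaeArch()) -> np.ndarray:
    """Embed XICs as latent means (inference mode; min-max normalized)."""
    x = np.atleast_2d(np.asarray(xics, dtype=float))
    _check_dim(x, arch.input_dim, "XIC")
    out = encode(normalize_xic(x), params, arch, training=False)
    return np.atleast_2d(out.mu)


# ---------------------------------------------------------------------------
# checkpointing


def save_params(params: Dict[str, np.ndarray], path, meta: Optional[dict] = None):
    """Single-file checkpoint: arrays keyed by layer name plus JSON meta."""
    import json
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta or {}).encode(), dtype=np.uint8), **params)


def load_params(path) -> Tuple[Dict[str, np.ndarray], dict]:
    import json
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode()) if "__meta__" in npz else {}
        params = {k: npz[k].copy() for k in npz.files if k != "__meta__"}
    return params, meta
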