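"""CNN co-elution classifier for precursor-fragment groups.

The top-6 fragment XICs matched to a candidate peptide (descending apex
intensity, each min-max normalized to [0,1], zero-padded rows when fewer
than 6 match) form a 6x20 matrix. A 4-branch (1-2-2-1) convolutional
network in the Inception style scores how consistently the six traces
co-elute: branch kernels are 1x1 | 1x1->3x3 | 1x1->5x5 | 3x3-maxpool->1x1
with 16 channels each, concatenated along channels, flattened, passed
through a 512-unit fully connected layer and squashed by a final sigmoid
unit, so the similarity score always lies in [0,1]. Training minimizes
binary cross entropy on groups labeled 1 (fragments of one peptide) or 0
(mixed peptides), using the shared from-scratch Adam optimizer.

A group is accepted when its score strictly exceeds the threshold theta
(default 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _nn
from ._nn import Tensor
from .embed_vae import AdamState, adam_step, normalize_xic

__all__ = [
    "CnnArch", "init_cnn_params", "build_group_matrix", "score_group",
    "bce_loss", "train_classifier", "accept_group",
]

N_ROWS = 6
XIC_LEN = 20


@dataclass(frozen=True)
class CnnArch:
    channels: int = 16
    fc_dim: int = 512
    rows: int = N_ROWS
    cols: int = XIC_LEN

    @property
    def concat_channels(self) -> int:
        return 4 * self.channels

    @property
    def flat_dim(self) -> int:
        return self.concat_channels * self.rows * self.cols


def _init_conv(params, name, c_out, c_in, kh, kw, rng):
    bound = 1.0 / math.sqrt(c_in * kh * kw)
    params[f"{name}.W"] = rng.uniform(-bound, bound, size=(c_out, c_in, kh, kw))
    params[f"{name}.b"] = np.zeros(c_out)


def init_cnn_params(arch: CnnArch = CnnArch(), seed: int = 0) -> Dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    p: Dict[str, np.ndarray] = {}
    c = arch.channels
    _init_conv(p, "b1.c1", c, 1, 1, 1, rng)
    _init_conv(p, "b2.c1", c, 1, 1, 1, rng)
    _init_conv(p, "b2.c2", c, c, 3, 3, rng)
    _init_conv(p, "b3.c1", c, 1, 1, 1, rng)
    _init_conv(p, "b3.c2", c, c, 5, 5, rng)
    _init_conv(p, "b4.c1", c, 1, 1, 1, rng)
    bound = 1.0 / math.sqrt(arch.flat_dim)
    p["fc1.W"] = rng.uniform(-bound, bound, size=(arch.flat_dim, arch.fc_dim))
    p["fc1.b"] = np.zeros(arch.fc_dim)
    bound = 1.0 / math.sqrt(arch.fc_dim)
    p["fc2.W"] = rng.uniform(-bound, bound, size=(arch.fc_dim, 1))
    p["fc2.b"] = np.zeros(1)
    return p


def build_group_matrix(xics: Sequence[np.ndarray]) -> np.ndarray:
    """Top-6 XICs by apex intensity as a 6x20 row-normalized matrix."""
    xics = [np.asarray(x, dtype=float) for x in xics]
    for x in xics:
        if x.shape != (XIC_LEN,):
            raise ValueError(f"XIC must have length {XIC_LEN}")
    order = sorted(range(len(xics)), key=lambda i: -float(xics[i].max()))
    mat = np.zeros((N_ROWS, XIC_LEN))
    for row, i in enumerate(order[:N_ROWS]):
        mat[row] = normalize_xic(xics[i])
    return mat


def _forward(x: Tensor, pt, arch: CnnArch) -> Tensor:
    """x: (N, 1, 6, 20) -> (N,) sigmoid scores."""
    def conv(h, name):
        return _nn.relu(_nn.conv2d_same(h, pt[f"{name}.W"], pt[f"{name}.b"]))
    b1 = conv(x, "b1.c1")
    b2 = conv(conv(x, "b2.c1"), "b2.c2")
    b3 = conv(conv(x, "b3.c1"), "b3.c2")
    b4 = conv(_nn.maxpool3_same(x), "b4.c1")
    for br in (b1, b2, b3, b4):
        assert br.shape[2:] == x.shape[2:], "branch changed spatial dims"
    h = _nn.concat([b1, b2, b3, b4], axis=1)
    n = h.shape[0]
    h = h.reshape(n, arch.flat_dim)
    h = _nn.relu(h @ pt["fc1.W"] + pt["fc1.b"])
    out = _nn.sigmoid(h @ pt["fc2.W"] + pt["fc2.b"])
    return out.reshape(n)


def _as_tensors(params) -> Dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=True) for k, v in params.items()}


def _check_matrix(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[-2:] != (N_ROWS, XIC_LEN):
        raise ValueError(f"group matrix must be {N_ROWS}x{XIC_LEN}, "
                         f"got {matrix.shape}")
    return matrix


def score_group(matrix: np.ndarray, params,
                arch: CnnArch = CnnArch()) -> float:
    """Similarity score in [0,1] of one 6x20 fragment-group matrix."""
    m = _check_matrix(matrix)
    batch = m[None, None] if m.ndim == 2 else m[:, None]
    scores = _forward(Tensor(batch), _as_tensors(params), arch).data
    return float(scores[0]) if m.ndim == 2 else scores


def bce_loss(scores, labels) -> float:
    """Binary cross entropy, mean over the batch; scores clamped to
    [1e-12, 1-1e-12] with a warning at exact 0/1."""
    y = np.atleast_1d(np.asarray(scores, dtype=float))
    t = np.atleast_1d(np.asarray(labels, dtype=float))
    if y.shape != t.shape:
        raise ValueError("scores and labels must align")
    if np.any((y <= 0) | (y >= 1)):
        import warnings
        warnings.warn("scores at 0/1 clamped to 1e-12")
        y = np.clip(y, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(t * np.log(y) + (1 - t) * np.log(1 - y)))


def train_classifier(pairs: Sequence[Tuple[np.ndarray, int]],
                     epochs: int = 5, batch_size: int = 64, seed: int = 0,
                     arch: CnnArch = CnnArch(), eta: float = 0.001,
                     params: Optional[Dict[str, np.ndarray]] = None
                     ) -> Tuple[Dict[str, np.ndarray], List[float]]:
    """Train the CNN on labeled group matrices; returns (params, history)."""
    pairs = list(pairs)
    labels = np.array([int(t) for _, t in pairs], dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training stream must contain both labels")
    x = np.stack([_check_matrix(m) for m, _ in pairs])[:, None]  # (N,1,6,20)
    rng = np.random.default_rng(seed)
    if params is None:
        params = init_cnn_params(arch, seed=seed)
    state = AdamState.init(params, eta=eta)
    history: List[float] = []
    n = len(pairs)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            pt = _as_tensors(params)
            scores = _forward(Tensor(x[idx]), pt, arch)
            t = Tensor(labels[idx])
            loss = -(t * _nn.log(scores)
                     + (1.0 - t) * _nn.log(1.0 - scores)).mean()
            loss.backward()
            grads = {k: tt.grad for k, tt in pt.items() if tt.grad is not None}
            adam_step(params, grads, state)
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return params, history


def accept_group(score: float, theta: float = 0.5) -> bool:
    """Gate: accepted iff score strictly exceeds theta."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    return score > theta
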