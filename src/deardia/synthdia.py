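"""Synthetic SWATH run generator with known ground truth.

Emulates the acquisition geometry of a SWATH experiment — interleaved duty
cycles of one MS1 scan followed by one MS2 scan per isolation window — with
a fully seeded forward model:

* peptides are random tryptic sequences (ending in K/R); precursor and b/y
  fragment m/z come from the same mass arithmetic the search index uses;
* every precursor elutes as a Gaussian in cycle index (sigma 1.5-4 cycles,
  so a full peak fits inside one width-20 slider) and carries a 3-peak
  isotope envelope spaced 1.00335/z Th with averagine-like ratios;
* fragments share the precursor's apex and width (co-elution is the core
  modeling assumption) scaled by log-normal relative intensities, with at
  least 6 fragments per peptide inside the recorded m/z range;
* background noise: per scan, a Poisson number of singleton peaks at
  uniform m/z with log-normal intensities.

Besides full runs the module derives the labeled training objects the two
networks need: triplets (anchor/positive from one peptide, negative from
another) and 6x20 fragment-group matrices labeled same-peptide (1) or
mixed (0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .embed_vae import TripletExample
from .groupscore import build_group_matrix
from .msio import Run, Spectrum
from .pindex import MONO_RESIDUE_MASS, fragment_mzs, precursor_mz
from .preprocess import NEUTRON_SPACING

__all__ = [
    "SimConfig", "GroundTruthPeptide", "simulate_run", "make_triplets",
    "make_training_xics", "make_group_examples", "write_truth_fasta",
]

_AA = "ACDEFGHILMNPQSTVWY"  # K/R only at the C-terminus (tryptic)


@dataclass(frozen=True)
class SimConfig:
    n_peptides: int = 20
    n_cycles: int = 45
    window_scheme: tuple = ((400.0, 600.0), (600.0, 800.0), (800.0, 1000.0))
    ms2_mz_range: tuple = (100.0, 1199.0)
    min_fragments: int = 6
    charges: tuple = (2, 3)
    abundance_range: tuple = (5e3, 5e4)       # apex intensity, log-uniform
    elution_sigma_range: tuple = (1.5, 4.0)   # cycles
    noise_peaks_per_scan: float = 60.0        # Poisson mean
    noise_intensity_mu: float = 3.5           # log-normal of intensities
    noise_intensity_sigma: float = 0.8
    mz_jitter: float = 0.001                  # Th, per-scan peak jitter
    cycle_time: float = 3.3                   # seconds per duty cycle
    seed: int = 0


@dataclass
class GroundTruthPeptide:
    sequence: str
    charge: int
    precursor_mz: float
    fragment_mzs: np.ndarray
    apex_cycle: float
    apex_rt: float
    sigma_cycles: float
    abundance: float
    fragment_rel_intensities: np.ndarray
    window_index: int


def _random_tryptic_sequence(rng: np.random.Generator) -> str:
    n = int(rng.integers(8, 16))
    # no leading P (trypsin cannot cleave K/R-P, so a P-initial peptide
    # could never be released from a protein context)
    first = str(rng.choice([a for a in _AA if a != "P"]))
    body = "".join(rng.choice(list(_AA), size=n - 2))
    return first + body + str(rng.choice(["K", "R"]))


def _isotope_ratios(mass: float) -> np.ndarray:
    """Averagine-flavored 3-peak envelope, normalized to the monoisotope."""
    lam = mass * 4.886e-4
    p = np.array([1.0, lam, lam ** 2 / 2.0]) * math.exp(-lam)
    return p / p[0]


def _covering_window(mz: float, scheme) -> Optional[int]:
    for i, (lo, hi) in enumerate(scheme):
        if lo <= mz < hi:
            return i
    return None


def _draw_peptides(sim: SimConfig, rng: np.random.Generator
                   ) -> List[GroundTruthPeptide]:
    truths: List[GroundTruthPeptide] = []
    seen = set()
    attempts = 0
    lo_rt = 0.55 * 20  # keep the full elution peak inside the cycle range
    while len(truths) < sim.n_peptides and attempts < 200 * sim.n_peptides:
        attempts += 1
        seq = _random_tryptic_sequence(rng)
        if seq in seen:
            continue
        z = int(rng.choice(sim.charges))
        pmz = precursor_mz(seq, z)
        w = _covering_window(pmz, sim.window_scheme)
        if w is None:
            continue
        b, y = fragment_mzs(seq)
        frags = np.sort(np.concatenate([b, y]))
        frags = frags[(frags >= sim.ms2_mz_range[0])
                      & (frags < sim.ms2_mz_range[1])]
        if frags.size < sim.min_fragments:
            continue
        n_frag = min(frags.size, 12)
        chosen = np.sort(rng.choice(frags, size=n_frag, replace=False))
        sigma = float(rng.uniform(*sim.elution_sigma_range))
        apex = float(rng.uniform(lo_rt / 2, sim.n_cycles - lo_rt / 2))
        abundance = float(np.exp(rng.uniform(
            math.log(sim.abundance_range[0]), math.log(sim.abundance_range[1]))))
        rel = np.exp(rng.normal(0.0, 0.6, size=n_frag))
        rel = rel / rel.max()
        seen.add(seq)
        truths.append(GroundTruthPeptide(
            sequence=seq, charge=z, precursor_mz=pmz, fragment_mzs=chosen,
            apex_cycle=apex, apex_rt=apex * sim.cycle_time,
            sigma_cycles=sigma, abundance=abundance,
            fragment_rel_intensities=rel, window_index=w))
    if len(truths) < sim.n_peptides:
        warnings.warn(f"only {len(truths)} of {sim.n_peptides} peptides "
                      "fell inside the window scheme")
    return truths


def _gauss(c: float, apex: float, sigma: float) -> float:
    return math.exp(-0.5 * ((c - apex) / sigma) ** 2)


def _assemble(mzs: List[float], intens: List[float]) -> Tuple[np.ndarray, np.ndarray]:
    mz = np.asarray(mzs, dtype=float)
    it = np.asarray(intens, dtype=float)
    order = np.argsort(mz)
    mz, it = mz[order], it[order]
    # merge exact duplicates to keep m/z strictly increasing
    uniq, inv = np.unique(mz, return_inverse=True)
    summed = np.zeros_like(uniq)
    np.add.at(summed, inv, it)
    return uniq, summed


def simulate_run(sim: SimConfig = SimConfig(),
                 truths: Optional[List[GroundTruthPeptide]] = None
                 ) -> Tuple[Run, List[GroundTruthPeptide]]:
    """Generate a synthetic Run and its ground truth, fully seeded."""
    rng = np.random.default_rng(sim.seed)
    if truths is None:
        truths = _draw_peptides(sim, rng)
    n_win = len(sim.window_scheme)
    scan_dt = sim.cycle_time / (n_win + 1)
    spectra: List[Spectrum] = []
    scan_id = 0
    ms1_range = (min(w[0] for w in sim.window_scheme) - 60.0,
                 max(w[1] for w in sim.window_scheme) + 60.0)
    cutoff = 1e-4  # drop peaks below this fraction of apex amplitude
    for c in range(sim.n_cycles):
        scan_id += 1
        mzs, its = [], []
        for t in truths:
            amp = t.abundance * _gauss(c, t.apex_cycle, t.sigma_cycles)
            if amp < cutoff * t.abundance:
                continue
            ratios = _isotope_ratios((t.precursor_mz - 1.007276) * t.charge)
            for k, r in enumerate(ratios):
                mzs.append(t.precursor_mz + k * NEUTRON_SPACING / t.charge
                           + rng.normal(0, sim.mz_jitter))
                its.append(amp * r)
        n_noise = rng.poisson(sim.noise_peaks_per_scan)
        mzs.extend(rng.uniform(*ms1_range, size=n_noise))
        its.extend(np.exp(rng.normal(sim.noise_intensity_mu,
                                     sim.noise_intensity_sigma, size=n_noise)))
        mz, it = _assemble(mzs, its)
        spectra.append(Spectrum(scan_id=scan_id, ms_level=1,
                                rt=c * sim.cycle_time, mz=mz, intensity=it))
        for w, (lo, hi) in enumerate(sim.window_scheme):
            scan_id += 1
            mzs, its = [], []
            for t in truths:
                if t.window_index != w:
                    continue
                amp = t.abundance * _gauss(c, t.apex_cycle, t.sigma_cycles)
                if amp < cutoff * t.abundance:
                    continue
                for fmz, rel in zip(t.fragment_mzs,
                                    t.fragment_rel_intensities):
                    mzs.append(fmz + rng.normal(0, sim.mz_jitter))
                    its.append(amp * rel * 0.5)
            n_noise = rng.poisson(sim.noise_peaks_per_scan)
            mzs.extend(rng.uniform(*sim.ms2_mz_range, size=n_noise))
            its.extend(np.exp(rng.normal(sim.noise_intensity_mu,
                                         sim.noise_intensity_sigma,
                                         size=n_noise)))
            mz, it = _assemble(mzs, its)
            spectra.append(Spectrum(
                scan_id=scan_id, ms_level=2,
                rt=c * sim.cycle_time + (w + 1) * scan_dt,
                mz=mz, intensity=it, window=(lo, hi)))
    return Run(spectra=spectra,
               window_scheme=[tuple(w) for w in sim.window_scheme]), truths


# ---------------------------------------------------------------------------
# labeled training material


def _noisy_trace(apex, sigma, amplitude, rng, width=20,
                 noise_frac=0.05, baseline=2.0) -> np.ndarray:
    c = np.arange(width, dtype=float)
    y = amplitude * np.exp(-0.5 * ((c - apex) / sigma) ** 2)
    y = y * (1.0 + noise_frac * rng.standard_normal(width)) \
        + baseline * rng.random(width)
    y[y < baseline] = np.where(rng.random((y < baseline).sum()) < 0.5,
                               0.0, y[y < baseline])
    return np.clip(y, 0.0, None)


def make_training_xics(n_peptides: int = 200, fragments_per_peptide: int = 8,
                       width: int = 20, seed: int = 0
                       ) -> Dict[int, List[np.ndarray]]:
    """Labeled fragment XICs from the elution model: peptide id -> XIC list.

    Cheap stand-in for extracting every XIC from a full simulated run; the
    traces follow the same Gaussian co-elution forward model.
    """
    rng = np.random.default_rng(seed)
    out: Dict[int, List[np.ndarray]] = {}
    for p in range(n_peptides):
        apex = rng.uniform(5.0, width - 5.0)
        sigma = rng.uniform(1.5, 4.0)
        amp0 = np.exp(rng.uniform(np.log(5e2), np.log(5e4)))
        out[p] = [_noisy_trace(apex, sigma,
                               amp0 * np.exp(rng.normal(0, 0.6)), rng, width)
                  for _ in range(fragments_per_peptide)]
    return out


def make_triplets(xics_by_peptide: Dict[int, List[np.ndarray]],
                  n: int, seed: int = 0) -> List[TripletExample]:
    """Sample n triplets: anchor/positive share a peptide, negative differs."""
    peptides = [p for p, xs in xics_by_peptide.items() if len(xs) >= 2]
    if len(peptides) < 2:
        raise ValueError("need >= 2 peptides with >= 2 fragments each")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        pa, pn = rng.choice(len(peptides), size=2, replace=False)
        xs = xics_by_peptide[peptides[pa]]
        ia, ip = rng.choice(len(xs), size=2, replace=False)
        xneg = xics_by_peptide[peptides[pn]]
        out.append(TripletExample(
            anchor=np.asarray(xs[ia], dtype=float),
            positive=np.asarray(xs[ip], dtype=float),
            negative=np.asarray(xneg[int(rng.integers(len(xneg)))], dtype=float)))
    return out


def make_group_examples(n: int, seed: int = 0, width: int = 20
                        ) -> List[Tuple[np.ndarray, int]]:
    """Labeled 6x20 matrices: co-eluting (1) vs mixed-peptide (0) groups."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        label = int(i % 2 == 0)
        if label:
            apex, sigma = rng.uniform(4, width - 4), rng.uniform(1.5, 4.0)
            xics = [_noisy_trace(apex, sigma,
                                 np.exp(rng.uniform(np.log(1e3), np.log(3e4))),
                                 rng, width)
                    for _ in range(6)]
        else:
            xics = []
            for _ in range(6):
                apex, sigma = rng.uniform(2, width - 2), rng.uniform(1.0, 5.0)
                xics.append(_noisy_trace(
                    apex, sigma,
                    np.exp(rng.uniform(np.log(1e3), np.log(3e4))), rng, width))
        out.append((build_group_matrix(xics), label))
    return out


def write_truth_fasta(truths: Sequence[GroundTruthPeptide], path,
                      n_decoy_proteins: int = 10, seed: int = 0) -> None:
    """FASTA whose tryptic digest contains every ground-truth peptide.

    Each true peptide is embedded in its own synthetic protein (flanked so
    cleavage reproduces it exactly); decoy proteins of random tryptic
    peptides pad the search space. Synthetic stand-in for a real database.
    """
    rng = np.random.default_rng(seed)
    lines = []
    for i, t in enumerate(truths):
        flank_n = _random_tryptic_sequence(rng)
        flank_c = _random_tryptic_sequence(rng)
        lines.append(f">sp|SYN{i:04d}|TRUE_{t.sequence}")
        lines.append(flank_n + t.sequence + flank_c)
    for d in range(n_decoy_proteins):
        seq = "".join(_random_tryptic_sequence(rng) for _ in range(6))
        lines.append(f">sp|DEC{d:04d}|DECOY_SYNTH")
        lines.append(seq)
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
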