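"""MS1 m/z recalibration against internal calibrants.

Confidently identified precursor-fragment groups supply (observed,
theoretical) m/z pairs; a least-squares curve fit in the sqrt(m) basis
corrects systematic instrument mass drift:

    time of flight:  m' = A*m + B*sqrt(m) + C
    orbitrap:        m' = A*m + B*sqrt(m)

Both models are linear in their coefficients, so the fit is an ordinary
least-squares solve, the post-fit residual RMS (in ppm) never exceeds the
pre-fit RMS, and three non-collinear calibrants determine the tof model
exactly. When too few calibrants pass the confidence filter the identity
calibration is returned and m/z values pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CalibrantSet", "Calibration", "select_calibrants", "fit_calibration",
    "apply_calibration", "identity_calibration",
]


@dataclass
class CalibrantSet:
    """(observed, theoretical) m/z pairs from accepted groups."""
    observed: np.ndarray
    theoretical: np.ndarray

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.theoretical = np.asarray(self.theoretical, dtype=float)
        if self.observed.shape != self.theoretical.shape:
            raise ValueError("observed/theoretical lengths differ")
        if np.any(self.observed <= 0) or np.any(self.theoretical <= 0):
            raise ValueError("m/z values must be positive")

    def __len__(self):
        return self.observed.size


@dataclass
class Calibration:
    instrument_model: str  # "tof" | "orbitrap" | "identity"
    A: float = 1.0
    B: float = 0.0
    C: float = 0.0
    residual_rms_ppm: float = 0.0


def identity_calibration() -> Calibration:
    return Calibration(instrument_model="identity")


def _n_params(model: str) -> int:
    return {"tof": 3, "orbitrap": 2}[model]


def select_calibrants(matches: Sequence, max_expect: float = 0.001,
                      min_hyperscore: float = 0.0) -> CalibrantSet:
    """Filter accepted groups down to calibrant pairs.

    `matches` carry observed_mz, theoretical_mz, a peptide identifier and a
    hyperscore; an optional `expect` attribute (engine-supplied expectation
    value) is screened against max_expect when present. Duplicate peptides
    keep only their best-scoring occurrence.
    """
    best = {}
    for m in matches:
        expect = getattr(m, "expect", None)
        if expect is not None and expect >= max_expect:
            continue
        score = getattr(m, "hyperscore", 0.0)
        if score < min_hyperscore:
            continue
        key = getattr(m, "peptide", None) or getattr(m, "peptide_index")
        if key not in best or score > best[key][0]:
            best[key] = (score, float(m.observed_mz), float(m.theoretical_mz))
    if not best:
        return CalibrantSet(np.empty(0), np.empty(0))
    _, obs, theo = zip(*best.values())
    return CalibrantSet(np.array(obs), np.array(theo))


def fit_calibration(cal: CalibrantSet, model: str = "tof") -> Calibration:
    """Least-squares fit of the drift model on a calibrant set."""
    n_par = _n_params(model)
    if len(cal) < n_par:
        raise ValueError(f"{model} model needs >= {n_par} calibrants, "
                         f"got {len(cal)}")
    m = cal.observed
    cols = [m, np.sqrt(m)] + ([np.ones_like(m)] if model == "tof" else [])
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < n_par:
        raise ValueError("degenerate calibrant design (collinear m/z values)")
    coef, *_ = np.linalg.lstsq(design, cal.theoretical, rcond=None)
    calib = Calibration(instrument_model=model, A=float(coef[0]),
                        B=float(coef[1]),
                        C=float(coef[2]) if model == "tof" else 0.0)
    fitted = apply_calibration(calib, m)
    calib.residual_rms_ppm = float(np.sqrt(np.mean(
        ((fitted - cal.theoretical) / cal.theoretical) ** 2)) * 1e6)
    # least squares: absolute residual RMS cannot exceed the no-fit RMS
    assert (np.mean((fitted - cal.theoretical) ** 2)
            <= np.mean((m - cal.theoretical) ** 2) + 1e-12)
    return calib


def apply_calibration(cal: Calibration, mz):
    """Corrected m/z; the identity calibration passes input through."""
    mz = np.asarray(mz, dtype=float)
    if np.any(mz <= 0):
        raise ValueError("m/z must be positive")
    if cal.instrument_model == "identity":
        out = mz
    else:
        out = cal.A * mz + cal.B * np.sqrt(mz) + cal.C
    return float(out) if out.ndim == 0 else out
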