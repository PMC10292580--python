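"""Slider construction, m/z binning and candidate-ion detection.

Each isolation window's data is cut into fixed-width retention-time sliders
(width 20 cycles, stride 1): the slider is the minimal deconvolution unit,
and 20 is also the length of every extracted ion chromatogram (XIC).
Spectra are binned on a truncated m/z grid (30 bins per Th, max 1200 Th ->
vectors of length 36,000). Candidate precursors come from SNR peak finding
plus deisotoping on the summed MS1 profile; candidate fragments are the MS2
bin traces that pass two sparsity/dynamic-range filters:

* more than 5 nonzero points in the XIC, and
* max / smallest-nonzero ratio larger than 4 (both strict).

Alongside the plain intensity grid the binner accumulates intensity-weighted
m/z, so each candidate ion gets a sub-bin centroid m/z estimate (the bin
center alone is up to ~half a bin off, too coarse for ppm-level matching).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .msio import Run, Spectrum

__all__ = [
    "BinnedSpectrum", "Slider", "CandidatePrecursor", "CandidateFragment",
    "bin_spectrum", "make_sliders", "find_ms1_peaks", "deisotope",
    "extract_xic", "filter_fragment_xics",
    "DEFAULT_WIDTH", "DEFAULT_BINS_PER_MZ", "DEFAULT_MAX_MZ",
    "NEUTRON_SPACING",
]

DEFAULT_WIDTH = 20
DEFAULT_BINS_PER_MZ = 30
DEFAULT_MAX_MZ = 1200.0
NEUTRON_SPACING = 1.00335  # Th, isotope spacing at charge 1


@dataclass
class BinnedSpectrum:
    """Fixed-length intensity vector over the truncated m/z grid.

    `mz_weight[i]` holds sum(intensity * mz) of the peaks in bin i so that
    `mz_weight[i] / values[i]` is the intensity-weighted m/z centroid.
    """
    values: np.ndarray
    bins_per_mz: int = DEFAULT_BINS_PER_MZ
    max_mz: float = DEFAULT_MAX_MZ
    mz_weight: Optional[np.ndarray] = None


@dataclass
class Slider:
    """One isolation window x one RT block of `width` duty cycles."""
    window_index: int
    start: int  # first MS1 cycle index (half-open [start, start+width))
    width: int
    ms1_block: np.ndarray   # (width, n_bins)
    ms2_block: np.ndarray   # (width, n_bins)
    rts: np.ndarray         # (width,) MS1 scan RTs, seconds
    ms1_mzw: Optional[np.ndarray] = None
    ms2_mzw: Optional[np.ndarray] = None

    @property
    def apex_rt(self) -> float:
        """RT of the max-TIC MS1 cycle in the block."""
        return float(self.rts[int(np.argmax(self.ms1_block.sum(axis=1)))])


@dataclass
class CandidatePrecursor:
    bin_index: int
    mz: float       # first (monoisotopic) peak, sub-bin centroid
    charge: int
    xic: np.ndarray
    n_isotopes: int = 2


@dataclass
class CandidateFragment:
    bin_index: int
    mz: float
    xic: np.ndarray


def _bin_count(bins_per_mz: int, max_mz: float) -> int:
    return int(math.ceil(max_mz * bins_per_mz))


def bin_spectrum(spectrum: Spectrum,
                 bins_per_mz: int = DEFAULT_BINS_PER_MZ,
                 max_mz: float = DEFAULT_MAX_MZ) -> BinnedSpectrum:
    """Accumulate peak intensities into bins at floor(mz * bins_per_mz).

    Peaks at or beyond max_mz are dropped with a warning. Starts from the
    zero vector; intensity within a bin adds up.
    """
    if bins_per_mz <= 0 or max_mz <= 0:
        raise ValueError("bins_per_mz and max_mz must be positive")
    n = _bin_count(bins_per_mz, max_mz)
    values = np.zeros(n)
    mzw = np.zeros(n)
    if spectrum.mz.size:
        keep = spectrum.mz < max_mz
        if not keep.all():
            warnings.warn(f"scan {spectrum.scan_id}: "
                          f"{int((~keep).sum())} peaks at m/z >= {max_mz} dropped")
        idx = np.floor(spectrum.mz[keep] * bins_per_mz).astype(int)
        np.add.at(values, idx, spectrum.intensity[keep])
        np.add.at(mzw, idx, spectrum.intensity[keep] * spectrum.mz[keep])
    return BinnedSpectrum(values=values, bins_per_mz=bins_per_mz,
                          max_mz=max_mz, mz_weight=mzw)


def slider_count(n_cycles: int, width: int, stride: int) -> int:
    if n_cycles < width:
        return 0
    return (n_cycles - width) // stride + 1


def make_sliders(run: Run, width: int = DEFAULT_WIDTH, stride: int = 1,
                 bins_per_mz: int = DEFAULT_BINS_PER_MZ,
                 max_mz: float = DEFAULT_MAX_MZ) -> List[Slider]:
    """Cut every isolation window's data into overlapping RT sliders.

    A duty cycle is one MS1 scan plus the MS2 scans that follow it; the
    MS2 block of a slider is drawn from the same cycles as its MS1 block.
    Returns sliders for all windows, ordered by (window_index, start).
    """
    ms1 = run.ms1()
    n_cycles = len(ms1)
    if n_cycles < width:
        warnings.warn(f"run has {n_cycles} cycles < slider width {width}; "
                      "no sliders produced")
        return []
    n_bins = _bin_count(bins_per_mz, max_mz)

    ms1_vals = np.zeros((n_cycles, n_bins))
    ms1_mzw = np.zeros((n_cycles, n_bins))
    rts = np.zeros(n_cycles)
    for c, s in enumerate(ms1):
        b = bin_spectrum(s, bins_per_mz, max_mz)
        ms1_vals[c], ms1_mzw[c] = b.values, b.mz_weight
        rts[c] = s.rt

    # assign each MS2 scan to the duty cycle of the preceding MS1 scan
    ms1_rts = rts
    sliders: List[Slider] = []
    n_sliders = slider_count(n_cycles, width, stride)
    for w_idx in range(len(run.window_scheme)):
        ms2 = run.ms2_for_window(w_idx)
        ms2_vals = np.zeros((n_cycles, n_bins))
        ms2_mzw = np.zeros((n_cycles, n_bins))
        for s in ms2:
            c = int(np.searchsorted(ms1_rts, s.rt, side="right")) - 1
            if c < 0:
                continue
            b = bin_spectrum(s, bins_per_mz, max_mz)
            ms2_vals[c] += b.values
            ms2_mzw[c] += b.mz_weight
        for k in range(n_sliders):
            start = k * stride
            sl = slice(start, start + width)
            sliders.append(Slider(
                window_index=w_idx, start=start, width=width,
                ms1_block=ms1_vals[sl], ms2_block=ms2_vals[sl],
                rts=rts[sl], ms1_mzw=ms1_mzw[sl], ms2_mzw=ms2_mzw[sl]))
    sliders.sort(key=lambda s: (s.window_index, s.start))
    return sliders


def _as_block(block) -> np.ndarray:
    if isinstance(block, np.ndarray):
        return block
    return np.asarray([b.values if isinstance(b, BinnedSpectrum) else b
                       for b in block])


def find_ms1_peaks(ms1_block, snr_min: float = 3.0,
                   baseline_halfwidth: int = 15) -> List[int]:
    """Local maxima of the summed m/z profile with apex/baseline >= snr_min.

    The local baseline is the median of nonzero profile values within
    +-baseline_halfwidth bins of the apex, sampled only at bins that are
    not themselves peaks (raw local maxima and their +-1 neighbors are
    excluded — e.g. a neighboring isotope peak is signal, not baseline).
    An apex with no measurable baseline passes unconditionally.
    """
    block = _as_block(ms1_block)
    if block.size == 0:
        return []
    profile = block.sum(axis=0)
    if not profile.any():
        return []
    padded = np.concatenate([[0.0], profile, [0.0]])
    apexes, _ = find_peaks(padded)
    apexes = apexes - 1
    peakish = np.zeros(profile.size, dtype=bool)
    for d in (-1, 0, 1):
        idx = np.clip(apexes + d, 0, profile.size - 1)
        peakish[idx] = True
    out = []
    for a in apexes:
        lo = max(0, a - baseline_halfwidth)
        hi = min(profile.size, a + baseline_halfwidth + 1)
        neigh = profile[lo:hi][~peakish[lo:hi]]
        nz = neigh[neigh > 0]
        if nz.size == 0 or profile[a] / np.median(nz) >= snr_min:
            out.append(int(a))
    return sorted(out)


def extract_xic(block, bin_index: int) -> np.ndarray:
    """Intensity of one bin across the scans of a block, in RT order."""
    block = _as_block(block)
    if not 0 <= bin_index < block.shape[1]:
        raise IndexError(f"bin {bin_index} outside [0, {block.shape[1]})")
    return block[:, bin_index].copy()


def _centroid_mz(profile_sum, mzw_sum, b: int, bins_per_mz: int) -> float:
    if mzw_sum is not None and profile_sum[b] > 0:
        return float(mzw_sum[b] / profile_sum[b])
    return (b + 0.5) / bins_per_mz


def _xic_correlation(x: np.ndarray, y: np.ndarray,
                     min_overlap: int = 4) -> float:
    """Pearson correlation, guarded against sparse coincidences: traces
    sharing fewer than `min_overlap` nonzero scans score 0."""
    if np.count_nonzero((x > 0) & (y > 0)) < min_overlap:
        return 0.0
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def deisotope(ms1_block, peak_bins: Sequence[int],
              bins_per_mz: int = DEFAULT_BINS_PER_MZ,
              max_charge: int = 5,
              min_corr: float = 0.6,
              max_ratio_step: float = 1.6,
              mzw_block=None) -> List[CandidatePrecursor]:
    """Assign charges to detected MS1 peaks from their isotope envelopes.

    For each peak, charges 1..max_charge are tested for companion peaks at
    +k * 1.00335/z Th. A companion counts when its XIC correlates with the
    apex XIC (Pearson >= min_corr) and the envelope stays plausible (each
    isotope at most max_ratio_step times the previous one). Peaks with at
    least two consecutive isotopes at some charge become candidate
    precursors; the rest are dropped.
    """
    block = _as_block(ms1_block)
    profile = block.sum(axis=0)
    mzw_sum = _as_block(mzw_block).sum(axis=0) if mzw_block is not None else None
    peak_set = set(int(b) for b in peak_bins)
    consumed: set = set()  # bins explained as isotope companions

    def xic3(bb: int) -> np.ndarray:
        # +-1-bin sum: robust to peaks jittering across a bin boundary
        return block[:, max(0, bb - 1):bb + 2].sum(axis=1)

    def prof3(bb: int) -> float:
        return float(profile[max(0, bb - 1):bb + 2].sum())

    out = []
    for b in sorted(peak_set):
        if b in consumed:
            continue
        mz0 = _centroid_mz(profile, mzw_sum, b, bins_per_mz)
        apex_xic = xic3(b)
        best = None  # ((n_isotopes, mean_corr, -z), charge, companion bins)
        for z in range(1, max_charge + 1):
            n_iso, corrs, companions, prev_int = 1, [], [], prof3(b)
            for k in range(1, 4):
                mzk = mz0 + k * NEUTRON_SPACING / z
                bk = int(math.floor(mzk * bins_per_mz))
                if bk + 1 >= profile.size:
                    break
                cand = bk - 1 + int(np.argmax(profile[bk - 1:bk + 2]))
                if profile[cand] <= 0 or prof3(cand) > max_ratio_step * prev_int:
                    break
                c = _xic_correlation(apex_xic, xic3(cand))
                if c < min_corr:
                    break
                n_iso += 1
                corrs.append(c)
                companions.append(cand)
                prev_int = prof3(cand)
            if n_iso >= 2:
                key = (n_iso, float(np.mean(corrs)), -z)
                if best is None or key > best[0]:
                    best = (key, z, companions)
        if best is not None:
            out.append(CandidatePrecursor(
                bin_index=b, mz=mz0, charge=best[1],
                xic=apex_xic.copy(), n_isotopes=best[0][0]))
            consumed.update(best[2])
    return out


def filter_fragment_xics(ms2_block,
                         min_nonzero: int = 5,
                         min_dynamic_ratio: float = 4.0,
                         bins_per_mz: int = DEFAULT_BINS_PER_MZ,
                         mzw_block=None) -> List[CandidateFragment]:
    """Candidate fragments: MS2 bin XICs passing both SNR filters.

    Candidate bins are the local maxima of the summed MS2 profile (adjacent
    bins filled by the same profile peak collapse onto the strongest one).
    A bin XIC is kept iff count_nonzero(xic) > min_nonzero (strict) and
    max(xic) / min(nonzero xic) > min_dynamic_ratio (strict).
    """
    block = _as_block(ms2_block)
    profile = block.sum(axis=0)
    if not profile.any():
        return []
    mzw_sum = _as_block(mzw_block).sum(axis=0) if mzw_block is not None else None
    padded = np.concatenate([[0.0], profile, [0.0]])
    apexes, _ = find_peaks(padded)
    out = []
    for a in apexes:
        b = int(a) - 1
        xic = block[:, b]
        nz = xic[xic > 0]
        if nz.size <= min_nonzero:
            continue
        if nz.max() / nz.min() <= min_dynamic_ratio:
            continue
        out.append(CandidateFragment(
            bin_index=b, mz=_centroid_mz(profile, mzw_sum, b, bins_per_mz),
            xic=xic.copy()))
    return out
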