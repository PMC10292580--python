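"""End-to-end orchestration: run -> sliders -> embeddings -> clusters ->
peptide matches -> CNN gate -> recalibration -> pseudo-tandem MGF.

Per slider the two-stage procedure runs: (1) embed the candidate fragment
XICs, k-means them into k = #candidate-precursors classes, assign each
cluster a peptide via the inverted index + hyperscore, gate the top match
with the co-elution CNN; (2) remove the fragments of accepted groups,
re-cluster the remainder with k2 = #unmatched-precursors and repeat the
matching/gating once. Accepted groups from overlapping sliders (stride 1
makes one elution appear in ~width consecutive sliders) are merged when
they share a peptide index and their apex RTs lie within width/2 cycles,
keeping the highest hyperscore. Finally all accepted groups supply
internal calibrants, the fitted curve recalibrates every precursor m/z,
and one MGF entry is written per surviving group.

Everything is deterministic given the config seed; sliders are independent
work units merged in (window, slider) order.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import cluster as _cluster
from . import embed_vae, groupscore, msio, pindex, preprocess, recal

logger = logging.getLogger("deardia")

__all__ = ["PipelineConfig", "AcceptedGroup", "SliderResult",
           "process_slider", "run_pipeline", "detect_precursors"]


@dataclass
class PipelineConfig:
    """Run-level and per-module settings (defaults match the method)."""
    input_path: Optional[str] = None
    fasta_path: Optional[str] = None
    output_path: Optional[str] = None
    run_name: str = "run"
    seed: int = 0
    # slider / binning
    slider_width: int = preprocess.DEFAULT_WIDTH
    slider_stride: int = 1
    bins_per_mz: int = preprocess.DEFAULT_BINS_PER_MZ
    max_mz: float = preprocess.DEFAULT_MAX_MZ
    # candidate filters
    snr_min: float = 3.0
    min_nonzero: int = 5
    min_dynamic_ratio: float = 4.0
    max_charge: int = 5
    # matching
    precursor_tol_ppm: float = 20.0
    fragment_tol_mz: float = 0.03
    # gate
    theta: float = 0.5
    # recalibration
    recal_model: str = "tof"
    recal_min_calibrants: int = 5
    recal_min_hyperscore: float = 0.0

    def validate(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0,1]")
        if self.slider_width < 1 or self.slider_stride < 1:
            raise ValueError("slider width/stride must be >= 1")
        return self


@dataclass
class AcceptedGroup:
    peptide_index: int
    peptide: str
    charge: int
    observed_mz: float
    theoretical_mz: float
    hyperscore: float
    cnn_score: float
    apex_rt: float
    window_index: int
    slider_start: int
    fragments: list  # (mz, apex intensity)


@dataclass
class SliderResult:
    window_index: int
    slider_start: int
    n_candidate_fragments: int = 0
    n_clusters: int = 0
    accepted: List[AcceptedGroup] = field(default_factory=list)
    unassigned_clusters: int = 0


def detect_precursors(slider: preprocess.Slider, cfg: PipelineConfig,
                      window: Tuple[float, float]
                      ) -> List[preprocess.CandidatePrecursor]:
    """Candidate precursors of one slider restricted to one window."""
    peaks = preprocess.find_ms1_peaks(slider.ms1_block, snr_min=cfg.snr_min)
    cands = preprocess.deisotope(
        slider.ms1_block, peaks, bins_per_mz=cfg.bins_per_mz,
        max_charge=cfg.max_charge, mzw_block=slider.ms1_mzw)
    lo, hi = window
    return [c for c in cands if lo <= c.mz < hi]


def _match_stage(assignment, fragments, precursors, matched_precursors,
                 index, cnn_params, cfg, accepted_fragids, slider, result,
                 frag_ids=None):
    """One clustering stage: try to assign each cluster to a precursor."""
    ids = frag_ids if frag_ids is not None else np.arange(len(fragments))
    for c in range(assignment.centroids.shape[0]):
        member_ids = assignment.members(c)
        if member_ids.size == 0:
            continue
        cluster_frags = [fragments[i] for i in member_ids]
        best = None  # (hyperscore, match, precursor)
        for pi, prec in enumerate(precursors):
            if pi in matched_precursors:
                continue
            matches = index.match_cluster(prec, cluster_frags)
            if matches and (best is None
                            or matches[0].hyperscore > best[0]):
                best = (matches[0].hyperscore, matches[0], pi)
        if best is None:
            result.unassigned_clusters += 1
            continue
        _, match, pi = best
        prec = precursors[pi]
        matched_local = [member_ids[j] for j in match.matched_fragment_ids]
        top = sorted(matched_local,
                     key=lambda i: -float(fragments[i].xic.max()))[:6]
        matrix = groupscore.build_group_matrix(
            [fragments[i].xic for i in top])
        score = groupscore.score_group(matrix, cnn_params)
        if not groupscore.accept_group(score, cfg.theta):
            result.unassigned_clusters += 1
            continue
        entry = index.entries[match.peptide_index]
        apex_scan = int(np.argmax(prec.xic))
        result.accepted.append(AcceptedGroup(
            peptide_index=match.peptide_index, peptide=entry.sequence,
            charge=entry.precursor_charge, observed_mz=prec.mz,
            theoretical_mz=entry.precursor_mz,
            hyperscore=match.hyperscore, cnn_score=float(score),
            apex_rt=float(slider.rts[apex_scan]),
            window_index=slider.window_index, slider_start=slider.start,
            fragments=[(fragments[i].mz, float(fragments[i].xic.max()))
                       for i in matched_local]))
        matched_precursors.add(pi)
        accepted_fragids.update(int(i) for i in matched_local)


def process_slider(slider: preprocess.Slider,
                   precursors: Sequence[preprocess.CandidatePrecursor],
                   vae_params, cnn_params, index: pindex.PeptideIndex,
                   cfg: PipelineConfig) -> SliderResult:
    """Two-stage deconvolution of one slider; deterministic given cfg.seed."""
    result = SliderResult(window_index=slider.window_index,
                          slider_start=slider.start)
    fragments = preprocess.filter_fragment_xics(
        slider.ms2_block, min_nonzero=cfg.min_nonzero,
        min_dynamic_ratio=cfg.min_dynamic_ratio,
        bins_per_mz=cfg.bins_per_mz, mzw_block=slider.ms2_mzw)
    result.n_candidate_fragments = len(fragments)
    if not fragments or not precursors:
        return result
    embeddings = embed_vae.embed_xics([f.xic for f in fragments], vae_params)
    km_seed = (cfg.seed * 100003 + slider.window_index * 1009
               + slider.start) % (2 ** 31)
    matched_precursors: Set[int] = set()
    accepted_fragids: Set[int] = set()

    k1 = int(min(max(len(precursors), 1), len(fragments)))
    first = _cluster.kmeans_cluster(embeddings, k1, seed=km_seed)
    result.n_clusters += k1
    _match_stage(first, fragments, precursors, matched_precursors, index,
                 cnn_params, cfg, accepted_fragids, slider, result)

    remaining_prec = len(precursors) - len(matched_precursors)
    n_left = len(fragments) - len(accepted_fragids)
    if remaining_prec > 0 and n_left > 0:
        second = _cluster.second_pass_cluster(
            embeddings, first, accepted_fragids,
            k2=remaining_prec, seed=km_seed + 1)
        result.n_clusters += second.centroids.shape[0]
        _match_stage(second, fragments, precursors, matched_precursors,
                     index, cnn_params, cfg, accepted_fragids, slider, result)

    # pipeline count invariants
    assert len(result.accepted) <= result.n_clusters <= 2 * len(fragments)
    seen: Set[int] = set()
    for g in result.accepted:
        assert g.cnn_score > cfg.theta and g.fragments
    return result


def _merge_groups(groups: List[AcceptedGroup], cfg: PipelineConfig,
                  cycle_time: float) -> List[AcceptedGroup]:
    """Merge duplicates of one elution across overlapping sliders."""
    rt_window = cfg.slider_width / 2.0 * cycle_time
    by_peptide: Dict[int, List[AcceptedGroup]] = {}
    for g in sorted(groups, key=lambda g: (g.peptide_index, g.apex_rt)):
        bucket = by_peptide.setdefault(g.peptide_index, [])
        for kept in bucket:
            if abs(kept.apex_rt - g.apex_rt) <= rt_window:
                if g.hyperscore > kept.hyperscore:
                    kept_idx = bucket.index(kept)
                    bucket[kept_idx] = g
                break
        else:
            bucket.append(g)
    merged = [g for b in by_peptide.values() for g in b]
    merged.sort(key=lambda g: (g.window_index, g.slider_start,
                               g.peptide_index))
    return merged


def run_pipeline(cfg: PipelineConfig, vae_params, cnn_params,
                 index: pindex.PeptideIndex,
                 run: Optional[msio.Run] = None) -> dict:
    """Process a full run into an MGF file; returns the run report."""
    cfg.validate()
    if run is None:
        run = msio.read_run(cfg.input_path)
    report = {"n_spectra": len(run.spectra),
              "n_windows": len(run.window_scheme),
              "per_stage": {"sliders": 0, "candidate_fragments": 0,
                            "clusters": 0, "accepted_groups": 0},
              "calibration": None, "n_pseudo_spectra": 0}
    sliders = preprocess.make_sliders(
        run, width=cfg.slider_width, stride=cfg.slider_stride,
        bins_per_mz=cfg.bins_per_mz, max_mz=cfg.max_mz)
    if not sliders:
        warnings.warn("empty run: no sliders; writing no spectra")
        if cfg.output_path:
            Path(cfg.output_path).write_text("")
        return report
    ms1_rts = [s.rt for s in run.ms1()]
    cycle_time = float(np.median(np.diff(ms1_rts))) if len(ms1_rts) > 1 else 1.0

    # precursor detection depends only on the MS1 block -> cache per start
    prec_cache: Dict[int, list] = {}
    results: List[SliderResult] = []
    for slider in sliders:
        if slider.start not in prec_cache:
            peaks = preprocess.find_ms1_peaks(slider.ms1_block,
                                              snr_min=cfg.snr_min)
            prec_cache[slider.start] = preprocess.deisotope(
                slider.ms1_block, peaks, bins_per_mz=cfg.bins_per_mz,
                max_charge=cfg.max_charge, mzw_block=slider.ms1_mzw)
        lo, hi = run.window_scheme[slider.window_index]
        precursors = [c for c in prec_cache[slider.start] if lo <= c.mz < hi]
        res = process_slider(slider, precursors, vae_params, cnn_params,
                             index, cfg)
        results.append(res)
        report["per_stage"]["sliders"] += 1
        report["per_stage"]["candidate_fragments"] += res.n_candidate_fragments
        report["per_stage"]["clusters"] += res.n_clusters
    all_groups = [g for r in results for g in r.accepted]
    merged = _merge_groups(all_groups, cfg, cycle_time)
    report["per_stage"]["accepted_groups"] = len(merged)

    # recalibration from the accepted groups
    class _Cal:  # calibrant view of an accepted group
        def __init__(self, g):
            self.peptide = (g.peptide_index,)
            self.hyperscore = g.hyperscore
            self.observed_mz = g.observed_mz
            self.theoretical_mz = g.theoretical_mz
    cal_set = recal.select_calibrants(
        [_Cal(g) for g in merged], min_hyperscore=cfg.recal_min_hyperscore)
    n_par = 3 if cfg.recal_model == "tof" else 2
    if len(cal_set) >= max(cfg.recal_min_calibrants, n_par):
        try:
            calibration = recal.fit_calibration(cal_set, model=cfg.recal_model)
        except ValueError as e:
            warnings.warn(f"recalibration skipped: {e}")
            calibration = recal.identity_calibration()
    else:
        warnings.warn("too few calibrants; identity calibration used")
        calibration = recal.identity_calibration()
    report["calibration"] = {
        "model": calibration.instrument_model, "A": calibration.A,
        "B": calibration.B, "C": calibration.C,
        "residual_rms_ppm": calibration.residual_rms_ppm,
        "n_calibrants": len(cal_set)}

    pseudo = []
    for rank, g in enumerate(merged):
        mz_cal = float(recal.apply_calibration(calibration, g.observed_mz))
        pseudo.append(msio.PseudoSpectrum(
            precursor_mz=mz_cal, charge=g.charge, rt=g.apex_rt,
            fragments=sorted(g.fragments),
            title=f"{cfg.run_name}.{g.window_index}.{g.slider_start}.{rank}"))
    report["n_pseudo_spectra"] = len(pseudo)
    if cfg.output_path:
        if pseudo:
            msio.write_mgf(pseudo, cfg.output_path)
        else:
            warnings.warn("no accepted groups; writing empty MGF")
            Path(cfg.output_path).write_text("")
    report["pseudo_spectra"] = pseudo
    logger.info("pipeline: %s", json.dumps(
        {k: v for k, v in report.items() if k != "pseudo_spectra"}))
    return report
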