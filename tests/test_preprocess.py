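"""Binning, sliders, peak finding, deisotoping and fragment filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deardia import preprocess, synthdia
from deardia.msio import Run, Spectrum
from deardia.preprocess import (
    NEUTRON_SPACING, bin_spectrum, deisotope, extract_xic,
    filter_fragment_xics, find_ms1_peaks, make_sliders, slider_count,
)


def _ms1(scan_id, rt, mz, inten):
    return Spectrum(scan_id, 1, rt=rt, mz=np.asarray(mz, float),
                    intensity=np.asarray(inten, float))


class TestBinning:
    def test_vector_length_is_36000_at_defaults(self):
        b = bin_spectrum(_ms1(1, 0.0, [500.0], [1.0]))
        assert b.values.size == 36000

    def test_empty_peak_list_gives_zero_vector(self):
        b = bin_spectrum(_ms1(1, 0.0, [], []))
        assert not b.values.any()

    def test_nearby_peaks_accumulate_in_one_bin(self):
        b = bin_spectrum(_ms1(1, 0.0, [100.005, 100.015], [10.0, 5.0]))
        assert b.values[3000] == pytest.approx(15.0)
        assert np.count_nonzero(b.values) == 1

    def test_out_of_range_peaks_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            b = bin_spectrum(_ms1(1, 0.0, [100.0, 1500.0], [1.0, 2.0]))
        assert b.values.sum() == pytest.approx(1.0)

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError):
            bin_spectrum(_ms1(1, 0.0, [100.0], [1.0]), bins_per_mz=0)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.tuples(st.floats(50, 1199.9), st.floats(0.1, 1e5)),
                    min_size=1, max_size=40))
    def test_binning_conserves_in_range_intensity(self, peaks):
        mz = np.sort(np.unique([p[0] for p in peaks]))
        inten = np.array([p[1] for p in peaks[:len(mz)]])
        b = bin_spectrum(_ms1(1, 0.0, mz, inten))
        assert b.values.sum() == pytest.approx(inten.sum(), rel=1e-9)


def _synthetic_run(n_cycles, n_windows=1):
    scheme = [(400.0 + 100 * i, 500.0 + 100 * i) for i in range(n_windows)]
    spectra = []
    sid = 0
    for c in range(n_cycles):
        sid += 1
        spectra.append(_ms1(sid, c * 3.0, [450.0], [1.0]))
        for w, win in enumerate(scheme):
            sid += 1
            spectra.append(Spectrum(sid, 2, rt=c * 3.0 + 0.3 * (w + 1),
                                    mz=np.array([200.0]),
                                    intensity=np.array([1.0]), window=win))
    return Run(spectra=spectra, window_scheme=scheme)


class TestSliders:
    @pytest.mark.parametrize("n_cycles,expected", [(25, 6), (20, 1)])
    def test_slider_arithmetic(self, n_cycles, expected):
        sliders = make_sliders(_synthetic_run(n_cycles))
        assert len(sliders) == expected

    def test_hundred_cycles_three_windows_counting_oracle(self):
        run = _synthetic_run(100, n_windows=3)
        sliders = make_sliders(run)
        # brute-force enumeration of all window starts
        expected = [(w, s) for w in range(3) for s in range(0, 81)]
        got = [(s.window_index, s.start) for s in sliders]
        assert sorted(got) == sorted(expected)
        assert len(sliders) == 81 * 3

    def test_too_few_cycles_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert make_sliders(_synthetic_run(5)) == []

    @settings(deadline=None, max_examples=50)
    @given(st.integers(1, 60), st.integers(1, 60), st.integers(1, 5))
    def test_count_formula(self, n_cycles, width, stride):
        expected = (0 if n_cycles < width
                    else (n_cycles - width) // stride + 1)
        assert slider_count(n_cycles, width, stride) == expected

    def test_ms2_block_from_same_cycles(self):
        sliders = make_sliders(_synthetic_run(25))
        for sl in sliders:
            assert sl.ms1_block.shape == sl.ms2_block.shape == (20, 36000)


class TestFindMs1Peaks:
    def test_single_gaussian_over_flat_baseline(self):
        profile = np.ones(200)
        profile[95:106] += 100 * np.exp(-0.5 * ((np.arange(95, 106) - 100) / 2) ** 2)
        block = profile[None, :]
        peaks = find_ms1_peaks(block, snr_min=3)
        assert peaks == [100]

    def test_flat_spectrum_has_no_peaks(self):
        assert find_ms1_peaks(np.ones((4, 100)), snr_min=3) == []

    def test_snr_threshold_vs_brute_force(self):
        # peaks with SNR 10 and 2 over baseline 1; threshold 4 keeps only one
        profile = np.ones(300)
        profile[100] = 10.0
        profile[200] = 2.0
        peaks = find_ms1_peaks(profile[None, :], snr_min=4)
        # brute-force oracle: all strict local maxima with apex/median >= 4
        brute = [i for i in range(1, 299)
                 if profile[i] > profile[i - 1] and profile[i] > profile[i + 1]
                 and profile[i] / 1.0 >= 4]
        assert peaks == brute == [100]

    def test_all_zero_block_empty(self):
        assert find_ms1_peaks(np.zeros((3, 50))) == []


class TestExtractXic:
    def test_constant_bin(self):
        block = np.zeros((20, 100))
        block[:, 7] = 5.0
        np.testing.assert_array_equal(extract_xic(block, 7), np.full(20, 5.0))

    def test_absent_bin_is_zero_vector(self):
        assert not extract_xic(np.zeros((20, 100)), 3).any()

    def test_out_of_range_bin_raises(self):
        with pytest.raises(IndexError):
            extract_xic(np.zeros((20, 10)), 10)


def _envelope_block(mz0, charge, ratios, apex=10.0, sigma=2.5,
                    amplitude=1000.0, width=20, bins_per_mz=30):
    """Isotope envelope on a shared Gaussian elution, plus flat noise floor."""
    n_bins = 36000
    block = np.zeros((width, n_bins))
    profile = amplitude * np.exp(-0.5 * ((np.arange(width) - apex) / sigma) ** 2)
    for k, r in enumerate(ratios):
        b = int(np.floor((mz0 + k * NEUTRON_SPACING / charge) * bins_per_mz))
        block[:, b] += r * profile
    return block


class TestDeisotope:
    def test_doubly_charged_envelope(self):
        block = _envelope_block(550.25, 2, [1.0, 0.8, 0.3])
        peaks = find_ms1_peaks(block, snr_min=3)
        cands = deisotope(block, peaks)
        assert len(cands) == 1
        assert cands[0].charge == 2
        assert cands[0].mz == pytest.approx(550.25, abs=1 / 30)

    def test_isolated_peak_is_dropped(self):
        block = _envelope_block(550.25, 2, [1.0])  # no isotope partner
        peaks = find_ms1_peaks(block, snr_min=3)
        assert deisotope(block, peaks) == []

    def test_overlapping_charge_states_resolved(self):
        block = (_envelope_block(550.25, 2, [1.0, 0.8, 0.3])
                 + _envelope_block(700.40, 1, [1.0, 0.5]))
        peaks = find_ms1_peaks(block, snr_min=3)
        cands = deisotope(block, peaks)
        got = sorted((round(c.mz, 1), c.charge) for c in cands)
        assert got == [(550.2, 2), (700.4, 1)]

    def test_generator_recovery_at_high_snr(self, small_run):
        """>= 90% of injected precursors recover charge at SNR >= 10."""
        run, truths, sim = small_run
        sliders = preprocess.make_sliders(run)
        hits = 0
        for t in truths:
            start = int(max(0, min(sim.n_cycles - 20,
                                   round(t.apex_cycle) - 10)))
            sl = next(s for s in sliders
                      if s.window_index == t.window_index and s.start == start)
            peaks = find_ms1_peaks(sl.ms1_block, snr_min=3)
            cands = deisotope(sl.ms1_block, peaks, mzw_block=sl.ms1_mzw)
            hits += any(abs(c.mz - t.precursor_mz) < 0.02
                        and c.charge == t.charge for c in cands)
        assert hits / len(truths) >= 0.9


class TestFragmentFilters:
    def _block_with_xic(self, xic, bin_index=3000, width=20):
        block = np.zeros((width, 36000))
        block[:len(xic), bin_index] = xic
        return block

    def test_five_nonzero_points_rejected(self):
        xic = np.zeros(20)
        xic[:5] = [10, 20, 100, 20, 10]  # exactly 5 nonzero: not > 5
        assert filter_fragment_xics(self._block_with_xic(xic)) == []

    def test_dynamic_ratio_exactly_four_rejected(self):
        xic = np.zeros(20)
        xic[:8] = [2, 4, 8, 8, 8, 4, 2, 2]  # max/min = 4: not > 4
        assert filter_fragment_xics(self._block_with_xic(xic)) == []

    def test_good_xic_kept(self):
        xic = np.zeros(20)
        xic[:10] = [1, 5, 20, 60, 100, 80, 40, 10, 3, 1]
        out = filter_fragment_xics(self._block_with_xic(xic))
        assert len(out) == 1
        assert out[0].bin_index == 3000
        np.testing.assert_array_equal(out[0].xic, xic)

    def test_every_candidate_satisfies_predicates(self, small_run):
        run, _, _ = small_run
        sliders = preprocess.make_sliders(run)
        checked = 0
        for sl in sliders[::7]:
            for f in filter_fragment_xics(sl.ms2_block, mzw_block=sl.ms2_mzw):
                nz = f.xic[f.xic > 0]
                assert nz.size > 5
                assert nz.max() / nz.min() > 4
                checked += 1
        assert checked > 0
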