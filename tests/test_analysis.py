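"""Spectral summaries, state classification, sweeps, and the eta metric."""

import numpy as np
import pytest

from thalcort.analysis import (
    FiringState,
    ParameterPlaneMap,
    classify_state,
    default_saturation_threshold,
    spectral_summary,
    stable_extrema,
    swd_reduction,
    sweep_parameter,
    sweep_plane,
)
from thalcort.model import ModelParameters
from thalcort.simulate import SimulationConfig, cortical_mean, integrate

FS = 1000.0


def _sine(freq, duration=20.0, mean=0.0, amp=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return mean + amp * np.sin(2 * np.pi * freq * t)


class TestSpectralSummary:
    def test_pure_sinusoid_frequency_recovered(self):
        spec = spectral_summary(_sine(3.0), FS, discard=5.0)
        assert spec.dominant_frequency == pytest.approx(3.0, abs=0.05)

    def test_constant_series_reports_zero(self):
        spec = spectral_summary(np.full(20000, 1.3), FS, discard=5.0)
        assert spec.dominant_frequency == 0.0
        assert spec.amplitude == 0.0

    def test_random_frequencies_within_one_bin(self, rng):
        for freq in rng.uniform(0.5, 20.0, 20):
            spec = spectral_summary(_sine(freq), FS, discard=2.0)
            assert spec.dominant_frequency == pytest.approx(freq, abs=0.06)

    def test_power_normalized_to_unit_maximum(self):
        spec = spectral_summary(_sine(4.0), FS, discard=2.0)
        assert spec.power.max() == pytest.approx(1.0)
        assert np.all(spec.power >= 0.0)

    def test_swd_simulation_in_absence_band(self, swd_cortical_mean):
        spec = spectral_summary(swd_cortical_mean, FS, discard=5.0)
        assert 2.0 <= spec.dominant_frequency <= 4.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            spectral_summary(np.zeros(1000), FS, discard=0.0)


class TestStableExtrema:
    def test_constant_gives_singleton(self):
        ext = stable_extrema(np.full(20000, 0.7), FS, discard=2.0)
        np.testing.assert_allclose(ext, [0.7])

    def test_sinusoid_gives_two_values(self):
        ext = stable_extrema(_sine(3.0, mean=0.2, amp=0.5), FS, discard=2.0)
        assert len(ext) == 2
        np.testing.assert_allclose(ext, [-0.3, 0.7], atol=1e-4)

    def test_swd_waveform_has_spike_and_wave_extrema(self, swd_cortical_mean):
        # spike + wave per cycle: at least 4 distinct extrema values
        ext = stable_extrema(swd_cortical_mean, FS, discard=5.0)
        assert len(ext) >= 4


class TestClassifyState:
    @pytest.mark.parametrize("C7,C11,expected", [
        (6.0, 0.1, FiringState.HIGH_SATURATED),
        (1.0, 0.1, FiringState.LOW_SATURATED),
        (2.0, 0.1, FiringState.SWD),
        (0.02, 0.1, FiringState.TONIC),
        (2.0, 1.0, FiringState.CLONIC_LOW),
        (1.0, 1.0, FiringState.CLONIC_HIGH),
    ])
    def test_canonical_regimes(self, C7, C11, expected):
        cfg = SimulationConfig(params=ModelParameters(C7=C7, C11=C11))
        cm = cortical_mean(integrate(cfg))
        rep = classify_state(cm, FS, discard=5.0)
        assert rep.label is expected

    def test_saturated_labels_report_zero_frequency(self):
        thr = default_saturation_threshold()
        for level, label in ((thr + 1.0, FiringState.HIGH_SATURATED),
                             (thr - 1.0, FiringState.LOW_SATURATED)):
            rep = classify_state(np.full(20000, level), FS, discard=2.0)
            assert rep.label is label
            assert rep.dominant_frequency == 0.0

    def test_constant_series_never_oscillatory(self, rng):
        for level in rng.uniform(-2, 2, 5):
            rep = classify_state(np.full(20000, level), FS, discard=2.0)
            assert not rep.label.oscillatory

    def test_bands_partition_oscillatory_labels(self, rng):
        # every oscillatory report falls in exactly one of III-VI
        for freq in rng.uniform(0.5, 20.0, 15):
            rep = classify_state(_sine(freq, amp=0.5), FS, discard=2.0)
            assert rep.label.oscillatory
            if rep.dominant_frequency > 10.0:
                assert rep.label is FiringState.TONIC
            elif rep.dominant_frequency >= 5.0:
                assert rep.label is FiringState.CLONIC_HIGH
            else:
                # single-peak sinusoid: low band classifies as clonic
                assert rep.label is FiringState.CLONIC_LOW

    def test_classification_stationary_under_extra_discard(self, swd_cortical_mean):
        a = classify_state(swd_cortical_mean, FS, discard=5.0)
        b = classify_state(swd_cortical_mean, FS, discard=6.0)
        assert a.label is b.label


class TestSweeps:
    def test_single_value_sweep_equals_direct_classification(self):
        params = ModelParameters(C11=0.1)
        scan = sweep_parameter("C7", [2.0], params)
        cfg = SimulationConfig(params=params.replace(C7=2.0))
        rep = classify_state(cortical_mean(integrate(cfg)), FS, discard=5.0)
        assert scan.reports[0].label is rep.label
        assert scan.reports[0].dominant_frequency == pytest.approx(
            rep.dominant_frequency)

    def test_oscillation_region_boundary_near_printed_window(self):
        # below the first Hopf point the zero state reaches the tonic
        # cycle; above it (clear of the slow near-Hopf transients) it rests
        scan = sweep_parameter("C7", [0.18, 0.6], ModelParameters(C11=0.1))
        assert scan.reports[0].label.oscillatory
        assert not scan.reports[1].label.oscillatory

    def test_oscillation_ceases_above_offset(self):
        scan = sweep_parameter("C7", [4.9, 5.4], ModelParameters(C11=0.1))
        assert scan.reports[0].label.oscillatory
        assert scan.reports[1].label is FiringState.HIGH_SATURATED

    def test_one_by_one_plane_matches_classify(self):
        pm = sweep_plane("C7", [2.0], "C11", [0.1])
        assert pm.labels[0, 0] is FiringState.SWD

    def test_plane_frequency_zero_iff_saturated(self):
        pm = sweep_plane("C7", [1.0, 2.0, 6.0], "C11", [0.1, 1.0])
        sat = np.isin(pm.labels, [FiringState.HIGH_SATURATED,
                                  FiringState.LOW_SATURATED])
        assert np.all((pm.frequencies == 0.0) == sat)

    def test_plane_order_independence(self):
        # transposing the axes transposes the matrices (order-free contract)
        a = sweep_plane("C7", [1.0, 2.0], "C11", [0.1, 1.0])
        b = sweep_plane("C11", [0.1, 1.0], "C7", [1.0, 2.0])
        assert np.array_equal(a.labels, b.labels.T)
        np.testing.assert_allclose(a.frequencies, b.frequencies.T)

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError):
            sweep_parameter("C99", [1.0])


def _plane_of(labels):
    labels = np.asarray(labels, dtype=object)
    return ParameterPlaneMap("C7", np.arange(labels.shape[0], dtype=float),
                             "C11", np.arange(labels.shape[1], dtype=float),
                             labels, np.zeros(labels.shape))


class TestSwdReduction:
    def test_identical_maps_give_zero(self):
        m = _plane_of([[FiringState.SWD, FiringState.TONIC]])
        assert swd_reduction(m, m).eta == 0.0

    def test_full_clearance_gives_one(self):
        before = _plane_of([[FiringState.SWD, FiringState.SWD]])
        after = _plane_of([[FiringState.LOW_SATURATED, FiringState.TONIC]])
        assert swd_reduction(before, after).eta == 1.0

    def test_partial_reduction_arithmetic(self):
        before = _plane_of([[FiringState.SWD] * 10] * 10)
        labels = np.full((10, 10), FiringState.SWD, dtype=object)
        labels.flat[:13] = FiringState.LOW_SATURATED  # 87 SWD remain
        after = _plane_of(labels)
        assert swd_reduction(before, after).eta == pytest.approx(0.13)

    def test_invariant_to_non_swd_relabelling(self):
        before = _plane_of([[FiringState.SWD, FiringState.TONIC,
                             FiringState.CLONIC_LOW]])
        after1 = _plane_of([[FiringState.SWD, FiringState.CLONIC_HIGH,
                             FiringState.LOW_SATURATED]])
        after2 = _plane_of([[FiringState.SWD, FiringState.HIGH_SATURATED,
                             FiringState.TONIC]])
        assert swd_reduction(before, after1).eta == swd_reduction(
            before, after2).eta

    def test_no_swd_reference_rejected(self):
        m = _plane_of([[FiringState.TONIC]])
        with pytest.raises(ValueError):
            swd_reduction(m, m)

    def test_mismatched_grids_rejected(self):
        a = _plane_of([[FiringState.SWD]])
        b = _plane_of([[FiringState.SWD, FiringState.SWD]])
        with pytest.raises(ValueError):
            swd_reduction(a, b)
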