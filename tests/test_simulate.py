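import numpy as np
import pytest
import scipy.signal as sig

from sensomap.connectivity import ALPHA
from sensomap.containers import SourceTimeCourses
from sensomap.simulate import (ONE_POINT, TWO_POINT, SimulationConfig,
                               draw_cohort_truths, envelope_weights,
                               mix_to_sensors, sef_waveform,
                               simulate_behavior, simulate_cohort,
                               simulate_evoked_trials, simulate_source_rest,
                               subject_rng)


def _rest_cfg(mesh162, rho, seed=0, dur=60.0, **kw):
    return SimulationConfig(sfreq=250.0, rest_duration=dur, bands=(ALPHA,),
                            seed_vertex=5, target_vertices=(100,),
                            planted_env_corr=rho, rng_seed=seed, **kw)


def _env_corr(src: SourceTimeCourses, a=5, b=100, band=None):
    x = src.data[[a, b]]
    if band is not None:
        from sensomap.connectivity import fir_band_filter
        x = fir_band_filter(x, band, src.sfreq)
    env = np.abs(sig.hilbert(x, axis=-1))[:, 300:-300]
    return np.corrcoef(env)[0, 1]


class TestConfigValidation:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError, match="sfreq"):
            SimulationConfig(sfreq=-1)
        with pytest.raises(ValueError, match="env_corr"):
            SimulationConfig(planted_env_corr=1.5)
        with pytest.raises(ValueError, match="gating"):
            SimulationConfig(planted_gating={"N20m": -0.1})
        with pytest.raises(ValueError, match="degenerate"):
            SimulationConfig(seed_vertex=3, target_vertices=(3,))

    def test_vertex_range_check(self, mesh162):
        cfg = SimulationConfig(seed_vertex=1000)
        with pytest.raises(ValueError, match="out of range"):
            cfg.validate_vertices(mesh162.n_vertices)


class TestEnvelopeCalibration:
    def test_closed_form_weights(self):
        a, b = envelope_weights(1.0, 0.5)
        assert a == pytest.approx(0.5) and b == pytest.approx(0.0)
        a, b = envelope_weights(0.0, 0.5)
        assert a == 0.0 and b == pytest.approx(0.5)

    def test_full_shared_envelope_near_perfect_correlation(self, mesh162):
        src, _ = simulate_source_rest(_rest_cfg(mesh162, 1.0), mesh162)
        assert _env_corr(src) >= 0.99

    def test_zero_correlation_case(self, mesh162):
        vals = [_env_corr(simulate_source_rest(
            _rest_cfg(mesh162, 0.0, seed=k, dur=120.0), mesh162)[0])
            for k in range(3)]
        assert max(abs(v) for v in vals) < 0.15

    def test_intermediate_correlation_recovered(self, mesh162):
        """planted 0.6 over 300 s lands within the Monte-Carlo band."""
        src, _ = simulate_source_rest(
            _rest_cfg(mesh162, 0.6, dur=300.0), mesh162)
        assert _env_corr(src, band=ALPHA) == pytest.approx(0.6, abs=0.1)


class TestDeterminismAndMixing:
    def test_same_seed_bit_identical(self, mesh162):
        a, _ = simulate_source_rest(_rest_cfg(mesh162, 0.6, dur=10.0),
                                    mesh162)
        b, _ = simulate_source_rest(_rest_cfg(mesh162, 0.6, dur=10.0),
                                    mesh162)
        assert np.array_equal(a.data, b.data)
        c, _ = simulate_source_rest(_rest_cfg(mesh162, 0.6, dur=10.0,
                                              seed=1), mesh162)
        assert not np.array_equal(a.data, c.data)

    def test_mixing_superposition(self, mesh162, helmet48, leadfield162):
        rng = np.random.default_rng(0)
        s1 = np.zeros((162, 500))
        s2 = np.zeros((162, 500))
        s1[10] = rng.standard_normal(500)
        s2[90] = rng.standard_normal(500)
        r1 = mix_to_sensors(SourceTimeCourses(s1, 250.0), leadfield162,
                            helmet48)
        r2 = mix_to_sensors(SourceTimeCourses(s2, 250.0), leadfield162,
                            helmet48)
        r12 = mix_to_sensors(SourceTimeCourses(s1 + s2, 250.0),
                             leadfield162, helmet48)
        assert np.allclose(r12.data, r1.data + r2.data)
        # single vertex: proportional to the lead-field column
        col = leadfield162.constrained[:, 10]
        outer = np.outer(col, s1[10])
        assert np.allclose(r1.data, outer)

    def test_zero_sources_noise_variance(self, mesh162, helmet48,
                                         leadfield162):
        z = SourceTimeCourses(np.zeros((162, 20000)), 250.0)
        rec = mix_to_sensors(z, leadfield162, helmet48, noise_sd=2.0,
                             rng=np.random.default_rng(1))
        assert rec.data.var() == pytest.approx(4.0, rel=0.05)

    def test_dimension_mismatch_rejected(self, helmet48, leadfield162):
        with pytest.raises(ValueError, match="column count"):
            mix_to_sensors(SourceTimeCourses(np.zeros((10, 100)), 250.0),
                           leadfield162, helmet48)


class TestEvokedTrials:
    def _cfg(self, gating, seed=0, noise=0.0):
        return SimulationConfig(
            sfreq=500.0, n_sp_trials=8, n_pp_trials=8,
            isi_range_s=(1.0, 1.2), seed_vertex=5, noise_sd=noise,
            planted_gating=gating, rng_seed=seed)

    def test_unity_gating_duplicates_response(self, mesh162, helmet48,
                                              leadfield162):
        cfg = self._cfg({"N20m": 1.0, "P35m": 1.0, "P60m": 1.0})
        rec, events, _ = simulate_evoked_trials(cfg, mesh162, leadfield162,
                                                helmet48)
        pp = events[events.condition == "PP"].iloc[0]["sample"]
        first = rec.data[:, pp:pp + 50]
        second = rec.data[:, pp + 50:pp + 100]
        assert np.allclose(first, second)

    def test_zero_gating_makes_pp_equal_sp(self, mesh162, helmet48,
                                           leadfield162):
        cfg = self._cfg({"N20m": 0.0, "P35m": 0.0, "P60m": 0.0})
        rec, events, _ = simulate_evoked_trials(cfg, mesh162, leadfield162,
                                                helmet48)
        sp = events[events.condition == "SP"].iloc[0]["sample"]
        pp = events[events.condition == "PP"].iloc[0]["sample"]
        w = 200
        assert np.allclose(rec.data[:, sp:sp + w], rec.data[:, pp:pp + w])

    def test_waveform_peaks_in_component_windows(self):
        t = np.arange(0, 100, 0.5)
        w = np.abs(sef_waveform(t))
        from sensomap.gating import COMPONENT_WINDOWS_MS
        for comp, (lo, hi) in COMPONENT_WINDOWS_MS.items():
            win = (t >= lo) & (t <= hi)
            assert w[win].max() > 0.2 * w.max()

    def test_negative_gating_rejected(self):
        with pytest.raises(ValueError, match="gating"):
            self._cfg({"N20m": -0.5})


class TestBehavior:
    def test_midpoint_rate_half(self):
        tab = simulate_behavior(2.5, 3.0, distances=(2.5,),
                                trials_per_distance=20000,
                                rng=np.random.default_rng(0))
        rate = (tab.response == TWO_POINT).mean()
        assert rate == pytest.approx(0.5, abs=0.02)

    def test_steep_slope_step_function(self):
        tab = simulate_behavior(2.5, 1e6, trials_per_distance=50,
                                rng=np.random.default_rng(1))
        g = tab.groupby("distance_mm")["response"].agg(
            lambda r: (r == TWO_POINT).mean())
        assert (g[g.index < 2.5] == 0.0).all()
        assert (g[g.index > 2.5] == 1.0).all()

    def test_empty_distances_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_behavior(2.5, 3.0, distances=())

    def test_responses_are_binary_labels(self):
        tab = simulate_behavior(2.5, 3.0, rng=np.random.default_rng(2))
        assert set(tab.response.unique()) <= {TWO_POINT, ONE_POINT}
        assert len(tab) == 160


class TestCohort:
    def test_truths_recorded_before_data_and_deterministic(self):
        cfg = SimulationConfig(n_subjects=10, rng_seed=7)
        t1, _ = draw_cohort_truths(cfg)
        t2, _ = draw_cohort_truths(cfg)
        assert t1 == t2
        rhos = [t.true_env_corr["alpha"] for t in t1]
        assert all(0.2 <= r <= 0.8 for r in rhos)

    def test_zero_coupling_uncorrelated(self):
        cfg = SimulationConfig(n_subjects=42, coupling_slope=0.0,
                               rng_seed=1)
        truths, _ = draw_cohort_truths(cfg)
        from sensomap.stats import spearman
        r = spearman([t.true_env_corr["alpha"] for t in truths],
                     [t.true_threshold_mm for t in truths])
        assert abs(r.statistic) < 0.45

    def test_noise_free_negative_coupling_perfectly_monotone(self):
        cfg = SimulationConfig(n_subjects=20, coupling_slope=-2.0,
                               threshold_noise_sd=0.0, rng_seed=2)
        truths, _ = draw_cohort_truths(cfg)
        from sensomap.stats import spearman
        r = spearman([t.true_env_corr["alpha"] for t in truths],
                     [t.true_threshold_mm for t in truths])
        assert r.statistic == pytest.approx(-1.0)

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError, match="8 subjects"):
            draw_cohort_truths(SimulationConfig(n_subjects=4))

    def test_cohort_bundle_tables(self):
        cfg = SimulationConfig(n_subjects=8, rng_seed=3)
        bundle = simulate_cohort(cfg)
        assert len(bundle.truths) == 8
        assert set(bundle.behavior.subject.unique()) == set(range(8))
        table = bundle.truth_table
        assert {"true_threshold_mm", "env_corr_alpha",
                "gating_N20m"} <= set(table.columns)


def test_subject_rng_streams_independent():
    cfg = SimulationConfig(rng_seed=0)
    a = subject_rng(cfg, 0, 0).standard_normal(5)
    b = subject_rng(cfg, 0, 1).standard_normal(5)
    c = subject_rng(cfg, 1, 0).standard_normal(5)
    assert not np.allclose(a, b) and not np.allclose(a, c)
    assert np.allclose(a, subject_rng(cfg, 0, 0).standard_normal(5))
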