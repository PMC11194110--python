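"""Monte-Carlo generators: determinism, closed-form limits, truth records."""

import math

import numpy as np
import pytest

from curtainkit.model_survival import FrameSchedule, KineticParams, survival_model
from curtainkit.synthetic import (
    KymoSimConfig,
    SpotSimConfig,
    make_default_substrate,
    simulate_binding_positions,
    simulate_intensity_trace,
    simulate_kymogram,
    simulate_spot_disappearance,
    simulate_transcription_cohort,
    TranscriptionSimConfig,
)


def _spot_cfg(**kw):
    base = dict(seed=7, schedule=FrameSchedule(0.1, 10.0), n_spots=10_000,
                tau=3000.0, tau_nu=30.0, N=4, l=0.52, recording_end=math.inf)
    base.update(kw)
    return SpotSimConfig(**base)


class TestSpotDisappearance:
    def test_same_seed_identical_output(self):
        a, _ = simulate_spot_disappearance(_spot_cfg(n_spots=500))
        b, _ = simulate_spot_disappearance(_spot_cfg(n_spots=500))
        np.testing.assert_array_equal(a.disappearance_times, b.disappearance_times)
        np.testing.assert_array_equal(a.censored, b.censored)

    def test_bleach_only_mean(self):
        # tau = inf, N = 1: mean disappearance is r * tau_nu
        ds, truth = simulate_spot_disappearance(
            _spot_cfg(tau=math.inf, N=1, l=1.0, schedule=FrameSchedule(0.1, 4.0))
        )
        assert ds.disappearance_times.mean() == pytest.approx(
            truth["r"] * 30.0, rel=0.03
        )

    def test_max_of_four_exponentials_mean(self):
        ds, _ = simulate_spot_disappearance(
            _spot_cfg(tau=600.0, tau_nu=math.inf, N=4, l=1.0)
        )
        expected = 600.0 * (1 + 1 / 2 + 1 / 3 + 1 / 4)
        assert ds.disappearance_times.mean() == pytest.approx(expected, rel=0.03)

    @pytest.mark.parametrize("N, l", [(1, 1.0), (4, 0.52), (4, 1.0)])
    def test_empirical_survival_matches_model(self, N, l):
        ds, truth = simulate_spot_disappearance(_spot_cfg(N=N, l=l))
        t = np.sort(ds.disappearance_times)
        empirical = 1.0 - np.arange(1, t.size + 1) / t.size
        p = KineticParams(tau=3000.0, tau_nu=30.0, r=truth["r"], N=N, l=l)
        assert np.max(np.abs(empirical - survival_model(t, p))) < 0.02

    def test_component_truncation_respects_cutoff(self):
        ds, _ = simulate_spot_disappearance(_spot_cfg(c=50.0, n_spots=2000))
        assert ds.disappearance_times.min() > 50.0

    def test_censoring_applied(self):
        ds, truth = simulate_spot_disappearance(
            _spot_cfg(recording_end=500.0, n_spots=2000)
        )
        assert truth["n_censored"] == int(ds.censored.sum()) > 0
        assert ds.disappearance_times.max() <= 500.0

    def test_zero_labeling_rejected(self):
        with pytest.raises(ValueError):
            simulate_spot_disappearance(_spot_cfg(l=0.0))


class TestIntensityTraces:
    def test_zero_steps_flat(self):
        trace, truth = simulate_intensity_trace(0, 5.0, seed=1, n_frames=200)
        assert truth["n_steps_realized"] == 0
        assert np.ptp(trace.intensities) < 2.0  # noise only

    def test_infinite_snr_exact_discontinuities(self):
        trace, truth = simulate_intensity_trace(2, math.inf, seed=2)
        jumps = np.flatnonzero(np.diff(trace.intensities) != 0)
        assert jumps.size == truth["n_steps_realized"] == 2

    def test_programmed_count_histogram(self, rng):
        realized = []
        for k in range(300):
            ns = int(rng.integers(1, 6))
            _, truth = simulate_intensity_trace(ns, 5.0, seed=9000 + k)
            realized.append((ns, truth["n_steps_realized"]))
        # with ~1000-frame headroom nearly all programmed steps realize
        frac_full = np.mean([a == b for a, b in realized])
        assert frac_full > 0.9


class TestKymogram:
    def test_zero_molecules_pure_noise(self):
        kymo, truth = simulate_kymogram(KymoSimConfig(seed=1, n_static=0, n_diffusing=0))
        assert truth == []
        assert kymo.intensity.mean() == pytest.approx(20.0, rel=0.05)

    def test_static_molecule_zero_displacement(self):
        _, truth = simulate_kymogram(KymoSimConfig(seed=2, n_static=1, n_diffusing=0))
        pos = np.asarray(truth[0]["positions_bp"])
        assert truth[0]["kind"] == "static"
        assert np.ptp(pos) == 0.0


class TestTranscriptionCohort:
    def test_determinism(self):
        cfg = TranscriptionSimConfig(seed=4, n_traces=20)
        a, ta = simulate_transcription_cohort(cfg)
        b, tb = simulate_transcription_cohort(cfg)
        assert ta == tb
        np.testing.assert_array_equal(a[0].positions, b[0].positions)

    def test_early_stop_below_10kb_by_construction(self):
        cfg = TranscriptionSimConfig(seed=5, n_traces=60, proportions=(0, 1, 0))
        traces, truth = simulate_transcription_cohort(cfg)
        assert all(c == "early_stop" for c in truth["classes"])
        for tr in traces:
            assert tr.positions[-1] < 10_000

    def test_invalid_proportions(self):
        with pytest.raises(ValueError):
            simulate_transcription_cohort(
                TranscriptionSimConfig(seed=1, proportions=(0.5, 0.2, 0.2))
            )


class TestBindingPositions:
    def test_fold_zero_empty_cbs_bins(self, substrate_4x):
        from curtainkit.kymo_positions import PositionSet, bin_positions

        ps = simulate_binding_positions(seed=3, n=300, fold=0.0, substrate=substrate_4x)
        h = bin_positions(ps, substrate_4x)
        assert h.counts[h.cbs_bins].sum() == 0


class TestDefaultSubstrate:
    def test_geometry_and_determinism(self, substrate_4x, substrate_1x):
        assert substrate_4x.length == 48_502
        cbs = substrate_4x.cbs_features()
        assert len(cbs) == 8
        starts = sorted(f.start for f in cbs)
        assert starts[1] - starts[0] == 129
        assert starts[4] - starts[0] == 13_000
        assert len(substrate_1x.cbs_features()) == 1
        again = make_default_substrate("4x")
        assert again.sequence == substrate_4x.sequence

    def test_both_at_classes_present(self, substrate_4x):
        track = substrate_4x.at_track(500)
        assert (track >= 0.5).any() and (track < 0.5).any()

    def test_promoters_optional(self):
        sub = make_default_substrate("4x", include_promoters=True)
        proms = [f for f in sub.features if f.kind == "promoter"]
        assert len(proms) == 2
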