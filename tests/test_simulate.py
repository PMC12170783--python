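"""The synthetic cohort generator: hypnograms, nights, artifacts, cohorts."""

import numpy as np
import pytest

from sleepbai.core import Hypnogram, ValidationError
from sleepbai.simulate import (
    DEFAULT_TRANSITION,
    GroupSpec,
    SimulationConfig,
    event_rates,
    inject_artifacts,
    simulate_cohort,
    simulate_cohort_table,
    simulate_hypnogram,
    simulate_night,
    stage_template_db,
    stationary_distribution,
    subject_night,
)
from sleepbai.spectral import band_power, multitaper_psd_array

ROW = {"subject_id": "sim-1", "age": 40.0, "true_brain_age_offset": 0.0}


def _epochs(rec):
    n = int(30 * rec.fs)
    E = rec.n_epochs
    return rec.signal[:, :E * n].reshape(2, E, n).transpose(1, 0, 2)


class TestHypnogram:
    def test_quarter_hour_is_30_epochs(self):
        hyp = simulate_hypnogram(0.25, SimulationConfig(seed=0), 1)
        assert len(hyp) == 30

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=0)
        assert simulate_hypnogram(1.0, cfg, 5).stages == simulate_hypnogram(1.0, cfg, 5).stages

    def test_stage_fractions_match_stationary_oracle(self):
        # oracle: left eigenvector of the transition matrix
        cfg = SimulationConfig(seed=0)
        target = stationary_distribution(cfg.transition)
        counts = np.zeros(5)
        for k in range(1000):
            hyp = simulate_hypnogram(8.0, cfg, 10_000 + k)
            for i, s in enumerate(("W", "N1", "N2", "N3", "REM")):
                counts[i] += hyp.stages.count(s)
        frac = counts / counts.sum()
        assert np.abs(frac - target).max() < 0.03

    def test_invalid_matrix_rejected(self):
        bad = DEFAULT_TRANSITION.copy()
        bad[0, 0] += 0.1
        with pytest.raises(ValidationError):
            SimulationConfig(transition=bad)

    def test_duration_bounds(self):
        with pytest.raises(ValidationError):
            simulate_hypnogram(0.0, SimulationConfig(), 1)
        with pytest.raises(ValidationError):
            simulate_hypnogram(15.0, SimulationConfig(), 1)


class TestNight:
    def test_n3_delta_dominates_alpha(self):
        cfg = SimulationConfig(seed=1)
        hyp = Hypnogram(("N3",) * 20)
        rec = simulate_night(ROW, hyp, "wearable", cfg, 3)
        f, psd = multitaper_psd_array(_epochs(rec), rec.fs)
        assert np.all(band_power(f, psd, 1, 4) > band_power(f, psd, 8, 12))

    def test_spectral_fidelity_within_1db(self):
        # noiseless config: generated band log-power matches the template curve
        from sleepbai.simulate import _interp_log_psd

        cfg = SimulationConfig(seed=2, subject_sd_db=0.0, night_sd_db=0.0,
                               epoch_sd_db=0.0, spindle_rate_at_ref=0.0,
                               kcomplex_rate_at_ref=0.0, spindle_rate_per_year=0.0,
                               kcomplex_rate_per_year=0.0)
        for stage in ("W", "N1", "N2", "N3", "REM"):
            hyp = Hypnogram((stage,) * 100)
            rec = simulate_night(ROW, hyp, "psg", cfg, 4)
            f, psd = multitaper_psd_array(_epochs(rec), rec.fs)
            lv = stage_template_db(stage, 40.0, cfg)
            curve = _interp_log_psd(
                np.array([[lv["delta"], lv["theta"], lv["alpha"], lv["sigma"]]]),
                f, cfg.floor_db)[0]
            for lo, hi in [(1, 4), (4, 8), (8, 12), (11, 15)]:
                sel = (f >= lo) & (f < hi)
                got = 10 * np.log10(psd[..., sel].mean())
                expect = 10 * np.log10((10 ** (curve[sel] / 10)).mean())
                assert abs(got - expect) < 1.0, (stage, lo, hi)

    def test_age_contrast_matches_configured_slope(self):
        # same subject id => same trait jitter; 50 years ≈ 50·0.15 dB in N3 delta
        cfg = SimulationConfig(seed=3)
        hyp = Hypnogram(("N3",) * 60)
        young = simulate_night(dict(ROW, age=25.0), hyp, "psg", cfg, 7)
        old = simulate_night(dict(ROW, age=75.0), hyp, "psg", cfg, 7)
        f, py = multitaper_psd_array(_epochs(young), young.fs)
        f, po = multitaper_psd_array(_epochs(old), old.fs)
        dy = 10 * np.log10(band_power(f, py, 1, 4))
        do = 10 * np.log10(band_power(f, po, 1, 4))
        diff = dy.mean() - do.mean()
        expected = 50 * abs(cfg.aging_db_per_year[("N3", "delta")])
        se = np.sqrt(dy.var(ddof=1) / dy.size + do.var(ddof=1) / do.size)
        assert abs(diff - expected) < 3 * se + 0.5

    def test_gaussian_limit_without_events(self):
        # zero event rates and a flat template leave plain Gaussian noise
        from scipy.stats import kurtosis

        flat = {s: {"delta": 5.0, "theta": 5.0, "alpha": 5.0, "sigma": 5.0}
                for s in ("W", "N1", "N2", "N3", "REM")}
        cfg = SimulationConfig(seed=4, templates_db=flat, floor_db=5.0,
                               aging_db_per_year={}, subject_sd_db=0.0,
                               night_sd_db=0.0, epoch_sd_db=0.0,
                               spindle_rate_at_ref=0.0, kcomplex_rate_at_ref=0.0,
                               spindle_rate_per_year=0.0, kcomplex_rate_per_year=0.0)
        rec = simulate_night(ROW, Hypnogram(("N2",) * 30), "psg", cfg, 8)
        k = kurtosis(_epochs(rec), axis=-1, fisher=True)
        assert np.abs(k.mean()) < 0.3

    def test_aging_parameters_monotone(self):
        # Spearman ρ = −1 on noiseless template values across probe ages
        from scipy.stats import spearmanr

        cfg = SimulationConfig()
        ages = [20, 35, 50, 65, 80]
        delta = [stage_template_db("N3", a, cfg)["delta"] for a in ages]
        spindle = [event_rates(a, cfg)[0] for a in ages]
        assert spearmanr(ages, delta).statistic == pytest.approx(-1.0)
        assert spearmanr(ages, spindle).statistic == pytest.approx(-1.0)

    def test_age_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            simulate_night(dict(ROW, age=92.0), Hypnogram(("W",)), "wearable",
                           SimulationConfig(), 0)

    def test_device_geometry(self):
        cfg = SimulationConfig(seed=5)
        hyp = Hypnogram(("N2",) * 4)
        w = simulate_night(ROW, hyp, "wearable", cfg, 1)
        p = simulate_night(ROW, hyp, "psg", cfg, 1)
        assert (w.fs, len(w.channels)) == (250.0, 2)
        assert (p.fs, len(p.channels)) == (200.0, 2)
        assert w.channels == ("F7-O1", "F8-O2")
        hh = int(w.start_clock[:2])
        assert hh >= 21 or hh < 1


class TestArtifactInjection:
    def test_rate_zero_is_identity(self, wearable_recording):
        rec, _ = wearable_recording
        out, labels = inject_artifacts(rec, 0.0, 1)
        assert labels == ["clean"] * rec.n_epochs
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_planted_count_within_binomial_interval(self):
        from scipy.stats import binom

        from sleepbai.core import EEGRecording

        rng = np.random.default_rng(0)
        rec = EEGRecording("s", 1, "wearable", ("F7-O1", "F8-O2"), 250.0,
                           rng.normal(0, 20, (2, 1000 * 7500 // 10)))
        # 100 epochs per pass, 10 passes for 1000 epochs total
        total = 0
        for k in range(10):
            _, labels = inject_artifacts(rec, 0.1, k)
            total += sum(l != "clean" for l in labels)
        lo, hi = binom.ppf([0.005, 0.995], 1000, 0.1)
        assert lo <= total <= hi

    def test_burst_exceeds_definite_threshold(self, wearable_recording):
        rec, _ = wearable_recording
        out, labels = inject_artifacts(rec, 0.5, 3)
        n = int(30 * rec.fs)
        bursts = [i for i, l in enumerate(labels) if l == "burst"]
        assert bursts
        for e in bursts:
            assert np.abs(out.signal[:, e * n:(e + 1) * n]).max() > 500.0

    def test_flatline_matches_definite_rule(self, wearable_recording):
        from sleepbai.artifact import flag_definite

        rec, _ = wearable_recording
        out, labels = inject_artifacts(rec, 0.5, 4)
        n = int(30 * rec.fs)
        flats = [i for i, l in enumerate(labels) if l == "flatline"]
        assert flats
        for e in flats:
            flag, reason = flag_definite(out.signal[:, e * n:(e + 1) * n], rec.fs)
            assert reason == "low_amplitude"


class TestCohort:
    def test_offsets_and_nights_recorded(self):
        cfg = SimulationConfig(groups=[
            GroupSpec("reference", 5, 50, 10, brain_age_offset=0.0),
            GroupSpec("meditator", 5, 36, 7, brain_age_offset=-6.0),
        ], seed=1)
        table = simulate_cohort_table(cfg)
        med = table[table["group"] == "meditator"]
        assert (med["true_brain_age_offset"] == -6.0).all()
        assert table["n_nights"].between(1, 4).all()
        assert table["age"].between(18, 80).all()

    def test_same_seed_identical_table(self):
        cfg = SimulationConfig(seed=9)
        t1 = simulate_cohort_table(cfg).to_csv()
        t2 = simulate_cohort_table(SimulationConfig(seed=9)).to_csv()
        assert t1 == t2

    def test_too_small_group_rejected(self):
        cfg = SimulationConfig(groups=[GroupSpec("solo", 1, 40, 5)])
        with pytest.raises(ValidationError):
            simulate_cohort_table(cfg)

    def test_materialized_cohort_aligns(self):
        cfg = SimulationConfig(groups=[GroupSpec("g", 2, 40, 5, nights_probs={2: 1.0})],
                               seed=3)
        table, recs, hyps = simulate_cohort(cfg, duration_hr=0.1)
        assert len(recs) == 4 and set(recs) == set(hyps)
        for key, rec in recs.items():
            assert rec.n_epochs == len(hyps[key])

    def test_subject_night_deterministic(self):
        cfg = SimulationConfig(seed=4)
        row = {"subject_id": "d-1", "age": 44.0, "true_brain_age_offset": 0.0,
               "device": "wearable"}
        r1, h1, _ = subject_night(row, 1, cfg, duration_hr=0.1)
        r2, h2, _ = subject_night(row, 1, cfg, duration_hr=0.1)
        np.testing.assert_array_equal(r1.signal, r2.signal)
        assert h1.stages == h2.stages
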