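"""Generator contracts: event counts, rates, mixture structure, and
self-consistency of the stored ground truth."""

import numpy as np
import pytest
from scipy import stats as sstats

import mobifof as m
from mobifof.core import G
from mobifof.simulate import (default_phenotype, solve_rise_height,
                              _min_jerk_profiles)


class TestPhenotypeSpec:
    def test_defaults_valid(self):
        for group in ("FOF+", "FOF-"):
            default_phenotype(group).validate()

    @pytest.mark.parametrize("bad", [
        dict(gait_speed_mode1=1.0, gait_speed_mode2=0.5),
        dict(mode_mix_weight=1.2),
        dict(turns_per_hour=-1),
        dict(fes_i=25),          # FES-I > 19 but group FOF-
        dict(group_label="FOF?"),
        dict(body_mass=-10),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            default_phenotype("FOF-", **bad)

    def test_fes_i_group_consistency_boundary(self):
        # 19 is still FOF-; 20 requires FOF+
        default_phenotype("FOF-", fes_i=19)
        with pytest.raises(ValueError):
            default_phenotype("FOF-", fes_i=20)


class TestLabSession:
    def test_session_event_counts(self, lab_session):
        _, tl = lab_session
        # 1 TUG sit-to-stand + 5 per 5xSTS block
        assert len(tl.sit_to_stands) == 11
        assert len(tl.turns) == 2
        assert len(tl.walking_bouts) == 2
        assert len(tl.stand_to_sits) == 11

    def test_tug_turns_near_spec(self):
        spec = default_phenotype("FOF-", turn_peak_omega_mean=160.0)
        _, tl = m.generate_lab_session(spec, seed=1, synthesize=False)
        for turn in tl.turns[:2]:
            assert abs(abs(turn.angle) - 180.0) < 1e-9
            assert abs(turn.peak_omega - 160.0) < 3 * spec.turn_peak_omega_sd

    def test_configurable_cycle_count(self, fofneg_spec):
        _, tl = m.generate_lab_session(fofneg_spec, seed=2, synthesize=False,
                                       sts_cycles=3)
        assert len(tl.sit_to_stands) == 1 + 3 + 3

    def test_noiseless_rest_reads_gravity(self, fofneg_spec):
        rec, tl = m.generate_lab_session(fofneg_spec, seed=0, noise_acc=0.0,
                                         noise_gyro=0.0, tilt_deg=0.0)
        vert = rec.acc[:, rec.axis("vertical")]
        # outside any event the vertical axis reads +g
        busy = np.zeros(rec.n_samples, bool)
        for ev in (tl.sit_to_stands + tl.stand_to_sits + tl.turns + tl.walking_bouts):
            i0, i1 = int(ev.start * rec.sample_rate), int(ev.end * rec.sample_rate)
            busy[max(0, i0 - 5):i1 + 5] = True
        assert np.allclose(vert[~busy], G, atol=1e-9)
        assert np.allclose(rec.gyro[~busy], 0.0, atol=1e-9)

    def test_timeline_valid_and_in_span(self, lab_session):
        _, tl = lab_session
        tl.validate()


class TestMinJerkPower:
    def test_solved_height_reproduces_target_power(self):
        for target in (15.0, 40.0, 80.0):
            h = solve_rise_height(target, 1.5, 80.0)
            tau = np.linspace(0, 1, 2000)
            _, v, a = _min_jerk_profiles(h, 1.5, tau * 1.5)
            assert np.max(80.0 * (a + G) * v) == pytest.approx(target, rel=1e-3)


class TestDailyGeneration:
    def test_n_days_validated(self, fofneg_spec):
        with pytest.raises(ValueError):
            m.generate_daily_recording(fofneg_spec, 0, seed=1)

    def test_zero_bout_spec_yields_no_walking(self):
        spec = default_phenotype("FOF-", bouts_per_day_by_class=(0, 0, 0))
        days = m.generate_daily_recording(spec, 3, seed=1, synthesize=False)
        assert all(len(tl.walking_bouts) == 0 for _, tl in days)

    def test_short_wear_fails_validity_downstream(self):
        from mobifof.daily import DayEvents, NoValidDaysError, filter_valid_days

        spec = default_phenotype("FOF-", wear_hours_per_day=5.0)
        days = [DayEvents.from_timeline(tl)
                for _, tl in m.generate_daily_recording(spec, 3, seed=2,
                                                        synthesize=False)]
        with pytest.raises(NoValidDaysError):
            filter_valid_days(days)

    def test_turn_rate_matches_poisson_expectation(self):
        spec = default_phenotype("FOF-", turns_per_hour=90.0)
        days = m.generate_daily_recording(spec, 14, seed=5, synthesize=False)
        hours = sum(tl.duration for _, tl in days) / 3600.0
        count = sum(len(tl.turns) for _, tl in days)
        tol = 3.0 * np.sqrt(90.0 * hours) / hours
        assert abs(count / hours - 90.0) < tol

    def test_event_counts_follow_configured_rates(self):
        """Dispersion (chi-square) test of per-day Poisson counts at the
        configured rates, 50 seeded days per replicate, evidence pooled
        over three replicates by Fisher's method."""
        for rate, getter in ((4.0, lambda tl: len(tl.sit_to_stands)),
                             (60.0, lambda tl: len(tl.turns))):
            ps = []
            for seed in (0, 1, 2):
                spec = default_phenotype("FOF-", sts_per_hour=4.0,
                                         turns_per_hour=60.0)
                days = m.generate_daily_recording(spec, 50, seed=seed,
                                                  synthesize=False,
                                                  wear_hours=2.0)
                obs = np.array([getter(tl) for _, tl in days], float)
                exp = np.array([rate * tl.duration / 3600.0 for _, tl in days])
                chi2 = float(((obs - exp) ** 2 / exp).sum())
                ps.append(float(sstats.chi2.sf(chi2, df=len(obs))))
            combined = sstats.combine_pvalues(ps, method="fisher").pvalue
            assert combined > 0.01, f"rate {rate}/h: dispersion p={ps}"

    def test_turn_rules_respected_in_truth(self):
        spec = default_phenotype("FOF-")
        _, tl = m.generate_daily_recording(spec, 1, seed=4, synthesize=False)[0]
        for t in tl.turns:
            assert 0.5 <= t.duration <= 10.0
            assert abs(t.angle) > 45.0

    def test_pooled_speeds_recover_mixture_modes(self):
        spec = default_phenotype("FOF-", gait_speed_mode1=0.5,
                                 gait_speed_mode2=0.9, mode_mix_weight=0.5,
                                 speed_jitter_sd=0.05,
                                 bouts_per_day_by_class=(30, 10, 10))
        days = m.generate_daily_recording(spec, 6, seed=6, synthesize=False)
        pooled = np.concatenate([b.per_second_speed
                                 for _, tl in days for b in tl.walking_bouts])
        assert pooled.size > 10_000
        fit = m.fit_bimodal_modes(pooled, seed=0)
        assert not fit.degenerate
        assert abs(fit.v_mu1 - 0.5) < 0.05
        assert abs(fit.v_mu2 - 0.9) < 0.05

    def test_yaw_integral_recovers_turn_angle(self):
        """Noiseless yaw pulse integrates back to the stored angle < 1 deg."""
        from mobifof.simulate import synthesize_day

        spec = default_phenotype("FOF-", bouts_per_day_by_class=(0, 0, 0),
                                 sts_per_hour=0.0, turns_per_hour=40.0)
        rng = np.random.default_rng(0)
        _, tl = m.generate_daily_recording(spec, 1, seed=7, synthesize=False,
                                           wear_hours=0.2)[0]
        rec = synthesize_day(tl, spec, rng, noise_acc=0.0, noise_gyro=0.0,
                             tilt_deg=0.0)
        vert = rec.axis("vertical")
        for t in tl.turns:
            i0, i1 = int(t.start * rec.sample_rate), int(t.end * rec.sample_rate)
            angle = np.trapezoid(rec.gyro[i0:i1, vert], dx=1 / rec.sample_rate)
            assert abs(angle - t.angle) < 1.0


class TestCohort:
    def test_cohort_shape_and_labels(self):
        subs = m.generate_cohort(9, 17, seed=0, n_days=1)
        assert len(subs) == 26
        assert sum(s.spec.group_label == "FOF+" for s in subs) == 9
        for s in subs:
            assert (s.spec.fes_i > 19) == (s.spec.group_label == "FOF+")

    def test_sizes_validated(self):
        with pytest.raises(ValueError):
            m.generate_cohort(0, 5, seed=0)

    def test_zero_shift_groups_exchangeable(self):
        from mobifof.pipeline import cohort_feature_table
        from mobifof.stats import effect_size_table
        from mobifof.daily import HOME_FEATURES
        from mobifof.lab import LAB_FEATURES

        subs = m.generate_cohort(9, 17, m.GroupEffectConfig.zero(), seed=21,
                                 n_days=2)
        cohort = cohort_feature_table(subs, seed=21)
        feats = [f for f in LAB_FEATURES + list(HOME_FEATURES)
                 if cohort[f].notna().all()]
        es = effect_size_table(cohort, feats)
        # under the null, |r| ~ 0.2/sqrt(n-ish): large values must be rare
        assert (es["r"].abs() > 0.5).sum() <= 4
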