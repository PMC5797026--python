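"""Endpoint derivation, Kaplan-Meier, log-rank and Aalen-Johansen."""

import numpy as np
import pytest

from nkaml import (
    OutcomeRecord,
    aalen_johansen,
    cif_at,
    derive_endpoints,
    kaplan_meier,
    logrank,
    survival_at,
    survival_point,
)
from nkaml.io import ValidationError
from nkaml.survival import CENSORED, DEATH_WITHOUT_RELAPSE, RELAPSE

from conftest import competing_risk_sample


def record(**kw):
    base = dict(
        patient_id="P1", age=50.0, sex="M", wbc=20.0, bm_blast_pct=70.0,
        cr_achieved=False, last_followup_time=60.0,
    )
    base.update(kw)
    return OutcomeRecord(**base)


class TestEndpoints:
    def test_relapse_clock_restarts_at_cr(self):
        ep = derive_endpoints(
            record(cr_achieved=True, cr_time=1.5, relapse_time=10.0,
                   death_time=14.0, last_followup_time=14.0)
        )
        assert ep.relapse_entry == 1.5
        assert ep.relapse_time == pytest.approx(8.5)
        assert ep.relapse_event_code == RELAPSE
        assert ep.os_event and ep.os_time == 14.0
        assert ep.efs_event and ep.efs_time == 10.0

    def test_long_term_survivor_censored_everywhere(self):
        ep = derive_endpoints(
            record(cr_achieved=True, cr_time=1.5, last_followup_time=70.0)
        )
        assert not ep.os_event and ep.os_time == 70.0
        assert not ep.efs_event and ep.efs_time == 70.0
        assert ep.relapse_event_code == CENSORED
        assert ep.relapse_time == pytest.approx(68.5)

    def test_induction_failure_is_an_efs_event(self):
        ep = derive_endpoints(
            record(cr_achieved=False, death_time=3.0, last_followup_time=3.0)
        )
        assert ep.efs_event and ep.efs_time == 1.0  # failure assessed before death
        assert ep.os_event and ep.os_time == 3.0

    def test_death_before_failure_assessment_caps_efs(self):
        ep = derive_endpoints(
            record(cr_achieved=False, death_time=0.4, last_followup_time=0.4)
        )
        assert ep.efs_event and ep.efs_time == pytest.approx(0.4)

    def test_death_without_relapse_is_the_competing_event(self):
        ep = derive_endpoints(
            record(cr_achieved=True, cr_time=1.0, death_time=9.0,
                   last_followup_time=9.0)
        )
        assert ep.relapse_event_code == DEATH_WITHOUT_RELAPSE
        assert ep.relapse_time == pytest.approx(8.0)

    def test_sct_never_censors(self):
        ep = derive_endpoints(
            record(cr_achieved=True, cr_time=1.0, sct_time=4.0,
                   death_time=20.0, last_followup_time=20.0)
        )
        assert ep.os_event and ep.os_time == 20.0 and ep.sct_time == 4.0

    def test_inconsistent_chronology_raises(self):
        with pytest.raises(ValidationError):
            derive_endpoints(
                record(cr_achieved=True, cr_time=12.0, relapse_time=3.0,
                       last_followup_time=20.0)
            )


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [True, False, True])
        assert list(km.times) == [1.0, 3.0]
        assert km.estimates[0] == pytest.approx(2 / 3)
        assert km.estimates[1] == pytest.approx(0.0)
        assert km.greenwood_se[0] == pytest.approx((2 / 3) * np.sqrt(1 / 6))

    def test_all_censored_is_flat_one(self):
        km = kaplan_meier([5.0, 8.0, 2.0], [False] * 3)
        assert survival_at(km, 7.0) == 1.0

    def test_negative_time_is_an_error(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1.0, 2.0], [True, True])

    def test_no_censoring_reduces_to_empirical_survival(self, rng):
        t = rng.exponential(10, 200)
        km = kaplan_meier(t, np.ones_like(t, dtype=bool))
        for q in (2.0, 5.0, 15.0):
            assert survival_at(km, q) == pytest.approx(np.mean(t > q), abs=1e-12)

    def test_estimates_match_exponential_closed_form(self, rng):
        lam, n = 0.03, 4000
        t_true = rng.exponential(1 / lam, n)
        c = rng.uniform(0, 200, n)
        t = np.minimum(t_true, c)
        km = kaplan_meier(t, t_true <= c)
        grid = np.arange(5, 100, 5.0)
        err = max(abs(survival_at(km, g) - np.exp(-lam * g)) for g in grid)
        assert err < 0.03

    def test_permutation_invariance(self, rng):
        t = rng.exponential(10, 80)
        e = rng.random(80) < 0.7
        km1 = kaplan_meier(t, e)
        perm = rng.permutation(80)
        km2 = kaplan_meier(t[perm], e[perm])
        assert np.allclose(km1.estimates, km2.estimates)

    def test_agrees_with_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, 150)
        e = rng.random(150) < 0.6
        km = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        theirs = kmf.survival_function_at_times(km.times).to_numpy()
        assert np.allclose(km.estimates, theirs, atol=1e-12)

    def test_evaluation_beyond_followup_warns(self):
        km = kaplan_meier([1.0, 2.0], [True, False])
        with pytest.warns(UserWarning, match="extrapolation"):
            assert survival_at(km, 60.0) == pytest.approx(0.5)

    def test_survival_point_interval_is_clamped(self):
        km = kaplan_meier([1.0] * 2 + [50.0] * 8, [True] * 2 + [False] * 8)
        pt = survival_point(km, 10.0)
        assert pt.estimate == pytest.approx(0.8)
        assert 0.0 <= pt.ci_low <= pt.estimate <= pt.ci_high <= 1.0


class TestLogrank:
    def test_identical_groups_give_zero(self):
        g = ([1.0, 2.0, 3.0, 4.0], [True, True, False, True])
        res = logrank([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_tabulation(self):
        # deaths alternate A(1,3,5) / B(2,4,6); O-E = 23/30, V = 5456/4500
        res = logrank([([1, 3, 5], [1, 1, 1]), ([2, 4, 6], [1, 1, 1])])
        o_minus_e = 3 - (0.5 + 0.4 + 0.5 + 1 / 3 + 0.5)
        var = 0.25 + 0.24 + 0.25 + 2 / 9 + 0.25
        assert res.statistic == pytest.approx(o_minus_e**2 / var, abs=1e-12)

    def test_zero_subject_group_is_an_error(self):
        with pytest.raises(ValueError):
            logrank([([1.0], [True]), ([], [])])

    def test_agrees_with_lifelines_multivariate(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        ts, es, gs = [], [], []
        for g in range(3):
            t = rng.exponential(10 + 3 * g, 40)
            c = rng.uniform(0, 25, 40)
            ts.append(np.minimum(t, c))
            es.append(t <= c)
            gs.append(np.full(40, g))
        res = logrank(list(zip(ts, es)))
        ll = multivariate_logrank_test(
            np.concatenate(ts), np.concatenate(gs), np.concatenate(es)
        )
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-8)
        assert res.df == 2


class TestAalenJohansen:
    def test_single_cause_equals_one_minus_km(self, rng):
        t = rng.exponential(10, 100)
        e = rng.random(100) < 0.7
        cif = aalen_johansen(t, np.where(e, 1, 0))
        km = kaplan_meier(t, e)
        for q in (2.0, 8.0, 20.0):
            assert cif_at(cif, q, cause=1) == pytest.approx(
                1 - survival_at(km, q), abs=1e-12
            )

    def test_five_subject_hand_tabulation(self):
        cif = aalen_johansen([1, 2, 3, 4, 5], [1, 2, 0, 1, 0])
        assert list(cif.times) == [1, 2, 4]
        assert np.allclose(cif.cif[1], [0.2, 0.2, 0.5])
        assert np.allclose(cif.cif[2], [0.0, 0.2, 0.2])
        assert np.allclose(cif.km_allcause, [0.8, 0.6, 0.3])

    def test_conservation_identity_on_random_data(self, rng):
        for _ in range(20):
            t, code = competing_risk_sample(rng, 60)
            cif = aalen_johansen(t, code)
            total = cif.cif[1] + cif.cif[2] + cif.km_allcause
            assert np.max(np.abs(total - 1.0)) < 1e-12

    def test_unknown_code_is_an_error(self):
        with pytest.raises(ValueError, match="unknown"):
            aalen_johansen([1.0, 2.0], [1, 7])

    def test_matches_independent_reference_values(self):
        # frozen from an independent competing-risks implementation
        # (R cmprsk::cuminc) on this exact fixture
        rng = np.random.default_rng(5)
        n = 60
        t1 = rng.exponential(1.0, n)
        t2 = rng.exponential(2.0, n)
        c = rng.uniform(0.2, 3.0, n)
        t = np.minimum(np.minimum(t1, t2), c)
        code = np.where(t == c, 0, np.where(t == t1, 1, 2))
        cif = aalen_johansen(t, code)
        assert cif_at(cif, 0.5, cause=1) == pytest.approx(0.3539476, abs=1e-6)
        assert cif_at(cif, 1.0, cause=1) == pytest.approx(0.5347666, abs=1e-6)
        assert cif_at(cif, 1.0, cause=2) == pytest.approx(0.2206425, abs=1e-6)

    def test_left_truncated_risk_sets(self):
        # delayed entry removes not-yet-entered subjects from early risk sets
        cif = aalen_johansen([2.0, 3.0, 4.0], [1, 1, 0], entry=[1.5, 0.0, 0.0])
        assert cif.at_risk[0] == 3.0
        cif2 = aalen_johansen([2.0, 3.0, 4.0], [1, 1, 0], entry=[0.0, 2.5, 0.0])
        assert cif2.at_risk[0] == 2.0
        with pytest.raises(ValueError):
            aalen_johansen([2.0], [1], entry=[3.0])
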