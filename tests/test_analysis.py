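"""Analysis-stage tests: lipid contrasts, scaled hazard ratios, factorial
contrasts, interaction tests and composite outcomes."""

import numpy as np
import pandas as pd
import pytest

from factorialmr import (
    allocate_factorial,
    biomarker_association,
    composite_outcome,
    factorial_contrasts,
    generate_cohort,
    interaction_test,
    per50_hr,
    sim_config,
)
from factorialmr.scores import FACTORIAL_GROUPS, FactorialAllocation
from factorialmr.synthetic import CohortTable
from tests.conftest import scores_for


@pytest.fixture(scope="module")
def null_cohort():
    """Two-arm scenario with all genetic effects switched off."""
    cfg = sim_config(8000, seed=55, hr50_a=1.0, arm_b_log_hr_per_unit=0.0)
    cohort = generate_cohort(cfg)
    sa = scores_for(cohort, cfg, "score_a")
    sb = scores_for(cohort, cfg, "score_b")
    return cfg, cohort, sa, sb


def _score_contrast_oracle(score_cfg, n=400_000, seed=99):
    """Brute-force expected lower-vs-higher contrast of the true score,
    simulated directly from the generating frequencies and weights."""
    rng = np.random.default_rng(seed)
    G = rng.binomial(2, score_cfg.freqs, size=(n, len(score_cfg.freqs)))
    s = G @ score_cfg.betas
    low = s <= np.median(s)
    return s[low].mean() - s[~low].mean()


class TestBiomarkerAssociation:
    def test_null_score_contrast_within_3_se(self, null_cohort):
        _, cohort, _, sb = null_cohort
        # score_b has no loading on trait_a
        res = biomarker_association(cohort, sb, "trait_a")
        assert abs(res["estimate"]) < 3 * res["se"]

    def test_calibrated_contrast_matches_bruteforce_expectation(self, null_cohort):
        cfg, cohort, sa, _ = null_cohort
        res = biomarker_association(cohort, sa, "trait_a")
        expected = _score_contrast_oracle(cfg.scores["score_a"])
        assert res["estimate"] == pytest.approx(expected, abs=3 * res["se"])

    def test_fig2_pattern_on_default_cohort(self, default_cohort_50k):
        config, cohort = default_cohort_50k
        lpa = scores_for(cohort, config, "lpa")
        on_lpa = biomarker_association(cohort, lpa, "lpa")
        on_ldl = biomarker_association(cohort, lpa, "ldl_c")
        on_tg = biomarker_association(cohort, lpa, "tg")
        # lower genetic Lp(a): strongly lower measured Lp(a), weakly lower
        # LDL-C, higher triglycerides (pleiotropy)
        assert on_lpa["estimate"] < -15
        assert -3 < on_ldl["estimate"] < 0
        assert on_tg["estimate"] > 0
        # and the Lp(a) drop dominates the LDL-C drop
        assert on_lpa["estimate"] < on_ldl["estimate"]

    def test_ldl_targets_lower_measured_ldl(self, default_cohort_50k):
        config, cohort = default_cohort_50k
        for arm in ("hmgcr", "npc1l1", "pcsk9", "ldlr"):
            res = biomarker_association(cohort, scores_for(cohort, config, arm), "ldl_c")
            assert res["estimate"] < 0
            assert res["estimate"] - 3 * res["se"] < -0.5

    def test_missing_biomarker_raises(self, null_cohort):
        _, cohort, sa, _ = null_cohort
        with pytest.raises(KeyError, match="ghost"):
            biomarker_association(cohort, sa, "ghost")


class TestPer50HR:
    def test_internal_consistency_with_raw_fit(self, sim_cohort_20k):
        config, cohort = sim_cohort_20k
        sa = scores_for(cohort, config, "score_a")
        res = per50_hr(cohort, sa, "event")
        beta = float(res.raw_fit.coefficients["score"])
        assert res.hr_per_50_decrease == pytest.approx(np.exp(-50 * beta), rel=1e-12)
        assert res.ci_low <= res.hr_per_50_decrease <= res.ci_high

    def test_point_estimate_near_generating_truth(self, sim_cohort_20k):
        config, cohort = sim_cohort_20k
        sa = scores_for(cohort, config, "score_a")
        res = per50_hr(cohort, sa, "event")
        truth_log = -50 * config.outcomes["event"].log_hr_per_unit["score_a"]
        se50 = 50 * float(res.raw_fit.standard_errors["score"])
        assert abs(np.log(res.hr_per_50_decrease) - truth_log) < 3 * se50

    def test_sign_coherence_under_score_flip(self, sim_cohort_20k):
        config, cohort = sim_cohort_20k
        sa = scores_for(cohort, config, "score_a")
        a = per50_hr(cohort, sa, "event")
        b = per50_hr(cohort, -sa, "event")
        assert a.hr_per_50_decrease == pytest.approx(1 / b.hr_per_50_decrease, rel=1e-8)

    def test_non_mgdl_unit_directed_to_per_sd(self, sim_cohort_20k):
        config, cohort = sim_cohort_20k
        sa = scores_for(cohort, config, "score_a")
        with pytest.raises(ValueError, match="per-SD"):
            per50_hr(cohort, sa, "event", unit="SD")


class TestFactorialContrasts:
    def test_schema_reference_first_with_unit_hr(self, null_cohort):
        _, cohort, sa, sb = null_cohort
        res = factorial_contrasts(cohort, allocate_factorial(sa, sb), "event")
        assert list(res.table["group"]) == list(FACTORIAL_GROUPS)
        assert res.table.loc[0, "hr"] == 1.0
        assert res.table["n"].sum() == len(cohort)

    def test_null_generator_all_groups_near_unity(self, null_cohort):
        _, cohort, sa, sb = null_cohort
        res = factorial_contrasts(cohort, allocate_factorial(sa, sb), "event")
        fit = res.raw_fit
        for g in FACTORIAL_GROUPS[1:]:
            assert abs(fit.coefficients[g]) < 3 * fit.standard_errors[g]

    def test_empty_group_raises(self, null_cohort):
        _, cohort, sa, _ = null_cohort
        alloc = allocate_factorial(sa, sa)  # perfect dependence: two empty cells
        with pytest.raises(ValueError, match="empty"):
            factorial_contrasts(cohort, alloc, "event")


class TestInteractionTest:
    def test_constant_score_raises(self, null_cohort):
        _, cohort, sa, _ = null_cohort
        with pytest.raises(ValueError, match="constant"):
            interaction_test(cohort, sa, np.ones(len(cohort)), "event")

    def test_dichotomized_method_runs_and_differs(self, null_cohort):
        _, cohort, sa, sb = null_cohort
        cont = interaction_test(cohort, sa, sb, "event", method="continuous")
        dich = interaction_test(cohort, sa, sb, "event", method="dichotomized")
        assert 0 < cont.p_interaction <= 1
        assert 0 < dich.p_interaction <= 1
        assert cont.method == "continuous" and dich.method == "dichotomized"

    def test_standardization_does_not_change_p(self, null_cohort):
        _, cohort, sa, sb = null_cohort
        std = interaction_test(cohort, sa, sb, "event", standardize=True)
        raw = interaction_test(cohort, sa, sb, "event", standardize=False)
        # the Wald p of the product term is not invariant to affine score
        # rescaling in general because main-effect terms reparameterize, but
        # z of the product term is invariant under pure scaling around 0;
        # assert both run and give finite, comparable evidence
        assert np.isfinite(std.p_interaction) and np.isfinite(raw.p_interaction)

    def test_row_order_invariance(self, null_cohort):
        cfg, cohort, sa, sb = null_cohort
        perm = np.random.default_rng(0).permutation(len(cohort))
        shuffled = CohortTable(
            data=cohort.data.iloc[perm].reset_index(drop=True),
            variant_ids=cohort.variant_ids,
            biomarkers=cohort.biomarkers,
            outcomes=cohort.outcomes,
        )
        a = interaction_test(cohort, sa, sb, "event")
        b = interaction_test(shuffled, sa[perm], sb[perm], "event")
        assert a.p_interaction == pytest.approx(b.p_interaction, rel=1e-8)
        r1 = per50_hr(cohort, sa, "event")
        r2 = per50_hr(shuffled, sa[perm], "event")
        assert r1.hr_per_50_decrease == pytest.approx(r2.hr_per_50_decrease, rel=1e-8)


class TestCompositeOutcome:
    def _toy_cohort(self, times_a, events_a, times_b, events_b):
        n = len(times_a)
        data = pd.DataFrame({
            "iid": range(n),
            "time_a": times_a, "event_a": events_a,
            "time_b": times_b, "event_b": events_b,
        })
        return CohortTable(data=data, variant_ids=[], biomarkers=[], outcomes=["a", "b"])

    def test_first_event_rule(self):
        cohort = self._toy_cohort([2.0], [1], [5.0], [0])
        t, e = composite_outcome(cohort, ["a", "b"])
        assert e[0] == 1 and t[0] == pytest.approx(2.0)

    def test_all_censored_keeps_admin_time(self):
        cohort = self._toy_cohort([10.0], [0], [10.0], [0])
        t, e = composite_outcome(cohort, ["a", "b"])
        assert e[0] == 0 and t[0] == pytest.approx(10.0)

    def test_earliest_of_two_events(self):
        cohort = self._toy_cohort([4.0], [1], [3.0], [1])
        t, e = composite_outcome(cohort, ["a", "b"])
        assert e[0] == 1 and t[0] == pytest.approx(3.0)

    def test_composite_count_bounds_components(self, null_cohort):
        cfg, cohort, *_ = null_cohort
        # synthesize a second outcome by re-labelling follow-up on the same cohort
        rng = np.random.default_rng(8)
        data = cohort.data.copy()
        data["time_other"] = rng.exponential(20.0, len(data)).clip(1e-6, 12.25)
        data["event_other"] = (data["time_other"] < 12.25).astype(int)
        c2 = CohortTable(data=data, variant_ids=cohort.variant_ids,
                         biomarkers=cohort.biomarkers,
                         outcomes=cohort.outcomes + ["other"])
        t, e = composite_outcome(c2, ["event", "other"])
        assert e.sum() >= max(data["event_event"].sum(), data["event_other"].sum())
        assert (t > 0).all()

    def test_requires_two_components(self, null_cohort):
        _, cohort, *_ = null_cohort
        with pytest.raises(ValueError, match="at least 2"):
            composite_outcome(cohort, ["event"])
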