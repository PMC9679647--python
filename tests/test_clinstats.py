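import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmbforge.clinstats import (
    ClinicalCohort,
    compare_tmb_groups,
    cox_multivariate,
    derive_dcb,
    fisher_exact_rates,
    km_curve,
    logrank_test,
    roc_auc,
    select_cutoff,
)
from tmbforge.simdata import ClinicalModel, simulate_clinical


def brute_force_auc(scores, labels):
    """Mann-Whitney probability by exhaustive pair counting (ties = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _cohort(tmb, dcb, times=None, events=None):
    n = len(tmb)
    return ClinicalCohort(
        pd.DataFrame(
            {
                "tmb": tmb,
                "dcb": dcb,
                "os_months": times if times is not None else np.ones(n),
                "os_event": events if events is not None else np.ones(n, dtype=int),
                "pfs_months": np.ones(n),
                "pfs_event": np.ones(n, dtype=int),
                "age": np.full(n, 60),
                "gender": ["M"] * n,
                "drug": ["anti-PD-1"] * n,
                "cancer_type": ["LUAD"] * n,
            }
        )
    )


class TestDeriveDcb:
    @pytest.mark.parametrize(
        "response,weeks,expected",
        [
            ("CR", None, True),
            ("PR", None, True),
            ("SD", 24.0, True),
            ("SD", 23.9, False),
            ("SD", 60.0, True),
            ("PD", None, False),
        ],
    )
    def test_definition_boundaries(self, response, weeks, expected):
        assert derive_dcb(response, weeks) is expected

    def test_sd_without_duration_rejected(self):
        with pytest.raises(ValueError):
            derive_dcb("SD", None)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            derive_dcb("MR", None)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, sweep = roc_auc([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert auc == 1.0
        assert sweep["youden_j"].max() == pytest.approx(1.0)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(6, 25))
            scores = rng.integers(0, 10, n).astype(float)  # many ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels))

    def test_label_inversion_complements_auc(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        auc, _ = roc_auc(scores, labels)
        inv, _ = roc_auc(scores, ~labels)
        assert auc + inv == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [True, True, True])


def independent_logrank_chisq(times, events, groups):
    """Hand-rolled log-rank chi-square, vectorized over label columns.

    ``groups`` is (n_patients, n_labelings); returns one statistic per
    labeling.  Shares no code with the implementation under test.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    G = np.asarray(groups, float)
    event_times = np.unique(times[events])
    at_risk = times[None, :] >= event_times[:, None]  # (T, n)
    died = (times[None, :] == event_times[:, None]) & events[None, :]
    n_i = at_risk.sum(axis=1)
    d_i = died.sum(axis=1)
    n1 = at_risk @ G  # (T, k)
    d1 = died @ G
    frac = n1 / n_i[:, None]
    O = d1.sum(axis=0)
    E = (d_i[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_i = (
            d_i[:, None]
            * frac
            * (1 - frac)
            * ((n_i - d_i) / np.maximum(n_i - 1, 1))[:, None]
        )
    V = v_i.sum(axis=0)
    return (O - E) ** 2 / V


def permutation_logrank_p(times, events, group, n_perm=10_000, seed=0):
    """Permutation distribution of the independent log-rank statistic."""
    group = np.asarray(group, bool)
    obs = independent_logrank_chisq(times, events, group[:, None].astype(float))[0]
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(group) for _ in range(n_perm)], axis=1)
    stats_perm = independent_logrank_chisq(times, events, perms)
    return float(np.mean(stats_perm >= obs - 1e-12))


class TestLogrank:
    def test_identical_duplicated_groups_give_null(self):
        times = [3.0, 5.0, 8.0, 12.0] * 2
        events = [1, 1, 0, 1] * 2
        group = [True] * 4 + [False] * 4
        chisq, p = logrank_test(times, events, group)
        assert chisq == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_statistic_matches_independent_formula(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            times = rng.exponential(6, 40)
            events = rng.random(40) < 0.7
            group = rng.random(40) < 0.5
            if group.all() or not group.any():
                continue
            chisq, _ = logrank_test(times, events, group)
            mine = independent_logrank_chisq(
                times, events, group[:, None].astype(float)
            )[0]
            assert chisq == pytest.approx(mine, rel=1e-6)

    def test_matches_permutation_oracle_within_mc_error(self):
        rng = np.random.default_rng(9)
        times = np.concatenate([rng.exponential(5, 15), rng.exponential(12, 15)])
        events = rng.random(30) < 0.8
        group = np.array([True] * 15 + [False] * 15)
        _, p = logrank_test(times, events, group)
        p_perm = permutation_logrank_p(times, events, group, n_perm=10_000, seed=1)
        mc_sd = np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / 10_000)
        assert abs(p - p_perm) < 4 * mc_sd + 0.01

    def test_power_under_strong_separation(self):
        rng = np.random.default_rng(10)
        significant = 0
        n_rep = 60
        for _ in range(n_rep):
            t_high = rng.exponential(10, 30)
            t_low = rng.exponential(2, 30)  # hazard ratio 5
            times = np.concatenate([t_high, t_low])
            events = np.ones(60, bool)
            _, p = logrank_test(times, events, [True] * 30 + [False] * 30)
            significant += p < 0.05
        assert significant / n_rep >= 0.95

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(300):
            times = rng.exponential(6, 40)
            events = rng.random(40) < 0.8
            group = rng.permutation([True] * 20 + [False] * 20)
            _, p = logrank_test(times, events, group)
            ps.append(p)
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [True, True])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        km = km_curve([5.0, 8.0, 11.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_textbook_remission_data_product_limit(self):
        # classic 6-MP maintenance arm (21 patients, * = censored)
        times = [6, 6, 6, 6, 7, 9, 10, 10, 11, 13, 16, 17, 19, 20, 22, 23, 25, 32, 32, 34, 35]
        events = [1, 1, 1, 0, 1, 0, 1, 0, 0, 1, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0]
        km = km_curve([float(t) for t in times], events)
        lookup = dict(zip(km["time"], km["survival"]))
        # hand-computed product-limit values
        assert lookup[6.0] == pytest.approx(18 / 21, abs=1e-4)
        assert lookup[7.0] == pytest.approx(18 / 21 * 16 / 17, abs=1e-4)
        assert lookup[10.0] == pytest.approx(18 / 21 * 16 / 17 * 14 / 15, abs=1e-4)
        assert lookup[22.0] == pytest.approx(0.5378, abs=1e-3)
        assert lookup[23.0] == pytest.approx(0.4482, abs=1e-3)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1.0, 2.0], [1, 1])


class TestSelectCutoff:
    def test_constructed_separation_at_seven(self):
        tmb = np.array([2, 3, 4, 5, 6, 7, 8, 9, 10, 12] * 4, dtype=float)
        dcb = tmb >= 7
        times = np.where(dcb, 20.0, 5.0) + np.linspace(0, 1, 40)
        cohort = _cohort(tmb, dcb, times, np.ones(40, int))
        res = select_cutoff(cohort)
        assert res.cutoff == 7.0
        assert res.auc == 1.0
        assert res.youden_j == pytest.approx(1.0)
        assert res.logrank_p < 0.001

    def test_exchangeable_labels_flagged_non_informative(self):
        rng = np.random.default_rng(21)
        tmb = rng.gamma(2, 4, 2000)
        dcb = rng.random(2000) < 0.4  # independent of TMB
        cohort = _cohort(tmb, dcb, rng.exponential(10, 2000), np.ones(2000, int))
        res = select_cutoff(cohort)
        assert abs(res.youden_j) < 0.1
        assert not res.informative

    def test_recovers_generative_center_within_one(self):
        cutoffs = []
        for seed in range(9):
            rng = np.random.default_rng(200 + seed)
            tmb = rng.gamma(2.0, 4.0, 66)
            table = simulate_clinical(tmb, ClinicalModel(), seed=seed)
            res = select_cutoff(ClinicalCohort.from_table(table))
            cutoffs.append(res.cutoff)
        assert abs(np.median(cutoffs) - 7.0) <= 1.0

    def test_invariant_to_patient_order_and_monotone_transform(self):
        rng = np.random.default_rng(22)
        tmb = rng.gamma(2, 4, 80)
        dcb = rng.random(80) < 1 / (1 + np.exp(-(tmb - 7)))
        if dcb.all() or not dcb.any():
            pytest.skip("degenerate draw")
        times = rng.exponential(10, 80)
        cohort = _cohort(tmb, dcb, times, np.ones(80, int))
        res = select_cutoff(cohort)
        perm = rng.permutation(80)
        shuffled = _cohort(tmb[perm], dcb[perm], times[perm], np.ones(80, int))
        assert select_cutoff(shuffled).cutoff == res.cutoff
        # strictly monotone transform preserves the ROC-ranked AUC
        squashed = _cohort(np.sqrt(tmb), dcb, times, np.ones(80, int))
        assert select_cutoff(
            squashed, candidates=np.sqrt(np.arange(1, 21))
        ).auc == pytest.approx(res.auc)

    def test_degenerate_single_class_rejected(self):
        cohort = _cohort([1.0, 2.0, 8.0, 9.0], [True] * 4)
        with pytest.raises(ValueError):
            select_cutoff(cohort)


class TestCox:
    def test_recovers_simulated_hazard_ratio(self):
        rng = np.random.default_rng(30)
        n = 400
        high = np.repeat([True, False], n // 2)
        hazard = np.where(high, 0.05, 0.10)  # HR 2 for the low-TMB group
        times = rng.exponential(1 / hazard)
        cens = rng.exponential(40, n)
        cohort = _cohort(
            np.where(high, 10.0, 2.0), rng.random(n) < 0.5,
            np.minimum(times, cens), (times <= cens).astype(int),
        )
        out = cox_multivariate(cohort, cutoff=7.0, covariates=())
        hr = out.loc["tmb_high", "hr"]
        assert out.loc["tmb_high", "hr_lo"] < 0.5 < out.loc["tmb_high", "hr_hi"]
        assert hr == pytest.approx(0.5, abs=0.15)

    def test_null_covariate_ci_spans_one_in_most_replicates(self):
        rng = np.random.default_rng(31)
        spans = 0
        n_rep = 30
        for _ in range(n_rep):
            n = 120
            times = rng.exponential(8, n)
            cohort = _cohort(
                rng.gamma(2, 4, n), rng.random(n) < 0.5, times, np.ones(n, int)
            )
            out = cox_multivariate(cohort, cutoff=7.0, covariates=())
            spans += (out.loc["tmb_high", "hr_lo"] <= 1.0 <= out.loc["tmb_high", "hr_hi"])
        assert spans / n_rep >= 0.9

    def test_zero_events_rejected(self):
        cohort = _cohort([1.0, 9.0] * 5, [False, True] * 5,
                         np.ones(10), np.zeros(10, int))
        with pytest.raises(ValueError):
            cox_multivariate(cohort, cutoff=7.0)


class TestCompareTmbGroups:
    def test_identical_groups_null(self):
        t, p = compare_tmb_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_three_sigma_shift_detected(self):
        rng = np.random.default_rng(40)
        a = rng.normal(10, 1, 50)
        b = rng.normal(13, 1, 50)
        _, p = compare_tmb_groups(a, b)
        assert p < 0.001

    def test_swap_flips_sign_same_p(self):
        rng = np.random.default_rng(41)
        a, b = rng.normal(5, 2, 20), rng.normal(7, 2, 20)
        t1, p1 = compare_tmb_groups(a, b)
        t2, p2 = compare_tmb_groups(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_tmb_groups([1.0], [1.0, 2.0])


class TestFisher:
    def test_matches_scipy_on_2x2(self):
        odds, p = fisher_exact_rates(8, 10, 2, 10)
        odds2, p2 = stats.fisher_exact([[8, 2], [2, 8]])
        assert odds == pytest.approx(odds2) and p == pytest.approx(p2)
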