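import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from dsaflow import stats as st


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, labels):
    """Brute-force concordant-pair AUC (ties half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_scan(scores, labels):
    """Exhaustive scan over all observed cut-points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    best = None
    for cut in np.unique(scores):
        pred = scores >= cut
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1.0
        if best is None or (j, spec, cut) > best[0]:
            best = ((j, spec, cut), float(cut), float(j))
    return best[1], best[2]


# ---------------------------------------------------------------------------
# roc_auc
# ---------------------------------------------------------------------------

class TestRocAuc:
    def test_perfect_separation(self):
        assert st.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_six_point_brute_force(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9]
        labels = [0, 0, 1, 1, 0, 1]
        assert st.roc_auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_random(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 51))
        scores = r.choice(np.linspace(0, 1, 10), size=n)  # force ties
        labels = r.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert st.roc_auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12)

    def test_independent_scores_near_half(self):
        r = np.random.default_rng(0)
        n = 4000
        scores = r.normal(size=n)
        labels = r.integers(0, 2, size=n)
        n1 = labels.sum()
        n0 = n - n1
        se = math.sqrt((n0 + n1 + 1) / (12 * n0 * n1))
        assert abs(st.roc_auc(scores, labels) - 0.5) < 3 * se

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            st.roc_auc([1, 2, 3], [1, 1, 1])

    @given(hst.lists(hst.floats(-5, 5), min_size=4, max_size=30),
           hst.randoms())
    @settings(max_examples=40, deadline=None)
    def test_property_brute_force(self, scores, rnd):
        labels = [rnd.randint(0, 1) for _ in scores]
        if len(set(labels)) < 2:
            labels[0] = 1 - labels[0]
        assert st.roc_auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# delong_test
# ---------------------------------------------------------------------------

class TestDelong:
    def test_identical_scores(self):
        r = np.random.default_rng(1)
        s = r.normal(size=40)
        y = r.integers(0, 2, size=40)
        y[:2] = [0, 1]
        auc_a, auc_b, z, p = st.delong_test(s, s, y)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_monotone_transform_invariance(self):
        r = np.random.default_rng(2)
        sa = r.normal(size=60)
        sb = r.normal(size=60)
        y = r.integers(0, 2, size=60)
        y[:2] = [0, 1]
        ref = st.delong_test(sa, sb, y)
        tr = st.delong_test(np.exp(sa), sb, y)
        assert tr[0] == pytest.approx(ref[0], abs=1e-12)
        assert tr[2] == pytest.approx(ref[2], abs=1e-9)
        assert tr[3] == pytest.approx(ref[3], abs=1e-9)

    def test_against_bootstrap_z(self):
        r = np.random.default_rng(3)
        n = 120
        y = np.concatenate([np.ones(60), np.zeros(60)]).astype(int)
        latent = y + r.normal(0, 1.2, size=n)
        sa = latent + r.normal(0, 0.6, size=n)
        sb = latent + r.normal(0, 1.4, size=n)
        _, _, z, _ = st.delong_test(sa, sb, y)
        diffs = []
        for _ in range(600):
            idx = r.integers(0, n, size=n)
            if len(np.unique(y[idx])) < 2:
                continue
            diffs.append(st.roc_auc(sa[idx], y[idx]) - st.roc_auc(sb[idx], y[idx]))
        z_boot = (st.roc_auc(sa, y) - st.roc_auc(sb, y)) / np.std(diffs)
        assert z == pytest.approx(z_boot, rel=0.20)

    def test_degenerate_variance_rejected(self):
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError):
            st.delong_test([1.0, 2.0, 1.0, 2.0], [0.0, 0.0, 0.0, 0.0], y)


# ---------------------------------------------------------------------------
# youden_threshold
# ---------------------------------------------------------------------------

class TestYouden:
    def test_perfect_separation(self):
        thr, j = st.youden_threshold([1, 2, 3, 8, 9], [0, 0, 0, 1, 1])
        assert j == 1.0
        assert 3 < thr <= 8

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_scan(self, seed):
        r = np.random.default_rng(seed)
        scores = r.choice(np.linspace(0, 1, 8), size=20)
        labels = r.integers(0, 2, size=20)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert st.youden_threshold(scores, labels) == youden_scan(scores, labels)

    def test_label_flip(self):
        r = np.random.default_rng(9)
        scores = r.normal(size=20)
        labels = r.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        _, j = st.youden_threshold(scores, labels)
        _, j_flip = st.youden_threshold(-scores, 1 - labels)
        assert j_flip == pytest.approx(youden_scan(-scores, 1 - labels)[1])
        assert j >= 0 or j_flip >= 0  # one orientation is informative

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            st.youden_threshold([1, 2], [1, 1])


# ---------------------------------------------------------------------------
# diagnostic_metrics
# ---------------------------------------------------------------------------

class TestDiagnosticMetrics:
    def test_all_correct(self):
        m = st.diagnostic_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert m == {"sensitivity": 100.0, "specificity": 100.0,
                     "ppv": 100.0, "npv": 100.0}

    def test_printed_scale_confusion(self):
        # TP=45 FN=7 FP=6 TN=48
        pred = [1] * 45 + [0] * 7 + [1] * 6 + [0] * 48
        true = [1] * 45 + [1] * 7 + [0] * 6 + [0] * 48
        m = st.diagnostic_metrics(pred, true)
        assert round(m["sensitivity"], 1) == 86.5
        assert m["specificity"] == pytest.approx(100 * 48 / 54)
        assert m["ppv"] == pytest.approx(100 * 45 / 51)

    def test_no_positive_predictions_ppv_nan(self):
        m = st.diagnostic_metrics([0, 0, 0], [1, 0, 1])
        assert math.isnan(m["ppv"])
        assert m["sensitivity"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.diagnostic_metrics([], [])


# ---------------------------------------------------------------------------
# relative_risk / rate_percent
# ---------------------------------------------------------------------------

class TestRelativeRisk:
    @pytest.mark.parametrize("a,na,b,nb,rr2dp", [
        (7, 87, 17, 81, 0.38),    # severe PTS
        (22, 87, 36, 81, 0.57),   # IVC filter
        (2, 87, 6, 81, 0.31),     # major bleeding
        (3, 87, 9, 81, 0.31),     # PE, recomputed from counts
    ])
    def test_printed_counts(self, a, na, b, nb, rr2dp):
        rr, lo, hi = st.relative_risk(st.TwoByTwo(a, na, b, nb))
        assert round(rr, 2) == rr2dp
        assert lo < rr < hi

    def test_katz_ci_closed_form(self):
        t = st.TwoByTwo(7, 87, 17, 81)
        rr, lo, hi = st.relative_risk(t)
        se = math.sqrt(1 / 7 - 1 / 87 + 1 / 17 - 1 / 81)
        assert lo == pytest.approx(rr * math.exp(-1.96 * se))
        assert hi == pytest.approx(rr * math.exp(1.96 * se))

    def test_equal_proportions(self):
        rr, _, _ = st.relative_risk(st.TwoByTwo(10, 50, 10, 50))
        assert rr == 1.0

    def test_zero_events_a(self):
        rr, lo, hi = st.relative_risk(st.TwoByTwo(0, 50, 5, 50))
        assert rr == 0.0 and math.isnan(lo) and math.isnan(hi)

    def test_zero_events_b_rejected(self):
        with pytest.raises(ValueError):
            st.relative_risk(st.TwoByTwo(5, 50, 0, 50))

    def test_rate_percent(self):
        assert round(st.rate_percent(63, 168), 1) == 37.5
        assert round(st.rate_percent(17, 81), 1) == 21.0


# ---------------------------------------------------------------------------
# hosmer_lemeshow
# ---------------------------------------------------------------------------

class TestHosmerLemeshow:
    def test_two_group_hand_computation(self):
        probs = np.array([0.2] * 5 + [0.8] * 5)
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 0])
        chi2, p = st.hosmer_lemeshow(probs, labels, n_groups=2)
        # group lo: n=5, O=2, E=1.0 -> (2-1)^2/(5*0.2*0.8) = 1.25
        # group hi: n=5, O=4, E=4.0 -> 0
        assert chi2 == pytest.approx(1.25)
        assert p == pytest.approx(float(sps.chi2.sf(1.25, 1)))

    def test_perfectly_matched_rates(self):
        probs = np.full(40, 0.25)
        labels = np.array(([1] + [0] * 3) * 10)
        chi2, _ = st.hosmer_lemeshow(probs, labels, n_groups=2)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_case_order_invariance(self):
        r = np.random.default_rng(4)
        probs = r.uniform(0.05, 0.95, 200)
        labels = (r.random(200) < probs).astype(int)
        chi2_a, _ = st.hosmer_lemeshow(probs, labels)
        perm = r.permutation(200)
        chi2_b, _ = st.hosmer_lemeshow(probs[perm], labels[perm])
        assert chi2_a == pytest.approx(chi2_b)

    def test_type_one_error_uniform_p(self):
        """df = g - 2 is calibrated for probabilities from a fitted logistic
        model; under a correctly specified model the p-values are uniform."""
        import statsmodels.api as sm
        r = np.random.default_rng(11)
        pvals = []
        n = 400
        for _ in range(150):
            x = r.normal(size=n)
            eta = -0.3 + 1.1 * x
            labels = (r.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            fit = sm.Logit(labels, sm.add_constant(x)).fit(disp=False)
            probs = np.asarray(fit.predict())
            pvals.append(st.hosmer_lemeshow(probs, labels)[1])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            st.hosmer_lemeshow([0.5] * 5, [1] * 5, n_groups=10)


# ---------------------------------------------------------------------------
# decision_curve
# ---------------------------------------------------------------------------

class TestDecisionCurve:
    def test_treat_none_zero(self):
        df = st.decision_curve([0.9, 0.1], [1, 0], [0.2, 0.5])
        assert (df["treat_none"] == 0).all()

    def test_perfect_model(self):
        labels = np.array([1, 1, 0, 0, 0])
        df = st.decision_curve(labels.astype(float), labels, [0.1, 0.5, 0.9])
        assert np.allclose(df["net_benefit"], 0.4)

    def test_hand_computation_at_02(self):
        probs = np.array([0.9, 0.6, 0.3, 0.1])
        labels = np.array([1, 0, 1, 0])
        df = st.decision_curve(probs, labels, [0.2])
        # predictions at 0.2: [1,1,1,0] -> TP=2/4, FP=1/4, odds=0.25
        assert df["net_benefit"].iloc[0] == pytest.approx(0.5 - 0.25 * 0.25)
        assert df["treat_all"].iloc[0] == pytest.approx(0.5 - 0.5 * 0.25)

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            st.decision_curve([0.5], [1], [0.0, 0.5])


# ---------------------------------------------------------------------------
# bootstrap_ci
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_constant_statistic(self):
        lo, hi = st.bootstrap_ci(lambda x: 1.0, np.arange(50), n_boot=100, seed=0)
        assert lo == hi == 1.0

    def test_seed_determinism(self):
        data = np.random.default_rng(5).normal(size=100)
        a = st.bootstrap_ci(np.mean, data, n_boot=200, seed=42)
        b = st.bootstrap_ci(np.mean, data, n_boot=200, seed=42)
        c = st.bootstrap_ci(np.mean, data, n_boot=200, seed=43)
        assert a == b
        assert a != c

    def test_coverage_of_zero_mean(self):
        r = np.random.default_rng(6)
        cover = 0
        n_rep = 120
        for _ in range(n_rep):
            data = r.normal(size=200)
            lo, hi = st.bootstrap_ci(np.mean, data, n_boot=200,
                                     seed=int(r.integers(1 << 30)))
            cover += lo <= 0 <= hi
        assert 0.88 <= cover / n_rep <= 0.99

    def test_failures_skipped(self):
        def stat(x):
            if x.sum() % 2 == 0:
                raise RuntimeError("boom")
            return float(x.mean())
        lo, hi = st.bootstrap_ci(stat, np.arange(20), n_boot=100, seed=1)
        assert lo <= hi

    def test_n_boot_floor(self):
        with pytest.raises(ValueError):
            st.bootstrap_ci(np.mean, np.arange(10), n_boot=50)
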