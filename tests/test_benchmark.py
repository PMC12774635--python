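"""Labelling, classification statistics and group tests against oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from structbind.benchmark import (
    BenchmarkConfig,
    BenchmarkError,
    benchmark_report,
    bootstrap_ci,
    dunn_holm,
    label_pairs,
    mann_whitney_bh,
    orient_scores,
    pr_auc,
    roc_auc,
    spearman_vs_pbs,
    weighted_mcc,
)
from structbind.metrics import MetricSet
from structbind.model_io import AllelePair


def pair(pid, pbs, pbs_p, tf="TF1"):
    ref = "A" * 20 + "T" + "G" * 19
    alt = "A" * 20 + "C" + "G" * 19
    return AllelePair(pid, tf, "chr1", 100, "T", "C", ref, alt, 21, pbs, pbs_p)


class TestLabelPairs:
    def test_rules(self):
        pairs = [
            pair("a", 2.1, 0.005),
            pair("b", -3.0, 0.001),
            pair("c", -1.0, 0.6),
            pair("d", 1.0, 0.1),
        ]
        assert label_pairs(pairs) == ["ref_pref", "alt_pref", "non_pb", "unclassified"]

    def test_zero_pbs_with_significance_is_contradiction(self):
        with pytest.raises(BenchmarkError, match="PBS == 0"):
            label_pairs([pair("a", 0.0, 0.005)])


class TestOrientScores:
    def test_pb_task_orientations(self):
        out = orient_scores(
            {"d_iptm": np.array([-0.05]), "sasa_cor": np.array([0.95]),
             "ddg_max_iptm": np.array([-1.2])},
            "pb_vs_nonpb",
        )
        assert out["d_iptm"][0] == pytest.approx(0.05)
        assert out["sasa_cor"][0] == pytest.approx(-0.95)
        assert out["ddg_max_iptm"][0] == pytest.approx(-1.2)  # raw

    def test_direction_task_keeps_signs(self):
        out = orient_scores({"d_iptm": np.array([-0.05])}, "direction")
        assert out["d_iptm"][0] == pytest.approx(-0.05)

    def test_unknown_metric_rejected(self):
        with pytest.raises(BenchmarkError):
            orient_scores({"bogus": np.array([1.0])}, "direction")
        with pytest.raises(BenchmarkError):
            orient_scores({"sasa_cor": np.array([1.0])}, "direction")


def auc_bruteforce(scores, labels):
    """Concordant-pair counting oracle (ties count one half)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_and_tied(self):
        assert roc_auc([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0
        assert roc_auc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_worked_example(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_matches_bruteforce_on_random_data(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 8, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                auc_bruteforce(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        base = roc_auc(scores, labels)
        for f in (np.exp, np.tanh, lambda v: 3 * v + 7):
            assert roc_auc(f(scores), labels) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(BenchmarkError):
            roc_auc([1.0, 2.0], [1, 1])


def pr_auc_numeric(scores, labels, n_grid=200_000):
    """Fine-grained numerical integration oracle over interpolated TP."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order].astype(bool)
    s = np.asarray(scores)[order]
    tp = np.cumsum(y).astype(float)
    fp = np.cumsum(~y).astype(float)
    keep = np.r_[s[1:] != s[:-1], True]
    tp, fp = np.r_[0.0, tp[keep]], np.r_[0.0, fp[keep]]
    P = tp[-1]
    area = 0.0
    for (tpa, fpa), (tpb, fpb) in zip(zip(tp, fp), zip(tp[1:], fp[1:])):
        if tpb == tpa:
            continue
        xs = np.linspace(tpa, tpb, n_grid // len(tp) + 2)
        fps = fpa + (fpb - fpa) * (xs - tpa) / (tpb - tpa)
        with np.errstate(invalid="ignore"):
            prec = xs / (xs + fps)
        # 0/0 at the origin: precision limit along the segment is 1/(1+b)
        b = (fpb - fpa) / (tpb - tpa)
        prec[np.isnan(prec)] = 1.0 / (1.0 + b)
        area += np.trapezoid(prec, xs) / P
    return area


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc([4, 3, 2, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(31)
        n, pi = 4000, 0.3
        labels = (rng.random(n) < pi).astype(int)
        scores = rng.random(n)
        assert pr_auc(scores, labels) == pytest.approx(labels.mean(), abs=0.03)

    def test_matches_numerical_integration_oracle(self):
        cases = [
            ([0.9, 0.8, 0.7, 0.4, 0.3, 0.1], [1, 0, 1, 1, 0, 0]),
            ([0.9, 0.9, 0.5, 0.5, 0.2, 0.2], [1, 0, 1, 0, 1, 0]),
        ]
        rng = np.random.default_rng(41)
        for _ in range(20):
            n = int(rng.integers(5, 25))
            s = rng.integers(0, 6, size=n) / 6.0
            l = rng.integers(0, 2, size=n)
            if 0 < l.sum() < n:
                cases.append((s.tolist(), l.tolist()))
        for scores, labels in cases:
            assert pr_auc(scores, labels) == pytest.approx(
                pr_auc_numeric(scores, labels), abs=1e-6
            )

    def test_single_class_rejected(self):
        with pytest.raises(BenchmarkError):
            pr_auc([1.0, 2.0], [1, 1])


class TestBootstrapCi:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        a = bootstrap_ci(roc_auc, scores, labels, n_boot=200, seed=9)
        b = bootstrap_ci(roc_auc, scores, labels, n_boot=200, seed=9)
        assert a == b

    def test_constant_statistic_gives_zero_width(self):
        scores = np.r_[np.ones(20), np.zeros(20)]
        labels = np.r_[np.ones(20), np.zeros(20)].astype(int)
        lo, hi = bootstrap_ci(roc_auc, scores, labels, n_boot=100, seed=1)
        assert lo == hi == 1.0

    def test_nominal_coverage_on_simulated_datasets(self):
        """Percentile interval covers the true AUC at roughly nominal rate."""
        rng = np.random.default_rng(77)
        n_per, delta = 30, 1.0
        # true AUC of normal shift model: Phi(delta / sqrt(2))
        true_auc = stats.norm.cdf(delta / math.sqrt(2))
        hits = 0
        n_datasets = 200
        for k in range(n_datasets):
            x = np.r_[rng.normal(delta, 1, n_per), rng.normal(0, 1, n_per)]
            y = np.r_[np.ones(n_per), np.zeros(n_per)].astype(int)
            lo, hi = bootstrap_ci(roc_auc, x, y, n_boot=200, seed=1000 + k)
            hits += lo <= true_auc <= hi
        assert 0.90 <= hits / n_datasets <= 0.985

    def test_too_small_input_rejected(self):
        with pytest.raises(BenchmarkError):
            bootstrap_ci(roc_auc, np.ones(5), np.array([1, 1, 0, 0, 1]), seed=0)


class TestWeightedMcc:
    def test_perfect_agreement_is_one(self):
        rng = np.random.default_rng(3)
        signs = rng.choice([-1.0, 1.0], size=30)
        w = rng.uniform(0.1, 5, size=30)
        assert weighted_mcc(signs, signs, w) == pytest.approx(1.0)

    def test_unit_weights_equal_classical_mcc(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(13)
        checked = 0
        while checked < 300:
            n = int(rng.integers(4, 40))
            pred = rng.choice([-1.0, 1.0], size=n)
            true = rng.choice([-1.0, 1.0], size=n)
            ours = weighted_mcc(pred, true, np.ones(n))
            if ours is None:
                continue
            assert ours == pytest.approx(matthews_corrcoef(true, pred), abs=1e-12)
            checked += 1

    def test_heavy_error_drags_mcc_down(self):
        pred = np.array([1.0, 1, -1, -1, 1])
        true = np.array([1.0, 1, -1, -1, -1])  # last one wrong
        w_light = np.array([1.0, 1, 1, 1, 0.1])
        w_heavy = np.array([1.0, 1, 1, 1, 10.0])
        assert weighted_mcc(pred, true, w_heavy) < weighted_mcc(pred, true, w_light)

    def test_zero_margin_is_undefined(self):
        assert weighted_mcc([1.0, 1.0], [1.0, -1.0], [1.0, 1.0]) is None

    def test_bad_weights_rejected(self):
        with pytest.raises(BenchmarkError):
            weighted_mcc([1.0], [1.0], [0.0])
        with pytest.raises(BenchmarkError):
            weighted_mcc([1.0, -1.0], [1.0, 1.0], [1.0, -1.0])


def bh_oracle(ps):
    """Step-up Benjamini-Hochberg by the textbook formula."""
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        prev = min(prev, ps[idx] * m / k)
        adj[idx] = prev
    return adj


def holm_oracle(ps):
    """Step-down Holm by the textbook formula."""
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * ps[idx])
        adj[idx] = min(1.0, running)
    return adj


class TestMannWhitneyBH:
    def test_identical_groups_p_near_one(self):
        g = np.arange(20.0)
        out = mann_whitney_bh({"TF1": (g, g)})
        assert out["TF1"][0] > 0.9

    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            bh_oracle([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )
        # and the library path agrees with the oracle on random inputs
        rng = np.random.default_rng(19)
        from statsmodels.stats.multitest import multipletests

        for _ in range(200):
            ps = rng.uniform(0, 1, size=int(rng.integers(1, 12)))
            np.testing.assert_allclose(
                multipletests(ps, method="fdr_bh")[1], bh_oracle(ps), atol=1e-12
            )

    def test_adjusted_ge_raw_and_family_excludes_empty(self):
        rng = np.random.default_rng(29)
        groups = {
            f"TF{i}": (rng.normal(0, 1, 15), rng.normal(0.5, 1, 15))
            for i in range(4)
        }
        groups["EMPTY"] = (np.array([]), rng.normal(0, 1, 5))
        out = mann_whitney_bh(groups)
        assert out["EMPTY"] == (None, None)
        for tf in (f"TF{i}" for i in range(4)):
            raw, adj = out[tf]
            assert adj >= raw

    def test_agrees_with_permutation_oracle_small_n(self):
        rng = np.random.default_rng(37)
        x = rng.normal(0, 1, 8)
        y = rng.normal(1.2, 1, 8)
        p_asym = mann_whitney_bh({"t": (x, y)})["t"][0]
        # exact permutation distribution of U
        pooled = np.r_[x, y]
        u_obs = stats.mannwhitneyu(x, y).statistic
        count = 0
        trials = 20000
        for _ in range(trials):
            perm = rng.permutation(pooled)
            u = stats.mannwhitneyu(perm[:8], perm[8:]).statistic
            n1n2 = 64
            if abs(u - n1n2 / 2) >= abs(u_obs - n1n2 / 2):
                count += 1
        p_perm = count / trials
        assert p_asym == pytest.approx(p_perm, abs=0.02)


class TestDunnHolm:
    def test_holm_hand_example(self):
        np.testing.assert_allclose(holm_oracle([0.01, 0.04]), [0.02, 0.04])

    def test_holm_library_matches_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(43)
        for _ in range(200):
            ps = rng.uniform(0, 1, size=int(rng.integers(1, 10)))
            np.testing.assert_allclose(
                multipletests(ps, method="holm")[1], holm_oracle(ps), atol=1e-12
            )

    def test_null_simulation_rarely_significant(self):
        rng = np.random.default_rng(47)
        n_sig = 0
        n_sims = 40
        for _ in range(n_sims):
            g = {k: rng.normal(0, 1, 25) for k in "abc"}
            res = dunn_holm(g)
            n_sig += any(padj < 0.05 for _, _, padj in res.values())
        assert n_sig / n_sims < 0.25  # family-wise error stays controlled

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(53)
        g = {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40),
             "c": rng.normal(2.5, 1, 40)}
        res = dunn_holm(g)
        assert res[("a", "c")][2] < 0.01
        assert res[("b", "c")][2] < 0.01
        assert res[("a", "b")][2] > 0.05

    def test_identical_values_error(self):
        with pytest.raises(BenchmarkError):
            dunn_holm({"a": np.ones(5), "b": np.ones(5), "c": np.ones(5)})


class TestSpearmanVsPbs:
    def test_perfect_and_inverse(self):
        x = np.arange(12.0)
        rho, p = spearman_vs_pbs(x, x)
        assert rho == pytest.approx(1.0) and p == 0.0
        rho, _ = spearman_vs_pbs(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_monotone_with_noise_matches_scipy(self):
        rng = np.random.default_rng(59)
        x = rng.normal(size=60)
        y = x + rng.normal(0, 0.7, size=60)
        rho, p = spearman_vs_pbs(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_is_none(self):
        assert spearman_vs_pbs(np.ones(12), np.arange(12.0)) is None


class TestBenchmarkReport:
    @staticmethod
    def _cohort(rng, n=120, effect=1.0):
        pairs, sets = [], []
        for i in range(n):
            delta = 0.0 if rng.random() < 0.5 else effect * rng.choice([-1.0, 1.0])
            pbs = delta + rng.normal(0, 0.1)
            pbs_p = min(1.0, 2 * stats.norm.sf(abs(pbs) / 0.1))
            pairs.append(pair(f"p{i}", pbs, pbs_p))
            sets.append(
                MetricSet(
                    f"p{i}",
                    ddg_sym=delta + rng.normal(0, 0.1),
                    d_interface=delta + rng.normal(0, 0.1),
                    d_iptm=float(np.clip(delta + rng.normal(0, 0.1), -1, 1)),
                    ddg_max_iptm=abs(delta) + rng.normal(0, 0.1),
                    sasa_cor=float(1.0 - abs(delta) * rng.random()),
                )
            )
        return sets, pairs

    def test_strong_effect_recovers_direction(self):
        rng = np.random.default_rng(61)
        sets, pairs = self._cohort(rng)
        res = benchmark_report(sets, pairs, BenchmarkConfig(n_boot=50, seed=1))
        assert res.lookup_auc("pooled", "direction", "d_iptm") >= 0.95

    def test_zero_effect_aucs_near_half(self):
        rng = np.random.default_rng(67)
        sets, pairs = self._cohort(rng, effect=0.0)
        res = benchmark_report(sets, pairs, BenchmarkConfig(n_boot=50, seed=1))
        df = res.classification
        pooled = df[(df.group == "pooled") & (df.positive_class == 1)]
        assert ((pooled.auroc > 0.35) & (pooled.auroc < 0.65)).all()

    def test_report_deterministic(self, tmp_path):
        rng = np.random.default_rng(71)
        sets, pairs = self._cohort(rng, n=80)
        cfg = BenchmarkConfig(n_boot=50, seed=4)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        benchmark_report(sets, pairs, cfg).to_tsv(a)
        benchmark_report(sets, pairs, cfg).to_tsv(b)
        assert a.read_bytes() == b.read_bytes()

    def test_mismatched_pair_ids_rejected(self):
        rng = np.random.default_rng(73)
        sets, pairs = self._cohort(rng, n=40)
        with pytest.raises(BenchmarkError, match="mismatch"):
            benchmark_report(sets[:-1], pairs, BenchmarkConfig(n_boot=10, seed=1))

    def test_all_unclassified_rejected(self):
        pairs = [pair(f"p{i}", 0.5, 0.2) for i in range(20)]
        sets = [MetricSet(f"p{i}", d_iptm=0.1) for i in range(20)]
        with pytest.raises(BenchmarkError, match="labelled"):
            benchmark_report(sets, pairs, BenchmarkConfig(n_boot=10, seed=1))

    def test_tasks_subset_respected(self):
        rng = np.random.default_rng(79)
        sets, pairs = self._cohort(rng)
        res = benchmark_report(
            sets, pairs, BenchmarkConfig(tasks=("direction",), n_boot=20, seed=2)
        )
        assert set(res.classification.task) == {"direction"}
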