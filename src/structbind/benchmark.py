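"""SNP-SELEX-style benchmarking of structural allele-preference metrics.

Allele pairs are labelled from their preferential binding score (PBS)
statistics: significant pairs (p < .01) are preferentially bound (pbSNPs),
direction given by the PBS sign; clearly non-significant pairs (p > .5)
are non-pbSNPs; the intermediate band stays unclassified.  Metrics are
then evaluated on two tasks — separating pbSNPs from non-pbSNPs, and
calling the preference direction within pbSNPs — via ROC and
precision-recall AUCs with bootstrap confidence intervals, a
|PBS|-weighted Matthews correlation coefficient, Spearman correlation
against PBS over the full dataset, and nonparametric group tests
(Dunn/Holm across preference groups, Mann-Whitney/Benjamini-Hochberg
per transcription factor).
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model_io import AllelePair
from .metrics import MetricSet
from .sasa import DegenerateCorrelationError, spearman

__all__ = [
    "BenchmarkError",
    "BenchmarkConfig",
    "BenchmarkResult",
    "label_pairs",
    "orient_scores",
    "roc_auc",
    "pr_auc",
    "bootstrap_ci",
    "weighted_mcc",
    "mann_whitney_bh",
    "dunn_holm",
    "spearman_vs_pbs",
    "benchmark_report",
]

LABELS = ("ref_pref", "alt_pref", "non_pb", "unclassified")

#: metric -> orientation used when separating pbSNPs from non-pbSNPs.
#: Magnitudes discriminate for the signed metrics; the SASA correlation is
#: negated so that higher scores mean a shifted (more likely pb) site.
_PB_ORIENT: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "ddg_sym": np.abs,
    "d_interface": np.abs,
    "d_iptm": np.abs,
    "ddg_max_iptm": lambda v: v,
    "sasa_cor": lambda v: -v,
}
_DIRECTION_METRICS = ("ddg_sym", "d_interface", "d_iptm", "ddg_max_iptm")


class BenchmarkError(ValueError):
    """A benchmarking operation received invalid input."""


# ---------------------------------------------------------------------------
# Labelling and orientation
# ---------------------------------------------------------------------------

def label_pairs(pairs: Sequence[AllelePair]) -> list[str]:
    """PBS-based preference labels for each pair.

    p < .01 with positive PBS -> ``ref_pref``; with negative PBS ->
    ``alt_pref``; p > .5 -> ``non_pb``; anything else ``unclassified``.
    A significant pair with PBS exactly 0 is contradictory and an error.
    """
    labels = []
    for p in pairs:
        if p.pbs_p < 0.01:
            if p.pbs > 0:
                labels.append("ref_pref")
            elif p.pbs < 0:
                labels.append("alt_pref")
            else:
                raise BenchmarkError(
                    f"pair {p.pair_id}: significant (p={p.pbs_p}) but PBS == 0"
                )
        elif p.pbs_p > 0.5:
            labels.append("non_pb")
        else:
            labels.append("unclassified")
    return labels


def orient_scores(
    metric_values: Mapping[str, np.ndarray],
    task: str,
) -> dict[str, np.ndarray]:
    """Orient metric values for a classification task.

    ``pb_vs_nonpb`` uses |ddg_sym|, |d_interface|, |d_iptm|, raw
    ddg_max_iptm and negated sasa_cor (higher = more likely pb);
    ``direction`` uses the raw signed metrics with reference preference
    as the positive class.
    """
    if task == "pb_vs_nonpb":
        table = _PB_ORIENT
    elif task == "direction":
        table = {m: (lambda v: v) for m in _DIRECTION_METRICS}
    else:
        raise BenchmarkError(f"unknown task {task!r}")
    out = {}
    for name, values in metric_values.items():
        if name not in table:
            raise BenchmarkError(f"unknown metric {name!r} for task {task!r}")
        out[name] = table[name](np.asarray(values, dtype=float))
    return out


# ---------------------------------------------------------------------------
# Classification statistics
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC (Mann-Whitney concordance; ties count 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise BenchmarkError("both classes required for ROC AUC")
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _pr_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (TP, FP) at each distinct descending score threshold."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # keep the last index of each tied-score run
    keep = np.r_[s[1:] != s[:-1], True]
    return tp[keep].astype(float), fp[keep].astype(float)


def pr_auc(scores: np.ndarray, labels: np.ndarray, positive_class: int = 1) -> float:
    """Area under the precision-recall curve, Davis-Goadrich interpolation.

    Between consecutive operating points, false positives grow linearly in
    true positives, giving the nonlinear (hyperbolic) precision
    interpolation; each segment's area is integrated in closed form.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive_class
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise BenchmarkError("both classes required for PR AUC")
    tp, fp = _pr_points(scores, y)
    tp = np.r_[0.0, tp]
    fp = np.r_[0.0, fp]
    area = 0.0
    for (tpa, fpa), (tpb, fpb) in zip(zip(tp, fp), zip(tp[1:], fp[1:])):
        if tpb == tpa:
            continue  # recall unchanged, no area
        b = (fpb - fpa) / (tpb - tpa)
        a = fpa - b * tpa
        c = 1.0 + b
        # integral of x / (c x + a) dx over [tpa, tpb]
        if a == 0.0:
            seg = (tpb - tpa) / c
        else:
            seg = (tpb - tpa) / c - (a / c**2) * math.log(
                (c * tpb + a) / (c * tpa + a)
            )
        area += seg / n_pos
    return float(area)


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a score/label statistic.

    Cases are resampled with replacement; a resample containing a single
    class is redrawn (up to ``max_redraws`` attempts, then counted as
    undefined).  More than half the replicates undefined is an error.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(scores)
    if n < 10 or len(np.unique(labels)) < 2:
        raise BenchmarkError("need n >= 10 with both classes for bootstrap")
    rng = np.random.default_rng(seed)
    values = []
    n_undefined = 0
    for _ in range(n_boot):
        stat = None
        for _attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if len(np.unique(lab)) < 2:
                continue
            try:
                stat = statistic(scores[idx], lab)
            except (BenchmarkError, DegenerateCorrelationError):
                stat = None
            break
        if stat is None or not math.isfinite(stat):
            n_undefined += 1
        else:
            values.append(stat)
    if n_undefined > n_boot / 2:
        raise BenchmarkError(
            f"statistic undefined on {n_undefined}/{n_boot} bootstrap replicates"
        )
    lo, hi = np.percentile(values, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def weighted_mcc(
    predicted_sign: np.ndarray,
    true_sign: np.ndarray,
    weights: np.ndarray,
) -> float | None:
    """Matthews correlation on a weight-accumulated 2x2 table.

    Signs are +/-1; each observation contributes its weight (|PBS| in the
    benchmark) to the corresponding confusion cell, so strong experimental
    effects dominate and near-zero PBS pairs contribute minimally.
    Returns ``None`` when a table margin is zero (MCC undefined).
    """
    pred = np.sign(np.asarray(predicted_sign, dtype=float))
    true = np.sign(np.asarray(true_sign, dtype=float))
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise BenchmarkError("weights must be >= 0")
    if w.sum() == 0:
        raise BenchmarkError("weights must not all be zero")
    if not (set(np.unique(pred)) <= {-1.0, 1.0} and set(np.unique(true)) <= {-1.0, 1.0}):
        raise BenchmarkError("signs must be strictly +/- (no zeros)")
    tp = w[(pred > 0) & (true > 0)].sum()
    tn = w[(pred < 0) & (true < 0)].sum()
    fp = w[(pred > 0) & (true < 0)].sum()
    fn = w[(pred < 0) & (true > 0)].sum()
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return None
    return float((tp * tn - fp * fn) / math.sqrt(denom))


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def mann_whitney_bh(
    groups_by_tf: Mapping[str, tuple[np.ndarray, np.ndarray]],
    exact_small: bool = False,
) -> dict[str, tuple[float | None, float | None]]:
    """Two-sided Mann-Whitney U per TF, BH-adjusted across the TF family.

    Uses the tie- and continuity-corrected normal approximation (matching
    R's default); ``exact_small`` switches to the exact distribution when
    both groups have n <= 10 and no ties.  TFs with an empty group are
    reported as ``None`` and excluded from the adjustment family.
    """
    raw: dict[str, float | None] = {}
    for tf, (a, b) in groups_by_tf.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) == 0 or len(b) == 0:
            raw[tf] = None
            continue
        method = "asymptotic"
        if exact_small and len(a) <= 10 and len(b) <= 10:
            if len(np.unique(np.r_[a, b])) == len(a) + len(b):
                method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        raw[tf] = float(res.pvalue)
    family = [tf for tf, p in raw.items() if p is not None]
    out: dict[str, tuple[float | None, float | None]] = {
        tf: (None, None) for tf in raw
    }
    if family:
        adj = multipletests([raw[tf] for tf in family], method="fdr_bh")[1]
        for tf, p_adj in zip(family, adj):
            out[tf] = (raw[tf], float(p_adj))
    return out


def dunn_holm(
    groups: Mapping[str, np.ndarray],
) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Dunn's pairwise rank test with Holm correction.

    All observations are pooled and ranked once (average ranks for ties);
    the z statistic for a pair of groups compares their mean ranks under
    the tie-corrected Kruskal-Wallis variance.  Returns, per group pair,
    (z, raw two-sided p, Holm-adjusted p).
    """
    names = list(groups)
    if len(names) < 3:
        raise BenchmarkError("Dunn's test needs >= 3 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for nm, arr in zip(names, arrays):
        if len(arr) < 2:
            raise BenchmarkError(f"group {nm!r} has n < 2")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise BenchmarkError("all values identical: no rank variance")
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # tie correction: sum over tied groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(((counts**3) - counts).sum())
    var_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    mean_ranks = {}
    start = 0
    for nm, arr in zip(names, arrays):
        mean_ranks[nm] = ranks[start:start + len(arr)].mean()
        start += len(arr)
    sizes = {nm: len(arr) for nm, arr in zip(names, arrays)}
    comparisons = [
        (a, b) for i, a in enumerate(names) for b in names[i + 1:]
    ]
    zs, raws = [], []
    for a, b in comparisons:
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        zs.append(z)
        raws.append(2.0 * stats.norm.sf(abs(z)))
    adj = multipletests(raws, method="holm")[1]
    return {
        pair: (float(z), float(p), float(pa))
        for pair, z, p, pa in zip(comparisons, zs, raws, adj)
    }


def spearman_vs_pbs(
    metric_values: np.ndarray,
    pbs_values: np.ndarray,
) -> tuple[float, float] | None:
    """Spearman rho between a metric and PBS, with a t-approximation p.

    Returns ``None`` when either input is constant (correlation
    undefined).  Requires at least 10 paired observations.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(pbs_values, dtype=float)
    if len(x) != len(y) or len(x) < 10:
        raise BenchmarkError("need >= 10 paired observations")
    try:
        rho = spearman(x, y)
    except DegenerateCorrelationError:
        return None
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


# ---------------------------------------------------------------------------
# Report composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkConfig:
    tasks: tuple[str, ...] = ("pb_vs_nonpb", "direction")
    n_boot: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    min_class_n: int = 5  # smallest class size for AUC rows


@dataclass
class BenchmarkResult:
    """Per-TF and pooled benchmark statistics.

    ``classification``: rows (group, task, metric, positive_class, n_pos,
    n_neg, auroc, pr_auc, pr_lo, pr_hi).  ``mcc``: rows (group, metric,
    weighted_mcc).  ``correlation``: rows (group, metric, rho, p).
    ``dunn``: rows (metric, group_a, group_b, z, p, p_holm).
    ``mann_whitney``: rows (metric, tf, p, p_bh).
    """

    classification: pd.DataFrame
    mcc: pd.DataFrame
    correlation: pd.DataFrame
    dunn: pd.DataFrame
    mann_whitney: pd.DataFrame
    class_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        frames = []
        for section, df in (
            ("classification", self.classification),
            ("mcc", self.mcc),
            ("correlation", self.correlation),
            ("dunn", self.dunn),
            ("mann_whitney", self.mann_whitney),
        ):
            if len(df):
                d = df.copy()
                d.insert(0, "section", section)
                frames.append(d)
        pd.concat(frames, ignore_index=True).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classification": self.classification.to_dict(orient="records"),
            "mcc": self.mcc.to_dict(orient="records"),
            "correlation": self.correlation.to_dict(orient="records"),
            "dunn": self.dunn.to_dict(orient="records"),
            "mann_whitney": self.mann_whitney.to_dict(orient="records"),
            "class_counts": self.class_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))

    def lookup_auc(self, group: str, task: str, metric: str) -> float:
        df = self.classification
        row = df[
            (df["group"] == group) & (df["task"] == task) & (df["metric"] == metric)
        ]
        if row.empty:
            raise KeyError((group, task, metric))
        return float(row.iloc[0]["auroc"])


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if o is None or (isinstance(o, float) and math.isnan(o)):
        return None
    raise TypeError(type(o))


def _metric_frame(metric_sets: Sequence[MetricSet]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [m.pair_id for m in metric_sets],
            "ddg_sym": [m.ddg_sym for m in metric_sets],
            "d_interface": [m.d_interface for m in metric_sets],
            "d_iptm": [m.d_iptm for m in metric_sets],
            "ddg_max_iptm": [m.ddg_max_iptm for m in metric_sets],
            "sasa_cor": [m.sasa_cor for m in metric_sets],
        }
    )


def benchmark_report(
    metric_sets: Sequence[MetricSet],
    pairs: Sequence[AllelePair],
    config: BenchmarkConfig | None = None,
) -> BenchmarkResult:
    """Evaluate every metric per TF and pooled, as in the study design.

    The pb-vs-nonpb task uses labelled pairs only; the direction task uses
    pbSNPs only; Spearman correlations against PBS use the full dataset
    including unclassified pairs.  Metric sets and pairs must cover the
    same pair_ids.
    """
    config = config or BenchmarkConfig()
    mdf = _metric_frame(metric_sets)
    pdf = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "tf": [p.tf for p in pairs],
            "pbs": [p.pbs for p in pairs],
            "label": label_pairs(pairs),
        }
    )
    if set(mdf.pair_id) != set(pdf.pair_id):
        only_m = sorted(set(mdf.pair_id) - set(pdf.pair_id))[:5]
        only_p = sorted(set(pdf.pair_id) - set(mdf.pair_id))[:5]
        raise BenchmarkError(
            f"pair_id mismatch between metrics and PBS table "
            f"(metrics-only: {only_m}..., pbs-only: {only_p}...)"
        )
    df = pdf.merge(mdf, on="pair_id", validate="one_to_one")
    if not (df.label.isin(("ref_pref", "alt_pref", "non_pb"))).any():
        raise BenchmarkError("no labelled pairs (all unclassified)")

    groups = ["pooled"] + sorted(df.tf.unique())
    cls_rows, mcc_rows, cor_rows, mw_rows = [], [], [], []
    dunn_rows = []
    class_counts: dict[str, dict[str, int]] = {}

    def subset(group: str) -> pd.DataFrame:
        return df if group == "pooled" else df[df.tf == group]

    for group in groups:
        sub = subset(group)
        class_counts[group] = sub.label.value_counts().to_dict()

        if "pb_vs_nonpb" in config.tasks:
            labelled = sub[sub.label.isin(("ref_pref", "alt_pref", "non_pb"))]
            y = (labelled.label != "non_pb").to_numpy().astype(int)
            for metric in _PB_ORIENT:
                vals = labelled[metric].to_numpy(dtype=float)
                ok = np.isfinite(vals)
                yv, sv = y[ok], vals[ok]
                if min((yv == 1).sum(), (yv == 0).sum()) < config.min_class_n:
                    continue
                sv = orient_scores({metric: sv}, "pb_vs_nonpb")[metric]
                _add_cls_rows(
                    cls_rows, group, "pb_vs_nonpb", metric, sv, yv, config
                )

        if "direction" in config.tasks:
            pb = sub[sub.label.isin(("ref_pref", "alt_pref"))]
            y = (pb.label == "ref_pref").to_numpy().astype(int)
            for metric in _DIRECTION_METRICS:
                vals = pb[metric].to_numpy(dtype=float)
                ok = np.isfinite(vals)
                yv, sv = y[ok], vals[ok]
                if min((yv == 1).sum(), (yv == 0).sum()) < config.min_class_n:
                    continue
                sv = orient_scores({metric: sv}, "direction")[metric]
                _add_cls_rows(cls_rows, group, "direction", metric, sv, yv, config)
                nz = sv != 0
                if nz.sum() >= config.min_class_n:
                    w = np.abs(pb.pbs.to_numpy(dtype=float)[ok][nz])
                    mcc = weighted_mcc(
                        np.sign(sv[nz]), np.where(yv[nz] == 1, 1.0, -1.0), w
                    )
                    mcc_rows.append(
                        {"group": group, "metric": metric, "weighted_mcc": mcc}
                    )

        for metric in _PB_ORIENT:
            vals = sub[metric].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if ok.sum() >= 10:
                res = spearman_vs_pbs(vals[ok], sub.pbs.to_numpy(dtype=float)[ok])
                if res is not None:
                    cor_rows.append(
                        {"group": group, "metric": metric,
                         "rho": res[0], "p": res[1]}
                    )

    # pooled Dunn tests across the three preference groups
    for metric in _PB_ORIENT:
        gd = {}
        for lab in ("ref_pref", "alt_pref", "non_pb"):
            vals = df.loc[df.label == lab, metric].dropna().to_numpy(dtype=float)
            if len(vals) >= 2:
                gd[lab] = vals
        if len(gd) == 3:
            try:
                res = dunn_holm(gd)
            except BenchmarkError:
                continue
            for (a, b), (z, p, ph) in res.items():
                dunn_rows.append(
                    {"metric": metric, "group_a": a, "group_b": b,
                     "z": z, "p": p, "p_holm": ph}
                )

    # per-TF Mann-Whitney, pb vs non-pb, on each oriented metric
    if "pb_vs_nonpb" in config.tasks:
        for metric in _PB_ORIENT:
            by_tf = {}
            for tf in sorted(df.tf.unique()):
                sub = df[df.tf == tf]
                pb_vals = sub.loc[
                    sub.label.isin(("ref_pref", "alt_pref")), metric
                ].dropna().to_numpy(dtype=float)
                npb_vals = sub.loc[sub.label == "non_pb", metric].dropna().to_numpy(
                    dtype=float
                )
                pb_o = orient_scores({metric: pb_vals}, "pb_vs_nonpb")[metric]
                npb_o = orient_scores({metric: npb_vals}, "pb_vs_nonpb")[metric]
                by_tf[tf] = (pb_o, npb_o)
            for tf, (p_raw, p_bh) in mann_whitney_bh(by_tf).items():
                mw_rows.append(
                    {"metric": metric, "tf": tf, "p": p_raw, "p_bh": p_bh}
                )

    return BenchmarkResult(
        classification=pd.DataFrame(
            cls_rows,
            columns=["group", "task", "metric", "positive_class", "n_pos",
                     "n_neg", "auroc", "pr_auc", "pr_lo", "pr_hi"],
        ),
        mcc=pd.DataFrame(mcc_rows, columns=["group", "metric", "weighted_mcc"]),
        correlation=pd.DataFrame(cor_rows, columns=["group", "metric", "rho", "p"]),
        dunn=pd.DataFrame(
            dunn_rows, columns=["metric", "group_a", "group_b", "z", "p", "p_holm"]
        ),
        mann_whitney=pd.DataFrame(mw_rows, columns=["metric", "tf", "p", "p_bh"]),
        class_counts=class_counts,
    )


def _add_cls_rows(rows, group, task, metric, scores, y, config: BenchmarkConfig):
    auroc = roc_auc(scores, y)
    # PR analysis with each class as the positive
    for positive in (1, 0):
        s = scores if positive == 1 else -scores
        yy = (y == positive).astype(int)
        pr = pr_auc(s, yy, positive_class=1)
        tag = zlib.crc32(f"{group}|{task}|{metric}|{positive}".encode())
        seed = (config.seed + tag) % (2**31)
        try:
            lo, hi = bootstrap_ci(
                lambda sc, lb: pr_auc(sc, lb, positive_class=1),
                s, yy, n_boot=config.n_boot, seed=seed, level=config.ci_level,
            )
        except BenchmarkError:
            lo = hi = float("nan")  # too few cases for a resampling interval
        rows.append(
            {
                "group": group, "task": task, "metric": metric,
                "positive_class": positive,
                "n_pos": int((y == 1).sum()), "n_neg": int((y == 0).sum()),
                "auroc": auroc, "pr_auc": pr, "pr_lo": lo, "pr_hi": hi,
            }
        )
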