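"""Evaluation machinery: ROC/AUC, DeLong's test, Youden threshold,
diagnostic metrics, relative risk with Katz CIs, Hosmer-Lemeshow
calibration, decision-curve analysis and seeded bootstrap CIs.

AUC uses the Mann-Whitney convention (ties counted half); DeLong placement
values use the same convention.  No multiple-testing adjustment is applied
anywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoByTwo:
    """Event counts in two groups (group A vs group B)."""

    events_a: int
    n_a: int
    events_b: int
    n_b: int

    def __post_init__(self) -> None:
        if self.n_a <= 0 or self.n_b <= 0:
            raise ValueError("group sizes must be positive")
        if not (0 <= self.events_a <= self.n_a and 0 <= self.events_b <= self.n_b):
            raise ValueError("event counts must lie in [0, n]")

    @property
    def rate_a(self) -> float:
        return self.events_a / self.n_a

    @property
    def rate_b(self) -> float:
        return self.events_b / self.n_b


@dataclass
class DiagnosticReport:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float   # percent
    specificity: float   # percent
    ppv: float           # percent (nan when undefined)
    npv: float           # percent (nan when undefined)
    threshold: float

    def __post_init__(self) -> None:
        lo, hi = self.auc_ci
        if not lo <= self.auc <= hi:
            raise ValueError("AUC must lie inside its confidence interval")


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    return (y == classes.max()).astype(int)


def roc_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count half)."""
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be the same length")
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (V10 for positives, V01 for negatives)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((n < pos) + 0.5 * (n == pos)) for n in neg])
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """Compare two correlated AUCs (paired scores on the same cases).

    Returns (auc_a, auc_b, z, two-sided p).  Identical score vectors give
    z = 0, p = 1; a degenerate variance with unequal AUCs is rejected.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = _check_binary(labels)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must be the same length")
    auc_a = roc_auc(sa, y)
    auc_b = roc_auc(sb, y)
    v10a, v01a = _placements(sa, y)
    v10b, v01b = _placements(sb, y)
    n1, n0 = v10a.size, v01a.size
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0)
    diff = auc_a - auc_b
    if var <= 0 or not math.isfinite(var):
        if math.isclose(diff, 0.0, abs_tol=1e-12):
            return auc_a, auc_b, 0.0, 1.0
        raise ValueError("degenerate DeLong variance with unequal AUCs; "
                         "scores may be constant")
    z = diff / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def youden_threshold(scores, labels) -> tuple[float, float]:
    """Threshold (predict positive when score >= threshold) maximizing
    J = sensitivity + specificity - 1; ties broken toward higher
    specificity, then toward the higher threshold."""
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    best = None
    for cut in np.unique(s):
        pred = s >= cut
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        j = sens + spec - 1.0
        key = (j, spec, cut)
        if best is None or key > best[0]:
            best = (key, float(cut), float(j))
    return best[1], best[2]


def diagnostic_metrics(predictions, labels) -> dict[str, float]:
    """Sensitivity/specificity/PPV/NPV as percentages.

    Undefined cells (no predicted positives/negatives, or a missing class)
    are reported as NaN, never silently as zero.
    """
    pred = np.asarray(predictions).astype(bool)
    y = np.asarray(labels).astype(bool)
    if pred.size == 0 or pred.shape != y.shape:
        raise ValueError("predictions and labels must be equal-length and nonempty")
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())

    def pct(num, den):
        return 100.0 * num / den if den > 0 else math.nan

    return {"sensitivity": pct(tp, tp + fn), "specificity": pct(tn, tn + fp),
            "ppv": pct(tp, tp + fp), "npv": pct(tn, tn + fn)}


def relative_risk(table: TwoByTwo) -> tuple[float, float, float]:
    """Risk ratio A/B with a 95% Katz log-method CI.

    Zero events in group A give rr = 0 with a non-estimable (NaN) CI; zero
    events in group B make the ratio infinite and are rejected.
    """
    if table.events_b == 0:
        raise ValueError("relative risk not estimable: no events in group B")
    rr = table.rate_a / table.rate_b
    if table.events_a == 0:
        return 0.0, math.nan, math.nan
    se = math.sqrt(1.0 / table.events_a - 1.0 / table.n_a
                   + 1.0 / table.events_b - 1.0 / table.n_b)
    lo = math.exp(math.log(rr) - 1.96 * se)
    hi = math.exp(math.log(rr) + 1.96 * se)
    return rr, lo, hi


def rate_percent(events: int, n: int) -> float:
    """Group event percentage, 100 * events / n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= events <= n:
        raise ValueError("events must lie in [0, n]")
    return 100.0 * events / n


def hosmer_lemeshow(probs, labels, n_groups: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-fit over deciles of predicted risk.

    Groups are quantile bins of the predicted probabilities; empty bins are
    merged with their neighbour (logged).  chi2 has df = g - 2.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probs and labels must be equal-length 1D arrays")
    if p.size < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} cases for {n_groups} groups")
    edges = np.quantile(p, np.linspace(0, 1, n_groups + 1))
    edges = np.unique(edges)
    if edges.size - 1 < n_groups:
        logger.warning("tied probabilities: merged to %d groups", edges.size - 1)
    bins = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, edges.size - 2)
    chi2 = 0.0
    g = 0
    for b in np.unique(bins):
        sel = bins == b
        n = int(sel.sum())
        if n == 0:  # pragma: no cover - unique() excludes empty bins
            continue
        obs = y[sel].sum()
        exp = p[sel].sum()
        pbar = exp / n
        denom = n * pbar * (1.0 - pbar)
        if denom <= 0:
            logger.warning("degenerate calibration group (mean prob %.3f) skipped", pbar)
            continue
        chi2 += (obs - exp) ** 2 / denom
        g += 1
    df = max(g - 2, 1)
    return float(chi2), float(sps.chi2.sf(chi2, df))


def decision_curve(probs, labels, threshold_grid) -> pd.DataFrame:
    """Net benefit per decision threshold, with treat-all / treat-none
    references: NB = TP/n - FP/n * t/(1-t)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(bool)
    t = np.asarray(threshold_grid, dtype=float)
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = y.size
    prev = y.mean()
    rows = []
    for thr in t:
        pred = p >= thr
        tp = (pred & y).sum() / n
        fp = (pred & ~y).sum() / n
        odds = thr / (1.0 - thr)
        rows.append((thr, tp - fp * odds, prev - (1 - prev) * odds, 0.0))
    return pd.DataFrame(rows, columns=["threshold", "net_benefit",
                                       "treat_all", "treat_none"])


def bootstrap_ci(statistic, data, n_boot: int = 1000, seed: int = 0,
                 ci: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI; deterministic for a fixed seed.

    `data` is an array or a tuple of aligned arrays resampled jointly.
    Resamples on which the statistic raises or returns NaN are skipped and
    their count logged.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    arrays = data if isinstance(data, tuple) else (np.asarray(data),)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = arrays[0].shape[0]
    rng = np.random.default_rng(seed)
    vals = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = tuple(a[idx] for a in arrays)
        try:
            v = statistic(*sample) if isinstance(data, tuple) else statistic(sample[0])
        except Exception:
            failures += 1
            continue
        if v is None or not math.isfinite(v):
            failures += 1
            continue
        vals.append(float(v))
    if failures:
        logger.warning("bootstrap: %d of %d resamples failed and were skipped",
                       failures, n_boot)
    if not vals:
        raise ValueError("statistic failed on every bootstrap resample")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
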