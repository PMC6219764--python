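"""Evaluation statistics for multi-site classifier studies.

AUC with DeLong variance and comparison tests, exact binomial (Clopper-
Pearson) intervals, chi-square tests of proportions, screening operating
points at a target sensitivity, the trivial prevalence-only ranker, and
calibration summaries.

The DeLong machinery is implemented here with the midrank formulation;
it is cross-checked in the test suite against brute-force enumeration of
positive-negative pairs and against a leave-one-out jackknife of the AUC
difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ScoredSet",
    "AUCEstimate",
    "ComparisonResult",
    "OperatingPoint",
    "CalibrationSummary",
    "auc",
    "delong_paired",
    "delong_unpaired",
    "clopper_pearson",
    "chi_square_proportions",
    "operating_point_at_sensitivity",
    "trivial_prevalence_ranker",
    "calibration_summary",
]


@dataclass
class ScoredSet:
    """Per-case continuous scores with binary labels (1 = diseased)."""

    scores: np.ndarray
    labels: np.ndarray
    sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have the same length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


@dataclass
class AUCEstimate:
    auc: float
    variance: float
    ci: tuple[float, float]


@dataclass
class ComparisonResult:
    delta_auc: float
    z: float
    p: float
    mode: str  # "paired" | "unpaired"


@dataclass
class RateWithCI:
    value: float
    ci: tuple[float, float]
    successes: int
    n: int


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: RateWithCI
    specificity: RateWithCI
    accuracy: RateWithCI
    ppv: RateWithCI
    npv: RateWithCI


@dataclass
class CalibrationSummary:
    slope: float | None
    intercept: float | None
    bins: list[tuple[float, float, int]]  # (mean predicted, observed rate, n)
    degenerate: bool = False


# ---------------------------------------------------------------------------
# DeLong structural components


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based); tied values share the average rank."""
    return sps.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """Return (auc, V10, V01): placement values for positives and negatives.

    V10[i] = P(score_neg < pos_i) + 0.5 P(score_neg == pos_i), and
    symmetrically for V01. The AUC is the mean of either vector.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute an AUC")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    a = v10.mean()
    return a, v10, v01


def auc(scored: ScoredSet, confidence: float = 0.95) -> AUCEstimate:
    """Mann-Whitney AUC (ties count one half) with DeLong variance.

    The confidence interval is a normal approximation on the AUC scale,
    clipped to [0, 1].
    """
    a, v10, v01 = _structural_components(scored.scores, scored.labels)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = sps.norm.ppf(0.5 + confidence / 2)
    half = z * math.sqrt(max(var, 0.0))
    ci = (max(0.0, a - half), min(1.0, a + half))
    return AUCEstimate(auc=float(a), variance=float(max(var, 0.0)), ci=ci)


def delong_paired(scores_a, scores_b, labels) -> ComparisonResult:
    """Paired DeLong test for two score vectors over the same cases."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired comparison requires identical case sets")
    a1, v10_a, v01_a = _structural_components(scores_a, labels)
    a2, v10_b, v01_b = _structural_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    delta = a1 - a2
    var = 0.0
    if m > 1:
        s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-16:
        if abs(delta) > 1e-12:
            warnings.warn(
                "degenerate DeLong variance with nonzero AUC difference",
                stacklevel=2,
            )
        return ComparisonResult(delta_auc=float(delta), z=0.0, p=1.0, mode="paired")
    z = delta / math.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return ComparisonResult(delta_auc=float(delta), z=float(z), p=float(p), mode="paired")


def delong_unpaired(scored_a: ScoredSet, scored_b: ScoredSet) -> ComparisonResult:
    """Unpaired DeLong test for AUCs from two independent case sets."""
    est_a = auc(scored_a)
    est_b = auc(scored_b)
    delta = est_a.auc - est_b.auc
    var = est_a.variance + est_b.variance
    if var <= 1e-16:
        if abs(delta) > 1e-12:
            warnings.warn(
                "degenerate DeLong variance with nonzero AUC difference",
                stacklevel=2,
            )
        return ComparisonResult(delta_auc=float(delta), z=0.0, p=1.0, mode="unpaired")
    z = delta / math.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return ComparisonResult(delta_auc=float(delta), z=float(z), p=float(p), mode="unpaired")


# ---------------------------------------------------------------------------
# Proportions


def clopper_pearson(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles.

    Lower bound is exactly 0 when successes = 0 and the upper bound exactly
    1 when successes = n.
    """
    if n < 1 or successes < 0 or successes > n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    alpha = 1.0 - confidence
    lower = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def chi_square_proportions(
    successes, totals, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test comparing m proportions.

    ``successes[i] / totals[i]`` are the group proportions; the statistic is
    computed on the implied 2 x m contingency table with m - 1 degrees of
    freedom, without continuity correction by default.
    """
    successes = np.asarray(successes, dtype=np.int64)
    totals = np.asarray(totals, dtype=np.int64)
    if (successes < 0).any() or (successes > totals).any():
        raise ValueError("need 0 <= successes <= totals per group")
    table = np.stack([successes, totals - successes])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined for a zero margin")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Screening operating point


def _rate(successes: int, n: int) -> RateWithCI:
    value = successes / n if n else float("nan")
    ci = clopper_pearson(successes, n) if n else (float("nan"), float("nan"))
    return RateWithCI(value=value, ci=ci, successes=int(successes), n=int(n))


def operating_point_at_sensitivity(scored: ScoredSet, target: float = 0.95) -> OperatingPoint:
    """Choose the highest threshold guaranteeing sensitivity >= target.

    The threshold is the ceil(target * n_pos)-th largest positive score;
    cases scoring at or above the threshold are called positive, so tied
    scores are classified positive (sensitivity can only exceed the target).
    This mimics a screening deployment where missing cases is the costly
    error.
    """
    if not 0 < target <= 1:
        raise ValueError("target sensitivity must be in (0, 1]")
    pos_scores = scored.scores[scored.labels == 1]
    n_pos = len(pos_scores)
    if n_pos == 0:
        raise ValueError("operating point requires at least one positive case")
    k = math.ceil(target * n_pos)
    threshold = float(np.sort(pos_scores)[::-1][k - 1])
    pred = scored.scores >= threshold
    tp = int(np.sum(pred & (scored.labels == 1)))
    fn = n_pos - tp
    fp = int(np.sum(pred & (scored.labels == 0)))
    tn = int(np.sum(~pred & (scored.labels == 0)))
    return OperatingPoint(
        threshold=threshold,
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        accuracy=_rate(tp + tn, len(scored.scores)),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
    )


def trivial_prevalence_ranker(sites, train_prevalence: dict) -> np.ndarray:
    """Score each case by its site's training-data disease prevalence.

    The resulting ranker ignores the image entirely; its AUC on a pooled
    test set measures how much of apparent performance is attributable to
    between-site prevalence differences alone.
    """
    sites = np.asarray(sites)
    unknown = set(np.unique(sites)) - set(train_prevalence)
    if unknown:
        raise ValueError(f"no training prevalence for site(s): {sorted(unknown)}")
    return np.array([train_prevalence[s] for s in sites], dtype=float)


def two_level_ranker_auc(p_pos_hi: float, p_neg_hi: float) -> float:
    """Closed-form AUC of a two-valued ranker.

    ``p_pos_hi`` is the fraction of positives carrying the higher score and
    ``p_neg_hi`` the fraction of negatives carrying it; ties count one half:
    AUC = P(pos hi, neg lo) + 0.5 [P(pos hi, neg hi) + P(pos lo, neg lo)].
    """
    p_pos_lo = 1.0 - p_pos_hi
    p_neg_lo = 1.0 - p_neg_hi
    return p_pos_hi * p_neg_lo + 0.5 * (p_pos_hi * p_neg_hi + p_pos_lo * p_neg_lo)


# ---------------------------------------------------------------------------
# Calibration


def calibration_summary(probabilities, labels, n_bins: int = 10) -> CalibrationSummary:
    """Logistic-recalibration slope/intercept plus reliability-plot bins.

    Observed outcomes are regressed on logit(predicted probability); a slope
    of 1 with intercept 0 indicates well-spread calibration, slopes below 1
    overconfidence and above 1 underconfidence. Probabilities are clamped
    away from {0, 1} (with a warning) before taking logits. Constant
    probability vectors have no defined slope and are flagged degenerate.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have the same length")
    if len(np.unique(y)) < 2:
        raise ValueError("calibration requires both outcome classes")
    eps = 1e-6
    if (p <= 0).any() or (p >= 1).any():
        warnings.warn("probabilities clamped to (1e-6, 1 - 1e-6)", stacklevel=2)
    p = np.clip(p, eps, 1 - eps)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    bins = []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            bins.append((float(p[mask].mean()), float(y[mask].mean()), int(mask.sum())))

    logits = np.log(p / (1 - p))
    if np.ptp(logits) < 1e-12:
        return CalibrationSummary(slope=None, intercept=None, bins=bins, degenerate=True)
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    lr.fit(logits.reshape(-1, 1), y)
    return CalibrationSummary(
        slope=float(lr.coef_[0, 0]),
        intercept=float(lr.intercept_[0]),
        bins=bins,
        degenerate=False,
    )
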