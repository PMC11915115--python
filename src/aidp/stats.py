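"""AUROC and DeLong inference, confusion metrics, multiple-testing control,
pooled run summaries, severity regressions, power analysis, and pathology
concordance accounting."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

#: Null AUROC for endpoint z tests; matches the study's power design.
NULL_AUROC_DEFAULT = 0.80


class StatsError(ValueError):
    """Raised for degenerate statistical input."""


@dataclass(frozen=True)
class ScoreSet:
    """Probability scores grouped by true class."""

    positives: np.ndarray
    negatives: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positives, dtype=float).ravel()
        neg = np.asarray(self.negatives, dtype=float).ravel()
        if pos.size < 1 or neg.size < 1:
            raise StatsError("need at least one score in each class")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
            raise StatsError("scores must be finite")
        object.__setattr__(self, "positives", pos)
        object.__setattr__(self, "negatives", neg)

    @classmethod
    def from_labels(cls, scores, labels, positive_label=1) -> "ScoreSet":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels)
        is_pos = labels == positive_label
        return cls(scores[is_pos], scores[~is_pos])


def auroc(scores: ScoreSet) -> float:
    """Mann-Whitney AUROC: P(pos > neg) + 0.5 * P(pos == neg)."""
    pos, neg = scores.positives, scores.negatives
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def _placements(scores: ScoreSet) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components (placement values) per positive/negative."""
    pos, neg = scores.positives, scores.negatives
    cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)  # V10 (per pos), 1-V01


def delong_variance(scores: ScoreSet) -> float:
    """Variance of the AUROC estimator from DeLong placement components."""
    pos, neg = scores.positives, scores.negatives
    if pos.size < 2 or neg.size < 2:
        raise StatsError("DeLong variance needs >= 2 scores per class")
    v10, v01_c = _placements(scores)
    v01 = 1.0 - v01_c
    s10 = np.var(v10, ddof=1)
    s01 = np.var(v01, ddof=1)
    return float(s10 / pos.size + s01 / neg.size)


def delong_ci(
    scores: ScoreSet, level: float = 0.95
) -> tuple[float, float, float, float]:
    """(auroc, ci_low, ci_high, variance); normal CI truncated to [0, 1]."""
    a = auroc(scores)
    var = delong_variance(scores)
    if var == 0.0:
        return a, a, a, 0.0
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return a, max(0.0, a - half), min(1.0, a + half), var


def auroc_z_test(
    scores: ScoreSet, null_auroc: float = NULL_AUROC_DEFAULT, one_sided: bool = True
) -> float:
    """z test of AUROC against a null value using the DeLong variance.

    One-sided upper-tail by default. Zero variance: p is 0.0 if the estimate
    beats the null, 1.0 if it trails, 0.5 at equality.
    """
    a = auroc(scores)
    var = delong_variance(scores)
    if var == 0.0:
        if a == null_auroc:
            return 0.5
        p_upper = 0.0 if a > null_auroc else 1.0
        return p_upper if one_sided else (0.0 if a != null_auroc else 1.0)
    z = (a - null_auroc) / math.sqrt(var)
    p_upper = float(sps.norm.sf(z))
    return p_upper if one_sided else float(2 * sps.norm.sf(abs(z)))


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def confusion_metrics(predictions, truths, positive_class=1) -> ConfusionMetrics:
    """Standard 2x2-table metrics; undefined ratios reported as None."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise StatsError("predictions/truths length mismatch")
    pos_truth = truths == positive_class
    if not pos_truth.any() or pos_truth.all():
        raise StatsError("need >= 1 positive and >= 1 negative truth")
    pos_pred = predictions == positive_class
    tp = int(np.sum(pos_pred & pos_truth))
    fp = int(np.sum(pos_pred & ~pos_truth))
    tn = int(np.sum(~pos_pred & ~pos_truth))
    fn = int(np.sum(~pos_pred & pos_truth))

    def ratio(num, den):
        return num / den if den > 0 else None

    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise StatsError("p_values must be a nonempty 1D sequence")
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


@dataclass(frozen=True)
class PooledSummary:
    mean_auroc: float
    ci_low: float | None
    ci_high: float | None
    n_runs: int


def pooled_summary(run_aurocs, level: float = 0.95) -> PooledSummary:
    """Mean AUROC over verification runs with a t-based CI on the mean."""
    runs = np.asarray(run_aurocs, dtype=float)
    if runs.size < 1:
        raise StatsError("no runs")
    mean = float(runs.mean())
    if runs.size == 1:
        return PooledSummary(mean, None, None, 1)
    se = runs.std(ddof=1) / math.sqrt(runs.size)
    half = float(sps.t.ppf(0.5 + level / 2, runs.size - 1) * se)
    return PooledSummary(mean, mean - half, mean + half, int(runs.size))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress_probability(probabilities, covariate) -> RegressionResult:
    """OLS of probability on a covariate with a two-sided slope test."""
    y = np.asarray(probabilities, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.size != x.size:
        raise StatsError("length mismatch")
    if y.size < 3:
        raise StatsError("need n >= 3")
    if np.ptp(x) == 0:
        raise StatsError("constant covariate")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(y.size),
    )


@dataclass(frozen=True)
class PowerDesign:
    null_auroc: float = 0.80
    alt_auroc: float = 0.90
    alpha: float = 0.05  # one-sided
    m: int = 60  # positives
    n: int = 85  # negatives

    def __post_init__(self) -> None:
        if not 0.5 <= self.null_auroc < self.alt_auroc <= 1.0:
            raise StatsError("need 0.5 <= null < alt <= 1")
        if not 0.0 < self.alpha < 0.5:
            raise StatsError("alpha must be in (0, 0.5)")


def _hanley_mcneil_variance(auc: float, m: int, n: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return (
        auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)
    ) / (m * n)


def _binormal_auroc_variance(auc: float, m: int, n: int) -> float:
    """AUROC estimator variance under the equal-variance binormal model.

    Both placement-value variances reduce to Var[Phi(X)], X ~ N(delta, 1),
    evaluated by Gauss-Hermite quadrature; the DeLong decomposition then
    gives S * (1/m + 1/n).
    """
    delta = math.sqrt(2.0) * sps.norm.ppf(auc)
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    phi_vals = sps.norm.cdf(nodes + delta)
    w = weights / weights.sum()
    mean = float(np.sum(w * phi_vals))
    second = float(np.sum(w * phi_vals**2))
    s = second - mean**2
    return s * (1.0 / m + 1.0 / n)


def binormal_scores(
    auc: float, m: int, n: int, rng: np.random.Generator
) -> ScoreSet:
    """Equal-variance binormal score sets with the given population AUROC."""
    delta = math.sqrt(2.0) * sps.norm.ppf(auc)
    return ScoreSet(rng.standard_normal(m) + delta, rng.standard_normal(n))


def power_auroc(
    design: PowerDesign,
    method: str = "simulation",
    n_reps: int = 2000,
    seed: int = 0,
) -> tuple[float, bool]:
    """Power of the one-sided AUROC z test under the design.

    ``simulation`` draws binormal scores at the alternative AUROC and counts
    rejections of the DeLong z test at the null; ``analytic`` evaluates
    Phi((alt - null)/SE_alt - z_alpha) with the binormal estimator variance
    at the alternative (the z test standardizes by the estimated variance of
    the observed AUROC, so the alternative-variance SE is the right scale).
    Returns (power, reliable); ``reliable`` is False when a group has fewer
    than 5 members.
    """
    reliable = design.m >= 5 and design.n >= 5
    if method == "analytic":
        z_alpha = sps.norm.ppf(1 - design.alpha)
        v1 = _binormal_auroc_variance(design.alt_auroc, design.m, design.n)
        z = (design.alt_auroc - design.null_auroc) / math.sqrt(v1) - z_alpha
        return float(sps.norm.cdf(z)), reliable
    if method != "simulation":
        raise StatsError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        scores = binormal_scores(design.alt_auroc, design.m, design.n, rng)
        if auroc_z_test(scores, design.null_auroc) < design.alpha:
            rejections += 1
    return rejections / n_reps, reliable


@dataclass(frozen=True)
class ConcordanceReport:
    """Percent agreement with pathology for model and clinical diagnoses."""

    model_agreement_pct: float
    clinical_agreement_pct: float
    gain_pct: float
    model_tallies: dict[str, tuple[int, int]] = field(default_factory=dict)
    clinical_tallies: dict[str, tuple[int, int]] = field(default_factory=dict)


def _pooled_pct(tallies: dict[str, tuple[int, int]]) -> float:
    correct = sum(c for c, _ in tallies.values())
    total = sum(t for _, t in tallies.values())
    if total == 0:
        raise StatsError("empty tallies")
    return round(100.0 * correct / total, 1)


def concordance_from_tallies(
    model_tallies: dict[str, tuple[int, int]],
    clinical_tallies: dict[str, tuple[int, int]],
) -> ConcordanceReport:
    """Pooled agreement (to one decimal) from per-class (correct, total)
    tallies; the gain is the difference of the rounded percentages."""
    model_pct = _pooled_pct(model_tallies)
    clinical_pct = _pooled_pct(clinical_tallies)
    return ConcordanceReport(
        model_agreement_pct=model_pct,
        clinical_agreement_pct=clinical_pct,
        gain_pct=round(model_pct - clinical_pct, 1),
        model_tallies=dict(model_tallies),
        clinical_tallies=dict(clinical_tallies),
    )


def concordance_report(
    predicted, clinical, pathology, classes=("PD", "MSA", "PSP")
) -> ConcordanceReport:
    """Per-class and pooled agreement of predicted and clinical labels against
    pathology ground truth."""
    predicted = np.asarray(predicted)
    clinical = np.asarray(clinical)
    pathology = np.asarray(pathology)
    if not (predicted.shape == clinical.shape == pathology.shape):
        raise StatsError("label arrays must have equal length")
    if predicted.size == 0:
        raise StatsError("empty input")
    model_tallies = {}
    clinical_tallies = {}
    for cls in classes:
        sel = pathology == cls
        total = int(sel.sum())
        if total == 0:
            continue
        model_tallies[cls] = (int(np.sum(predicted[sel] == cls)), total)
        clinical_tallies[cls] = (int(np.sum(clinical[sel] == cls)), total)
    return concordance_from_tallies(model_tallies, clinical_tallies)


def test_retest_compare(
    reports_session1: dict[str, ScoreSet], reports_session2: dict[str, ScoreSet]
) -> dict[str, tuple[float, float, float]]:
    """Per-endpoint (auroc_s1, auroc_s2, delta) across two scan sessions."""
    if set(reports_session1) != set(reports_session2):
        raise StatsError("endpoint sets differ between sessions")
    out = {}
    for name, s1 in reports_session1.items():
        s2 = reports_session2[name]
        if s1.positives.size != s2.positives.size or (
            s1.negatives.size != s2.negatives.size
        ):
            raise StatsError(f"subject sets differ for endpoint {name}")
        a1, a2 = auroc(s1), auroc(s2)
        out[name] = (a1, a2, a2 - a1)
    return out


@dataclass
class EndpointReport:
    """Full inferential summary for one binary endpoint in one regime."""

    endpoint: str
    regime: str
    auroc: float
    ci_low: float
    ci_high: float
    variance: float
    p_value: float
    null_auroc: float
    confusion: ConfusionMetrics
    bh_adjusted_p: float | None = None

    def to_dict(self) -> dict:
        c = self.confusion
        return {
            "endpoint": self.endpoint,
            "regime": self.regime,
            "auroc": self.auroc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "null_auroc": self.null_auroc,
            "bh_adjusted_p": self.bh_adjusted_p,
            "sensitivity": c.sensitivity,
            "specificity": c.specificity,
            "ppv": c.ppv,
            "npv": c.npv,
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
        }


def endpoint_report(
    endpoint: str,
    regime: str,
    scores: ScoreSet,
    predictions,
    truths,
    null_auroc: float = NULL_AUROC_DEFAULT,
) -> EndpointReport:
    """Assemble AUROC, DeLong CI, one-sided z p-value, and confusion metrics."""
    a, lo, hi, var = delong_ci(scores)
    p = auroc_z_test(scores, null_auroc)
    conf = confusion_metrics(predictions, truths)
    return EndpointReport(
        endpoint=endpoint, regime=regime, auroc=a, ci_low=lo, ci_high=hi,
        variance=var, p_value=p, null_auroc=null_auroc, confusion=conf,
    )


def attach_bh(reports: list[EndpointReport]) -> list[EndpointReport]:
    """BH-adjust p-values across the endpoints of one regime, in place."""
    adj = bh_adjust([r.p_value for r in reports])
    for r, a in zip(reports, adj):
        r.bh_adjusted_p = float(a)
    return reports
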