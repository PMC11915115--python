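"""Binary endpoints, stratified splits, cross-validated linear SVM training,
probability calibration, verification runs, and site-holdout evaluation.

Conventions: four binary endpoints; the atypical / later-listed class is the
positive class. Retrospective subjects always train and are never tested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from aidp import stats
from aidp._rng import substream, substream_seed

#: regularization grid: logarithmic 1e-3 .. 1e3, 13 points
C_GRID_DEFAULT = tuple(np.logspace(-3, 3, 13))

K_FOLDS = 5
DECISION_THRESHOLD = 0.5


class SplitError(ValueError):
    """Raised for infeasible split requests."""


@dataclass(frozen=True)
class EndpointSpec:
    """Maps each diagnosis to positive / negative / excluded."""

    name: str
    positive: frozenset
    negative: frozenset

    def label(self, diagnosis: str) -> int | None:
        if diagnosis in self.positive:
            return 1
        if diagnosis in self.negative:
            return 0
        return None


ENDPOINTS: dict[str, EndpointSpec] = {
    "PD_vs_AP": EndpointSpec("PD_vs_AP", frozenset({"MSA", "PSP"}), frozenset({"PD"})),
    "MSA_vs_PSP": EndpointSpec("MSA_vs_PSP", frozenset({"PSP"}), frozenset({"MSA"})),
    "PD_vs_MSA": EndpointSpec("PD_vs_MSA", frozenset({"MSA"}), frozenset({"PD"})),
    "PD_vs_PSP": EndpointSpec("PD_vs_PSP", frozenset({"PSP"}), frozenset({"PD"})),
}


@dataclass
class SplitPlan:
    """Train/test membership plus CV fold assignment for training subjects."""

    assignment: dict[str, str]  # subject_id -> "train" | "test"
    folds: dict[str, int] = field(default_factory=dict)  # subject_id -> 1..k
    regime: str = "primary"
    seed: int = 0

    @property
    def train_ids(self) -> list[str]:
        return [s for s, a in self.assignment.items() if a == "train"]

    @property
    def test_ids(self) -> list[str]:
        return [s for s, a in self.assignment.items() if a == "test"]


def check_no_leakage(plan: SplitPlan) -> bool:
    """A subject (hence every session of it) must be train xor test."""
    return all(a in ("train", "test") for a in plan.assignment.values()) and not (
        set(plan.train_ids) & set(plan.test_ids)
    )


def _repair_site_coverage(
    cohort: pd.DataFrame, assignment: dict[str, str], rng: np.random.Generator
) -> None:
    """Best-effort class-preserving swaps so every site with >= 2 prospective
    subjects appears in both train and test."""
    pro = cohort[cohort["cohort"] == "prospective"]
    for _ in range(len(pro)):
        by_side: dict[str, dict[str, list]] = {"train": {}, "test": {}}
        for _, row in pro.iterrows():
            side = assignment[row["subject_id"]]
            by_side[side].setdefault(row["site"], []).append(
                (row["subject_id"], row["diagnosis"])
            )
        swapped = False
        for missing_side, present_side in (("test", "train"), ("train", "test")):
            lacking = [
                s for s in pro["site"].unique()
                if s not in by_side[missing_side]
                and len(by_side[present_side].get(s, [])) >= 2
            ]
            for site in lacking:
                # move one subject of this site over; rebalance with a
                # same-class subject from a site with surplus on that side
                for sid, dx in by_side[present_side][site]:
                    partners = [
                        (s2, d2)
                        for other, members in by_side[missing_side].items()
                        if len(members) >= 2
                        for s2, d2 in members
                        if d2 == dx
                    ]
                    if partners:
                        s2, _ = partners[int(rng.integers(len(partners)))]
                        assignment[sid] = missing_side
                        assignment[s2] = present_side
                        swapped = True
                        break
                if swapped:
                    break
            if swapped:
                break
        if not swapped:
            break


def stratified_split(
    cohort: pd.DataFrame,
    test_counts: dict[str, int] | None = None,
    test_fraction: float | None = None,
    seed: int = 0,
    ensure_site_coverage: bool = True,
    regime: str = "primary",
) -> SplitPlan:
    """Stratified train/test split of the prospective cohort.

    Retrospective subjects are always assigned to training. Per-class test
    counts are matched exactly (from ``test_counts`` or rounded from
    ``test_fraction`` of each prospective class). When feasible, swaps keep
    every site represented on both sides.
    """
    if (test_counts is None) == (test_fraction is None):
        raise SplitError("give exactly one of test_counts / test_fraction")
    # keyed by seed only (not regime) so a verification run with the primary
    # seed reproduces the primary split exactly
    rng = substream(seed, "split")
    assignment: dict[str, str] = {}
    retro = cohort[cohort["cohort"] == "retrospective"]
    for sid in retro["subject_id"]:
        assignment[sid] = "train"
    pro = cohort[cohort["cohort"] == "prospective"]
    for dx, group in pro.groupby("diagnosis", sort=True):
        ids = group["subject_id"].to_numpy()
        if test_counts is not None:
            k = int(test_counts.get(dx, 0))
        else:
            k = int(round(test_fraction * len(ids)))
        if k > len(ids):
            raise SplitError(
                f"requested {k} test subjects for {dx}, only {len(ids)} available"
            )
        order = rng.permutation(len(ids))
        for i, idx in enumerate(order):
            assignment[ids[idx]] = "test" if i < k else "train"
    plan = SplitPlan(assignment=assignment, regime=regime, seed=seed)
    if ensure_site_coverage and plan.test_ids and plan.train_ids:
        _repair_site_coverage(cohort, plan.assignment, rng)
    return plan


def site_holdout_split(
    cohort: pd.DataFrame,
    n_holdout_sites: int = 6,
    seed: int = 0,
) -> SplitPlan:
    """Hold out whole sites: prospective subjects at the held-out sites test,
    everyone else (and all retrospective subjects) trains."""
    pro = cohort[cohort["cohort"] == "prospective"]
    sites = sorted(pro["site"].unique())
    if len(sites) <= n_holdout_sites:
        raise SplitError(
            f"{len(sites)} sites cannot provide {n_holdout_sites} holdout sites"
        )
    rng = substream(seed, "site-holdout")
    holdout = set(np.array(sites)[rng.permutation(len(sites))[:n_holdout_sites]])
    assignment = {}
    for _, row in cohort.iterrows():
        is_test = row["cohort"] == "prospective" and row["site"] in holdout
        assignment[row["subject_id"]] = "test" if is_test else "train"
    return SplitPlan(assignment=assignment, regime="site_holdout", seed=seed)


def make_cv_folds(
    plan: SplitPlan, cohort: pd.DataFrame, k: int = K_FOLDS, seed: int = 0
) -> dict[str, int]:
    """Class-stratified fold assignment (1..k) of the training subjects.

    Per class, fold sizes differ by at most one. All sessions of a subject
    share its fold because folds are keyed by subject. A class with fewer
    than k training subjects is an error.
    """
    train_ids = set(plan.train_ids)
    if not train_ids:
        raise SplitError("empty training set")
    rng = substream(seed, "cv-folds")
    folds: dict[str, int] = {}
    totals = {f: 0 for f in range(1, k + 1)}
    rows = cohort[cohort["subject_id"].isin(train_ids)]
    for dx, group in rows.groupby("diagnosis", sort=True):
        ids = group["subject_id"].to_numpy()
        if len(ids) < k:
            raise SplitError(f"class {dx} has {len(ids)} training subjects < k={k}")
        order = rng.permutation(len(ids))
        q, r = divmod(len(ids), k)
        # per-class q each, remainders to the currently lightest folds so
        # overall fold sizes stay as equal as the arithmetic allows
        by_load = sorted(totals, key=lambda f: (totals[f], f))
        per_fold = {f: q + (1 if i < r else 0) for i, f in enumerate(by_load)}
        cursor = 0
        for f in range(1, k + 1):
            for idx in order[cursor : cursor + per_fold[f]]:
                folds[ids[idx]] = f
            cursor += per_fold[f]
            totals[f] += per_fold[f]
    plan.folds = folds
    return folds


def _fit_platt(margins: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt sigmoid P(y=1|m) = 1 / (1 + exp(a*m + b)) on held-out margins."""
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return -1.0, 0.0
    # Platt's target smoothing
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * margins + b
        # log(1 + e^z) stable in both tails
        log1pez = np.logaddexp(0.0, z)
        return float(np.sum(t * log1pez + (1 - t) * (log1pez - z)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead")
    a, b = res.x
    if a >= 0:  # calibration must be monotone increasing in the margin
        a = -1e-6
    return float(a), float(b)


@dataclass
class LinearModel:
    """Linear max-margin classifier with training-set scaling and Platt
    calibration. ``weights`` act on scaled features."""

    weights: np.ndarray
    bias: float
    C: float
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    calib_a: float
    calib_b: float
    feature_names: tuple[str, ...] | None = None
    endpoint: str | None = None
    seed: int | None = None
    cv_auroc: float | None = None

    def margins(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.weights.size:
            raise ValueError(
                f"feature length {X.shape[1]} != model length {self.weights.size}"
            )
        Xs = (X - self.scale_mean) / self.scale_sd
        return Xs @ self.weights + self.bias

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        m = self.margins(X)
        return 1.0 / (1.0 + np.exp(np.clip(self.calib_a * m + self.calib_b, -500, 500)))

    def predict_label(self, X: np.ndarray, threshold: float = DECISION_THRESHOLD):
        return (self.predict_proba(X) >= threshold).astype(int)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "C": self.C,
            "scale_mean": self.scale_mean.tolist(),
            "scale_sd": self.scale_sd.tolist(),
            "calib_a": self.calib_a,
            "calib_b": self.calib_b,
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "endpoint": self.endpoint,
            "seed": self.seed,
            "cv_auroc": self.cv_auroc,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(d["weights"]),
            bias=float(d["bias"]),
            C=float(d["C"]),
            scale_mean=np.array(d["scale_mean"]),
            scale_sd=np.array(d["scale_sd"]),
            calib_a=float(d["calib_a"]),
            calib_b=float(d["calib_b"]),
            feature_names=tuple(d["feature_names"]) if d["feature_names"] else None,
            endpoint=d["endpoint"],
            seed=d["seed"],
            cv_auroc=d["cv_auroc"],
        )


def _fit_svm(X: np.ndarray, y: np.ndarray, C: float):
    scaler = StandardScaler().fit(X)
    svm = SVC(kernel="linear", C=C)
    svm.fit(scaler.transform(X), y)
    return scaler, svm


def tune_and_train(
    features: np.ndarray,
    labels: np.ndarray,
    folds: np.ndarray,
    C_grid=C_GRID_DEFAULT,
    feature_names: tuple[str, ...] | None = None,
    endpoint: str | None = None,
    seed: int | None = None,
) -> LinearModel:
    """5-fold CV over the C grid, refit at the best C, Platt calibration.

    The winning C maximizes mean validation AUROC (ties go to the smallest
    C, i.e. the strongest regularization). Calibration uses out-of-fold
    margins at the winning C, so no validation information leaks into it.
    Zero-variance features get unit scale (weight mass flows elsewhere).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    folds = np.asarray(folds, dtype=int)
    if X.shape[0] != y.size or y.size != folds.size:
        raise ValueError("features/labels/folds length mismatch")
    fold_ids = np.unique(folds)
    for f in fold_ids:
        if len(np.unique(y[folds == f])) < 2:
            raise SplitError(f"fold {f} does not contain both classes")
    mean_aurocs = []
    for C in C_grid:
        scores = []
        for f in fold_ids:
            tr, va = folds != f, folds == f
            scaler, svm = _fit_svm(X[tr], y[tr], C)
            m = svm.decision_function(scaler.transform(X[va]))
            scores.append(stats.auroc(stats.ScoreSet.from_labels(m, y[va])))
        mean_aurocs.append(float(np.mean(scores)))
    best = int(np.argmin([-a for a in mean_aurocs]))  # first max -> smallest C
    best_C = float(C_grid[best])
    # out-of-fold margins at the winning C for calibration
    oof = np.empty(y.size)
    for f in fold_ids:
        tr, va = folds != f, folds == f
        scaler, svm = _fit_svm(X[tr], y[tr], best_C)
        oof[va] = svm.decision_function(scaler.transform(X[va]))
    a, b = _fit_platt(oof, y)
    scaler, svm = _fit_svm(X, y, best_C)
    return LinearModel(
        weights=svm.coef_.ravel(),
        bias=float(svm.intercept_[0]),
        C=best_C,
        scale_mean=scaler.mean_.copy(),
        scale_sd=scaler.scale_.copy(),
        calib_a=a,
        calib_b=b,
        feature_names=feature_names,
        endpoint=endpoint,
        seed=seed,
        cv_auroc=mean_aurocs[best],
    )


@dataclass(frozen=True)
class ProbabilityEstimate:
    subject_id: str
    endpoint: str
    probability: float
    margin: float


def predict(
    model: LinearModel, features: np.ndarray, subject_ids=None
) -> list[ProbabilityEstimate]:
    """Calibrated positive-class probabilities for a feature matrix."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    m = model.margins(X)
    p = model.predict_proba(X)
    if subject_ids is None:
        subject_ids = [f"row-{i}" for i in range(X.shape[0])]
    return [
        ProbabilityEstimate(
            subject_id=str(sid),
            endpoint=model.endpoint or "unknown",
            probability=float(pi),
            margin=float(mi),
        )
        for sid, pi, mi in zip(subject_ids, p, m)
    ]


def evaluate_split(
    X: np.ndarray,
    cohort: pd.DataFrame,
    plan: SplitPlan,
    endpoints=("PD_vs_AP", "MSA_vs_PSP", "PD_vs_MSA", "PD_vs_PSP"),
    C_grid=C_GRID_DEFAULT,
    null_auroc: float = stats.NULL_AUROC_DEFAULT,
    seed: int = 0,
    X_test_override: np.ndarray | None = None,
) -> tuple[list[stats.EndpointReport], dict[str, list[ProbabilityEstimate]]]:
    """Train and test every endpoint under one split plan.

    ``X`` rows align with ``cohort`` rows. ``X_test_override`` (same shape as
    ``X``) substitutes test-subject features, e.g. the retest session.
    Returns BH-adjusted endpoint reports and per-endpoint test-set
    probability estimates.
    """
    if not check_no_leakage(plan):
        raise SplitError("split plan leaks subjects between train and test")
    sids = cohort["subject_id"].to_numpy()
    dx = cohort["diagnosis"].to_numpy()
    side = np.array([plan.assignment[s] for s in sids])
    if not plan.folds:
        make_cv_folds(plan, cohort, K_FOLDS, seed=substream_seed(seed, "folds"))
    reports = []
    estimates: dict[str, list[ProbabilityEstimate]] = {}
    for name in endpoints:
        spec = ENDPOINTS[name]
        y = np.array([spec.label(d) if spec.label(d) is not None else -1 for d in dx])
        tr = (side == "train") & (y >= 0)
        te = (side == "test") & (y >= 0)
        if te.sum() == 0:
            raise SplitError(f"no test subjects for endpoint {name}")
        folds = np.array([plan.folds[s] for s in sids[tr]])
        model = tune_and_train(
            X[tr], y[tr], folds, C_grid,
            endpoint=name, seed=seed,
        )
        X_te = (X_test_override if X_test_override is not None else X)[te]
        est = predict(model, X_te, subject_ids=sids[te])
        probs = np.array([e.probability for e in est])
        preds = (probs >= DECISION_THRESHOLD).astype(int)
        scores = stats.ScoreSet.from_labels(probs, y[te])
        reports.append(
            stats.endpoint_report(name, plan.regime, scores, preds, y[te], null_auroc)
        )
        estimates[name] = est
    stats.attach_bh(reports)
    return reports, estimates


def run_verification(
    X: np.ndarray,
    cohort: pd.DataFrame,
    test_counts: dict[str, int],
    n_runs: int = 49,
    seed: int = 0,
    endpoints=("PD_vs_AP", "MSA_vs_PSP", "PD_vs_MSA", "PD_vs_PSP"),
    C_grid=C_GRID_DEFAULT,
    null_auroc: float = stats.NULL_AUROC_DEFAULT,
) -> list[list[stats.EndpointReport]]:
    """Repeat the stratified-split experiment under run-specific seeds.

    Run 0 uses the primary seed itself, so a single-run verification matches
    the primary endpoint experiment exactly.
    """
    if n_runs < 1:
        raise SplitError("n_runs must be >= 1")
    out = []
    for run in range(n_runs):
        run_seed = seed if run == 0 else substream_seed(seed, f"verify-{run}")
        plan = stratified_split(
            cohort, test_counts=test_counts, seed=run_seed, regime="verification"
        )
        reports, _ = evaluate_split(
            X, cohort, plan, endpoints, C_grid, null_auroc, seed=run_seed
        )
        out.append(reports)
    return out
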