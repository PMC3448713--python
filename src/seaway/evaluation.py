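"""Model-assessment battery: K-fold CV, ROC/AUC against pseudo-absences,
equal-sensitivity-specificity thresholds, omission tests, permutation
importance, jackknife gain, and median tests."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import maxent_engine
from .covariates import SampleMatrix
from .maxent_engine import FeatureSet, MaxEntModel, expand_features
from .seasons import rng_for

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "kfold_cv",
    "roc_auc",
    "equal_ss_threshold",
    "binomial_omission_test",
    "permutation_importance",
    "jackknife_gain",
    "median_test",
    "evaluate_season",
]


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(test_scores: np.ndarray, background_scores: np.ndarray):
    """AUC (ties count 1/2) plus ROC points against background pseudo-absences.

    AUC is the probability that a random presence outranks a random
    background point; computed via midranks, so it equals the exhaustive
    pairwise estimator exactly.
    """
    t = np.asarray(test_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if t.size < 1 or b.size < 2:
        raise ValueError("need >= 1 presence score and >= 2 background scores")
    allv = np.concatenate([t, b])
    if np.all(allv == allv[0]):
        warnings.warn("all scores identical; AUC is 0.5 by convention", stacklevel=2)
        auc = 0.5
    else:
        ranks = stats.rankdata(allv)  # midranks handle ties as 1/2
        auc = (ranks[: t.size].sum() - t.size * (t.size + 1) / 2.0) / (t.size * b.size)

    thresholds = np.unique(allv)[::-1]
    sens = (t[np.newaxis, :] >= thresholds[:, np.newaxis]).mean(axis=1)
    fpr = (b[np.newaxis, :] >= thresholds[:, np.newaxis]).mean(axis=1)
    roc = pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "fpr": fpr})
    return float(auc), roc


def equal_ss_threshold(test_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Threshold where sensitivity and specificity are closest.

    Candidates are all distinct observed scores; ties break toward the lower
    threshold (favoring sensitivity over specificity, i.e. tolerating false
    positives rather than false absences).
    """
    t = np.asarray(test_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    cands = np.unique(np.concatenate([t, b]))
    if cands.size == 1:
        warnings.warn("degenerate scores; threshold equals the single value", stacklevel=2)
        return float(cands[0])
    sens = (t[np.newaxis, :] >= cands[:, np.newaxis]).mean(axis=1)
    spec = (b[np.newaxis, :] < cands[:, np.newaxis]).mean(axis=1)
    gap = np.abs(sens - spec)
    # candidates ascending, so the first within float noise of the minimum
    # is the lowest-threshold tie
    best = np.flatnonzero(gap <= gap.min() + 1e-12)[0]
    return float(cands[best])


def binomial_omission_test(n_test: int, n_omitted: int, fractional_predicted_area: float) -> float:
    """One-sided p-value that held-out presences beat a random prediction.

    p = P(X >= n_test - n_omitted) for X ~ Binomial(n_test, area).
    """
    if not 0 <= n_omitted <= n_test:
        raise ValueError(f"n_omitted must be in [0, {n_test}], got {n_omitted}")
    a = fractional_predicted_area
    if a <= 0.0 or a >= 1.0:
        warnings.warn("degenerate fractional predicted area; p-value is an indicator",
                      stacklevel=2)
        hits = n_test - n_omitted
        if a <= 0.0:
            return 1.0 if hits == 0 else 0.0
        return 1.0
    hits = n_test - n_omitted
    return float(stats.binom.sf(hits - 1, n_test, a))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class Fold:
    train_presence_idx: np.ndarray
    test_presence_idx: np.ndarray
    model: MaxEntModel
    train_auc: float
    test_auc: float
    test_scores: np.ndarray
    background_scores: np.ndarray


def kfold_cv(
    samples: SampleMatrix,
    K: int = 10,
    seed: int = 0,
    r: float = 3.0,
    classes=maxent_engine.DEFAULT_CLASSES,
    hinge_knots: int = 5,
    tol: float = 1e-5,
    max_iter: int = 10000,
) -> list[Fold]:
    """Random K-fold CV over presences; the background sample is shared by
    every fold (only presences are partitioned)."""
    m = samples.n_presence
    if K < 2:
        raise ValueError("K must be at least 2 (K=1 leaves no held-out part)")
    if K > m:
        raise ValueError(f"K={K} exceeds the presence count {m}")
    rng = rng_for(seed, "kfold")
    perm = rng.permutation(m)
    parts = np.array_split(perm, K)

    pres = samples.presence_rows().reset_index(drop=True)
    bg = samples.background_rows().reset_index(drop=True)
    folds = []
    for kx, test_idx in enumerate(parts):
        train_idx = np.setdiff1d(perm, test_idx)
        train_data = pd.concat([pres.iloc[train_idx], bg], ignore_index=True)
        labels = np.concatenate([np.ones(train_idx.size, int), np.zeros(len(bg), int)])
        sub = SampleMatrix(train_data, labels, samples.season)
        feats = expand_features(sub, classes=classes, hinge_knots=hinge_knots)
        model = maxent_engine.fit(sub, feats, r=r, tol=tol, max_iter=max_iter)

        bg_scores = maxent_engine.predict(model, bg).logistic
        train_scores = maxent_engine.predict(model, pres.iloc[train_idx]).logistic
        test_scores = maxent_engine.predict(model, pres.iloc[test_idx]).logistic
        train_auc, _ = roc_auc(train_scores, bg_scores)
        test_auc, _ = roc_auc(test_scores, bg_scores)
        folds.append(
            Fold(train_idx, test_idx, model, train_auc, test_auc, test_scores, bg_scores)
        )
        logger.debug("fold %d/%d: train AUC %.3f test AUC %.3f", kx + 1, K, train_auc, test_auc)
    return folds


# ---------------------------------------------------------------------------
# covariate importance
# ---------------------------------------------------------------------------


def permutation_importance(
    model: MaxEntModel, samples: SampleMatrix, seed: int = 0
) -> dict[str, float]:
    """Percent importance per covariate from AUC drop under permutation.

    The covariate column is permuted jointly across presence + background
    rows (all features derived from it move together); drops are floored at
    zero and normalized to sum to 100.
    """
    rng = rng_for(seed, "perm-importance")
    pres_mask = samples.labels == 1
    base_scores = maxent_engine.predict(model, samples.data).logistic
    base_auc, _ = roc_auc(base_scores[pres_mask], base_scores[~pres_mask])
    drops = {}
    for cov in model.features.covariates:
        shuffled = samples.data.copy()
        shuffled[cov] = rng.permutation(shuffled[cov].to_numpy())
        s = maxent_engine.predict(model, shuffled).logistic
        auc, _ = roc_auc(s[pres_mask], s[~pres_mask])
        drops[cov] = max(base_auc - auc, 0.0)
    total = sum(drops.values())
    if total == 0:
        return {c: 0.0 for c in drops}
    return {c: 100.0 * d / total for c, d in drops.items()}


def _gain(model: MaxEntModel, samples: SampleMatrix) -> float:
    """Penalized average presence log-likelihood relative to the uniform null."""
    pres = samples.presence_rows()
    F = model.features.transform(pres)
    avg_ll = float((F @ model.lam).mean()) - model.log_z
    penalty = float(model.beta @ np.abs(model.lam))
    null_ll = -np.log(model.n_background)
    return (avg_ll - penalty) - null_ll


def jackknife_gain(
    samples: SampleMatrix,
    r: float = 3.0,
    classes=maxent_engine.DEFAULT_CLASSES,
    hinge_knots: int = 5,
    tol: float = 1e-5,
    max_iter: int = 10000,
) -> dict[str, dict[str, float]]:
    """Training gain with each covariate removed and each alone.

    Returns ``{covariate: {"without": g, "alone": g, "full": g}}`` plus the
    convergence flag of each sub-fit under key ``"converged"``.
    """
    covs = list(samples.data.columns)
    if len(covs) < 2:
        raise ValueError("jackknife needs at least 2 covariates")

    def fit_on(cols: list[str]):
        sub = SampleMatrix(samples.data[cols].copy(), samples.labels, samples.season)
        feats = expand_features(sub, classes=classes, hinge_knots=hinge_knots)
        model = maxent_engine.fit(sub, feats, r=r, tol=tol, max_iter=max_iter)
        return _gain(model, sub), model.converged

    full_gain, full_conv = fit_on(covs)
    out: dict[str, dict[str, float]] = {}
    for c in covs:
        g_wo, conv_wo = fit_on([x for x in covs if x != c]) if len(covs) > 1 else (0.0, True)
        g_alone, conv_alone = fit_on([c])
        out[c] = {
            "without": g_wo,
            "alone": g_alone,
            "full": full_gain,
            "converged": float(full_conv and conv_wo and conv_alone),
        }
    return out


# ---------------------------------------------------------------------------
# median test
# ---------------------------------------------------------------------------


def median_test(*groups: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """K-sample median test: chi-square on the above/at-or-below pooled-median
    contingency table (G-1 df, no continuity correction by default)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("median test needs at least 2 groups")
    for g in gs:
        if g.size < 5:
            raise ValueError("each group needs n >= 5")
    pooled = np.concatenate(gs)
    med = np.median(pooled)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; median test undefined, p = 1", stacklevel=2)
        return 0.0, 1.0
    table = np.array([[(g > med).sum(), (g <= med).sum()] for g in gs]).T
    if (table.sum(axis=0) == 0).any():
        warnings.warn("a group has no observations on one side of the median", stacklevel=2)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def median_test_presence_background(
    presence_values: np.ndarray, background_values_by_season: dict[str, np.ndarray]
) -> tuple[float, float, float]:
    """Presence sample versus per-season background samples.

    Returns (overall pooled median, chi-square, p)."""
    groups = list(background_values_by_season.values()) + [np.asarray(presence_values)]
    med = float(np.median(np.concatenate([np.asarray(g, float) for g in groups])))
    chi2, p = median_test(*groups)
    return med, chi2, p


# ---------------------------------------------------------------------------
# season-level report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    season: str
    train_auc_folds: list[float]
    test_auc_folds: list[float]
    mean_train_auc: float
    mean_test_auc: float
    sd_train_auc: float
    sd_test_auc: float
    logistic_threshold: float
    omission_rate: float
    prevalence: float
    fractional_predicted_area: float
    binomial_p: float
    importance: dict[str, float]
    jackknife: dict[str, dict[str, float]] = field(default_factory=dict)
    median_tests: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))

    @staticmethod
    def table1(reports: list["EvaluationReport"]) -> pd.DataFrame:
        """Season-by-statistic summary table (one column per season)."""
        cols = {}
        for rep in reports:
            col = {
                "Average Training AUC": rep.mean_train_auc,
                "Average Test AUC": rep.mean_test_auc,
                "Prevalence": rep.prevalence,
                "Logistic Threshold": rep.logistic_threshold,
                "Test Site Omission Rate": rep.omission_rate,
            }
            for cov, v in rep.importance.items():
                col[f"{cov} Importance"] = v
            cols[rep.season] = col
        return pd.DataFrame(cols)


def evaluate_season(
    samples: SampleMatrix,
    K: int = 10,
    seed: int = 0,
    r: float = 3.0,
    classes=maxent_engine.DEFAULT_CLASSES,
    hinge_knots: int = 5,
    with_jackknife: bool = True,
    tol: float = 1e-5,
    max_iter: int = 10000,
) -> tuple[EvaluationReport, MaxEntModel]:
    """Run the full assessment battery for one seasonal sample matrix.

    Returns the report and the full-data fitted model.  The threshold is the
    equal-sensitivity-specificity point on the pooled held-out presence
    scores versus the full-model background scores.
    """
    folds = kfold_cv(samples, K=K, seed=seed, r=r, classes=classes,
                     hinge_knots=hinge_knots, tol=tol, max_iter=max_iter)
    feats = expand_features(samples, classes=classes, hinge_knots=hinge_knots)
    full_model = maxent_engine.fit(samples, feats, r=r, tol=tol, max_iter=max_iter)

    bg_scores = maxent_engine.predict(full_model, samples.background_rows()).logistic
    pooled_test = np.concatenate([f.test_scores for f in folds])
    threshold = equal_ss_threshold(pooled_test, bg_scores)
    omission = float((pooled_test < threshold).mean())
    area = float((bg_scores >= threshold).mean())
    p = binomial_omission_test(pooled_test.size, int((pooled_test < threshold).sum()), area)

    importance = permutation_importance(full_model, samples, seed=seed)
    jk = jackknife_gain(samples, r=r, classes=classes, hinge_knots=hinge_knots,
                        tol=tol, max_iter=max_iter) if with_jackknife else {}

    train = [f.train_auc for f in folds]
    test = [f.test_auc for f in folds]
    report = EvaluationReport(
        season=samples.season,
        train_auc_folds=train,
        test_auc_folds=test,
        mean_train_auc=float(np.mean(train)),
        mean_test_auc=float(np.mean(test)),
        sd_train_auc=float(np.std(train, ddof=1)) if len(train) > 1 else 0.0,
        sd_test_auc=float(np.std(test, ddof=1)) if len(test) > 1 else 0.0,
        logistic_threshold=threshold,
        omission_rate=omission,
        prevalence=float(bg_scores.mean()),
        fractional_predicted_area=area,
        binomial_p=p,
        importance=importance,
        jackknife=jk,
    )
    return report, full_model
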