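"""Presence-only maximum-entropy density-ratio model.

The model fits a Gibbs density ``exp(lambda . f(x)) / Z`` over the background
sample so that penalized feature expectations match the presence sample.
Fitting maximizes

    mean_presence(lambda . f) - log Z(lambda) - sum_j beta_j |lambda_j|

by proximal gradient ascent with backtracking (monotone in the penalized
objective).  Per-feature L1 penalties are ``beta_j = r * b_class(m) *
sd_j / sqrt(m)`` with ``m`` the presence count and ``b_class`` the
feature-class base penalty interpolated over sample size (documented
constants below).

Outputs follow the conventional transforms: *raw* (normalized to sum to 1
over the background sample), *cumulative* (percentile of raw among
background), and *logistic*
``p = tau exp(eta) / (1 - tau + tau exp(eta))`` with
``eta = lambda . f - log Z + H`` where ``H`` is the entropy of the fitted
background distribution and ``tau`` the assumed prevalence (0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .covariates import SampleMatrix

logger = logging.getLogger(__name__)

__all__ = ["FeatureDef", "FeatureSet", "MaxEntModel", "expand_features", "fit",
           "predict", "response_curve"]

DEFAULT_CLASSES = frozenset({"linear", "quadratic", "product", "hinge"})
ALL_CLASSES = frozenset({"linear", "quadratic", "product", "hinge", "threshold", "categorical"})

# feature-class base L1 penalties, interpolated over presence-sample size
# (published reference-software defaults)
_BASE_PENALTY = {
    "linear": [(0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05)],
    "quadratic": [(0, 1.3), (10, 0.8), (17, 0.5), (30, 0.25), (100, 0.05)],
    "product": [(0, 2.6), (10, 1.6), (17, 1.0), (30, 0.5), (100, 0.05)],
    "hinge": [(0, 0.5), (1, 0.5)],
    "threshold": [(0, 2.0), (100, 1.0)],
    "categorical": [(0, 0.65), (10, 0.5), (17, 0.25)],
}


def _base_penalty(kind: str, m: int) -> float:
    pts = _BASE_PENALTY[kind]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return float(np.interp(m, xs, ys))


@dataclass(frozen=True)
class FeatureDef:
    """One scalar feature: a deterministic transform of covariate value(s)."""

    kind: str
    cov: str
    cov2: str | None = None  # second covariate for products
    knot: float | None = None
    reverse: bool = False  # reverse hinge
    lo: float = 0.0  # min-max scaling constants (raw feature scale)
    hi: float = 1.0

    @property
    def name(self) -> str:
        if self.kind == "linear":
            return self.cov
        if self.kind == "quadratic":
            return f"{self.cov}^2"
        if self.kind == "product":
            return f"{self.cov}*{self.cov2}"
        tag = {"hinge": "rhinge" if self.reverse else "hinge", "threshold": "thr",
               "categorical": "cat"}[self.kind]
        return f"{tag}({self.cov},{self.knot:.6g})"

    def raw(self, X: pd.DataFrame) -> np.ndarray:
        x = X[self.cov].to_numpy(dtype=float)
        if self.kind == "linear":
            return x
        if self.kind == "quadratic":
            return x**2
        if self.kind == "product":
            return x * X[self.cov2].to_numpy(dtype=float)
        if self.kind == "hinge":
            return np.maximum(0.0, (self.knot - x) if self.reverse else (x - self.knot))
        if self.kind == "threshold":
            return (x > self.knot).astype(float)
        if self.kind == "categorical":
            return (x == self.knot).astype(float)
        raise ValueError(f"unknown feature kind {self.kind!r}")

    def value(self, X: pd.DataFrame) -> np.ndarray:
        raw = self.raw(X)
        if self.hi > self.lo:
            return (raw - self.lo) / (self.hi - self.lo)
        return np.zeros_like(raw)


@dataclass
class FeatureSet:
    """Expanded features with their scaling and clamp bounds."""

    covariates: list[str]
    features: list[FeatureDef]
    clamp_bounds: dict[str, tuple[float, float]]

    def transform(self, X: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        """Feature matrix (n_rows, n_features); optionally clamp covariates
        to their training range first (projection behaviour)."""
        missing = [c for c in self.covariates if c not in X.columns]
        if missing:
            raise KeyError(f"covariates missing from input: {missing}")
        X = X[self.covariates]
        bad = ~np.isfinite(X.to_numpy(dtype=float))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite covariate value at row {r}, column {X.columns[c]!r}"
            )
        if clamp:
            Xc = X.copy()
            n_clamped = 0
            for cov, (lo, hi) in self.clamp_bounds.items():
                col = Xc[cov].to_numpy(dtype=float)
                n_clamped += int(((col < lo) | (col > hi)).sum())
                Xc[cov] = np.clip(col, lo, hi)
            if n_clamped:
                logger.info("clamped %d covariate values to the training range", n_clamped)
            X = Xc
        return np.column_stack([f.value(X) for f in self.features])


def expand_features(
    samples: SampleMatrix,
    classes: frozenset[str] | set[str] = DEFAULT_CLASSES,
    hinge_knots: int = 5,
) -> FeatureSet:
    """Expand covariates into scaled model features.

    Linear and quadratic terms per covariate, products per covariate pair,
    forward/reverse hinges and thresholds at ``hinge_knots`` empirical
    quantiles.  Each feature is min-max scaled to [0, 1] over the combined
    presence + background sample; constant covariates are dropped with a
    warning.
    """
    unknown = set(classes) - ALL_CLASSES
    if unknown:
        raise ValueError(f"unknown feature classes {sorted(unknown)}; valid: {sorted(ALL_CLASSES)}")
    X = samples.data
    covs = []
    for c in X.columns:
        vals = X[c].to_numpy(dtype=float)
        if np.unique(vals).size < 2:
            logger.warning("covariate %r is constant over the sample; dropped", c)
            continue
        covs.append(c)

    defs: list[FeatureDef] = []
    for c in covs:
        if "linear" in classes:
            defs.append(FeatureDef("linear", c))
        if "quadratic" in classes:
            defs.append(FeatureDef("quadratic", c))
    if "product" in classes:
        for i, a in enumerate(covs):
            for b in covs[i + 1:]:
                defs.append(FeatureDef("product", a, cov2=b))
    if {"hinge", "threshold"} & set(classes):
        qs = np.linspace(0, 1, hinge_knots + 2)[1:-1]
        for c in covs:
            knots = np.unique(np.quantile(X[c].to_numpy(dtype=float), qs))
            for k in knots:
                if "hinge" in classes:
                    defs.append(FeatureDef("hinge", c, knot=float(k)))
                    defs.append(FeatureDef("hinge", c, knot=float(k), reverse=True))
                if "threshold" in classes:
                    defs.append(FeatureDef("threshold", c, knot=float(k)))

    scaled: list[FeatureDef] = []
    for fd in defs:
        raw = fd.raw(X)
        lo, hi = float(raw.min()), float(raw.max())
        if hi <= lo:
            continue  # degenerate feature (e.g. threshold beyond data range)
        scaled.append(FeatureDef(fd.kind, fd.cov, fd.cov2, fd.knot, fd.reverse, lo, hi))

    clamp = {c: (float(X[c].min()), float(X[c].max())) for c in covs}
    return FeatureSet(covs, scaled, clamp)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class MaxEntModel:
    features: FeatureSet
    lam: np.ndarray
    beta: np.ndarray
    log_z: float  # log sum over background of exp(lambda . f)
    entropy: float  # entropy of the fitted background distribution (nats)
    tau: float
    reg_multiplier: float
    n_background: int
    converged: bool
    iterations: int
    final_gap: float
    bg_raw_sorted: np.ndarray  # for cumulative output
    sample_means: dict[str, float]  # covariate means (response curves)
    objective_trace: list[float] = field(default_factory=list)  # not serialized

    # -- persistence: plain-text lambdas file -------------------------------

    def to_text(self, path: str | Path) -> None:
        lines = [
            "# seaway maxent model",
            f"tau {self.tau!r}",
            f"log_z {self.log_z!r}",
            f"entropy {self.entropy!r}",
            f"reg_multiplier {self.reg_multiplier!r}",
            f"n_background {self.n_background}",
            f"converged {int(self.converged)}",
            f"iterations {self.iterations}",
            f"final_gap {self.final_gap!r}",
            "covariates " + ",".join(self.features.covariates),
        ]
        for c, (lo, hi) in self.features.clamp_bounds.items():
            lines.append(f"clamp {c} {float(lo)!r} {float(hi)!r}")
        for c, mu in self.sample_means.items():
            lines.append(f"mean {c} {float(mu)!r}")
        for fd, l, b in zip(self.features.features, self.lam, self.beta):
            lines.append(
                "feature "
                f"{fd.kind} {fd.cov} {fd.cov2 or '-'} "
                f"{'-' if fd.knot is None else repr(float(fd.knot))} {int(fd.reverse)} "
                f"{float(fd.lo)!r} {float(fd.hi)!r} {float(l)!r} {float(b)!r}"
            )
        lines.append("bg_raw " + ",".join(repr(float(v)) for v in self.bg_raw_sorted))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "MaxEntModel":
        scalars: dict[str, str] = {}
        clamp: dict[str, tuple[float, float]] = {}
        means: dict[str, float] = {}
        feats: list[FeatureDef] = []
        lams: list[float] = []
        betas: list[float] = []
        covariates: list[str] = []
        bg_raw = np.array([])
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition(" ")
            if key == "clamp":
                c, lo, hi = rest.split()
                clamp[c] = (float(lo), float(hi))
            elif key == "mean":
                c, mu = rest.split()
                means[c] = float(mu)
            elif key == "covariates":
                covariates = rest.split(",")
            elif key == "feature":
                kind, cov, cov2, knot, rev, lo, hi, lam, beta = rest.split()
                feats.append(
                    FeatureDef(
                        kind, cov, None if cov2 == "-" else cov2,
                        None if knot == "-" else float(knot), bool(int(rev)),
                        float(lo), float(hi),
                    )
                )
                lams.append(float(lam))
                betas.append(float(beta))
            elif key == "bg_raw":
                bg_raw = np.array([float(v) for v in rest.split(",")])
            else:
                scalars[key] = rest
        return cls(
            features=FeatureSet(covariates, feats, clamp),
            lam=np.array(lams),
            beta=np.array(betas),
            log_z=float(scalars["log_z"]),
            entropy=float(scalars["entropy"]),
            tau=float(scalars["tau"]),
            reg_multiplier=float(scalars["reg_multiplier"]),
            n_background=int(scalars["n_background"]),
            converged=bool(int(scalars["converged"])),
            iterations=int(scalars["iterations"]),
            final_gap=float(scalars["final_gap"]),
            bg_raw_sorted=bg_raw,
            sample_means=means,
        )


def _soft(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def fit(
    samples: SampleMatrix,
    features: FeatureSet | None = None,
    r: float = 3.0,
    tol: float = 1e-5,
    max_iter: int = 10000,
    add_samples_to_background: bool = True,
) -> MaxEntModel:
    """Fit the penalized maximum-entropy model.

    Stops when the per-iteration gain in the penalized objective drops below
    ``tol`` or after ``max_iter`` iterations (the model is then returned
    flagged non-converged).  The objective is non-decreasing across
    iterations by construction.

    ``add_samples_to_background`` folds the presence rows into the background
    distribution (the reference-software default); this keeps the problem
    bounded when presences lie outside the background's covariate hull.
    """
    if features is None:
        features = expand_features(samples)
    m = samples.n_presence
    n_bg = len(samples.labels) - m
    if m < 1:
        raise ValueError("need at least one presence row")
    if n_bg < 100:
        raise ValueError(f"need at least 100 background rows, got {n_bg}")

    F_pres = features.transform(samples.presence_rows())
    F_bg = features.transform(samples.background_rows())
    if add_samples_to_background:
        F_bg = np.vstack([F_bg, F_pres])
        n_bg = F_bg.shape[0]
    fbar = F_pres.mean(axis=0)
    sd = np.concatenate([F_pres, F_bg]).std(axis=0)
    beta = np.array(
        [r * _base_penalty(fd.kind, m) * s / np.sqrt(m) for fd, s in zip(features.features, sd)]
    )

    k = len(features.features)
    lam = np.zeros(k)
    eta_bg = F_bg @ lam
    log_z = logsumexp(eta_bg)
    ll = float(fbar @ lam - log_z)
    obj = ll - float(beta @ np.abs(lam))
    step = 1.0
    gain = np.inf
    converged = False
    trace = [obj]
    it = 0
    g_prev = None
    lam_prev = None
    for it in range(1, max_iter + 1):
        q = np.exp(eta_bg - log_z)
        g = fbar - q @ F_bg
        # Barzilai-Borwein spectral step, safeguarded by backtracking below
        if g_prev is not None:
            dl = lam - lam_prev
            dg = g_prev - g  # gradient of -ll changes by g_prev - g
            denom = float(dl @ dg)
            if denom > 1e-30:
                step = min(max(float(dl @ dl) / denom, 1e-8), 1e8)
        g_prev, lam_prev = g, lam
        while True:
            lam_new = _soft(lam + step * g, step * beta)
            delta = lam_new - lam
            sq = float(delta @ delta)
            if sq == 0.0:
                break
            eta_new = F_bg @ lam_new
            log_z_new = logsumexp(eta_new)
            ll_new = float(fbar @ lam_new - log_z_new)
            if ll_new >= ll + float(g @ delta) - sq / (2.0 * step):
                break
            step *= 0.5
        if sq == 0.0:
            gain = 0.0
            converged = True
            break
        obj_new = ll_new - float(beta @ np.abs(lam_new))
        gain = obj_new - obj
        lam, eta_bg, log_z, ll, obj = lam_new, eta_new, log_z_new, ll_new, obj_new
        trace.append(obj)
        if gain < tol:
            converged = True
            break
    if not converged:
        logger.warning("maxent fit hit max_iter=%d without converging (last gain %.3g)",
                       max_iter, gain)

    q = np.exp(eta_bg - log_z)
    entropy = float(-(q * np.where(q > 0, np.log(np.maximum(q, 1e-300)), 0.0)).sum())
    bg_raw = np.sort(q)
    means = {c: float(samples.data[c].mean()) for c in features.covariates}
    return MaxEntModel(
        features=features, lam=lam, beta=beta, log_z=float(log_z), entropy=entropy,
        tau=0.5, reg_multiplier=r, n_background=n_bg, converged=converged,
        iterations=it, final_gap=float(gain), bg_raw_sorted=bg_raw, sample_means=means,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


@dataclass
class Prediction:
    raw: np.ndarray
    logistic: np.ndarray
    cumulative: np.ndarray


def predict(model: MaxEntModel, X: pd.DataFrame, clamp: bool = True) -> Prediction:
    """Raw, logistic and cumulative outputs for covariate rows.

    Raw values are normalized by the training background sum (they sum to 1
    over the background sample itself).  Covariates outside the training
    range are clamped when ``clamp`` is on.
    """
    F = model.features.transform(X, clamp=clamp)
    eta_lin = F @ model.lam
    raw = np.exp(np.clip(eta_lin - model.log_z, -700, 700))
    eta = eta_lin - model.log_z + model.entropy
    e = np.exp(np.clip(eta, -700, 700))
    logistic = model.tau * e / (1.0 - model.tau + model.tau * e)
    ranks = np.searchsorted(model.bg_raw_sorted, raw, side="right")
    cumulative = 100.0 * ranks / max(len(model.bg_raw_sorted), 1)
    return Prediction(raw=raw, logistic=logistic, cumulative=cumulative)


def response_curve(model: MaxEntModel, covariate: str, grid: np.ndarray) -> np.ndarray:
    """Marginal logistic response along ``grid`` with the other covariates
    held at their mean sample values."""
    if covariate not in model.features.covariates:
        raise KeyError(f"covariate {covariate!r} not in model "
                       f"(has {model.features.covariates})")
    grid = np.asarray(grid, dtype=float)
    rows = {c: np.full(grid.size, model.sample_means[c]) for c in model.features.covariates}
    rows[covariate] = grid
    return predict(model, pd.DataFrame(rows), clamp=False).logistic
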