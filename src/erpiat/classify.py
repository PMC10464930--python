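"""Exploratory group classification (ROC) and the ANCOVA power calculator.

Cluster-averaged contrast amplitudes, the behavioral D score and clinical
covariates are combined in a logistic model scored by ROC/AUC. The power
calculator answers the design-stage question: with two groups, k
covariates and a target effect size f (Cohen), what is the probability of
detecting the group effect in a fixed-effects ANCOVA?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve, auc as _trapezoid_auc
from sklearn.model_selection import StratifiedKFold

from .cluster import Cluster
from .preprocess import SubjectContrast

__all__ = [
    "PowerSpec",
    "ROCResult",
    "extract_cluster_feature",
    "build_feature_table",
    "fit_roc",
    "ancova_power",
]


def extract_cluster_feature(
    contrasts: list[SubjectContrast], cluster: Cluster
) -> pd.DataFrame:
    """Mean contrast amplitude over a cluster's cells, per participant."""
    if not cluster.cells:
        raise ValueError("cluster has no cells")
    ch = np.array([c for c, _ in cluster.cells])
    tp = np.array([t for _, t in cluster.cells])
    rows = [
        {"participant_id": c.participant_id, "feature": float(c.delta[ch, tp].mean())}
        for c in contrasts
    ]
    return pd.DataFrame(rows)


def build_feature_table(
    covariates: pd.DataFrame,
    dscores: pd.DataFrame | None = None,
    cluster_features: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Assemble participant_id + group + named feature columns.

    ``cluster_features`` maps a feature name to a frame from
    :func:`extract_cluster_feature`. Raises if any assembled value is
    missing.
    """
    out = covariates[["participant_id", "group"]].copy()
    if dscores is not None:
        out = out.merge(
            dscores[["participant_id", "d"]].rename(columns={"d": "d_score"}),
            on="participant_id", how="left",
        )
    for name, frame in (cluster_features or {}).items():
        out = out.merge(
            frame.rename(columns={"feature": name}), on="participant_id", how="left"
        )
    feature_cols = [c for c in out.columns if c not in ("participant_id", "group")]
    if out[feature_cols].isna().any().any():
        bad = out.loc[out[feature_cols].isna().any(axis=1), "participant_id"].tolist()
        raise ValueError(f"missing feature values for participants: {bad}")
    return out


@dataclass
class ROCResult:
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    cv_scheme: str
    penalized_fallback: bool


def _fit_logistic(Xs: np.ndarray, y: np.ndarray) -> tuple[LogisticRegression, bool]:
    """Unpenalized logistic fit; ridge fallback on separation/non-convergence.

    Complete separation is detected from the fitted scores (every case
    scored above every control), in which case the unpenalized MLE is
    unbounded and a small fixed ridge penalty is used instead, flagged to
    the caller.
    """
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(C=np.inf, max_iter=2000)
            model.fit(Xs, y)
            scores = model.decision_function(Xs)
            separated = scores[y == 1].min() > scores[y == 0].max()
            if not separated:
                return model, False
        except (ConvergenceWarning, Exception):
            pass
    model = LogisticRegression(C=100.0, max_iter=2000)
    model.fit(Xs, y)
    return model, True


def fit_roc(
    features: pd.DataFrame,
    predictors: list[str],
    cv: int | None = None,
    seed: int = 0,
    positive_group: str = "sibs",
) -> ROCResult:
    """Logistic scoring of group membership with trapezoidal ROC AUC.

    Without cross-validation the ROC is computed on in-sample scores. With
    ``cv=k``, out-of-fold scores from a seeded stratified k-fold pool into
    one curve. Complete separation triggers a ridge-penalized fallback
    (small fixed penalty) which is flagged on the result.
    """
    missing = [p for p in predictors if p not in features.columns]
    if missing:
        raise KeyError(f"predictors not in feature table: {missing}")
    y = (features["group"] == positive_group).to_numpy(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    X = features[list(predictors)].to_numpy(float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd

    fallback = False
    if cv is None:
        model, fallback = _fit_logistic(Xs, y)
        scores = model.decision_function(Xs)
        coefs = dict(zip(predictors, model.coef_[0]))
        scheme = "none"
    else:
        if cv < 2:
            raise ValueError("cv must be >= 2 folds")
        scores = np.empty(len(y), float)
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        for train, test in skf.split(Xs, y):
            model, fb = _fit_logistic(Xs[train], y[train])
            fallback = fallback or fb
            scores[test] = model.decision_function(Xs[test])
        full_model, fb = _fit_logistic(Xs, y)
        fallback = fallback or fb
        coefs = dict(zip(predictors, full_model.coef_[0]))
        scheme = f"stratified_{cv}_fold(seed={seed})"

    fpr, tpr, thr = roc_curve(y, scores)
    return ROCResult(
        predictors=tuple(predictors),
        coefficients={k: float(v) for k, v in coefs.items()},
        auc=float(_trapezoid_auc(fpr, tpr)),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        cv_scheme=scheme,
        penalized_fallback=fallback,
    )


@dataclass(frozen=True)
class PowerSpec:
    """Fixed-effects ANCOVA design for the power computation."""

    effect_size_f: float
    alpha: float = 0.05
    n_per_group: int = 27
    n_groups: int = 2
    n_covariates: int = 2

    def __post_init__(self) -> None:
        if self.effect_size_f < 0:
            raise ValueError("effect_size_f must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if min(self.n_per_group, self.n_groups) < 1 or self.n_covariates < 0:
            raise ValueError("counts must be positive")


def ancova_power(spec: PowerSpec) -> float:
    """Power of the group F test in an ANCOVA, by the noncentral F.

    With N total participants, df1 = groups - 1, df2 = N - groups -
    covariates, noncentrality lambda = f^2 * N; power = P(F' > F_crit)
    where F_crit is the central-F critical value at ``alpha``. At f = 0
    this reduces exactly to the test size alpha.
    """
    N = spec.n_per_group * spec.n_groups
    df1 = spec.n_groups - 1
    df2 = N - spec.n_groups - spec.n_covariates
    if df2 <= 0:
        raise ValueError("design too small: residual df <= 0")
    f_crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    lam = spec.effect_size_f**2 * N
    if lam == 0.0:
        return float(spec.alpha)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))
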