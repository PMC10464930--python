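"""Second-level mass-univariate ANCOVA over the channel x time grid.

Level 1 is the within-subject trial averaging done in :mod:`erpiat.preprocess`
(the subject contrast); level 2, here, regresses that contrast at every
channel x time cell on group, D score and age. Two fitting paths are
provided: closed-form OLS and a robust bisquare IRLS (Tukey biweight,
tuning 4.685) whose Wald F statistics downweight outlying subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import SubjectContrast

__all__ = ["DesignMatrix", "GLMField", "build_design", "fit_cell", "fit_field"]

DEFAULT_COLUMNS = ("intercept", "group", "d_score", "age_months")


@dataclass(frozen=True)
class DesignMatrix:
    """Participants x regressors matrix with centered continuous covariates."""

    X: np.ndarray
    columns: tuple[str, ...]
    participant_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise KeyError(f"regressor {name!r} not in design {self.columns}") from None

    def reorder(self, participant_ids) -> "DesignMatrix":
        idx = []
        lookup = {pid: i for i, pid in enumerate(self.participant_ids)}
        missing = [pid for pid in participant_ids if pid not in lookup]
        if missing:
            raise ValueError(f"participants absent from design: {missing}")
        idx = [lookup[pid] for pid in participant_ids]
        return DesignMatrix(self.X[idx], self.columns, tuple(participant_ids))


@dataclass
class GLMField:
    """Per-regressor beta / F / uncorrected-p arrays over channels x time."""

    columns: tuple[str, ...]
    beta: np.ndarray  # (p, channels, timepoints)
    F: np.ndarray
    p_uncorrected: np.ndarray
    df_model: int
    df_resid: int
    method: str
    channel_names: tuple[str, ...]
    times_ms: np.ndarray
    robust_fallback: np.ndarray | None = None  # (channels, timepoints) bool
    mean_robust_weight: float | None = None

    def regressor(self, name: str) -> dict:
        j = self.columns.index(name)
        return {
            "beta": self.beta[j],
            "F": self.F[j],
            "p_uncorrected": self.p_uncorrected[j],
        }


def build_design(
    covariates: pd.DataFrame,
    dscores: pd.DataFrame,
    participants: list[str] | None = None,
) -> DesignMatrix:
    """Assemble intercept + group(0/1) + centered D + centered age.

    Group is coded 0=control, 1=sibs so effects read as sibs minus control.
    Continuous covariates are mean-centered; the intercept then estimates
    the control-group contrast at average D and age.
    """
    df = covariates.merge(dscores[["participant_id", "d"]], on="participant_id", how="inner")
    if participants is not None:
        df = df.set_index("participant_id").loc[list(participants)].reset_index()
    missing = df[df[["group", "d", "age_months"]].isna().any(axis=1)]
    if len(missing):
        raise ValueError(
            f"missing covariates for participants: {missing['participant_id'].tolist()}"
        )
    n = len(df)
    d = df["d"].to_numpy(float)
    age = df["age_months"].to_numpy(float)
    X = np.column_stack([
        np.ones(n),
        (df["group"] == "sibs").to_numpy(float),
        d - d.mean(),
        age - age.mean(),
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        flat = [
            name for j, name in enumerate(DEFAULT_COLUMNS)
            if j > 0 and np.ptp(X[:, j]) == 0
        ]
        raise ValueError(
            "rank-deficient design; degenerate columns: "
            + (", ".join(flat) if flat else "collinear combination of regressors")
        )
    return DesignMatrix(X=X, columns=DEFAULT_COLUMNS,
                        participant_ids=tuple(df["participant_id"].astype(str)))


def _ols_stats(X: np.ndarray, Y: np.ndarray):
    """Vectorized OLS over cells. Y is (n, m); returns (B, F, p, df_resid)."""
    n, p = X.shape
    dfr = n - p
    pinv = np.linalg.pinv(X)
    B = pinv @ Y  # (p, m)
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / dfr  # (m,)
    c = np.diag(np.linalg.inv(X.T @ X))  # (p,)
    denom = np.maximum(sigma2[None, :] * c[:, None], 1e-300)
    F = B**2 / denom
    pval = stats.f.sf(F, 1, dfr)
    return B, F, np.clip(pval, np.finfo(float).tiny, 1.0), dfr


def _irls_batch(
    X: np.ndarray,
    Y: np.ndarray,
    tuning: float = 4.685,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Batched bisquare IRLS across cells.

    Returns (B, F, p, df_resid, converged_mask, mean_weight). Cells whose
    residual scale collapses to ~0 (perfect fit) get unit weights and thus
    coincide with OLS, as do cells that fail to converge (flagged False in
    the mask; callers may report the OLS fallback).
    """
    n, p = X.shape
    m = Y.shape[1]
    dfr = n - p
    B, _, _, _ = _ols_stats(X, Y)
    converged = np.zeros(m, dtype=bool)
    W = np.ones((n, m))
    for _ in range(max_iter):
        R = Y - X @ B
        scale = 1.4826 * np.median(np.abs(R), axis=0)  # (m,)
        tiny = scale <= 1e-12 * np.maximum(np.abs(Y).max(axis=0), 1.0)
        safe_scale = np.where(tiny, 1.0, scale)
        u = R / (tuning * safe_scale)
        W = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        W[:, tiny] = 1.0
        A = np.einsum("np,nm,nq->mpq", X, W, X)  # (m, p, p)
        b = np.einsum("np,nm,nm->mp", X, W, Y)  # (m, p)
        try:
            B_new = np.linalg.solve(A, b[..., None])[..., 0].T  # (p, m)
        except np.linalg.LinAlgError:
            A = A + 1e-10 * np.eye(p)[None]
            B_new = np.linalg.solve(A, b[..., None])[..., 0].T
        step = np.max(np.abs(B_new - B), axis=0)
        B = B_new
        converged = step < tol * (1.0 + np.max(np.abs(B), axis=0))
        if converged.all():
            break
    R = Y - X @ B
    sigma2 = np.einsum("nm,nm->m", W, R**2) / dfr
    Ainv = np.linalg.inv(np.einsum("np,nm,nq->mpq", X, W, X))
    cjj = np.einsum("mpp->mp", Ainv).T  # (p, m)
    denom = np.maximum(sigma2[None, :] * cjj, 1e-300)
    F = B**2 / denom
    pval = stats.f.sf(F, 1, dfr)
    return B, F, np.clip(pval, np.finfo(float).tiny, 1.0), dfr, converged, float(W.mean())


def fit_cell(y: np.ndarray, design: DesignMatrix, method: str = "ols") -> dict:
    """Fit one channel x time cell; returns betas, per-regressor F and p."""
    y = np.asarray(y, float)
    if y.ndim != 1 or y.size != design.n:
        raise ValueError("y must be a vector with one value per design row")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    Y = y[:, None]
    if method == "ols":
        B, F, p, dfr = _ols_stats(design.X, Y)
        converged = True
    elif method == "robust":
        B, F, p, dfr, conv, _ = _irls_batch(design.X, Y)
        converged = bool(conv[0])
        if not converged:
            B, F, p, dfr = _ols_stats(design.X, Y)
    else:
        raise ValueError("method must be 'ols' or 'robust'")
    return {
        "beta": B[:, 0],
        "F": F[:, 0],
        "p_uncorrected": p[:, 0],
        "df_model": design.p - 1,
        "df_resid": dfr,
        "converged": converged,
        "columns": design.columns,
    }


def contrasts_to_matrix(contrasts: list[SubjectContrast]) -> tuple[np.ndarray, tuple]:
    """Stack subject deltas into (n_subjects, n_cells); returns grid shape."""
    ref = contrasts[0]
    shape = ref.delta.shape
    for c in contrasts[1:]:
        if c.delta.shape != shape or c.channel_names != ref.channel_names:
            raise ValueError("contrast grids are not aligned across participants")
    Y = np.stack([c.delta.reshape(-1) for c in contrasts], axis=0)
    return Y, shape


def fit_field(
    contrasts: list[SubjectContrast],
    design: DesignMatrix,
    method: str = "robust",
) -> GLMField:
    """Apply the cell model over the whole channel x time grid.

    The design is row-aligned to the contrast list by participant id. For
    the robust path, cells where IRLS fails to converge are replaced by
    their OLS fit and flagged in ``robust_fallback``.
    """
    if not contrasts:
        raise ValueError("no contrasts supplied")
    pids = [c.participant_id for c in contrasts]
    design = design.reorder(pids)
    Y, shape = contrasts_to_matrix(contrasts)
    if method == "ols":
        B, F, p, dfr = _ols_stats(design.X, Y)
        fallback = None
        mean_w = None
    elif method == "robust":
        B, F, p, dfr, conv, mean_w = _irls_batch(design.X, Y)
        fallback = ~conv
        if fallback.any():
            Bo, Fo, po, _ = _ols_stats(design.X, Y[:, fallback])
            B[:, fallback], F[:, fallback], p[:, fallback] = Bo, Fo, po
    else:
        raise ValueError("method must be 'ols' or 'robust'")
    nch, nt = shape
    return GLMField(
        columns=design.columns,
        beta=B.reshape(design.p, nch, nt),
        F=F.reshape(design.p, nch, nt),
        p_uncorrected=p.reshape(design.p, nch, nt),
        df_model=design.p - 1,
        df_resid=dfr,
        method=method,
        channel_names=contrasts[0].channel_names,
        times_ms=contrasts[0].times_ms,
        robust_fallback=None if fallback is None else fallback.reshape(nch, nt),
        mean_robust_weight=mean_w,
    )
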