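"""DS-IAT behavioral scoring and group-level behavioral statistics.

The D score is the standardized IAT effect: the difference between mean
latencies of the two paired-block types divided by an inclusive pooled
standard deviation, after recoding extreme latencies. Here it is oriented
so that *faster death-congruent responding gives a positive D* — the sign
convention of death/suicide IAT studies, where D > 0 indicates a stronger
implicit association between "death" and "self".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ScoringPolicy",
    "DScoreResult",
    "UnscorableParticipantError",
    "compute_d_score",
    "score_all",
    "d_score_group_test",
    "cssrs_subscale_comparison",
]

PAIRED_CONDITIONS = ("death_congruent", "life_congruent")


class UnscorableParticipantError(ValueError):
    """A paired-block condition is empty after filtering; no D score exists."""


@dataclass(frozen=True)
class ScoringPolicy:
    """Tunable rules of the improved D-score algorithm.

    ``error_policy``: "penalty" replaces an error trial's latency with the
    mean correct latency of its block plus ``error_penalty_ms`` (the
    improved-algorithm built-in penalty); "drop" discards error trials.
    ``combine``: "pooled" pools practice+test blocks per condition with one
    inclusive SD; "averaged" computes D separately on the practice pair and
    the test pair and averages the two.
    ``recode_bounds``: (low, high) latency recode bounds in ms, or None to
    disable absolute recoding.
    """

    recode_bounds: tuple[float, float] | None = (300.0, 3000.0)
    drop_above_ms: float = 10_000.0
    error_policy: str = "penalty"  # "penalty" | "drop"
    error_penalty_ms: float = 600.0
    combine: str = "pooled"  # "pooled" | "averaged"

    def __post_init__(self) -> None:
        if self.error_policy not in ("penalty", "drop"):
            raise ValueError("error_policy must be 'penalty' or 'drop'")
        if self.combine not in ("pooled", "averaged"):
            raise ValueError("combine must be 'pooled' or 'averaged'")


@dataclass(frozen=True)
class DScoreResult:
    participant_id: str
    d: float
    mean_death_congruent_ms: float
    mean_life_congruent_ms: float
    pooled_sd_ms: float
    n_used: int
    n_recoded_low: int
    n_recoded_high: int
    n_dropped: int
    error_rate: float


def _apply_error_policy(df: pd.DataFrame, policy: ScoringPolicy) -> tuple[pd.DataFrame, int]:
    """Returns (frame with adjusted latencies, n dropped by the policy)."""
    if policy.error_policy == "drop":
        kept = df[df["correct"].astype(bool)]
        return kept, len(df) - len(kept)
    out = df.copy()
    lat = out["latency_ms"].to_numpy(float).copy()
    errors = ~out["correct"].astype(bool).to_numpy()
    if errors.any():
        for block, idx in out.groupby("block_index").groups.items():
            loc = out.index.get_indexer(idx)
            blk_err = errors[loc]
            if not blk_err.any():
                continue
            correct_lat = lat[loc][~blk_err]
            # fall back to the block's own mean if every trial is an error
            base = correct_lat.mean() if correct_lat.size else lat[loc].mean()
            lat[loc[blk_err]] = base + policy.error_penalty_ms
    out["latency_ms"] = lat
    return out, 0


def _d_from_sets(death: np.ndarray, life: np.ndarray) -> tuple[float, float]:
    """(d, inclusive sd) for one pair of latency sets; d > 0 = faster death."""
    both = np.concatenate([death, life])
    sd = float(both.std(ddof=1)) if both.size > 1 else 0.0
    diff = float(life.mean() - death.mean())
    if sd == 0.0:
        if diff == 0.0:
            return 0.0, sd
        raise UnscorableParticipantError("zero latency variance with nonzero difference")
    return diff / sd, sd


def compute_d_score(trials: pd.DataFrame, policy: ScoringPolicy = ScoringPolicy()) -> DScoreResult:
    """Score one participant's paired blocks with the improved algorithm.

    Processing order: drop latencies > ``drop_above_ms``; apply the error
    policy; recode latencies below/above the recode bounds to the bound;
    then form the oriented standardized difference. With ``combine=
    "pooled"`` all retained paired-block trials share one inclusive SD;
    with ``"averaged"`` the practice-pair and test-pair D values are
    averaged, each with its own inclusive SD.
    """
    ids = trials["participant_id"].unique()
    if len(ids) != 1:
        raise ValueError("compute_d_score expects trials of exactly one participant")
    pid = str(ids[0])
    lat_all = trials["latency_ms"].to_numpy(float)
    if not np.all(np.isfinite(lat_all)) or np.any(lat_all <= 0):
        raise ValueError("latency_ms must be finite and positive")

    paired = trials[trials["condition"].isin(PAIRED_CONDITIONS)]
    n_paired = len(paired)
    if n_paired == 0:
        raise UnscorableParticipantError(f"{pid}: no paired-block trials")
    error_rate = 1.0 - paired["correct"].astype(bool).mean()

    kept = paired[paired["latency_ms"] <= policy.drop_above_ms]
    n_dropped = n_paired - len(kept)
    kept, n_err_dropped = _apply_error_policy(kept, policy)
    n_dropped += n_err_dropped

    lat = kept["latency_ms"].to_numpy(float).copy()
    n_low = n_high = 0
    if policy.recode_bounds is not None:
        lo, hi = policy.recode_bounds
        n_low = int((lat < lo).sum())
        n_high = int((lat > hi).sum())
        lat = np.clip(lat, lo, hi)
    kept = kept.assign(latency_ms=lat)

    def _cond(frame: pd.DataFrame, cond: str) -> np.ndarray:
        vals = frame.loc[frame["condition"] == cond, "latency_ms"].to_numpy(float)
        if vals.size == 0:
            raise UnscorableParticipantError(f"{pid}: condition {cond!r} empty after filtering")
        return vals

    death_all = _cond(kept, "death_congruent")
    life_all = _cond(kept, "life_congruent")

    if policy.combine == "pooled":
        d, sd = _d_from_sets(death_all, life_all)
    else:
        ds, sds = [], []
        for role_set in (("practice",), ("test",)):
            sub = kept[kept["block_role"].isin(role_set)]
            d_i, sd_i = _d_from_sets(_cond(sub, "death_congruent"), _cond(sub, "life_congruent"))
            ds.append(d_i)
            sds.append(sd_i)
        d, sd = float(np.mean(ds)), float(np.mean(sds))

    return DScoreResult(
        participant_id=pid,
        d=float(d),
        mean_death_congruent_ms=float(death_all.mean()),
        mean_life_congruent_ms=float(life_all.mean()),
        pooled_sd_ms=sd,
        n_used=int(death_all.size + life_all.size),
        n_recoded_low=n_low,
        n_recoded_high=n_high,
        n_dropped=int(n_dropped),
        error_rate=float(error_rate),
    )


def score_all(
    trials: pd.DataFrame, policy: ScoringPolicy = ScoringPolicy()
) -> tuple[pd.DataFrame, list[str]]:
    """Score every participant; returns (result table, unscorable ids)."""
    rows, unscorable = [], []
    for pid, sub in trials.groupby("participant_id", sort=True):
        try:
            rows.append(compute_d_score(sub, policy).__dict__)
        except UnscorableParticipantError:
            unscorable.append(str(pid))
    return pd.DataFrame(rows), unscorable


def _gender_indicator(gender: pd.Series) -> np.ndarray:
    """Binary indicator (female=1) from a free-text gender column."""
    return gender.astype(str).str.lower().str.startswith("f").to_numpy(float)


def d_score_group_test(dscores: pd.DataFrame, covariates: pd.DataFrame) -> dict:
    """ANCOVA of D on group, controlling for age and gender.

    Fits ``d ~ group + age_months + gender`` by OLS (group coded 0=control,
    1=sibs) and returns the adjusted group difference with its partial F
    and two-sided p, plus unadjusted group means.
    """
    df = dscores.merge(covariates, on="participant_id", how="inner")
    counts = df["group"].value_counts()
    if counts.get("sibs", 0) < 3 or counts.get("control", 0) < 3:
        raise ValueError("need at least 3 participants per group")
    y = df["d"].to_numpy(float)
    X = np.column_stack([
        np.ones(len(df)),
        (df["group"] == "sibs").to_numpy(float),
        df["age_months"].to_numpy(float),
        _gender_indicator(df["gender"]),
    ])
    names = ["intercept", "group", "age_months", "gender"]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which non-intercept columns are redundant
        bad = [n for j, n in enumerate(names) if j > 0 and np.ptp(X[:, j]) == 0]
        raise ValueError(f"singular design; collinear/constant columns: {bad or names}")
    fit = sm.OLS(y, X).fit()
    coef = float(fit.params[1])
    if fit.ssr <= 1e-24:  # constant outcome: no group effect, nothing to test
        f_stat, p = 0.0, 1.0
    else:
        f_stat = float(fit.tvalues[1] ** 2)
        p = float(fit.pvalues[1])
    means = df.groupby("group")["d"].agg(["mean", "sem", "count"])
    return {
        "adjusted_group_difference": coef,
        "F": f_stat,
        "p": p,
        "df_model": int(fit.df_model),
        "df_resid": int(fit.df_resid),
        "group_means": {g: float(means.loc[g, "mean"]) for g in means.index},
        "group_sems": {g: float(means.loc[g, "sem"]) for g in means.index},
        "n": {g: int(means.loc[g, "count"]) for g in means.index},
    }


def cssrs_subscale_comparison(
    dscores: pd.DataFrame, covariates: pd.DataFrame, subscale: str
) -> dict:
    """Compare a C-SSRS intensity subscale between positive-D and
    negative-D patients, adjusting for depression severity (CDRS-R).

    Restricted to the patient (sibs) group. Returns stratum means/SDs and
    the adjusted p for the D-sign indicator in
    ``subscale ~ d_positive + cdrs_r_total``.
    """
    col = subscale if subscale.startswith("cssrs_") else f"cssrs_{subscale}"
    df = dscores.merge(covariates, on="participant_id", how="inner")
    df = df[df["group"] == "sibs"]
    if col not in df.columns:
        raise KeyError(f"subscale column {col!r} not found")
    pos = df[df["d"] > 0]
    neg = df[df["d"] <= 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("one D-sign stratum is empty; cannot stratify")
    y = df[col].to_numpy(float)
    X = np.column_stack([
        np.ones(len(df)),
        (df["d"] > 0).to_numpy(float),
        df["cdrs_r_total"].to_numpy(float),
    ])
    if np.ptp(y) == 0:
        diff, p = 0.0, 1.0
    else:
        fit = sm.OLS(y, X).fit()
        diff, p = float(fit.params[1]), float(fit.pvalues[1])
    return {
        "subscale": col,
        "mean_positive_d": float(pos[col].mean()),
        "sd_positive_d": float(pos[col].std(ddof=1)) if len(pos) > 1 else 0.0,
        "mean_negative_d": float(neg[col].mean()),
        "sd_negative_d": float(neg[col].std(ddof=1)) if len(neg) > 1 else 0.0,
        "adjusted_difference": diff,
        "p": p,
        "n_positive": int(len(pos)),
        "n_negative": int(len(neg)),
    }
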