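"""Replicate-study Monte-Carlo experiments on reduced synthetic designs.

These functions run the full analysis chain (simulate -> score ->
contrast -> ANCOVA -> cluster permutation) over many independently seeded
replicate studies to measure its operating characteristics: family-wise
false-positive rate under the null, recovery of an injected D-score
effect, detection of a strong effect at the injected location, and the
direction of the behavioral group difference.

The replicate studies use a reduced grid — 16 channels, 50 samples over
-200..800 ms (20 ms steps), 20 participants per group, 12 epochs per
condition — so hundreds of replicates run in minutes while every stage of
the pipeline is still exercised. The study conditions themselves (noise
model, ex-Gaussian latencies, component templates) are the package
defaults.
"""

from __future__ import annotations

import numpy as np

from . import behavior, glm
from .cluster import build_adjacency, permutation_null
from .montage import make_hemisphere_montage
from .preprocess import baseline_correct, build_contrast, qc_gate
from .synth import SimulationConfig, simulate_behavior, simulate_epochs

__all__ = [
    "reduced_study_config",
    "run_reduced_study",
    "fwer_null_rate",
    "beta_recovery",
    "cluster_sensitivity",
    "dscore_direction_rate",
]

#: neighbor threshold (mm) for the sparse 16-channel reduced montage
REDUCED_NEIGHBOR_MM = 65.0


def _sub_seed(master: int, k: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(k,)).generate_state(1)[0] % (2**31))


def reduced_study_config(seed: int, **overrides) -> SimulationConfig:
    """Reduced-grid study: 16 channels x 50 timepoints, n=20/group."""
    params = dict(
        n_per_group=20,
        seed=seed,
        n_channels=16,
        sampling_rate=50.0,
        epoch_window=(-200.0, 800.0),
        trials_per_block=20,
        epochs_per_condition=12,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def run_reduced_study(
    config: SimulationConfig,
    regressor: str = "d_score",
    n_permutations: int = 800,
    perm_seed: int = 0,
    use_truth_d: bool = False,
    neighbor_mm: float = REDUCED_NEIGHBOR_MM,
) -> dict:
    """One complete synthetic study through the whole pipeline.

    Returns the cluster result for ``regressor``, the OLS GLM field, the
    design, the contrasts and the simulation truth. ``use_truth_d``
    substitutes the latent D (the value the epoch simulator injected) for
    the behaviorally estimated D in the design, isolating GLM recovery
    from D-score measurement noise.
    """
    montage = make_hemisphere_montage(config.n_channels)
    trials, truth = simulate_behavior(config)
    dscores, _ = behavior.score_all(trials)
    if use_truth_d:
        dscores = truth[["participant_id", "d_true"]].rename(columns={"d_true": "d"})
    epochs = simulate_epochs(config, truth, montage)

    by_pid: dict[str, dict] = {}
    for ep in epochs:
        by_pid.setdefault(ep.participant_id, {})[ep.condition] = baseline_correct(ep)
    contrasts = []
    for pid in sorted(by_pid):
        conds = by_pid[pid]
        decision = qc_gate(conds["death_congruent"], conds["life_congruent"])
        if decision.included:
            contrasts.append(build_contrast(conds["death_congruent"], conds["life_congruent"]))

    design = glm.build_design(
        truth, dscores, participants=[c.participant_id for c in contrasts]
    )
    field = glm.fit_field(contrasts, design, method="ols")
    graph = build_adjacency(montage, neighbor_mm)
    result = permutation_null(
        contrasts, design, regressor, graph,
        n_permutations=n_permutations, seed=perm_seed,
    )
    return {
        "config": config,
        "truth": truth,
        "dscores": dscores,
        "contrasts": contrasts,
        "design": design,
        "field": field,
        "cluster_result": result,
        "montage": montage,
    }


def fwer_null_rate(
    n_studies: int = 200,
    seed: int = 0,
    n_permutations: int = 800,
    alpha: float = 0.05,
    regressor: str = "d_score",
) -> float:
    """Family-wise false-positive rate over null replicate studies.

    Every injected effect is zero, so any cluster with corrected p <=
    alpha is a false positive; the returned rate should sit near alpha.
    """
    hits = 0
    for k in range(n_studies):
        cfg = reduced_study_config(seed=_sub_seed(seed, k))
        res = run_reduced_study(
            cfg, regressor=regressor, n_permutations=n_permutations,
            perm_seed=_sub_seed(seed, 10_000 + k),
        )
        if res["cluster_result"].significant(alpha):
            hits += 1
    return hits / n_studies


def _effect_cell(study: dict) -> tuple[int, int]:
    """(channel, time) index of the injected component's centroid/peak."""
    cfg = study["config"]
    montage = study["montage"]
    specs = cfg.resolved_components(montage)
    spec = next(s for s in specs if s.name == cfg.effect_component)
    ch = montage.index(spec.centroid_channel)
    times = study["contrasts"][0].times_ms
    t = int(np.argmin(np.abs(times - spec.peak_latency_ms)))
    return ch, t


def beta_recovery(
    n_replicates: int = 100,
    seed: int = 0,
    beta_d: float = 0.5,
    n_per_group: int = 30,
) -> dict:
    """Coverage and bias of the estimated D slope at the injected cell.

    Each replicate injects ``beta_d`` µV per D-unit on the N100 template,
    fits the mass-univariate OLS model against the injected (latent) D,
    and checks whether the 95% CI at the centroid/peak cell covers the
    truth. Returns the coverage fraction and the mean estimate.
    """
    from scipy import stats

    covered = 0
    estimates = []
    for k in range(n_replicates):
        cfg = reduced_study_config(
            seed=_sub_seed(seed, k), beta_d=beta_d, n_per_group=n_per_group
        )
        montage = make_hemisphere_montage(cfg.n_channels)
        trials, truth = simulate_behavior(cfg)
        dscores = truth[["participant_id", "d_true"]].rename(columns={"d_true": "d"})
        epochs = simulate_epochs(cfg, truth, montage)
        by_pid: dict[str, dict] = {}
        for ep in epochs:
            by_pid.setdefault(ep.participant_id, {})[ep.condition] = baseline_correct(ep)
        contrasts = [
            build_contrast(by_pid[pid]["death_congruent"], by_pid[pid]["life_congruent"])
            for pid in sorted(by_pid)
        ]
        design = glm.build_design(
            truth, dscores, participants=[c.participant_id for c in contrasts]
        )
        field = glm.fit_field(contrasts, design, method="ols")
        j = field.columns.index("d_score")
        specs = cfg.resolved_components(montage)
        spec = next(s for s in specs if s.name == cfg.effect_component)
        ch = montage.index(spec.centroid_channel)
        t = int(np.argmin(np.abs(contrasts[0].times_ms - spec.peak_latency_ms)))
        b = field.beta[j, ch, t]
        F = field.F[j, ch, t]
        se = abs(b) / np.sqrt(F) if F > 0 else np.inf
        tcrit = stats.t.ppf(0.975, field.df_resid)
        if b - tcrit * se <= beta_d <= b + tcrit * se:
            covered += 1
        estimates.append(b)
    return {
        "coverage": covered / n_replicates,
        "mean_estimate": float(np.mean(estimates)),
        "beta_true": beta_d,
        "n_replicates": n_replicates,
    }


def cluster_sensitivity(
    n_replicates: int = 100,
    seed: int = 0,
    beta_d: float = 6.0,
    noise_sd: float = 3.0,
    n_permutations: int = 200,
    alpha: float = 0.05,
) -> float:
    """Fraction of high-SNR replicates whose significant D-score cluster
    contains the injected centroid/peak cell."""
    hits = 0
    for k in range(n_replicates):
        cfg = reduced_study_config(
            seed=_sub_seed(seed, k), beta_d=beta_d, noise_sd=noise_sd
        )
        study = run_reduced_study(
            cfg, regressor="d_score", n_permutations=n_permutations,
            perm_seed=_sub_seed(seed, 10_000 + k), use_truth_d=True,
        )
        cell = _effect_cell(study)
        for cl in study["cluster_result"].significant(alpha):
            if cell in set(cl.cells):
                hits += 1
                break
    return hits / n_replicates


def dscore_direction_rate(
    n_replicates: int = 200,
    seed: int = 0,
    group_shift_mean: float = 150.0,
    n_per_group: int = 30,
) -> float:
    """Fraction of replicates with mean estimated D(sibs) > D(control)."""
    hits = 0
    for k in range(n_replicates):
        cfg = SimulationConfig(
            n_per_group=n_per_group, seed=_sub_seed(seed, k),
            group_shift_mean=group_shift_mean,
        )
        trials, truth = simulate_behavior(cfg)
        dscores, _ = behavior.score_all(trials)
        merged = dscores.merge(truth[["participant_id", "group"]], on="participant_id")
        means = merged.groupby("group")["d"].mean()
        if means["sibs"] > means["control"]:
            hits += 1
    return hits / n_replicates
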