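"""Synthetic DS-IAT studies with known ground truth.

Generates the three ingredients of a two-group implicit-association ERP
study: (1) seven-block IAT reaction-time logs with a participant-level
latent congruency effect, (2) multichannel stimulus-locked epochs whose
condition contrast carries injected group / D-score / age effects on a
named component template, and (3) clinical covariates. Every quantity the
downstream pipeline estimates (D scores, contrast betas, cluster
locations) has a recorded truth, so calibration and recovery are testable
without any external recording.

Reaction times follow an ex-Gaussian model (Gaussian mu/sigma convolved
with an exponential tau), the standard description of IAT latencies.
A participant's latent congruency effect ``e`` is added to their
life-congruent paired blocks, so ``e > 0`` means slower life-congruent
responses and hence a positive D score (death-self association).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .montage import Montage, make_hemisphere_montage, save_montage
from .preprocess import EpochSet

__all__ = [
    "ConfigError",
    "ComponentSpec",
    "SimulationConfig",
    "default_component_specs",
    "simulate_behavior",
    "simulate_epochs",
    "write_fixture_study",
]

#: ex-Gaussian scale used to convert a latency shift (ms) into D units
def _latency_scale(sigma: float, tau: float) -> float:
    return float(np.sqrt(sigma**2 + tau**2))


class ConfigError(ValueError):
    """A simulation parameter is out of its valid range (names the field)."""


@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component template: Gaussian in time, Gaussian on the scalp.

    The template peaks at ``peak_latency_ms`` on ``centroid_channel`` with
    unit height; ``polarity`` (+1/-1) signs the baseline amplitude, so an
    N100-like spec has ``polarity=-1``.
    """

    name: str
    peak_latency_ms: float
    temporal_width_ms: float
    polarity: int
    centroid_channel: str
    spatial_sd_mm: float
    base_amplitude_uv: float

    def validate(self, window: tuple[float, float]) -> None:
        if self.temporal_width_ms <= 0:
            raise ConfigError(f"component {self.name}: temporal_width_ms must be > 0")
        if self.spatial_sd_mm <= 0:
            raise ConfigError(f"component {self.name}: spatial_sd_mm must be > 0")
        if self.polarity not in (-1, 1):
            raise ConfigError(f"component {self.name}: polarity must be +1 or -1")
        if not (window[0] <= self.peak_latency_ms <= window[1]):
            raise ConfigError(
                f"component {self.name}: peak_latency_ms outside epoch window"
            )


def default_component_specs(
    montage: Montage, window: tuple[float, float] = (-200.0, 1000.0)
) -> list[ComponentSpec]:
    """N100 / P200 / LPP-like templates placed on a given montage.

    Centroids are chosen geometrically: N100 left parieto-occipital, P200
    left frontal, LPP centro-parietal — matching the scalp regions where
    these components are classically observed in visual IAT paradigms.
    """
    r = float(np.linalg.norm(montage.positions, axis=1).mean())
    n100 = montage.nearest_channel(r * np.array([-0.45, -0.75, 0.45]))
    p200 = montage.nearest_channel(r * np.array([-0.55, 0.65, 0.5]))
    lpp = montage.nearest_channel(r * np.array([0.0, -0.35, 0.9]))
    specs = [
        ComponentSpec("N100", 200.0, 40.0, -1, n100, 45.0, 5.0),
        ComponentSpec("P200", 230.0, 45.0, +1, p200, 45.0, 4.0),
        ComponentSpec("LPP", 700.0, 150.0, +1, lpp, 60.0, 3.0),
    ]
    return [s for s in specs if window[0] <= s.peak_latency_ms <= window[1]]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; defaults emulate the target design.

    Two groups of ``n_per_group`` adolescents (patients with suicidal
    ideation/behavior, "sibs", vs healthy controls), a 7-block DS-IAT with
    doubled trial counts and 1300–1500 ms jittered ISI, and 64-channel
    epochs at 1000 Hz. ``beta_d`` / ``beta_group`` / ``beta_age`` inject a
    condition-contrast effect (µV per unit) on ``effect_component``.
    """

    n_per_group: int = 30
    seed: int = 0

    # --- behavior ---
    rt_mu: float = 500.0          # ms, ex-Gaussian Gaussian mean
    rt_sigma: float = 80.0        # ms, ex-Gaussian Gaussian SD
    rt_tau: float = 150.0         # ms, ex-Gaussian exponential mean
    congruency_shift_sd: float = 40.0   # ms, between-subject SD of latent effect
    group_shift_mean: float = 45.0      # ms, latent-effect difference sibs - control
    control_latent_mean: float = -60.0  # ms, control-group latent effect mean
    error_rate: float = 0.07
    trials_per_block: int = 40          # paired blocks; single blocks use half

    # --- epochs ---
    n_channels: int = 64
    sampling_rate: float = 1000.0       # Hz
    epoch_window: tuple[float, float] = (-200.0, 1000.0)  # ms
    component_specs: tuple[ComponentSpec, ...] | None = None
    effect_component: str = "N100"
    noise_ar_coeff: float = 0.95        # AR(1) coefficient of temporal noise
    noise_sd: float = 5.0               # µV, stationary SD before smoothing
    spatial_smoothing_mm: float = 30.0  # Gaussian kernel SD of spatial mixing
    beta_d: float = 0.0                 # µV per D-unit on the contrast
    beta_group: float = 0.0             # µV (sibs - control) on the contrast
    beta_age: float = 0.0               # µV per month (centered age)
    epochs_per_condition: int | None = None  # default: 2 * trials_per_block

    # --- covariates ---
    cssrs_controllability_effect: float = 0.0  # points added when d_true > 0

    def validate(self) -> None:
        positive = {
            "n_per_group": self.n_per_group,
            "rt_sigma": self.rt_sigma,
            "rt_tau": self.rt_tau,
            "trials_per_block": self.trials_per_block,
            "n_channels": self.n_channels,
            "sampling_rate": self.sampling_rate,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not (0.0 <= self.noise_ar_coeff < 1.0):
            raise ConfigError("noise_ar_coeff must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigError("error_rate must be in [0, 1)")
        if self.congruency_shift_sd < 0:
            raise ConfigError("congruency_shift_sd must be >= 0")
        lo, hi = self.epoch_window
        if not (lo < 0.0 < hi):
            raise ConfigError("epoch_window must straddle stimulus onset (start < 0 < end)")
        if self.epochs_per_condition is not None and self.epochs_per_condition <= 0:
            raise ConfigError("epochs_per_condition must be > 0")

    def resolved_components(self, montage: Montage) -> list[ComponentSpec]:
        specs = (
            list(self.component_specs)
            if self.component_specs is not None
            else default_component_specs(montage, self.epoch_window)
        )
        for s in specs:
            s.validate(self.epoch_window)
            if s.centroid_channel not in montage.labels:
                raise ConfigError(
                    f"component {s.name}: centroid_channel {s.centroid_channel!r} "
                    "not in montage"
                )
        return specs

    def n_epochs_per_condition(self) -> int:
        return (
            self.epochs_per_condition
            if self.epochs_per_condition is not None
            else 2 * self.trials_per_block
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epoch_window"] = list(self.epoch_window)
        if self.component_specs is not None:
            d["component_specs"] = [asdict(s) for s in self.component_specs]
        return d


def _rng(config: SimulationConfig, stage: int, participant: int) -> np.random.Generator:
    """Per-(stage, participant) substream; participant k reproducible alone."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stage, participant))
    )


_DEATH_WORDS = ["die", "dead", "deceased", "lifeless", "suicide"]
_LIFE_WORDS = ["alive", "survive", "live", "thrive", "breathing"]
_SELF_WORDS = ["I", "myself", "my", "mine", "self"]
_OTHER_WORDS = ["they", "them", "their", "theirs", "other"]


def _exgauss(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    return (
        cfg.rt_mu
        + cfg.rt_sigma * rng.standard_normal(n)
        + rng.exponential(cfg.rt_tau, n)
    )


def simulate_behavior(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate 7-block DS-IAT trial logs plus a participant truth table.

    Returns ``(trials, truth)``. ``trials`` has one row per trial with the
    standard log schema (participant_id, block_index, block_role,
    condition, stimulus, category, correct, latency_ms, isi_ms). ``truth``
    records group, age in months, gender, the latent congruency shift in
    ms, its D-unit equivalent ``d_true``, depression severity (CDRS-R) and
    C-SSRS ideation-intensity subscales.
    """
    config.validate()
    n_total = 2 * config.n_per_group
    scale = _latency_scale(config.rt_sigma, config.rt_tau)

    trial_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    single_n = max(config.trials_per_block // 2, 1)

    for i in range(n_total):
        rng = _rng(config, stage=0, participant=i)
        group = "sibs" if i >= config.n_per_group else "control"
        pid = f"P{i + 1:03d}"
        latent_mean = config.control_latent_mean + (
            config.group_shift_mean if group == "sibs" else 0.0
        )
        latent = latent_mean + config.congruency_shift_sd * rng.standard_normal()

        # counterbalance which pairing comes first
        first = "death_congruent" if i % 2 == 0 else "life_congruent"
        second = "life_congruent" if first == "death_congruent" else "death_congruent"
        blocks = [
            (1, "single", "none", single_n),
            (2, "single", "none", single_n),
            (3, "practice", first, config.trials_per_block),
            (4, "test", first, config.trials_per_block),
            (5, "single", "none", single_n),
            (6, "practice", second, config.trials_per_block),
            (7, "test", second, config.trials_per_block),
        ]
        recs: dict[str, list] = {k: [] for k in (
            "participant_id", "block_index", "block_role", "condition",
            "stimulus", "category", "correct", "latency_ms", "isi_ms")}
        for block_index, role, condition, n in blocks:
            lat = _exgauss(rng, n, config)
            if condition == "life_congruent":
                lat = lat + latent
            lat = np.maximum(lat, 1.0)
            correct = rng.random(n) >= config.error_rate
            isi = rng.uniform(1300.0, 1500.0, n)
            cats = []
            stims = []
            pools = (
                [("death", _DEATH_WORDS), ("life", _LIFE_WORDS),
                 ("self", _SELF_WORDS), ("other", _OTHER_WORDS)]
                if condition != "none"
                else [("death", _DEATH_WORDS), ("life", _LIFE_WORDS)]
            )
            for t in range(n):
                cat, words = pools[t % len(pools)]
                cats.append(cat)
                stims.append(words[t % len(words)])
            recs["participant_id"].extend([pid] * n)
            recs["block_index"].extend([block_index] * n)
            recs["block_role"].extend([role] * n)
            recs["condition"].extend([condition] * n)
            recs["stimulus"].extend(stims)
            recs["category"].extend(cats)
            recs["correct"].extend(correct.astype(int).tolist())
            recs["latency_ms"].extend(np.round(lat, 3).tolist())
            recs["isi_ms"].extend(np.round(isi, 1).tolist())
        trial_frames.append(pd.DataFrame(recs))

        d_true = latent / scale
        # gender proportions follow the demographic table of the emulated study
        p_female = 0.78 if group == "sibs" else 0.53
        gender = "female" if rng.random() < p_female else "male"
        age = int(rng.integers(156, 217))
        if group == "sibs":
            cdrs = float(np.clip(rng.normal(56.3, 10.3), 17, 113))
            cssrs = {
                k: int(np.clip(rng.integers(1, 6), 0, 5))
                for k in ("duration", "deterrents", "reasons", "frequency")
            }
            controllability = rng.integers(1, 6) + (
                config.cssrs_controllability_effect if d_true > 0 else 0.0
            )
            cssrs["controllability"] = int(np.clip(round(controllability), 0, 5))
        else:
            cdrs = float(np.clip(rng.normal(20.0, 3.0), 17, 113))
            cssrs = {k: 0 for k in (
                "duration", "deterrents", "reasons", "frequency", "controllability")}
        truth_rows.append({
            "participant_id": pid,
            "group": group,
            "age_months": age,
            "gender": gender,
            "latent_shift_ms": latent,
            "d_true": d_true,
            "cdrs_r_total": cdrs,
            **{f"cssrs_{k}": v for k, v in cssrs.items()},
        })

    trials = pd.concat(trial_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def _component_shapes(
    specs: list[ComponentSpec], montage: Montage, times_ms: np.ndarray
) -> np.ndarray:
    """Unit-height templates, (n_components, n_channels, n_times).

    The temporal Gaussian is zeroed before stimulus onset so the baseline
    interval carries noise only.
    """
    shapes = np.empty((len(specs), montage.n_channels, times_ms.size))
    for k, s in enumerate(specs):
        temporal = np.exp(-0.5 * ((times_ms - s.peak_latency_ms) / s.temporal_width_ms) ** 2)
        temporal[times_ms < 0] = 0.0
        ci = montage.index(s.centroid_channel)
        dist = np.linalg.norm(montage.positions - montage.positions[ci], axis=1)
        spatial = np.exp(-0.5 * (dist / s.spatial_sd_mm) ** 2)
        shapes[k] = spatial[:, None] * temporal[None, :]
    return shapes


def epoch_times_ms(config: SimulationConfig) -> np.ndarray:
    lo, hi = config.epoch_window
    dt = 1000.0 / config.sampling_rate
    n = int(round((hi - lo) / dt))
    return lo + dt * np.arange(n)


def simulate_epochs(
    config: SimulationConfig,
    truth: pd.DataFrame,
    montage: Montage | None = None,
) -> list[EpochSet]:
    """Simulate per-participant, per-condition epochs (channels x time x trials).

    Each trial is the sum of the component templates scaled by
    ``polarity * base_amplitude`` plus, on ``effect_component``, half the
    participant's condition contrast ``delta = beta_group*g + beta_d*d_true
    + beta_age*age_c`` (added for death-congruent, subtracted for
    life-congruent trials, so avg(death) - avg(life) = delta at the
    template peak), plus AR(1) temporal noise mixed spatially with a
    Gaussian kernel.
    """
    config.validate()
    if montage is None:
        montage = make_hemisphere_montage(config.n_channels)
    if montage.n_channels != config.n_channels:
        raise ConfigError("n_channels does not match the supplied montage")
    specs = config.resolved_components(montage)
    times = epoch_times_ms(config)
    shapes = _component_shapes(specs, montage, times)
    names = [s.name for s in specs]
    if config.effect_component not in names and (
        config.beta_d or config.beta_group or config.beta_age
    ):
        raise ConfigError(f"effect_component {config.effect_component!r} not among components")
    k_eff = names.index(config.effect_component) if config.effect_component in names else 0

    base = np.array([s.polarity * s.base_amplitude_uv for s in specs])
    base_signal = np.tensordot(base, shapes, axes=1)  # (ch, t)

    # spatial mixing matrix, rows normalized to sum 1 (convex combination)
    if config.spatial_smoothing_mm > 0:
        d = montage.distances()
        S = np.exp(-0.5 * (d / config.spatial_smoothing_mm) ** 2)
        S /= S.sum(axis=1, keepdims=True)
    else:
        S = None

    age_c = truth["age_months"].to_numpy(float)
    age_c = age_c - age_c.mean()
    n_trials = config.n_epochs_per_condition()
    burn = 100 if config.noise_ar_coeff > 0 else 0
    innov_sd = config.noise_sd * np.sqrt(1.0 - config.noise_ar_coeff**2)

    out: list[EpochSet] = []
    for i, row in enumerate(truth.itertuples(index=False)):
        rng = _rng(config, stage=1, participant=i)
        delta = (
            config.beta_group * (row.group == "sibs")
            + config.beta_d * row.d_true
            + config.beta_age * age_c[i]
        )
        for condition, sign in (("death_congruent", +1.0), ("life_congruent", -1.0)):
            signal = base_signal + sign * 0.5 * delta * shapes[k_eff]
            if config.noise_sd > 0:
                white = rng.standard_normal((n_trials, montage.n_channels, times.size + burn))
                noise = lfilter([1.0], [1.0, -config.noise_ar_coeff], innov_sd * white, axis=-1)
                noise = noise[..., burn:]
                if S is not None:
                    noise = np.einsum("cd,ndt->nct", S, noise)
                data = signal[None, :, :] + noise
            else:
                data = np.broadcast_to(signal, (n_trials, *signal.shape)).copy()
            out.append(
                EpochSet(
                    participant_id=row.participant_id,
                    condition=condition,
                    data=np.ascontiguousarray(np.moveaxis(data, 0, -1)),
                    sampling_rate=config.sampling_rate,
                    window=tuple(config.epoch_window),
                    channel_names=montage.labels,
                )
            )
    return out


def write_fixture_study(config: SimulationConfig, out_dir) -> dict:
    """Materialize a complete synthetic study on disk; returns the manifest.

    Writes ``trials.csv``, ``covariates.csv``, ``truth.csv``,
    ``montage.txt``, ``epochs.h5`` and ``manifest.json`` into ``out_dir``.
    The covariate file exposes only what a real study would have (group,
    age, gender, clinical scores); latent truth stays in ``truth.csv``.
    """
    from . import io as eio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials, truth = simulate_behavior(config)
    montage = make_hemisphere_montage(config.n_channels)
    epochs = simulate_epochs(config, truth, montage)

    trials.to_csv(out / "trials.csv", index=False)
    cov_cols = [
        "participant_id", "group", "age_months", "gender", "cdrs_r_total",
        "cssrs_duration", "cssrs_deterrents", "cssrs_reasons",
        "cssrs_frequency", "cssrs_controllability",
    ]
    truth[cov_cols].to_csv(out / "covariates.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    save_montage(montage, out / "montage.txt")
    eio.write_epochs(out / "epochs.h5", epochs)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_participants": int(2 * config.n_per_group),
        "participants": truth["participant_id"].tolist(),
        "files": {
            "trials": "trials.csv",
            "covariates": "covariates.csv",
            "truth": "truth.csv",
            "montage": "montage.txt",
            "epochs": "epochs.h5",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
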