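"""Per-subject ERP averaging: baseline correction, artifact handling, QC,
and the death-minus-life condition contrast that feeds the group-level model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EpochSet",
    "SubjectContrast",
    "QCDecision",
    "baseline_correct",
    "reject_artifacts",
    "qc_gate",
    "build_contrast",
]


@dataclass
class EpochSet:
    """Single-condition epochs for one participant.

    ``data`` is channels x timepoints x trials in µV; ``window`` is the
    epoch extent in ms relative to stimulus onset.
    """

    participant_id: str
    condition: str
    data: np.ndarray
    sampling_rate: float
    window: tuple[float, float]
    channel_names: tuple[str, ...]
    interpolation_log: list[dict] = field(default_factory=list)
    dropped_trials: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x timepoints x trials")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length does not match data")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite voltage in epochs")
        n_expected = int(round((self.window[1] - self.window[0]) * self.sampling_rate / 1000.0))
        if abs(self.data.shape[1] - n_expected) > 1:
            raise ValueError(
                f"timepoints ({self.data.shape[1]}) inconsistent with window/"
                f"sampling_rate (expected ~{n_expected})"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sampling_rate
        return self.window[0] + dt * np.arange(self.data.shape[1])

    def average(self) -> np.ndarray:
        """Trial-mean ERP, channels x timepoints."""
        return self.data.mean(axis=2)


@dataclass
class SubjectContrast:
    """Death-congruent minus life-congruent average, channels x timepoints."""

    participant_id: str
    delta: np.ndarray
    n_epochs_death: int
    n_epochs_life: int
    sampling_rate: float
    window: tuple[float, float]
    channel_names: tuple[str, ...]

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sampling_rate
        return self.window[0] + dt * np.arange(self.delta.shape[1])


@dataclass(frozen=True)
class QCDecision:
    participant_id: str
    included: bool
    n_epochs_death: int
    n_epochs_life: int
    reason: str


def baseline_correct(epochs: EpochSet, baseline: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract the per-channel, per-trial mean over ``baseline`` (ms)."""
    lo, hi = baseline
    w0, w1 = epochs.window
    if lo < w0 or hi > w1 or lo >= hi:
        raise ValueError(f"baseline {baseline} outside epoch window {epochs.window}")
    t = epochs.times_ms
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise ValueError("baseline interval contains no samples")
    means = epochs.data[:, mask, :].mean(axis=1, keepdims=True)
    return replace(epochs, data=epochs.data - means)


def _interpolation_weights(positions: np.ndarray, bad: int, good: np.ndarray) -> np.ndarray:
    """Inverse-squared-distance weights over good channels (sum to 1)."""
    d = np.linalg.norm(positions[good] - positions[bad], axis=1)
    d = np.maximum(d, 1e-6)
    w = 1.0 / d**2
    return w / w.sum()


def reject_artifacts(
    epochs: EpochSet,
    positions: np.ndarray,
    peak_to_peak_max: float = 100.0,
    max_bad_channels_per_trial: int = 10,
    channel_bad_fraction: float = 0.3,
) -> EpochSet:
    """Trial-by-trial artifact handling with channel interpolation.

    Per trial, a channel whose peak-to-peak amplitude exceeds
    ``peak_to_peak_max`` µV is interpolated for that trial from the good
    channels, weighted by inverse squared sensor distance. Trials with more
    than ``max_bad_channels_per_trial`` bad channels are dropped. Channels
    bad in more than ``channel_bad_fraction`` of trials are interpolated on
    every trial. Every action is appended to the interpolation log.
    """
    if peak_to_peak_max <= 0 or max_bad_channels_per_trial < 0:
        raise ValueError("thresholds must be positive")
    positions = np.asarray(positions, float)
    if positions.shape != (epochs.data.shape[0], 3):
        raise ValueError("positions must be (n_channels, 3)")

    data = epochs.data.copy()
    n_ch, _, n_tr = data.shape
    ptp = data.max(axis=1) - data.min(axis=1)  # (ch, trials)
    bad = ptp > peak_to_peak_max

    # channels globally bad are interpolated on all trials
    globally_bad = bad.mean(axis=1) > channel_bad_fraction
    log: list[dict] = []
    for ch in np.flatnonzero(globally_bad):
        bad[ch, :] = True
        log.append({"action": "interpolate_global", "channel": epochs.channel_names[ch]})

    keep = bad.sum(axis=0) <= max_bad_channels_per_trial
    dropped = np.flatnonzero(~keep).tolist()
    for tr in dropped:
        log.append({"action": "drop_trial", "trial": int(tr)})

    for tr in np.flatnonzero(keep):
        bad_ch = np.flatnonzero(bad[:, tr])
        if bad_ch.size == 0:
            continue
        good_ch = np.flatnonzero(~bad[:, tr])
        if good_ch.size == 0:
            continue  # nothing to interpolate from; trial survives untouched
        for ch in bad_ch:
            w = _interpolation_weights(positions, ch, good_ch)
            data[ch, :, tr] = w @ data[good_ch, :, tr]
            log.append({
                "action": "interpolate_trial",
                "channel": epochs.channel_names[ch],
                "trial": int(tr),
            })

    out = replace(
        epochs,
        data=data[:, :, keep],
        interpolation_log=epochs.interpolation_log + log,
        dropped_trials=epochs.dropped_trials + dropped,
    )
    return out


def qc_gate(
    epochs_death: EpochSet, epochs_life: EpochSet, min_epochs: int = 10
) -> QCDecision:
    """Exclude a participant iff either condition has < ``min_epochs`` trials."""
    nd, nl = epochs_death.n_trials, epochs_life.n_trials
    included = nd >= min_epochs and nl >= min_epochs
    reason = "ok" if included else f"too few epochs (<{min_epochs} per condition)"
    return QCDecision(
        participant_id=epochs_death.participant_id,
        included=included,
        n_epochs_death=nd,
        n_epochs_life=nl,
        reason=reason,
    )


def _decimate(avg: np.ndarray, factor: int) -> np.ndarray:
    """Boxcar low-pass of length ``factor`` then pick every ``factor``-th sample."""
    if factor <= 1:
        return avg
    n = (avg.shape[1] // factor) * factor
    return avg[:, :n].reshape(avg.shape[0], -1, factor).mean(axis=2)


def build_contrast(
    epochs_death: EpochSet,
    epochs_life: EpochSet,
    decimate: int = 1,
) -> SubjectContrast:
    """Per-subject condition contrast: avg(death) - avg(life), elementwise.

    ``decimate`` > 1 applies an identical boxcar average + downsample to
    both condition averages before differencing, to keep the downstream
    channel x time grid tractable; latencies stay expressed in original ms.
    """
    if epochs_death.participant_id != epochs_life.participant_id:
        raise ValueError("conditions belong to different participants")
    if epochs_death.channel_names != epochs_life.channel_names:
        raise ValueError("channel sets differ between conditions")
    if epochs_death.window != epochs_life.window or (
        epochs_death.sampling_rate != epochs_life.sampling_rate
    ):
        raise ValueError("epoch windows/sampling rates differ between conditions")
    avg_d = _decimate(epochs_death.average(), decimate)
    avg_l = _decimate(epochs_life.average(), decimate)
    return SubjectContrast(
        participant_id=epochs_death.participant_id,
        delta=avg_d - avg_l,
        n_epochs_death=epochs_death.n_trials,
        n_epochs_life=epochs_life.n_trials,
        sampling_rate=epochs_death.sampling_rate / decimate,
        window=epochs_death.window,
        channel_names=epochs_death.channel_names,
    )
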