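"""On-disk containers: HDF5 epochs/contrasts/GLM fields, CSV tables.

Epoch layout: ``/participant/<id>/condition/<label>`` holds a float array
(channels x time x trials); file-level attributes carry sampling_rate,
window (ms) and channel names, which are shared across the study.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .glm import GLMField
from .preprocess import EpochSet, SubjectContrast

__all__ = [
    "write_epochs", "read_epochs",
    "write_contrasts", "read_contrasts",
    "write_glm_field", "read_glm_field",
    "read_trials", "read_covariates",
]

TRIAL_COLUMNS = [
    "participant_id", "block_index", "block_role", "condition",
    "stimulus", "category", "correct", "latency_ms", "isi_ms",
]


def _write_common_attrs(f: h5py.File, sampling_rate, window, channel_names) -> None:
    f.attrs["sampling_rate"] = float(sampling_rate)
    f.attrs["window_ms"] = np.asarray(window, float)
    f.attrs["channel_names"] = np.array(list(channel_names), dtype="S32")


def _read_common_attrs(f: h5py.File):
    sr = float(f.attrs["sampling_rate"])
    window = tuple(float(v) for v in f.attrs["window_ms"])
    channels = tuple(n.decode() for n in f.attrs["channel_names"])
    return sr, window, channels


def write_epochs(path, epochs: list[EpochSet]) -> None:
    if not epochs:
        raise ValueError("no epochs to write")
    ref = epochs[0]
    with h5py.File(path, "w") as f:
        _write_common_attrs(f, ref.sampling_rate, ref.window, ref.channel_names)
        for ep in epochs:
            grp = f.require_group(f"participant/{ep.participant_id}/condition")
            grp.create_dataset(ep.condition, data=ep.data)


def read_epochs(path) -> list[EpochSet]:
    out: list[EpochSet] = []
    with h5py.File(path, "r") as f:
        sr, window, channels = _read_common_attrs(f)
        for pid in sorted(f["participant"]):
            cond_grp = f[f"participant/{pid}/condition"]
            for cond in sorted(cond_grp):
                out.append(EpochSet(
                    participant_id=pid,
                    condition=cond,
                    data=cond_grp[cond][()],
                    sampling_rate=sr,
                    window=window,
                    channel_names=channels,
                ))
    return out


def write_contrasts(path, contrasts: list[SubjectContrast]) -> None:
    if not contrasts:
        raise ValueError("no contrasts to write")
    ref = contrasts[0]
    with h5py.File(path, "w") as f:
        _write_common_attrs(f, ref.sampling_rate, ref.window, ref.channel_names)
        grp = f.require_group("contrast")
        for c in contrasts:
            ds = grp.create_dataset(c.participant_id, data=c.delta)
            ds.attrs["n_epochs_death"] = c.n_epochs_death
            ds.attrs["n_epochs_life"] = c.n_epochs_life


def read_contrasts(path) -> list[SubjectContrast]:
    out: list[SubjectContrast] = []
    with h5py.File(path, "r") as f:
        sr, window, channels = _read_common_attrs(f)
        grp = f["contrast"]
        for pid in sorted(grp):
            ds = grp[pid]
            out.append(SubjectContrast(
                participant_id=pid,
                delta=ds[()],
                n_epochs_death=int(ds.attrs["n_epochs_death"]),
                n_epochs_life=int(ds.attrs["n_epochs_life"]),
                sampling_rate=sr,
                window=window,
                channel_names=channels,
            ))
    return out


def write_glm_field(path, field: GLMField) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["df_model"] = field.df_model
        f.attrs["df_resid"] = field.df_resid
        f.attrs["method"] = field.method
        f.attrs["channel_names"] = np.array(list(field.channel_names), dtype="S32")
        f.attrs["times_ms"] = field.times_ms
        for j, name in enumerate(field.columns):
            grp = f.require_group(f"regressor/{name}")
            grp.create_dataset("beta", data=field.beta[j])
            grp.create_dataset("F", data=field.F[j])
            grp.create_dataset("p", data=field.p_uncorrected[j])
        if field.robust_fallback is not None:
            f.create_dataset("robust_fallback", data=field.robust_fallback)


def read_glm_field(path) -> GLMField:
    with h5py.File(path, "r") as f:
        names = tuple(f["regressor"].keys())
        # preserve canonical ordering if present
        order = [n for n in ("intercept", "group", "d_score", "age_months") if n in names]
        order += [n for n in names if n not in order]
        beta = np.stack([f[f"regressor/{n}/beta"][()] for n in order])
        F = np.stack([f[f"regressor/{n}/F"][()] for n in order])
        p = np.stack([f[f"regressor/{n}/p"][()] for n in order])
        return GLMField(
            columns=tuple(order),
            beta=beta,
            F=F,
            p_uncorrected=p,
            df_model=int(f.attrs["df_model"]),
            df_resid=int(f.attrs["df_resid"]),
            method=str(f.attrs["method"]),
            channel_names=tuple(n.decode() for n in f.attrs["channel_names"]),
            times_ms=f.attrs["times_ms"][()],
            robust_fallback=f["robust_fallback"][()] if "robust_fallback" in f else None,
        )


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing columns: {missing}")
    return df


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("participant_id", "group", "age_months", "gender"):
        if col not in df.columns:
            raise ValueError(f"covariate CSV missing column: {col}")
    if df["participant_id"].duplicated().any():
        raise ValueError("duplicate participant rows in covariate CSV")
    return df
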