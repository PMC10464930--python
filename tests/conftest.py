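import numpy as np
import pandas as pd
import pytest

from erpiat import SimulationConfig, simulate_behavior, simulate_epochs
from erpiat.montage import make_hemisphere_montage


@pytest.fixture(scope="session")
def small_config():
    """Tiny but complete study: 8 channels, 25 Hz grid, 4 per group."""
    return SimulationConfig(
        n_per_group=4,
        seed=7,
        n_channels=8,
        sampling_rate=25.0,
        epoch_window=(-200.0, 800.0),
        trials_per_block=8,
        epochs_per_condition=12,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    trials, truth = simulate_behavior(small_config)
    montage = make_hemisphere_montage(small_config.n_channels)
    epochs = simulate_epochs(small_config, truth, montage)
    return {
        "config": small_config,
        "trials": trials,
        "truth": truth,
        "montage": montage,
        "epochs": epochs,
    }


def make_participant_trials(
    pid="P001",
    death=(600, 650, 700, 750),
    life=(800, 850, 900, 950),
    correct=None,
    roles=None,
):
    """Minimal paired-block trial frame for D-score tests."""
    rows = []
    n = len(death) + len(life)
    correct = [1] * n if correct is None else list(correct)
    k = 0
    for cond, blocks, lats in (
        ("death_congruent", (3, 4), death),
        ("life_congruent", (6, 7), life),
    ):
        half = len(lats) // 2
        for i, lat in enumerate(lats):
            block = blocks[0] if i < half else blocks[1]
            role = "practice" if i < half else "test"
            rows.append({
                "participant_id": pid,
                "block_index": block,
                "block_role": role,
                "condition": cond,
                "stimulus": "word",
                "category": "death",
                "correct": correct[k],
                "latency_ms": float(lat),
                "isi_ms": 1400.0,
            })
            k += 1
    return pd.DataFrame(rows)
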