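"""Generate a synthetic DS-IAT/ERP study and look at its ground truth.

The generator emulates a two-group design (patients with suicidal
ideation/behavior vs healthy controls): seven-block IAT reaction-time
logs, 64-channel epochs with N100/P200/LPP-like components, and clinical
covariates. Here we use a reduced 16-channel grid so it runs in seconds.
"""

from erpiat import SimulationConfig, simulate_behavior, simulate_epochs
from erpiat.montage import make_hemisphere_montage

config = SimulationConfig(
    n_per_group=10,
    seed=7,
    n_channels=16,
    sampling_rate=50.0,
    epoch_window=(-200.0, 800.0),
    trials_per_block=20,
    epochs_per_condition=12,
)

trials, truth = simulate_behavior(config)
print(f"{len(trials)} trials across {truth.shape[0]} participants")
print("\nLatent congruency effect by group (ms; positive = slower "
      "life-congruent responding, i.e. a death-self association):")
print(truth.groupby("group")[["latent_shift_ms", "d_true"]].mean().round(3))

montage = make_hemisphere_montage(config.n_channels)
epochs = simulate_epochs(config, truth, montage)
ep = epochs[0]
print(f"\nFirst epoch set: {ep.participant_id} / {ep.condition}, "
      f"data {ep.data.shape} (channels x timepoints x trials)")
print("By default the control group carries a negative latent shift "
      "(faster life-congruent responding), so both groups have negative "
      "mean D with the patient group closer to zero.")
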