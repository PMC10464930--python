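"""Synthetic study generator: determinism, structure, injected effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import erpiat
from erpiat import (
    ConfigError,
    SimulationConfig,
    simulate_behavior,
    simulate_epochs,
    write_fixture_study,
)
from erpiat.montage import make_hemisphere_montage
from erpiat import io as eio


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs, named_field",
        [
            ({"n_per_group": 0}, "n_per_group"),
            ({"rt_sigma": -1.0}, "rt_sigma"),
            ({"noise_ar_coeff": 1.0}, "noise_ar_coeff"),
            ({"epoch_window": (100.0, 800.0)}, "epoch_window"),
            ({"error_rate": 1.5}, "error_rate"),
        ],
    )
    def test_invalid_config_names_offending_field(self, kwargs, named_field):
        with pytest.raises(ConfigError, match=named_field):
            SimulationConfig(**kwargs).validate()

    def test_unknown_centroid_channel_rejected(self):
        montage = make_hemisphere_montage(8)
        cfg = SimulationConfig(
            n_per_group=2, n_channels=8, sampling_rate=25.0,
            epoch_window=(-200.0, 800.0),
            component_specs=(erpiat.ComponentSpec(
                "N100", 200.0, 40.0, -1, "NOPE", 45.0, 5.0),),
        )
        _, truth = simulate_behavior(cfg)
        with pytest.raises(ConfigError, match="NOPE"):
            simulate_epochs(cfg, truth, montage)


class TestBehaviorSimulation:
    def test_block_layout(self, small_study):
        trials = small_study["trials"]
        one = trials[trials["participant_id"] == "P001"]
        assert sorted(one["block_index"].unique()) == [1, 2, 3, 4, 5, 6, 7]
        paired = one[one["condition"] != "none"]
        assert set(paired["block_index"]) == {3, 4, 6, 7}
        # each pairing spans one practice and one test block
        for cond in ("death_congruent", "life_congruent"):
            roles = set(paired.loc[paired["condition"] == cond, "block_role"])
            assert roles == {"practice", "test"}

    def test_determinism_same_seed(self, small_config):
        t1, truth1 = simulate_behavior(small_config)
        t2, truth2 = simulate_behavior(small_config)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_seed_sensitivity(self, small_config):
        from dataclasses import replace

        t1, _ = simulate_behavior(small_config)
        t2, _ = simulate_behavior(replace(small_config, seed=small_config.seed + 1))
        assert not t1["latency_ms"].equals(t2["latency_ms"])

    def test_degenerate_latent_effect_is_identical_zero(self):
        cfg = SimulationConfig(
            n_per_group=3, congruency_shift_sd=0.0, group_shift_mean=0.0,
            control_latent_mean=0.0, trials_per_block=4, seed=1,
        )
        _, truth = simulate_behavior(cfg)
        assert np.all(truth["latent_shift_ms"] == 0.0)
        assert np.all(truth["d_true"] == 0.0)

    def test_error_rate_in_declared_range(self, small_study):
        trials = small_study["trials"]
        rate = 1.0 - trials["correct"].mean()
        assert 0.02 <= rate <= 0.15  # nominal 7%, small-sample slack

    def test_latent_to_d_monotonicity(self):
        """Larger latent congruency shift -> larger estimated D (rank r > 0.9)."""
        cfg = SimulationConfig(
            n_per_group=30, seed=3, congruency_shift_sd=120.0, trials_per_block=40,
        )
        trials, truth = simulate_behavior(cfg)
        dscores, _ = erpiat.score_all(trials)
        merged = truth.merge(dscores, on="participant_id")
        rho = stats.spearmanr(merged["latent_shift_ms"], merged["d"]).statistic
        assert rho > 0.9


class TestEpochSimulation:
    def test_zero_noise_trials_equal_template_and_conditions_match(self):
        cfg = SimulationConfig(
            n_per_group=2, seed=5, n_channels=8, sampling_rate=25.0,
            epoch_window=(-200.0, 800.0), trials_per_block=4,
            epochs_per_condition=3, noise_sd=0.0,
        )
        _, truth = simulate_behavior(cfg)
        epochs = simulate_epochs(cfg, truth)
        by_pid = {}
        for ep in epochs:
            by_pid.setdefault(ep.participant_id, {})[ep.condition] = ep
        for conds in by_pid.values():
            for ep in conds.values():
                # every trial identical to the deterministic template sum
                assert np.allclose(ep.data, ep.data[:, :, :1])
            np.testing.assert_allclose(
                conds["death_congruent"].data, conds["life_congruent"].data
            )

    def test_baseline_interval_is_noise_only(self):
        cfg = SimulationConfig(
            n_per_group=1, seed=6, n_channels=8, sampling_rate=25.0,
            epoch_window=(-200.0, 800.0), trials_per_block=4,
            epochs_per_condition=2, noise_sd=0.0,
        )
        _, truth = simulate_behavior(cfg)
        ep = simulate_epochs(cfg, truth)[0]
        pre = ep.times_ms < 0
        assert np.all(ep.data[:, pre, :] == 0.0)

    def test_injected_contrast_appears_at_centroid_peak(self):
        cfg = SimulationConfig(
            n_per_group=3, seed=8, n_channels=16, sampling_rate=50.0,
            epoch_window=(-200.0, 800.0), trials_per_block=4,
            epochs_per_condition=2, noise_sd=0.0, beta_d=1.0,
        )
        montage = make_hemisphere_montage(16)
        _, truth = simulate_behavior(cfg)
        epochs = simulate_epochs(cfg, truth, montage)
        spec = next(
            s for s in cfg.resolved_components(montage) if s.name == "N100"
        )
        ch = montage.index(spec.centroid_channel)
        for i, pid in enumerate(truth["participant_id"]):
            death = next(e for e in epochs if e.participant_id == pid
                         and e.condition == "death_congruent")
            life = next(e for e in epochs if e.participant_id == pid
                        and e.condition == "life_congruent")
            t = np.argmin(np.abs(death.times_ms - spec.peak_latency_ms))
            delta = death.data[ch, t, 0] - life.data[ch, t, 0]
            assert delta == pytest.approx(truth["d_true"].iloc[i], abs=1e-10)

    def test_epoch_determinism(self, small_config, small_study):
        again = simulate_epochs(small_config, small_study["truth"], small_study["montage"])
        np.testing.assert_array_equal(again[0].data, small_study["epochs"][0].data)
        np.testing.assert_array_equal(again[-1].data, small_study["epochs"][-1].data)


class TestFixtureStudy:
    def test_roundtrip_and_manifest(self, small_config, tmp_path):
        manifest = write_fixture_study(small_config, tmp_path / "study")
        assert manifest["n_participants"] == 2 * small_config.n_per_group
        assert len(manifest["participants"]) == manifest["n_participants"]
        back = eio.read_epochs(tmp_path / "study" / "epochs.h5")
        fresh = simulate_epochs(
            small_config,
            pd.read_csv(tmp_path / "study" / "truth.csv"),
            make_hemisphere_montage(small_config.n_channels),
        )
        lookup = {(e.participant_id, e.condition): e for e in fresh}
        for ep in back:
            np.testing.assert_array_equal(
                ep.data, lookup[(ep.participant_id, ep.condition)].data
            )
        cov = pd.read_csv(tmp_path / "study" / "covariates.csv")
        assert "latent_shift_ms" not in cov.columns
        assert len(cov) == manifest["n_participants"]

    def test_two_seeds_differ(self, tmp_path):
        from dataclasses import replace

        cfg = SimulationConfig(n_per_group=2, seed=1, n_channels=8,
                               sampling_rate=25.0, epoch_window=(-200.0, 800.0),
                               trials_per_block=4, epochs_per_condition=2)
        write_fixture_study(cfg, tmp_path / "a")
        write_fixture_study(replace(cfg, seed=2), tmp_path / "b")
        ta = pd.read_csv(tmp_path / "a" / "trials.csv")
        tb = pd.read_csv(tmp_path / "b" / "trials.csv")
        assert not ta["latency_ms"].equals(tb["latency_ms"])
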