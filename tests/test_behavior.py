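"""D-score algorithm and behavioral group statistics."""

import numpy as np
import pandas as pd
import pytest

from erpiat import (
    ScoringPolicy,
    UnscorableParticipantError,
    compute_d_score,
    cssrs_subscale_comparison,
    d_score_group_test,
    score_all,
)
from conftest import make_participant_trials
from oracles import dscore_bruteforce


class TestComputeDScore:
    def test_hand_example(self):
        """Death 600-750, life 800-950, all correct: D = 200 / inclusive SD."""
        res = compute_d_score(make_participant_trials())
        assert res.d == pytest.approx(200.0 / 122.47448713915891, abs=1e-9)
        assert res.pooled_sd_ms == pytest.approx(122.47448713915891, abs=1e-9)
        assert res.n_used == 8
        assert res.mean_death_congruent_ms == 675.0
        assert res.mean_life_congruent_ms == 875.0

    def test_identical_multisets_give_zero(self):
        same = (600, 700, 800, 900)
        res = compute_d_score(make_participant_trials(death=same, life=same))
        assert res.d == 0.0

    def test_orientation_swap_negates_d(self):
        a = compute_d_score(make_participant_trials())
        b = compute_d_score(
            make_participant_trials(death=(800, 850, 900, 950), life=(600, 650, 700, 750))
        )
        assert b.d == pytest.approx(-a.d, abs=1e-12)

    def test_fast_latency_recoded_to_300(self):
        res = compute_d_score(make_participant_trials(death=(200, 650, 700, 750)))
        assert res.n_recoded_low == 1
        # the 200 ms trial enters the computation as 300 ms
        expected = compute_d_score(make_participant_trials(death=(300, 650, 700, 750)))
        assert res.d == pytest.approx(expected.d, abs=1e-12)

    def test_slow_latency_recoded_and_huge_dropped(self):
        res = compute_d_score(
            make_participant_trials(life=(3500, 850, 900, 950, 12_000, 800))
        )
        assert res.n_recoded_high == 1
        assert res.n_dropped == 1
        assert res.n_used == 9

    def test_scale_invariance_without_recode_bounds(self):
        policy = ScoringPolicy(recode_bounds=None, drop_above_ms=np.inf)
        base = compute_d_score(make_participant_trials(), policy)
        scaled = compute_d_score(
            make_participant_trials(
                death=tuple(3 * v for v in (600, 650, 700, 750)),
                life=tuple(3 * v for v in (800, 850, 900, 950)),
            ),
            policy,
        )
        assert scaled.d == pytest.approx(base.d, rel=1e-12)

    def test_error_penalty_uses_block_mean_plus_600(self):
        trials = make_participant_trials(correct=[0, 1, 1, 1, 1, 1, 1, 1])
        res = compute_d_score(trials)
        # block 3 holds latencies (600, 650); the error (600) becomes 650 + 600
        assert res.mean_death_congruent_ms == pytest.approx((1250 + 650 + 700 + 750) / 4)

    def test_drop_policy_removes_error_trials(self):
        trials = make_participant_trials(correct=[0, 1, 1, 1, 1, 1, 1, 1])
        res = compute_d_score(trials, ScoringPolicy(error_policy="drop"))
        assert res.n_used == 7
        assert res.n_dropped == 1

    def test_empty_condition_unscorable(self):
        trials = make_participant_trials()
        trials = trials[trials["condition"] != "life_congruent"]
        with pytest.raises(UnscorableParticipantError):
            compute_d_score(trials)

    def test_nonfinite_latency_rejected(self):
        trials = make_participant_trials()
        trials.loc[0, "latency_ms"] = np.nan
        with pytest.raises(ValueError):
            compute_d_score(trials)

    def test_averaged_variant_uses_per_pair_inclusive_sd(self):
        # practice pair: {600,650} vs {800,850}; test pair: {700,750} vs {900,950}
        # each pair: diff 200, inclusive SD sqrt(42500/3); averaged D = their mean
        trials = make_participant_trials()
        averaged = compute_d_score(trials, ScoringPolicy(combine="averaged"))
        expected = 200.0 / np.sqrt(42500.0 / 3.0)
        assert averaged.d == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_on_random_participants(self):
        """Dual-route check against an independent longhand implementation."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(6, 40))
            death = rng.uniform(120, 4000, n)
            life = rng.uniform(120, 4000, n)
            correct = rng.random(2 * n) > 0.1
            trials = make_participant_trials(
                death=tuple(death), life=tuple(life), correct=correct.astype(int)
            )
            mine = compute_d_score(trials).d
            ref = dscore_bruteforce(trials)
            assert mine == pytest.approx(ref, abs=1e-12)


class TestGroupTest:
    @staticmethod
    def _tables(rng, n=20, shift=0.0):
        pids = [f"P{i:03d}" for i in range(2 * n)]
        groups = ["control"] * n + ["sibs"] * n
        d = rng.normal(0, 0.3, 2 * n) + shift * (np.arange(2 * n) >= n)
        dscores = pd.DataFrame({"participant_id": pids, "d": d})
        cov = pd.DataFrame({
            "participant_id": pids,
            "group": groups,
            "age_months": rng.integers(156, 217, 2 * n),
            "gender": rng.choice(["female", "male"], 2 * n),
            "cdrs_r_total": rng.normal(40, 10, 2 * n),
            "cssrs_controllability": rng.integers(0, 6, 2 * n),
        })
        return dscores, cov

    def test_recovers_injected_group_shift(self):
        rng = np.random.default_rng(0)
        dscores, cov = self._tables(rng, n=200, shift=0.4)
        res = d_score_group_test(dscores, cov)
        assert res["adjusted_group_difference"] == pytest.approx(0.4, abs=0.1)
        assert res["p"] < 1e-6

    def test_constant_outcome_flagged_as_null(self):
        rng = np.random.default_rng(1)
        dscores, cov = self._tables(rng)
        dscores["d"] = 0.25
        res = d_score_group_test(dscores, cov)
        assert res["adjusted_group_difference"] == pytest.approx(0.0, abs=1e-10)
        assert res["p"] == 1.0

    def test_null_rejection_rate_near_alpha(self):
        """Under identical group generation, p<.05 in about 5% of replicates."""
        rng = np.random.default_rng(2)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            dscores, cov = self._tables(rng)
            if d_score_group_test(dscores, cov)["p"] < 0.05:
                rejections += 1
        # 95% binomial band around 0.05 with 400 reps: ~[0.030, 0.075]
        assert 0.02 <= rejections / n_reps <= 0.09

    def test_too_few_per_group_rejected(self):
        rng = np.random.default_rng(3)
        dscores, cov = self._tables(rng, n=2)
        with pytest.raises(ValueError):
            d_score_group_test(dscores, cov)


class TestCssrsComparison:
    @staticmethod
    def _tables(rng, n=27, shift=0.0):
        pids = [f"P{i:03d}" for i in range(n)]
        d = rng.normal(0, 0.4, n)
        sub = rng.normal(3.0, 1.0, n) + shift * (d > 0)
        dscores = pd.DataFrame({"participant_id": pids, "d": d})
        cov = pd.DataFrame({
            "participant_id": pids,
            "group": "sibs",
            "age_months": rng.integers(156, 217, n),
            "gender": rng.choice(["female", "male"], n),
            "cdrs_r_total": rng.normal(56, 10, n),
            "cssrs_controllability": sub,
        })
        return dscores, cov

    def test_constant_subscale_gives_zero_difference(self):
        rng = np.random.default_rng(4)
        dscores, cov = self._tables(rng)
        cov["cssrs_controllability"] = 3
        res = cssrs_subscale_comparison(dscores, cov, "controllability")
        assert res["adjusted_difference"] == 0.0
        assert res["mean_positive_d"] == res["mean_negative_d"] == 3.0

    def test_injected_shift_detected_with_power(self):
        """A 1.3-SD shift for the positive-D stratum at n=27 is detected in
        >=80% of replicates (two-sided t at ncp ~ 3.4 predicts ~0.90)."""
        rng = np.random.default_rng(5)
        detected = 0
        n_reps = 100
        for _ in range(n_reps):
            dscores, cov = self._tables(rng, shift=1.3)
            if cssrs_subscale_comparison(dscores, cov, "controllability")["p"] < 0.05:
                detected += 1
        assert detected / n_reps >= 0.80

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_reps = 300
        for _ in range(n_reps):
            dscores, cov = self._tables(rng)
            if cssrs_subscale_comparison(dscores, cov, "controllability")["p"] < 0.05:
                rejections += 1
        assert 0.015 <= rejections / n_reps <= 0.10

    def test_empty_stratum_raises(self):
        rng = np.random.default_rng(7)
        dscores, cov = self._tables(rng)
        dscores["d"] = np.abs(dscores["d"])  # all positive
        with pytest.raises(ValueError):
            cssrs_subscale_comparison(dscores, cov, "controllability")


def test_score_all_skips_unscorable_participants():
    good = make_participant_trials(pid="P001")
    bad = make_participant_trials(pid="P002")
    bad = bad[bad["condition"] != "life_congruent"]
    table, unscorable = score_all(pd.concat([good, bad], ignore_index=True))
    assert list(table["participant_id"]) == ["P001"]
    assert unscorable == ["P002"]
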