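"""Score DS-IAT trial logs and test the behavioral group difference.

D scores use the improved algorithm: latencies under 300 ms and over
3000 ms are recoded to the bounds, trials over 10 s dropped, error trials
penalized with their block mean + 600 ms, practice and test blocks pooled
per condition, and the oriented mean difference divided by the inclusive
pooled SD. Positive D = faster death-congruent responding.
"""

from erpiat import SimulationConfig, simulate_behavior, score_all, d_score_group_test

config = SimulationConfig(n_per_group=30, seed=11)
trials, truth = simulate_behavior(config)

dscores, unscorable = score_all(trials)
print(f"scored {len(dscores)} participants; {len(unscorable)} unscorable")
print(dscores[["participant_id", "d", "n_recoded_low", "n_recoded_high",
               "error_rate"]].head().round(3).to_string(index=False))

result = d_score_group_test(dscores, truth)
print("\nANCOVA of D on group (adjusting age + gender):")
for grp in ("control", "sibs"):
    print(f"  {grp:8s} mean D = {result['group_means'][grp]:+.3f} "
          f"(SE {result['group_sems'][grp]:.3f}, n = {result['n'][grp]})")
print(f"  adjusted difference (sibs - control) = "
      f"{result['adjusted_group_difference']:+.3f}, "
      f"F = {result['F']:.2f}, p = {result['p']:.4f}")
print("\nA positive adjusted difference means the patient group's implicit "
      "death-self association is stronger (D closer to zero or positive).")
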