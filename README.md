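# erpiat

ERP correlates of the Death/Suicide Implicit Association Test (DS-IAT):
a tested, reusable implementation of the analysis chain used to relate
implicit suicidality to event-related potentials in a two-group
(patients with suicidal ideation/behavior vs healthy controls) EEG study.

## What it does

Screening for suicidality leans on self-report, which is exactly what
at-risk adolescents may withhold. The DS-IAT measures the *implicit*
death–self association instead: a reaction-time task whose standardized
effect, the **D score**

    D = ( mean RT(life-congruent) − mean RT(death-congruent) ) / SD_inclusive

is positive when death+self responses are faster. This package implements
everything needed to link that behavioral measure to stimulus-locked EEG:

- **behavior** — improved-algorithm D scoring (recode <300 ms / >3000 ms,
  drop >10 s, error penalty = block mean + 600 ms, practice+test blocks
  pooled), group ANCOVA on D adjusting age and gender, and C-SSRS
  subscale comparisons between positive-D and negative-D patients.
- **preprocess** — baseline correction, trial-by-trial artifact
  interpolation/rejection, the <10-epochs-per-condition exclusion gate,
  and the per-subject contrast Δ = avg(death-congruent) −
  avg(life-congruent), the dependent variable of the group model.
- **glm** — mass-univariate ANCOVA Δ(ch,t) ~ group + D + age at every
  channel × time cell, as closed-form OLS or robust bisquare IRLS.
- **cluster** — spatiotemporal cluster-mass correction: suprathreshold
  cells joined over a sensor-distance adjacency graph and adjacent
  timepoints, family-wise p-values from a Freedman–Lane max-mass
  permutation null.
- **classify** — exploratory logistic ROC combining cluster-averaged ERP
  contrasts with behavioral/clinical measures, and a noncentral-F ANCOVA
  power calculator.
- **synth** — a generator for the whole study (7-block ex-Gaussian IAT
  logs, multichannel epochs with N100/P200/LPP-like templates carrying
  injected group/D/age effects, clinical covariates) with known ground
  truth, so calibration and recovery are testable end to end.

## Worked example

Score a simulated study and test the group difference
(`examples/02_behavioral_analysis.py`):

```text
ANCOVA of D on group (adjusting age + gender):
  control  mean D = -0.248 (SE 0.043, n = 30)
  sibs     mean D = -0.066 (SE 0.050, n = 30)
  adjusted difference (sibs - control) = +0.175, F = 6.25, p = 0.0154
```

Both groups lean "life" (negative D), but the patient group sits closer
to zero — a stronger implicit death–self association — and the adjusted
difference is significant.

Find the ERP correlate of D with the cluster permutation test
(`examples/03_cluster_analysis.py`; a 3 µV/D-unit effect is injected on
the N100 template at channel E8, 200 ms):

```text
cluster-forming threshold: F > 4.11 (per-cell p < 0.05)
9 clusters; 1 significant at alpha = .05

 cluster regressor  start_ms  end_ms  n_cells  n_channels            channels    mass  p_corrected
       1   d_score     100.0   460.0       37           6 E2,E3,E5,E8,E13,E16 606.420        0.012
       2   d_score     500.0   760.0       22           3            E2,E5,E8 127.978        0.261
```

The one family-wise-significant cluster covers the injected channel and
latency; its `p_corrected` is the fraction of permutation max-masses at
least as large. `examples/04_roc_and_power.py` adds the classification
and design-power side:

```text
ANCOVA power at f=0.5, n=27/group, 2 covariates: 0.950
ROC with erp_cluster_mean + d_score (stratified_5_fold(seed=3)):
  AUC = 0.948
```

`examples/01_simulate_study.py` and `examples/05_full_pipeline.py` show
the generator and the one-config end-to-end run (also available from the
shell: `erpiat run`, `erpiat score-iat`, `erpiat cluster`, `erpiat power`,
…). `docs/methods.md` documents the models, defaults and design
decisions.

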