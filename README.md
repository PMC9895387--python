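# eegdyn

Resting-state EEG carries two complementary descriptions of large-scale
brain dynamics: **microstates** — brief (~50–120 ms) periods during which
the scalp potential topography stays quasi-stable, conventionally labelled
A–D — and **band-limited rhythm energy on large-scale cortical networks**,
obtained by source-imaging the sensor signal and averaging current density
over network parcels.  Studies of acute interventions (e.g., exhaustive
exercise) compare both descriptions within subject, before vs. after, with
repeated-measures statistics.

`eegdyn` implements that whole analysis as a tested, reusable Python
library, together with a synthetic-EEG generator that plants known ground
truth so every stage can be validated quantitatively:

- **`eegdyn.synth`** — synthetic cohorts: piecewise-stable topographies
  with semi-Markov dwell structure, band-limited oscillations confined to
  one cortical network, pre/post effect multipliers, and an analytic
  ledger of every planted value.
- **`eegdyn.preproc`** — zero-phase FIR band-pass, mains notch, average
  reference, fixed-length epoching, amplitude-threshold artifact
  rejection.
- **`eegdyn.microstate`** — GFP peak extraction, polarity-invariant
  ("modified") k-means in which a prototype is the dominant eigenvector of
  its members' scatter, two-stage group maps, backfitting by absolute
  spatial correlation, and the five classical parameters: duration,
  occurrence, coverage, global explained variance (GEV), and the switch
  matrix.
- **`eegdyn.metacriterion`** — the number of classes chosen as the median
  vote of seven cluster-validity criteria under the `1 − |r|`
  dissimilarity.
- **`eegdyn.forward` / `eegdyn.mesh`** — three-shell spherical head model
  (Legendre-series dipole solution, with the homogeneous-sphere closed
  form as an independent oracle), icosphere source spaces, synthetic
  eight-network atlases.
- **`eegdyn.inverse`** — empirical-Bayes source inversion: sensor
  covariance modelled as `exp(λ0)·I + Σᵢ exp(λᵢ)·L·Vᵢ·Lᵀ` with network
  priors `Vᵢ` from the Green function (matrix exponential) of the mesh
  adjacency, hyperparameters by ReML (Fisher scoring on the free energy),
  and networks × bands mean-squared current-density tables.
- **`eegdyn.stats`** — two-factor fully-within-subject ANOVA with
  Mauchly's sphericity test, Greenhouse–Geisser correction, partial eta
  squared (η²p = F·df₁/(F·df₁+df₂)), Bonferroni-corrected paired t-tests.
- **`eegdyn.pipeline`** — the end-to-end cohort analysis producing
  parameter, transition and energy tables, ANOVA tables and significance
  flags, deterministic under one master seed.

## Worked example

`examples/simulate_and_recover_microstates.py` plants four template maps
(dwell means 70/75/85/80 ms, GFP SNR 5, 180 s at 250 Hz) and recovers
them:

```
6306 GFP peaks, total GEV 0.974
template |r| per class: [1. 1. 1. 1.]
label agreement with planted sequence: 0.932
state  duration(est/planted)  occurrence(est/planted)  coverage(est/planted)
  A     72.3 /  70.0 ms    3.14 / 3.23 per s   0.227 / 0.226
  B     75.6 /  75.0 ms    3.14 / 3.23 per s   0.237 / 0.242
  C     85.7 /  85.0 ms    3.23 / 3.23 per s   0.277 / 0.274
  D     82.4 /  80.0 ms    3.14 / 3.23 per s   0.259 / 0.258
max |switch-fraction error|: 0.0064
```

Prototypes are recovered essentially exactly (|r| ≈ 1.0), 93% of samples
get the planted label, and all temporal parameters land within a few
percent of the generator's analytic expectations.  The other examples
demonstrate the network-energy inversion (the planted visual-network
20–30 Hz source tops its band column), the statistics layer, and the full
pre/post cohort pipeline with its significance flags.

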