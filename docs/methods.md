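# Methods

This note records the models implemented in `eegdyn`, the assumptions they
make, the defaults and why, and what the synthetic validation does and
does not establish about real data.

## Signal conditioning

Band-pass filtering is windowed-sinc FIR (Hamming window, transition
bandwidth 25% of the lower edge, floored at 0.5 Hz), applied as a single
FFT convolution of the symmetric kernel with the group delay compensated —
exactly zero-phase for the odd-length symmetric taps used — with
odd-extension padding at the edges.  The mains notch is a zero-phase
(forward–backward) second-order IIR at 50 Hz, Q = 35.  Contracts, checked
by test: in-band tones preserved within 1%, stop-band tones ≤ 1%
amplitude, 50 Hz suppressed ≥ 30 dB with ≤ 5% change at 40 Hz.  Average
referencing subtracts the instantaneous channel mean and is idempotent.
Artifact handling is an amplitude threshold on fixed-length epochs
(default ±100 µV, boundary inclusive): synthetic recordings carry no
ocular or muscular artifacts, and a threshold is a reproducible stand-in
for manual component selection, which cannot be specified as an
algorithm.  Epochs are consecutive, non-overlapping, trailing remainder
discarded; analysis windows default to the first 3 minutes.

## Microstate model and pipeline

The working model: at any instant the scalp field is a scalar multiple of
one of K zero-mean unit-norm template topographies; the scalar's sign is
uninformative (a dipolar generator reverses polarity), so all comparisons
use the absolute spatial (Pearson) correlation |r| across channels.

*GFP peaks.* GFP is the spatial standard deviation of the instantaneous
map; strict local maxima of the GFP series index moments of high
topographic signal-to-noise and are the maps submitted to clustering.

*Clustering.* Modified (polarity-invariant) k-means: assignment maximizes
|r| to the prototypes; the update replaces each prototype by the dominant
eigenvector of its members' scatter matrix — the sign-invariant analogue
of the cluster mean.  Convergence is monitored by GEV (the GFP²-weighted
fraction of variance explained by the assigned prototypes); the best of
`n_restarts` (default 50 at the API, 20 in the pipeline) random
initializations wins; an emptied cluster is re-seeded from the worst-fit
map.  Equivalence with exhaustive partition search at small n is asserted
in the test suite.

*Number of classes.* Seven cluster-validity criteria (Krzanowski–Lai,
Silhouette, inverted Davies–Bouldin, Point-Biserial, Dunn,
Calinski–Harabasz, and a cross-validation criterion that inflates residual
map variance by the degrees of freedom consumed), all computed under the
`1 − |r|` dissimilarity; each votes for one k, the lower median of the
votes wins.  The battery composition is configurable — existing
"meta-criterion" implementations do not document a unique canonical
seven, so this default is an explicit, documented choice.  Criteria whose
between-cluster separations fall below 10⁻² on the dissimilarity scale
report their degenerate value instead of amplified round-off, so on
structureless data the parsimony tie rule (smaller k) prevails.

*Group maps.* Two-stage: per-subject prototypes are pooled with equal
weight and re-clustered at the group k.  How population maps should be
derived from subject maps is genuinely open; re-clustering the prototypes
is the simplest choice that preserves polarity invariance.  Classes are
then named A–D by optimal one-to-one assignment (|r|, Hungarian
algorithm) against a canonical reference set built from electrode
coordinates (A/B the two diagonal gradients, C anterior–posterior,
D fronto-central).  These reference maps are a naming fixture, not data.

*Backfitting and parameters.* Every GFP-peak sample takes the prototype
of largest |r|; samples between two peaks split at the midpoint (the
exactly equidistant sample goes with the later peak); samples outside the
first/last peak inherit that peak's label.  No temporal smoothing or
minimum-duration pruning is applied by default, and no correlation floor
gates assignment.  Duration is the mean dwell of maximal same-label runs
(edge-truncated runs included — negligible at minutes-long recordings);
occurrence is runs per second; coverage is the sample fraction; per-state
GEV sums over that state's samples; switch fractions count run boundaries
i→j over all boundaries.

## Synthetic microstate EEG

The generator renders a semi-Markov state sequence into sensor space:
`x(t) = gfp_scale · s(t) · sign(dwell) · template[state(t)] + noise`.

*Dwell law.* Gamma-distributed dwells (shape 3) by default, geometric
optional.  A memoryless law puts its mode at one sample (~4 ms at
250 Hz), contradicting the quasi-stable-state phenomenology being
emulated and filling the sequence with dwells no GFP-peak-based
segmentation could ever see; shape 3 keeps realistic dwell dispersion
while making sub-10-ms states rare.  Mean dwell defaults to 80 ms
(class-specific values configurable), within the 50–120 ms range typical
of resting EEG.

*Scalar `s(t)`.* Two families.  `rectified` (default): the absolute value
of 10-ms-smoothed Gaussian noise plus a floor of 0.25 of its RMS, giving
~36 GFP peaks/s — maximal temporal resolution for recovery studies — with
a random sign per dwell to exercise polarity invariance.  `oscillatory`:
narrowband (8–18 Hz) Gaussian noise with slow (300 ms) amplitude
waxing/waning — the alpha-carried regime of real resting EEG, whose
spectral content lies inside the 2–20 Hz analysis band so that the
standard filtering chain passes the signal undistorted.  Both multiply a
*boundary dip* (depth 0.5, Gaussian width 8 ms) at state transitions:
topographic handovers happen through low-GFP troughs, which is both the
classical picture of microstate syntax and what makes midpoint
backfitting well-posed.

The rectified family exists because within a 20-Hz-wide band GFP-peak
density is physically capped near 27/s, which caps nearest-peak label
agreement around 85–87% for 80-ms dwells regardless of SNR; broadband
recovery studies therefore use `rectified` on average-referenced data
without the 2–20 Hz filter (synthetic data needs no band selection),
while cohort simulations feeding the full filtered pipeline use
`oscillatory`.

*Noise and SNR.* White Gaussian sensor noise; the default level sets
GFP-scale SNR 5 (`noise_sd = gfp_scale / (√C · 5)` on C channels).

*Cohorts.* Twenty subjects by default (matching the df = 19 of the
pre/post design emulated), two conditions.  Post-condition effect
multipliers: state-C dwell ×1.5; state-D long-run coverage ×0.8 (the dwell
mean is solved exactly from the stationary semi-Markov coverage formula
`cov_i = π_i d_i / Σ_j π_j d_j`); A↔C and B↔D switch fractions ×1.5 and
×0.7, planted on the symmetrized pair-fraction matrix and renormalized
(so the embedded chain stays stationary; unplanted pairs absorb a ~3%
compensatory shift); visual-network 20–30 Hz source amplitude ×1.4.
Subject traits (dwell means ×lognormal 0.10, source amplitude ×lognormal
0.15) are shared across conditions; session-level fluctuations (amplitude
0.15, dwell means 0.08, chain entries 0.15, all lognormal per recording)
are not — real repeated recordings never share identical dynamics, and
without this variance floor the paired tests would resolve arbitrarily
small systematic measurement couplings.  The ledger records all planted
per-recording values plus the analytic expected duration, occurrence,
coverage and pair fractions.

*Network recordings.* Independent unit-RMS band-limited time courses
(4th-order Butterworth, forward–backward) on the active network's
vertices, scaled by `source_amp`, projected through the lead field;
optional broadband background on all vertices; white sensor noise.  True
per-network mean-squared current density is returned alongside.  In
cohorts the microstate and network signals are summed into one recording
per subject and condition (one recording, two analyses); the microstate
content lies below 20 Hz and the planted oscillation in its own band, so
each analysis sees its own ground truth, with two deliberate couplings
discussed under Limitations.

## Forward model

Three concentric homogeneous spherical conductors (brain/skull/scalp;
radii 0.87/0.92/1.0, conductivities 0.33/0.0042/0.33 S/m — standard
three-shell values, configurable), insulating exterior, dipoles strictly
inside the brain shell, electrodes on the outer surface.  Per spherical-
harmonic degree n the radial profile in each shell is `A rⁿ + B r⁻⁽ⁿ⁺¹⁾`;
the five coefficients follow from potential/current continuity at the two
interfaces and zero radial current at the scalp, solved as a 5×5 linear
system per degree — transparent, and it reduces exactly to the
homogeneous sphere when conductivities are equal.  The series (default 80
terms; b/R = 0.8 gives ~10⁻⁷ relative truncation error) is evaluated with
Legendre recurrences; the tangential term uses the identity
`m_t·ê_t sin γ = m_t·(ê − cos γ p̂)`, stable at γ → 0.  The homogeneous-
sphere closed form (generating-function sums, documented in the code) is
implemented independently and serves as the oracle.  Lead-field columns
are average-referenced.  Source spaces are trimesh icospheres (radius
0.8; 162/642/2562 vertices) with radial normals; the eight-network atlas
partitions vertices by nearest seed direction, seeds placed to caricature
the visual/somatomotor/attention/limbic/frontoparietal/default/deep
layout.  It is a stand-in geometry for recovery experiments, not an
anatomical parcellation.

## Inversion and band energies

Sensor covariance model `C = exp(λ0)·I + Σᵢ exp(λᵢ)·Qᵢ` with
`Qᵢ = L Vᵢ Lᵀ` scaled to trace = n_electrodes (putting hyperparameters on
one scale).  Priors `Vᵢ`: `G = expm(σ·A_rownorm)` of the mesh adjacency
(σ = 0.6 default; σ = 0 gives identity blocks), restricted to network i's
vertices, symmetrized and eigenvalue-floored at 0.  ReML maximizes the
restricted log-likelihood `−N/2 (log det C + tr(C⁻¹ Ĉ))` by Fisher
scoring with step halving (evidence non-decreasing within 10⁻⁸ slack,
asserted), λ clipped to ±32, convergence at 10⁻⁴ relative change, 128
iterations max.  Posterior mean operator `M = (Σᵢ exp(λᵢ)Vᵢ) Lᵀ C⁻¹`.
Band energies: one operator from the broadband epoch-averaged covariance,
applied to band-filtered epochs (linearity lets filtering and inversion
commute); per-vertex mean square over time, averaged over each network's
vertices, then over epochs.  Band edges: δ 0.5–4, θ 4–8, α1 8–10.5,
α2 10.5–13, β1 13–20, β2 20–30, γ 30–45 Hz — conventional splits of a
0.5–45 Hz analysis band; configurable.  Energies are relative (arbitrary
units): absolute current-density scales are not identifiable here and no
attempt is made to match any particular absolute normalization.  In the
pipeline the operator is estimated once per subject from the pooled
pre+post covariance (`operator_scope="subject"`, configurable to
`"condition"`): with per-condition operators, a condition that changes
one network's power changes the *operator*, which then reweights every
band's localization and manufactures spurious condition differences; a
shared operator makes pre/post contrasts reflect band energy alone.

## Statistics

Classical two-factor fully-within-subject partition; each effect is
tested against its own subject-by-effect interaction error term;
η²p = SS_eff/(SS_eff+SS_err) = F·df₁/(F·df₁+df₂).  Mauchly's W from the
determinant/trace of the orthonormal-contrast covariance with the
first-order χ² approximation; Greenhouse–Geisser ε from its eigenvalues
((Σλ)²/((k−1)Σλ²), clipped to [1/(k−1), 1]); interaction sphericity uses
Kronecker-product contrasts.  GG-corrected p-values are reported when
Mauchly rejects at 0.05 (policy configurable: always/never/mauchly).
Post hocs are two-sided paired t-tests with Bonferroni correction; the
pipeline's families are the 4 states per parameter measure, the 12
ordered transition pairs, and the 8 networks within each band — the
emulated analyses do not state their family sizes, so these are
documented choices.  Mean squares at round-off scale are treated as zero
so condition-invariant data yields F = 0.

## Validation scales and limitations

The acceptance suite runs recovery at 32 channels/250 Hz with 180-s
single recordings, 60-s recordings for cluster-count recovery, 40-s
recordings in the 25-cohort power simulation, and the 162-vertex source
space for inversion studies (642 vertices for the forward-model oracle) —
sizes chosen so the full suite runs on one desktop CPU in minutes while
leaving every claimed tolerance a comfortable margin.

What passing these suites does *not* show about real data:

- The generator's topographies switch instantaneously and its noise is
  white; real microstate boundaries are gradual and real EEG noise is
  spatially and temporally correlated.  Recovery rates here are upper
  bounds.
- Two measurement couplings are real and visible in cohort runs: the
  planted class-C map is posterior-dominant, so its increased coverage
  also raises low-band "visual network" energy after inversion; and
  32-electrode source imaging leaks the planted β2 increase into
  neighbouring networks.  The pipeline's β2/visual detection survives
  both; single-cell energy differences in other bands should not be
  over-read — which is also the operative caveat for the corresponding
  real-data analyses.
- A small segmentation coupling survives in transition statistics: with
  planted A↔C/B↔D changes, unplanted pairs shift by a few percent
  (renormalization plus boundary-labelling effects), producing
  Bonferroni-corrected false alarms on roughly 9% of unplanted pairs per
  cohort at n = 20 — above the pure-null rate, bounded and documented
  rather than hidden by inflating generator noise.
- The spherical head model and seed-based atlas test the *estimator*, not
  anatomical validity; nothing here speaks to the accuracy of realistic
  head models.
- ICA artifact removal is replaced by amplitude-threshold rejection;
  pipelines for real recordings need a genuine artifact strategy.
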