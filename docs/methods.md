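# Methods

`sensomap` implements a source-space MEG analysis chain for somatosensory
function — resting-state seed connectivity, paired-pulse gating, and their
relation to tactile spatial acuity — together with a synthetic cohort
generator that plants recoverable ground truth at every stage.  This note
describes the models, the defaults and why they were chosen, and what the
synthetic studies do and do not establish.

## Source space and sensor geometry

The synthetic cortical surface is a radially modulated icosphere
("wrinkled sphere", `mesh.make_cortical_mesh`): the radius of a unit
icosphere is modulated by a fixed random combination of spherical harmonics
(degrees 6–10, amplitude 0.15 of the 0.07 m mean radius, fixed seed 7).
The modulation is not cosmetic.  Under the cortical orientation constraint
each vertex carries a dipole along the outward surface normal, and in a
spherical conductor a radial dipole is magnetically silent — on a perfect
sphere the whole source model would produce zero signal.  The harmonic
bumps tilt normals off radial by ~16 degrees on average, giving every
vertex a visible tangential component while staying analytically inside
the spherical forward model.

Sensors are a helmet-like Fibonacci shell of point magnetometers at
0.12 m measuring the radial field; planar gradiometers are available as
differenced point magnetometers divided by the 17 mm baseline.

## Forward model

`forward.dipole_field` evaluates the closed-form magnetic field of a
current dipole in a homogeneous spherical conductor (the field depends on
the sphere center only, not its radius or conductivity).  Two exact
properties are used as oracles throughout: linearity in the dipole moment,
and the silence of radial dipoles.  The test suite additionally compares
the closed form against a fully independent numeric reference that
integrates the conductor's volume currents (in their exact boundary form,
with the potential from a spherical-harmonic series); agreement is ~1e-7
relative, far inside the 1% gate.

Lead fields can be globally rescaled so the median constrained column norm
is 1 (`normalize=True`); this fixes the sensor-unit scale of simulations
without affecting unit gain or any linearity property.

## Beamformer

`beamformer.lcmv_weights` computes the linearly constrained
minimum-variance filter from a data covariance that is regularized by the
median-eigenvalue rule: eigenvalues below the median are raised to the
median, eigenvectors untouched.  The covariance itself is the per-epoch
sample covariance over a stated window, averaged across epochs.

Orientation handling follows the weights-projection convention: the
free-orientation 3×C weights `(L'C⁻¹L)⁻¹L'C⁻¹` are projected onto the
outward normal.  One numerical subtlety is intrinsic to the spherical
model: the 3×3 Gram matrix is rank-2 *by physics* (the radial orientation
contributes nothing), so the inverse is taken as a rank-truncated
pseudo-inverse and the projected weight is rescaled to restore unit gain
`w·l = 1` exactly.  Vertices whose constrained lead field is numerically
silent are flagged and zeroed.  The alternative lead-field-projection
convention (`w = C⁻¹l/(l'C⁻¹l)`) is provided behind the `projection`
flag; both satisfy unit gain, and the weights-projection reading is the
default because it matches the verbal description of projecting 3D weights.

For localization the package reports the neural activity index — output
variance divided by the white-noise-projected variance `σ²ww'` — rather
than raw output power: unit-gain weights at weak-lead-field (near-radial)
vertices are large, so raw power is dominated by amplified noise there.
With the NAI, a planted dipole at SNR 5 on a 2562-vertex mesh is localized
with zero edge error in all seeded runs.

## Connectivity

Seed-based amplitude-envelope correlation per band (alpha 8–12 Hz, beta
15–29 Hz): the seed series is the mean of a 10-vertex scout *before* any
correlation; both series are band-filtered with an even-order linear-phase
FIR (single pass, group delay compensated, reflection padding), Hilbert
envelopes are taken, the first and last 200 ms of each 2 s epoch are
trimmed (Hilbert edge artifacts), and the Pearson correlation of the
envelopes is computed per epoch and averaged across epochs (plain mean by
default; Fisher-z averaging is a flag).

Leakage correction uses the pairwise time-resolved orthogonalization: the
component of the target's analytic signal in phase with the seed is removed
sample by sample, in both directions, and the two correlations averaged.
A target that is a real multiple of the seed contributes exactly zero; an
envelope-sharing target in phase quadrature is untouched.  Epoch averaging
sums per-epoch values in value-sorted order so the map is bit-identical
under epoch relabeling.

The leakage null is assessed against the family-wise (max-statistic)
permutation null built by epoch mispairing: in a one-source world the
maximum orthogonalized |AEC| over all off-seed vertices stays below the
95th percentile of the permuted map maxima, while the naive (uncorrected)
maximum is far outside it.  A per-vertex 95th-percentile rule would
by construction be exceeded at ~5% of vertices, so the map-maximum form
is the meaningful check.

## Evoked responses and gating

The synthetic S1 response is a sum of three Gabor-like deflections with
alternating polarity peaking at 22, 33 and 58 ms — inside the analysis
windows 20–26, 27–40 and 45–71 ms used for N20m, P35m and P60m.
Paired-pulse trials add a second copy at +100 ms with each deflection
scaled by the planted gating ratio.

The analysis path is: average epochs per condition; subtract the SP source
map from the PP map (signed, relying on linear superposition — the
absolute value is taken only afterwards, and identically for both
conditions: baseline-correct, then rectify); shift the subtracted map by
−100 ms so the second pulse sits at t = 0.  ROI scouts are the activation
peak plus its nine nearest mesh neighbors (ties to the lower vertex
index), defined per condition from the first-response map; the manual
scout drawing this replaces is not reconstructable, so a deterministic
rule is used.  Scout waveforms are the mean of the rectified per-vertex
series, which avoids sign cancellation across normals within a scout.
Peaks are the window maxima (earliest sample on ties); the gating ratio is
PP/SP.  At 300 trials per condition, a planted N20m ratio of 0.5 is
recovered within ±0.1, and the five planted levels 0–1 come back in
strictly increasing order.  At a planted ratio of 0, the recovered value
sits at the rectified-noise floor (~0.15 under the default noise), which
is the expected behavior of rectified subtracted waveforms near strong
inhibition.

## Psychometrics

Two-point discrimination uses the task design of 10 pin distances
(0–5 mm) × 16 trials; responses are Bernoulli draws from
`P(two | d) = logistic(slope·(d − threshold))`.  The fit is a trial-level
binomial logistic GLM (statsmodels); the 50% threshold is
`−intercept/slope`.  Perfect separation is caught and returned as a
flagged, slope-clamped (50 /mm) fit rather than an error, because
per-subject designs are small.  Calibration at truth (2.5 mm, slope 3):
mean absolute threshold error ≈ 0.085 mm over 100 replicates,
between-replicate SD ≈ 0.095 mm.

## Group statistics

Vertex-wise simple regression of connectivity on the behavioral covariate
gives a two-tailed t-map.  TFCE integrates `e(v,h)^E·h^H·dh` (E = 0.5,
H = 2) over a threshold ladder; by default `dh = (per-sign map max)/100`,
and the discretization error against the analytic single-vertex value
`h^(H+1)/(H+1)` is ~1.5%.  An explicit fixed `dh` is available; on a
common grid the enhancement is exactly monotone in the input map (the
adaptive grid is only approximately so, which is why the monotonicity
property is stated on a fixed grid).  Positive and negative tails are
enhanced separately and signed.

Family-wise error is controlled by the max-statistic permutation scheme:
the covariate is shuffled across subjects (the design has a single
regressor, so subjects are exchangeable under the null), the full
t → TFCE map is recomputed per permutation, and the null is the
distribution of the map maximum of |TFCE|.  Sampled permutations use the
add-one p-value estimator; for cohorts small enough that the requested
permutation count exceeds n!, the group is enumerated exactly.  Clusters
are first-order mesh-adjacency components of significant vertices with an
extent floor (k > 50 at the emulated scale; scaled to the mesh in the
demo).  In the null calibration (20 subjects, 500 permutations, 100
cohorts, 642-vertex mesh) the family-wise false-positive rate is 0.06,
inside the 0.05 ± 0.03 Monte-Carlo band; the planted coupling (−2 mm per
unit connectivity, map noise SD 0.08) is detected in ≥ 84% of replicates.

Spearman correlations are exact for n ≤ 9 (full permutation distribution
of the rank correlation, average ranks for ties) and t-approximate above;
Wilcoxon signed-rank tests use the exact rank-polynomial null up to 25
pairs (tied ranks handled by integer doubling) and the
continuity-corrected normal approximation beyond.  Both match exhaustive
enumeration on every tested instance.  Bonferroni adjustment multiplies p
by the stated family size (3 for the component-wise tests).

## Synthetic cohort: what it emulates and what it does not

The generator's defaults mirror the emulated acquisition: 1 kHz sampling,
5 min eyes-open rest segmented every 2000 ms, ~300 single-pulse and ~300
paired-pulse stimulations at 3.5–4.5 s intervals with a 100 ms
paired-pulse gap, alpha and beta oscillators, and the 160-trial
discrimination task.

Rest model.  An active cortical source is a 10-vertex patch whose members
share one log-normal amplitude envelope but carry independent
constant-amplitude FM carriers confined to the band.  Two deliberate
choices here: (1) constant-amplitude carriers make the Hilbert envelope of
the signal equal the planted envelope, so the closed-form weighting
`a² = ln(1 + ρ(e^{s²} − 1))` plants the pairwise envelope correlation ρ
exactly (a stochastic carrier's own Rayleigh envelope would cap the
measurable correlation near π/4 regardless of ρ); (2) incoherent carriers
within a patch prevent the minimum-variance filter from cancelling the
patch, which it provably does to perfectly coherent extended sources.
Envelope processes are Gaussian-smoothed at 150 ms, a compromise between
realistic envelope timescales and per-epoch estimator variance.  Inactive
vertices carry independent band noise at 0.3 rms; sensor noise is white
(SD 1 in normalized lead-field units).  Colored sensor noise, artifacts
(blinks, cardiac, movement) and inter-subject head geometry are *not*
modeled — the paired preprocessing steps that remove them (SSS, ICA) are
out of scope, so passing tests say nothing about artifact robustness.

Cohort model.  Per-subject envelope correlation is uniform on (0.2, 0.8);
the true threshold is `3.6 − 2.0·ρ + N(0, 0.3)` mm, floored at 0.3 mm —
negative coupling (stronger connectivity, better performance), group mean
≈ 2.6 mm and between-subject SD ≈ 0.46 mm, consistent with the scale of
young-adult two-point thresholds.  Psychometric slope is 3 /mm.  Gating
defaults are 0.5/0.6/0.7 for N20m/P35m/P60m (clear suppression, ordered
components).  Ground truth is recorded from the generating parameters
before noise injection and never recomputed from data.

Recovered-versus-planted envelope correlation through the full chain
(forward mixing, beamforming, orthogonalized AEC) is strongly attenuated —
planted 0/0.3/0.6/0.9 come back near 0/0.02/0.04/0.07 on the 162-vertex
desk mesh — because orthogonalization discards the in-phase signal
component and leakage mixes background into every vertex.  The chain
validation is therefore *order* recovery (strict monotonicity of the mean
across 25 seeds), not magnitude recovery; magnitude calibration holds at
the source level (planted 0.6 measured 0.6 ± 0.1 over 300 s).

## Problem sizes

Desk-scale studies use meshes of 162 (recovery chains), 642 (group
statistics) and 2562 vertices (localization), 32–64 magnetometers,
sampling rates of 250–500 Hz and permutation counts of 300–500.  These
are the package's chosen study conditions for fast, reproducible
validation; the emulated acquisition scale (15,000 vertices, 306
channels, 10,000 permutations) is supported by the same code paths but is
not exercised in the default suites.

## Reproducibility

Every random draw descends from one master seed through named
`SeedSequence` streams (subject × stream), so cohorts are subject-wise
independent yet bit-reproducible; the pipeline writes every stage's
provenance (config hash, seed) next to its outputs, and a rerun with the
same configuration is byte-identical.
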