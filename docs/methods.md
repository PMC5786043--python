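# Methods

`popgrasp` implements the population-analysis chain used to study how a
fronto-parietal grasping circuit encodes three task factors — acting hand
(left/right), grip type (power/precision) and handle orientation (five
angles) — in a delayed grasping task, and validates every stage on synthetic
spiking populations with planted, known structure.

## Task model and synthetic populations (`synth`)

A trial runs fixation (700–1100 ms, uniform) → cue (800 ms, fixed) → memory
(700–1100 ms, uniform) → go → reaction (normal around a 230 ms median, SD
20 ms, floored at 120 ms) → movement (normal around 305 ms, SD 30 ms) → hold
(300 ms) → reward. The 20 conditions (2 hand × 2 grip × 5 orientation) are
presented in pseudorandom order with a configurable number of trials per
condition (default 10, i.e. 200 trials — inside the 100–260 range a unit
must span to enter the database; at least 5 per condition is enforced).

Each unit's firing is an inhomogeneous Poisson process with intensity

    lambda_u(c, t) = max(0,  b + sum_k a_k * w_uk * p_k(c) * f_k(t)),

where `b` is the baseline (Hz), `a_k` component amplitudes (Hz), `w_uk`
standard-normal unit loadings, `p_k(c)` a signed condition pattern and
`f_k(t)` a smooth epoch-anchored time-course in [0, 1] (cue-phasic bumps,
cue/memory-sustained plateaus, movement-locked bumps). Patterns are
zero-mean along every factor axis the component's tag excludes, so each
planted component occupies exactly one task-factor marginalization; the
hand × orientation pattern is mirror-symmetric (`value(left, θ) =
value(right, −θ)`), the body-centric interaction structure. Rectification
at zero is the only nonlinearity; superposition is exact before it, and
with the default amplitudes (baseline 20 Hz, components ≤ 8 Hz) clipping is
rare. Spikes are drawn by thinning against a 1 ms piecewise-constant
intensity grid, which is exact for such intensities. Randomness uses one
counter-split stream per (dataset, unit, trial), so outputs are
byte-identical regardless of iteration order.

An optional *artifact* component plants a transient, cue/memory-confined
hand signal in exactly one dataset — the scenario the cross-dataset
selection stage is designed to catch (e.g. one animal making tiny premature
hand movements during the memory period).

What the generator deliberately omits: correlated (simultaneous) population
noise, non-Poisson spiking statistics, drifting baselines, and kinematic
signals beyond the artifact. Passing tests therefore certify the inference
machinery under its stated assumptions, not robustness to those real-data
departures.

## Firing rates (`rates`)

Rates are kernel estimates: a Gaussian of SD 57 ms, truncated at ±4 SD and
renormalized (<0.01% mass loss), summed over spikes and scaled to Hz.
Spikes are collected from a window extended by 4 SD so smoothing carries no
boundary bias. Rates are sampled every 10 ms in three alignments — cue
onset [−300, +1100] ms, movement onset [−500, +500] ms, reward
[−300, +500] ms (configurable; analysis windows are not uniquely determined
by the task, these cover the informative epochs without overlap at typical
delays). The three time axes are stored separately; nothing bridges them
implicitly. Variable-length epochs are handled by the three alignments
alone — no time warping. Units lacking 5 trials in any condition are
excluded (`exclude_unstable`).

## Per-unit tuning test (`cbpt`)

For each unit and factor, single-trial rate time-courses of two trial
groups are compared: the two hands, the two grips, or the preferred vs
non-preferred orientation (highest/lowest across-trial mean activity from
cue onset to reward onset, ties to the lowest level index and flagged).
A pooled-variance independent-samples t is computed per sample (Welch would
be a one-line swap; zero-variance samples give t = 0); contiguous
sign-homogeneous runs with |t| above the two-sided critical value at
α = 0.05 (df = nA + nB − 2) form clusters scored by Σ|t| (cluster mass).
Clusters cannot span alignment boundaries.

Significance comes from a max-cluster permutation null (1000 partitions,
group sizes preserved; partitions without clusters contribute mass 0). For
orientation, the preferred/non-preferred selection is itself part of the
statistic, so each permutation permutes the orientation labels of *all*
trials and re-selects the extreme levels before clustering — without this
the selection bias inflates the false-positive rate. A cluster is
significant when its mass exceeds the (1 − 0.05/3) null quantile; the
Bonferroni division by the number of factors keeps the family-wise error
over factors and time points below 5% (measured: 5.1 ± 0.7% over 1000 null
units). A unit is *task-related* if any factor has a significant cluster.
Population tuning-fraction curves report the percentage of units whose
significant clusters cover each sample, optionally restricted to contra- or
ipsi-lateral trials (the hand factor is then dropped and the correction
adjusted).

Caveat: preferred orientation is estimated from the same trials used in the
test (no split), mirroring common practice; the permutation null absorbs
the selection bias under H0, but under partial tuning the preferred-level
estimate remains optimistically biased.

## Demixed PCA (`dpca`)

The trial-averaged tensor X (units × conditions·time) is centered per unit
and decomposed into marginalizations: condition-independent (time), hand,
grip, orientation, the three pairwise interactions, and the residual
three-way interaction (kept explicitly so that Σ_φ X_φ equals centered X to
machine precision; on the balanced grid the terms are mutually orthogonal).
Every marginalization retains full time dependence.

For each marginalization, the encoder/decoder pair minimizes
‖X_φ − F_φ D_φ X‖² + λ‖F_φ D_φ‖² under a rank constraint: the ridge
solution A_φ = X_φ Xᵀ (X Xᵀ + μI)⁻¹ with μ = λ‖X‖²_F (λ is dimensionless,
so one value is meaningful across datasets; cross-validated values for the
original recordings were ~10⁻⁷–10⁻⁶) is rank-truncated via the leading left
singular vectors of A_φ X (computed from the units × units Gram matrix).
Candidates from all marginalizations are pooled and the top `n_components`
(default 30) kept by explained signal variance; cumulative variance is the
joint top-k reconstruction quality, which is bounded above by the ordinary
PCA curve at every rank. With a single marginalization equal to the
centered data and λ = 0 the procedure *is* PCA (verified to 1e−8).

λ is selected by held-out-trial cross-validation: one random trial per unit
and condition forms the test estimate, the rest are averaged for training;
the score is the per-marginalization reconstruction error of the held-out
marginalized data. Noiseless data drive λ to the grid minimum; noisy,
few-trial data select λ > 0.

## Cross-dataset shared components (`shared`)

dPCA is fitted per dataset and on the pooled population (datasets stacked
as extra unit rows over an identical condition-time grid, enforced). Each
pooled component's condition-time course (length C·T) is correlated with
every component of every per-dataset fit; because component sign is
arbitrary, |r| is compared. A pooled component is retained iff it reaches
|r| ≥ 0.6 in *every* dataset (all-of-N generalization of the two-animal
rule); zero-variance courses correlate 0 and are flagged. Contribution
scores (mean |decoder weight| per dataset's units) identify which dataset
drives a discarded component.

Back-projection reconstructs dataset d from retained components using only
its own rows of the pooled encoder/decoder: p̂ = (D_d F_d)⁻¹ D_d X_d,
X̂_d = F_d p̂. The gain inversion (pseudo-inverse, rcond 1e−6) is this
package's choice: without it a component shared equally between two
datasets is reconstructed at roughly half amplitude; with it the
reconstruction is unbiased for genuinely shared components while still
depending only on dataset-d data — structure absent from a dataset cannot
be conjured into it. Residual artifact leakage scales like
√(K_retained/n_units) of the artifact amplitude (random-loading overlap),
so artifact suppression is only quantitative at study-scale populations
(hundreds of units); the acceptance test runs at 200 units/dataset for this
reason.

The threshold re-test flags a unit as tuned at time t when the spread
between factor-level means of its reconstruction exceeds a single
threshold, chosen as the (1 − p0) quantile of the pre-cue baseline spread
pooled over units and baseline samples — p0 matched to the cluster test's
own pre-cue tuned fraction (or set explicitly). This is one defensible
reading of "a simple threshold matched to the baseline level of tuning";
the exact rule is not uniquely determined by its source.

The threshold re-test is a visualization aid, not a calibrated test, and
its false-positive rate does not transfer precisely from the baseline
window to task epochs. Two effects are at work. First, a rank-K
reconstruction's level-difference noise is carried by only K time-courses
shared across every unit, so with a 57 ms kernel the pre-cue window holds
roughly five independent samples of those courses and the calibrated
threshold is itself noisy; the resulting tuned fraction for a factor with
*no* planted structure scatters over several percentage points from run to
run and should only be interpreted as an average over repetitions. Second,
the fraction is biased upward at task times: Poisson noise variance grows
with the locally elevated firing rates, and the in-sample retention rule
can keep pooled components that are pure noise tagged with the probed
factor (their condition-time course correlates with each dataset's own fit
of the same noise), re-expressing factor-structured sampling noise
concentrated at high-variance epochs. Claims about absence of fabricated
*structure* rest on the artifact-removal test (shared signal preserved,
single-dataset signal removed), not on this thresholded fraction.

## Pseudo-trial decoding (`decode`)

Units are not simultaneously recorded, so test trials are pseudo-trials:
one held-out trial per unit per condition (stratified Monte-Carlo
leave-group-out, 100 iterations). Per iteration, dPCA is refit on the
training averages and the factor's leading demixed axis serves as a linear
classifier — nearest training-class mean of the projection, per time point,
ties to the lowest class index. Compound factors (e.g. hand × orientation)
decode the product classes. Chance comes from 100 shuffles permuting each
unit's trials over conditions (per-condition counts preserved) with the
full split/fit/classify pipeline re-run once per shuffle. Decoding is
significant where the *minimum* real accuracy over iterations exceeds the
*maximum* shuffle accuracy for at least 200 ms contiguously within one
alignment ("exceeds chance on all iterations", read conservatively; the
alternative — mean above the null's 95th percentile — is a two-line change
in `significant_intervals`).

## Numerical and scale choices

- Permutation p-values use (1 + #{null ≥ obs}) / (1 + n_perm), valid under
  exchangeability.
- The permutation core is vectorized (mask matrix products for group sums,
  a time-scan for max cluster masses), ~0.15 s per unit for the full
  three-factor test at 200 trials and 1000 permutations.
- Validation problem sizes: 1000 units for the null false-positive study;
  200 units × 2 datasets × 5 trials/condition over 20 seeds for artifact
  removal; 100 units × 2 datasets for the no-fabrication check; 60 units
  for mirror-symmetry recovery. Each matches the regime the corresponding
  claim concerns (per-animal populations of hundreds of units, ≥5
  trials/condition).
- Degenerate inputs: empty spike trains give zero rates; zero-variance
  t-test denominators give t = 0; flat units trigger the preferred-level
  tie rule with a flag; an empty retained set back-projects to zero with a
  warning.

## Known limitations

- Poisson, independent-unit noise only; no trial-to-trial correlations, so
  permutation exchangeability is exact here but only approximate for real
  data with slow drifts.
- The preferred/non-preferred reduction discards intermediate-orientation
  structure; a 5-level omnibus variant is not implemented (the reference
  analysis treated the test as strictly two-condition).
- Back-projection unbiasedness assumes the retained components are genuinely
  present in each dataset; for components near the 0.6 retention boundary
  the gain inversion can amplify noise.
- λ cross-validation and decoding refit dPCA per iteration; at hundreds of
  units this is the dominant cost of the decoding stage.
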