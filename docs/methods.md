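# Methods

This note documents the models, estimators and numerical choices behind
`desync`, and what the synthetic cohorts do and do not establish about
real data.

## The synthetic cohort generator

The generator emulates a densely sampled longitudinal crossover design:
a few participants scanned over many sessions, with baseline visits, one
stimulant-control (MTP) session, one psychedelic (psilocybin) session and
follow-up visits (`default_schedule`; crossover order alternates by
participant, and any schedule — e.g. two psilocybin doses — can be passed
explicitly).

**Signal model.** Parcel `p`'s time course in a scan is

    x_p(t) = s_p · c_p · ( L_net(p)(t) + a_p · γ · G(t) ) + σ ε_p(t)

where `L_k` are per-network latent series and `G` a global drive, both
AR(1) with φ = 0.4 (innovations scaled to unit marginal variance) to give
the latents BOLD-like temporal autocorrelation; `a_p` is +1 for
default-mode parcels, −1 for task-positive networks (fronto-parietal,
dorsal attention, salience, action-mode) and 0 otherwise, so γ = 0.3
plants the resting anticorrelation between the default-mode network and
task-positive systems; `ε_p` is white noise with σ = 1. The loading

    c_p = 1 + participant term (SD 0.5) + session term (SD 0.25)

gives every participant a stable individual connectome plus day-to-day
drift. The sync level `s_p` is 0.9 at baseline; psilocybin multiplies it
by (1 − realized desynchronization), where the realized effect is the
configured strength (default 0.6) times a per-session lognormal-ish
multiplier (Normal(1, 0.15), clipped). `s_p` can also be a per-parcel
vector, used to plant network-localized desynchronization. The stimulant
control perturbs only motor-network loadings (extra SD 0.25); task scans
halve the acute desynchronization (task engagement attenuates the drug
effect); drug sessions raise mean framewise displacement by 0.08 mm over a
0.12 mm baseline.

The variability scales (participant 0.5, day-to-day 0.25) were chosen once
so that the normalized condition profile of a default cohort is realistic
for precision-mapping data — day-to-day ≡ 1, stimulant ≈ 1.3, psilocybin
≈ 3.5 and between-person ≈ 3.5 — i.e. an acute psychedelic moves a
connectome about as far from its own baseline as two different people's
connectomes are from each other.

**Questionnaire scores.** Each drug session receives an MEQ30-like total,
`clip(150 · realized effect + Normal(0, 8), 0, 150)`, with four subscales
(maxima 75/30/30/15) generated as strongly correlated fractions of the
total. An optional "emesis" flag attenuates one psilocybin session's
effect ×0.1 to exercise the embedding's outlier case.

**Persistent effect.** For sessions within 21 days after psilocybin, one
designated non-medial default-mode parcel (the anterior-hippocampus
analogue) has its latent remixed toward a neighbouring network by the
`persistent_offset` fraction (default 0.1), shifting its seedmap without
touching the rest of the connectome.

**What the generator does not emulate:** hemodynamic convolution,
spatially structured noise, physiological confounds, scanner drift,
non-stationary drug pharmacokinetics within a scan, and vertex-level
(~80k channel) data. Passing tests therefore establish the correctness
and calibration of the estimators under a plausible covariance structure,
not properties of any real dataset; the study's published effect sizes
are not reproduced here because the underlying cohort is access-
controlled.

## Connectivity and distances

Pearson correlations are clipped to ±(1 − 1e−7) before the Fisher
transform so identical series stay finite; constant parcels are flagged
and propagated as missing rather than zeroed. Per-parcel FC change is the
mean over baseline scans of the seedmap distance (mean of distances, not
distance to the mean seedmap); same-session baselines are excluded when
scoring baseline scans, which is what makes the baseline-vs-baseline score
a day-to-day variability measure. Seedmap distances are RMS-normalized by
default (so the RMS over parcels of a change map equals the whole-brain
RMS edge distance exactly for a single baseline); the raw Euclidean norm
is available via `metric="euclidean"`. Whole-brain FC change divides by
the edge count before the square root, making scores comparable across
parcel counts. Frame censoring is a boolean mask from thresholding
framewise displacement at 0.3 mm, applied before correlation.

Condition aggregation uses baseline rest scans for the within-session /
day-to-day / between-person categories, drug rest scans against
same-participant baseline rest for the drug categories, and the two
highest-motion non-drug rest scans for the high-motion category. A
category with no eligible pairs is reported as missing, never as zero.

## NGSC

Channels are demeaned but not variance-normalized (covariance PCA): the
spectrum is normalized by total variance, and variance-normalizing first
would erase amplitude structure; a correlation-PCA flag exists. The
eigenvalues come from singular values of the demeaned matrix (cross-
checked against the covariance eigendecomposition at 1e−8). `m` is the
channel count even for rank-deficient input — zero eigenvalues contribute
no entropy but stay in the `ln m` normalization — and 0·ln 0 := 0. The
measure is logarithm-base invariant. Parcel-level NGSC applies the same
formula to within-parcel sub-channel groups; singleton groups are
undefined (NaN).

## Mixed-effects inference

The scan-level model regresses a metric on drug condition (treatment-coded
against baseline, with `between`/`after` kept as separate levels), mean
framewise displacement, task and task × drug, with a participant random
intercept and a session variance component nested within participant
(sessions are not crossed across participants). statsmodels MixedLM is
the estimation engine — REML for estimates and confidence intervals, ML
whenever log-likelihoods are compared. The default scipy optimizer stalls
on this likelihood surface, so fits try Powell/CG first and fall back to
L-BFGS and Nelder-Mead, rejecting non-finite likelihoods. Confidence
intervals are normal-approximation (coverage measured at ~95% in
simulation); t statistics carry residual degrees of freedom `n − p`.
Forcing both variance components to zero reduces the fit to OLS, used as
an oracle in tests.

The random-slope likelihood-ratio statistic, 2·Δll floored at zero, is
referred to the 50/50 mixture of χ²(1) and χ²(2) — the boundary null for
a slope variance plus its covariance with the intercept — with an optional
simulated-mixture p as a Monte-Carlo check. The equivalence test declares
equivalence iff the 90% CI of the post−pre contrast (mixed model when
participant labels are supplied, OLS otherwise) lies within ±δ, with δ
defaulting to 0.5 SD of the pre-period values.

`BalancedNestedLME` is a fast ML solver for the same two-variance-
component model on balanced designs (equal scans per session, equal
sessions per participant): an orthonormal basis splits the data into
within-session, between-session and participant-level strata in which the
covariance is diagonal with three distinct values, so the profiled ML
criterion costs O(n·p) per evaluation. It agrees with statsmodels ML to
~1e−3 in log-likelihood and exists because the wild bootstrap needs
thousands of refits per cohort.

## Wild bootstrap + TFCE

Per parcel, variance components are estimated once by ML under the
reduced model (tested drug term removed). The test statistic is the
full-model GLS t for the drug contrast evaluated at those null-model
components, with the residual scale re-profiled per fit. Bootstrap
samples are y* = reduced fitted values + sign-flipped reduced residuals,
with Rademacher signs drawn per session cluster by default (respecting
within-session correlation; per-observation flipping available), and each
sample is pushed through the identical statistic — which reduces to a
single matrix product per parcel. Evaluating the observed map with the
same statistic as the null maps is what makes the max-statistic procedure
calibrate: letting the observed t re-estimate its variance components per
parcel (while the null t's hold them fixed) adds estimation noise only to
the observed map and inflates the family-wise error rate severalfold.
Measured family-wise error at α = 0.05 is ~6–7% over 200 null cohorts.

TFCE on the parcel graph sums `extent^E · h^H · dh` over thresholds
`h = dh, 2dh, …, max t` (E = 0.5, H = 2, dh = max t/100 — standard
published defaults), where extent is the size of the connected
supra-threshold component containing the parcel; the implementation
processes thresholds top-down with an incremental union-find and matches
brute-force threshold integration to 1e−14. Negative effects are enhanced
by running the same transform on −t. Family-wise p-values are
`(1 + #{b : max null_b ≥ observed}) / (B + 1)`, floored at 1/(B+1).

## Spin test

One Haar-uniform rotation is drawn per permutation, applied to the left
hemisphere and, x-mirrored, to the right, so the hemispheres move together
and networks keep their sizes, shapes and relative positions. Labels are
reassigned by an exact one-to-one (Hungarian) matching of rotated source
centroids to target centroids — a permutation, so every network's parcel
count is preserved by construction; plain nearest-neighbour reassignment
does not guarantee that. Labels arriving from, or landing on, medial-wall
parcels are dropped from that permutation's network means. One caveat of
parcel-level spinning: rotations that map a network's patch onto itself
(a few percent of the rotation group, depending on patch size) reproduce
the observed mean exactly, so the p-value of even a perfectly localized
effect sits at or slightly above the 1/(n_perm+1) floor rather than on it.

The parcellation generator assigns network territories by
capacity-constrained nearest-anchor matching, giving every network a
contiguous patch of near-equal size on each hemisphere; uncapacitated
Voronoi assignment occasionally produces one-parcel networks, which are
both unrealistic and powerless under rotation nulls.

## MDS drug dimension

Classical (Torgerson) MDS double-centers the squared scan distances and
eigendecomposes; negative eigenvalues are truncated and their mass
reported. Eigenweights are the coordinate-weighted sums of centered FC
vectors; projecting a centered FC vector onto dimension d's weights and
dividing by E·λ_d reproduces a training scan's coordinate exactly on
full-rank data, which pins the projection normalization. Dimension signs
are fixed so the psilocybin-condition mean is positive. Embedding analyses
use a two-dose crossover schedule (eight sessions, psilocybin twice):
with a single dose the drug direction can lose the first dimension to
participant-identity variance in small cohorts, whereas two doses per
participant concentrate the shared drug direction in dimension 1.

## Problem sizes used in the validation suite

Simulation-based checks run on reduced cohorts chosen to keep each
property measurable with comfortable margins: typically 4–6 participants,
6–12 sessions, 2–3 scans of 80–200 frames, 24–30 parcels (120 parcels and
510 frames for spin-test power, where patch geometry and the distance
floor matter); 100–300 replicate cohorts per calibration check; B = 99
bootstrap samples and 99 spin permutations in replicated checks, with
1,000 as the single-analysis default. The planted persistent-effect test
uses offset 0.3, scaled to the reduced design's day-to-day variability.

## Known limitations

- The wild bootstrap's fast path requires balanced designs; unbalanced
  cohorts would need the statsmodels path per bootstrap sample (slow).
- Normal-approximation CIs are slightly anticonservative in principle at
  very small participant counts; Satterthwaite/Kenward-Roger adjustments
  are not implemented.
- The spin test operates at parcel, not vertex, resolution; its null is
  coarser than surface-based spinning.
- `between`/`after` sessions are modelled as separate treatment levels,
  not as a continuous recovery curve.
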