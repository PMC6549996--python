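# Methods

## Scope and purpose

`facevector` implements a data-driven model of facial attractiveness in a
PCA morphable face space, together with a synthetic stand-in for the two
components such studies cannot ship: the commercial face generator and the
human raters.  Every stage — face-space construction, stimulus sampling,
rating collection, attractiveness-vector estimation, face manipulation and
Bayesian validation — is executable and testable end to end with no external
data.

## Face representation and face space

A face is a fixed-topology triangle mesh (shape) plus a square RGB texture
map (reflectance).  Flattened, shape lives in R^(3*N_s) and reflectance in
R^(3*N_t).  The face space is the classic morphable-model construction:

    S = S_bar + sum_i alpha_i * Delta_i          (shape)
    T = T_bar + sum_i tau_i * Delta_i^refl       (reflectance)

with the two blocks fitted by *independent* PCAs.  Each offset row
`Delta_i` is the principal direction scaled by the training population's
standard deviation along it, so a coefficient of 1 means "one population
s.d. along PC i".  Training coefficients therefore have unit variance per
component by construction, which the tests verify directly from the
projections.  Texture channels are clipped to [0, 1] after the linear sum
(physical bounds); shape is never clipped.  PCA itself is scipy's SVD with a
deterministic sign convention (largest-magnitude loading positive).

Two scales are provided.  The desk scale — 146 vertices (a 12x12
latitude/longitude grid plus poles), 64x64 textures, 20+20 components,
fitting population 120 — runs the whole experiment in seconds and is the
default everywhere, including the acceptance script.  The `paper_design`
preset restores the full-resolution constants (2043 vertices, 256x256,
50+50 components, 10 000 candidates per sex); it is validated structurally
but not routinely executed.

### The procedural template

The commercial generator is proprietary, so the population source is a
procedural head: an ellipsoidal mesh with compactly supported displacement
fields at facial landmarks (eye size, nose size, jaw width, mouth width),
skin-colour modulation maps (lightness, redness, yellowness on cheek-weighted
maps), and a gender field.  Compact support makes locality exactly testable:
an eye-size change moves no vertex near the nose, mouth, jaw or chin.
Population diversity beyond the handful of semantic dials comes from banks
of seeded smooth idiosyncratic fields (low-frequency waves on the sphere for
shape, low-frequency cosine modes for texture), so the fitting population
has rank well above the requested number of components.  Only structural
agreement with a real generator is claimed — the synthetic basis shares the
algebra, not the statistics, of real faces.

### Gender handling

The gender control (-4 masculine to +4 feminine) is a separate dial, not one
of the PCs: the fitting population holds it at 0, candidates store it as
metadata (uniform in [-4,-1] for males, [+1,+4] for females), it is excluded
from the distance metric and from the estimation matrix F, and manipulation
never touches it.

## Stimulus sampling

Candidates draw every PC coefficient independently standard normal.  The
"most distinctive" subset is selected by ranking candidates on their average
Euclidean distance to all other pool members in the concatenated coefficient
space and keeping the top k, ties broken by lower index.  This is the
literal reading of a one-shot diversity criterion; an iterative max-min
("greedy") alternative is available behind a flag and recorded in pool
metadata.  Distances are computed on unscaled coefficients; the 0.5
coefficient scaling that pulls stimuli toward the average face is applied
afterwards, matching the stated order of operations, and exactly preserves
pairwise distance ratios.  Validation base faces receive the same scaling,
since the estimation matrix F must contain coefficients as raters saw them.

## Rating simulation

Each simulated rater applies an affine transform to a face's latent
attractiveness — the projection of its concatenated coefficients onto a
unit-norm ground-truth direction — and adds Gaussian noise:

    y_pf = intercept_p + slope_p * (w . c_f) + eps,  eps ~ N(0, noise_sd_p^2)

The ground truth splits its weight between blocks via `reflectance_weight`
(w in [0,1]): shape carries sqrt(1-w), reflectance sqrt(w).  The defaults
encode the finding the validation analysis should recover: w = 0 for male
faces (reflectance irrelevant) and w = 0.5 for female faces (blocks equally
weighted).

Discretization to the 1-9 scale is unspecified in any rating study we know;
the default maps each rater's observed latent range linearly onto [1, 9]
and rounds, which is monotone and uses the whole scale.  A fixed-window
alternative (mean +/- 3 latent s.d. onto the scale) sits behind a flag.

The reliability dial is `noise_ratio` = noise_sd / (slope * latent s.d.).
The default 1.0 was chosen once from the Spearman-Brown prophecy: a single
rater with noise ratio 1 has reliability 0.5, so a 20-rater panel's
Cronbach's alpha is 20*0.5/(1+19*0.5) ~= 0.95 before discretization, landing
the simulated panels in the 0.93-0.95 band typical of attractiveness-rating
studies.  Rater counts default to 20 for training and 16 per between-subject
condition for validation.

Standardization is per rater (z-scores with sample s.d.), within each
sex-session; the per-face mean of these z-scores is the rating vector r.
Cronbach's alpha treats raters as items and is computed over faces with
sample variances.

## The attractiveness vector

With F the K x n matrix whose columns are the rated faces' coefficients and
r the mean standardized ratings,

    t = F . r,    t_hat = t / ||t||

independently per block and per sex.  Because candidate coefficients are
isotropic, E[t] is proportional to the latent direction, and the expected
cosine between the estimated joint direction and the truth is approximately
sqrt(n*alpha / (n*alpha + d - 1)) for n rated faces in d dimensions — about
0.91 at the training design (n=200, alpha~0.94, d=40), which the direction-
recovery tests check across seeds.

Manipulation moves a face delta s.d. along the unit direction:
`alpha' = alpha + delta * t_hat`, restricted to one block for the
shape-only / reflectance-only conditions.  In the combined condition the
default applies each block's own unit vector scaled by delta (total
displacement delta*sqrt(2)), consistent with the per-block normalization of
t; a single joint 100-D unit vector is available behind a flag.  The
validation set crosses 10 novel base faces with 7 levels (-3..+3) and the
3 modes: 210 stimuli per sex.

## Bayesian validation

Per sex and condition, item-level means (item = face x level) are regressed
on the level under y ~ N(b0 + beta*x, sigma^2) with priors N(0, 10^2) on b0
and beta and half-Cauchy(0, 5) on sigma — weakly informative defaults, since
the analysis family rather than any particular prior is the target.  Per
sex, the three conditions' item-aligned means enter one trivariate normal
model (flat priors on means, half-Cauchy(0, 5) on s.d.s, uniform over valid
correlation matrices) and the contrast delta_rho = rho(combined, shape) -
rho(combined, reflectance) is summarized from the joint draws, so it
accounts for the shared condition; a two-bivariate-fit variant exists behind
a flag.  Items are analysed per sex (n = 70), never pooled across sexes.

The sampler is componentwise random-walk Metropolis (within Gibbs), all
chains advanced together as vectorized numpy operations, sigma sampled on
the log scale with the Jacobian, invalid correlation states rejected (which
realizes the uniform-over-PD prior).  Proposal scales adapt every 50 sweeps
toward 30-50% acceptance during burn-in only and are frozen afterwards, so
retained draws are valid MCMC.  Defaults: 5000 iterations, 500 burn-in, 4
chains from dispersed starts around moment estimates.  Summaries are the
posterior mean (EAP), the central 95% credible interval, and the split-chain
Gelman-Rubin Rhat (each chain halved; the estimator can sit a hair below 1
for iid chains, as in arviz, and is not floored).

Degenerate inputs are errors, not warnings: constant predictors, constant
vectors, all-zero rating vectors, zero within-chain variance, raters with
constant ratings (named in the message).

## What the synthetic data does and does not show

The generator reproduces the statistical *structure* the analysis assumes —
isotropic coefficients, a linear latent preference shared across raters,
affine rater idiosyncrasy, discrete bounded ratings, between-subject
validation conditions — with effect sizes set once from the design
constants.  It does not emulate real faces' non-isotropic coefficient
distributions, nonlinear preferences (averageness, symmetry), individual
taste differences, or photorealistic appearance.  Passing tests therefore
demonstrate that the pipeline correctly recovers what its model class can
express, not that human attractiveness judgements obey that model.
Quantities that depend on unreleased human data (the published descriptive
statistics and specific slope/correlation values) are reproduced in
structure, not in value.

## Numerical choices and known limitations

- Tolerances: basis orthogonality and PCA round-trips at 1e-8; oracle
  equivalence of t = F.r at 1e-12; standardization identities at 1e-10.
- Selection ties break to the lower candidate index via a stable sort.
- Tie-free determinism: every stochastic operation takes an explicit seed;
  stage seeds are blake2 hashes of (master seed, stage name), kept below
  2^31.
- The desk-scale problem sizes (146 vertices, 64x64 textures, 20+20 PCs,
  1000 candidates, 200 training faces, 10x7x3 validation stimuli per sex,
  100-replicate coverage checks) were chosen as the smallest design at which
  the statistical properties of the full design are preserved.
- The trivariate correlation model's uniform prior is over the PD region
  only; with near-singular condition correlations (>0.99) mixing slows,
  which the Rhat checks would flag.
- Mesh export writes Wavefront OBJ (via trimesh, with UVs when provided)
  and 8-bit RGB PNG textures; the model container is a JSON manifest plus
  flat little-endian float64/int32 arrays, round-tripping bit-identically.
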