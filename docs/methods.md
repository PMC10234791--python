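# Methods

## Shape model and dimorphism scoring

Faces are ordered 2D landmark configurations (the template is opaque to
the package: any consistent point count ≥ 3 works; 131 points is the
default study design).  Superimposition is partial Procrustes: each
configuration is centered, scaled to unit centroid size, and rotated to
the consensus; reflections are disallowed because faces have handedness
and a mirrored landmarking must not alias as shape change.  The GPA
iterates rotation-to-consensus / consensus-update until the consensus
moves less than 1e-10 (root-summed-square), with a 100-iteration cap;
in practice it converges in a handful of iterations.  The consensus is
the plain coordinate-wise mean of the aligned shapes (not renormalised),
so the stored consensus equals the mean of the stored shapes exactly.

References and targets are aligned **jointly** in one GPA (the common
geomorph-style workflow) rather than targets being fitted to a frozen
reference consensus; the two differ only at the level of Procrustes
residuals.  No tangent-space projection and no semilandmark sliding are
applied — at facial-shape variation scales the linear projection on
superimposed coordinates is adequate, but this is a known limitation
for samples with extreme shape variance.

The dimorphism score is the affine coordinate of a face along the line
from the female to the male reference mean, s = (x − m_F)·v/‖v‖² with
v = m_M − m_F: 0 at the female mean, 1 at the male mean.  This is one
monotone choice among several (some authors divide by ‖v‖ instead);
since the downstream analysis z-scores every predictor, any positive
affine rescaling yields identical standardized results.  The z-scored
variant is what enters the regressions.

Degenerate inputs fail loudly: zero centroid size, mismatched point
counts, a zero-length axis (identical sex means), and z-scoring of a
single target are all errors, not warnings.

## Ratings and self-report scales

Rater-level exclusion drops every record of a rater whose seriousness
(1–7) is below 5.  Per-face trait scores are unweighted means; rater-sex
subgroup scores ("male"/"female") exclude raters of other or unknown
sex, who still count toward the "all" aggregate.  No reliability
statistic is computed; the design leans on the ≥ 30 ratings-per-stimulus
coverage rule, which `coverage_check` verifies.

NFS (9 items) and each FIS subscale (20 items) are scored as the mean
of applicable 1–5 items, keeping all three instruments on one range.
NFS admits no not-applicable answers (an NA there is a data error); a
FIS subscale that is entirely NA is undefined and propagates as missing
into the per-model complete-case analysis.  The participant funnel
removes, in order: no usable photograph, seriousness < 5, language
issues, duplicate participation; each participant is counted under the
first reason that applies, so the per-reason counts always sum to
(input − kept).  A duplicate participant is represented as two roster
records sharing one id, both removed — which is how a roster of 312
with 28/21/2/1 flagged cases yields a final sample of exactly 259.

## Statistical engine

**Winsorisation** clips to mean ± k·SD (default k = 3) using the
moments of the original vector in a single pass — no re-estimation
after clipping — and is applied within each analysis sample (full or
fathers-only) before standardization.  Missing values pass through; a
constant vector is returned unchanged.

**Regression.**  Outcome and predictors are z-scored on the analysed
(complete) cases, then fitted by OLS.  The reported df is
n − p − 1, counting the intercept even though it is identically zero
after centering, to match the convention of fitting the model on raw
variables.  Correlations are pairwise-complete; regressions are
listwise per model.

**JZS Bayes factors.**  "Default priors" is operationalised as the
Zellner–Siow mixture of g-priors on standardized slopes with scale
r = √2/2 (exposed as `bf_prior_scale`).  The model-vs-intercept Bayes
factor is the one-dimensional integral over the mixing parameter g:

    BF₁₀ = ∫₀^∞ (1+g)^((n−1−p)/2) · (1+g(1−R²))^(−(n−1)/2) · π(g) dg,
    g ~ InverseGamma(1/2, n·r²/2),

evaluated after the substitution g = eᵘ by adaptive quadrature of the
peak-normalised integrand (the log-integrand is written with
`logaddexp` so it is finite over the whole real line; the quadrature
must reach a relative accuracy of 1e-6 or it raises with diagnostics).
The effect-level BF for one predictor is the ratio of the full and the
drop-one model's BFs against the common intercept-only null.  The test
suite pins this implementation to an independent 10⁶-node trapezoidal
quadrature of the same integrand to 0.1%.

**Power.**  The sample-size routine finds the smallest N for which the
focal term's noncentral-F test (df1 numerator df, N − p − 1 denominator
df, noncentrality λ = f²·N) reaches the target power at level α, by
iterating N upward.  Defaults α = 0.05 and df1 = 1 are conventional
and exposed as parameters.  With f² = 0.027, 80% power and a
two-predictor model this yields N = 293; the alternative
λ = f²·(df1+df2+1) convention would give 294 and is not used.

## Synthetic-data generator

The generator is a linear-Gaussian latent-trait model with ordinal
discretisation — the simplest structure satisfying every assumption the
analysis itself makes (linearity, additive noise).

*Geometry.*  A base shape (unit centroid size) plus a hidden unit
direction d, orthogonalised against translation, scaling and
infinitesimal rotation at the base so Procrustes cannot absorb the sex
difference.  A face at position t is base + t·L·d with L the axis
length (default 0.05 in centroid-size units), plus isotropic landmark
noise of SD `landmark_noise_frac · L` per coordinate (default frac
0.10, i.e. score noise of about 0.1 axis units), then a random
rotation/scale/translation into pixel coordinates.  Reference females
sit at t ~ N(0, 0.5²), reference males and participants at
t ~ N(1, 0.5²) — two overlapping Gaussians, participants drawn from
the male component.

*Latent traits.*  Attractiveness and perceived masculinity correlate
with standardized t at 0.16 and 0.28 respectively; each outcome is its
configured linear predictor plus a residual of complementary variance,
with the self-report residuals correlated 0.6 (NFS vs FIS-involved)
and 0.1 (FIS-desired vs both).  Default true effects: all dimorphism
effects zero; attractiveness −0.44 on perceived involvement and −0.13
on desired involvement.

*Measurement.*  Ratings discretise 5.5 + 1.5·latent + rater bias
(SD 0.5) + noise (SD 1.5) to integers 1–10; each of ~33 raters per
face per trait rates one trait only, and ~1% of the 422-rater pool is
flagged non-serious.  Scale items discretise 3 + 0.8·latent + noise
(SD 0.6) to 1–5, with 10% NA injected into FIS items.  Averaging 33
ratings (or 9–20 items) leaves reliabilities above 0.94, so observed
standardized effects are attenuated by only a few percent relative to
the latent truth.

*What it does not emulate.*  Photographic artefacts (head angle,
lighting, filters) that contaminate real dimorphism scores;
non-linear or heteroscedastic trait relations; rater drift and
stimulus-order effects; item-level factor structure within the scales.
Passing tests therefore demonstrate the pipeline's correctness and
calibration under the stated model, not robustness to those real-data
features.

*Fast tabular path.*  `simulate_analysis_table` shares the latent
model but replaces the geometry with its induced score-noise
equivalent and generates rating means directly (per-rating bias and
residual collapsed into one noise term, so the shared-rater covariance
across faces is dropped).  Replicated experiments
(`facecue.experiments`) use it to keep thousands of replicates cheap;
agreement between the tabular and full landmark paths is itself under
test.

## Replicated validity experiments

With the null default world, the focal dimorphism test's rejection
rate over 2,000 replicates at n = 259 is checked against the exact
binomial 99% interval around 0.05, and the median focal BF₁₀ must fall
below 1.  With a true attractiveness → perceived-involvement effect of
−0.44, the mean fitted standardized beta over 200 replicates at
n = 259 must land within ±0.10 of the truth (the small attenuation
from measurement discretisation is well inside that band).  These
problem sizes were chosen to give tight Monte-Carlo error while
keeping the default suite fast.

## Design choices that were genuinely open

- Joint vs sequential GPA of references and targets: joint (one shape
  space), as above.
- Projection normalisation (÷‖v‖² vs ÷‖v‖): affine 0–1 convention;
  immaterial after z-scoring.
- NFS scored as item mean rather than sum: keeps all instruments on
  the 1–5 range; standardized analyses are identical either way.
- Winsorisation within each analysis sample (not once globally): each
  model's outlier rule then refers to its own sample's moments; the
  run log records per-sample clip counts.
- JZS prior scale default √2/2 on standardized slopes, exposed as a
  parameter.
- Power-analysis conventions (α, df1, λ = f²·N) as above, exposed as
  parameters.
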