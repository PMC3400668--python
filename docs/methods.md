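# Methods

This note documents the models, numerical choices and limitations behind
swimkit, in the order the pipeline runs them.

## Study design emulated

The synthetic population follows a river-gradient design: five collection
sites — Yang-Jiao (YJ, lower/main), Hao-Kou (HK, lower/tributary), Si-Nan
(SN, middle/main), San-Du (SD, middle/tributary), Da-Guan (DG, upper/main)
— with the environmental covariates (river slope, water velocity,
temperature, altitude, predator size and abundance, dissolved oxygen)
carried in `synth.builtin_site_table()`. There is no upper-reach tributary
site; this structurally empty cell is what the ANOVA layer must survive.
Sample sizes default to 6, 6, 8, 8 and 7 fish per site, one-year females of
about 8.1 cm and 5.5 g. Site-level true means (`pipeline.SITE_TRUTH`) give
tributary and upper-reach fish higher Ucrit (50–64 cm s⁻¹ across sites),
higher RMR (140–185 mg O₂ kg⁻¹ h⁻¹), shallower steepness
(0.023–0.032 (cm s⁻¹)⁻¹, hence Uopt ≈ 31–43 cm s⁻¹), and identical
fast-start parameters everywhere (latency ≈ 12 ms, Vmax ≈ 1.2–1.4 m s⁻¹,
turning radius ≈ 10–15 mm): steady swimming varies along the river,
unsteady swimming does not. Individual truth varies around site means with
6 % CV.

## Respirometry

A closed-phase trace is `o2(t) = o2₀ − slope·t + ε`, sampled every 2 min
(default 20-min phase), ε i.i.d. Gaussian with SD 0.02 mg L⁻¹ by default
(a realistic optode noise floor). The analysis is the inverse model:
OLS slope of O₂ on time, converted min → h, with
`MO2 = slope·(VOL − V_fish)/m`. Choices worth noting:

* slopes are stored as positive depletion magnitudes; a rising O₂ trace
  (negative magnitude) is physically impossible in a sealed chamber and
  fails QC regardless of its r²;
* the QC threshold r² > 0.95 is a strict inequality;
* MO2 output is per hour even though sampling is per minute; the
  conversion happens inside the slope estimator;
* mass standardization uses the per-kg convention
  `MO2_std = MO2 · m^(1−b)` with b = 0.75, exposed as a single argument —
  this is the standard direction when rates are reported per kg at a 1-kg
  standard mass, and it is the one assumption a user may most plausibly
  want to flip;
* fish volume defaults to mass at 1.0 kg L⁻¹ (neutral buoyancy) when not
  measured.

RMR is deliberately *not* estimated from resting traces: it is defined as
the power-curve intercept (below), so the respirometry stage only produces
per-speed rates and MMR (the QC-passing maximum).

## Ucrit and the power curve

`gen_ucrit_trial` inverts Brett's formula exactly; fatigue falling on a
step boundary is assigned to t = 0 of the higher step, which makes the
round trip `compute_ucrit(gen_ucrit_trial(u)) = u` an identity for every
u above the starting speed, on or off the 6 cm s⁻¹ grid. Ucrit is reported
in absolute cm s⁻¹; the body-length-relative variant exists
(`relative_ucrit`) but is not used in group statistics because it inherits
a strong body-length artifact.

The cost curve MO2 = α·e^(βU) is fitted by unweighted nonlinear least
squares on the raw rates (scipy `curve_fit`), initialized at the log-linear
regression solution; `method="loglinear"` returns that seed itself for
users who prefer fitting on the log scale. The fit requires ≥ 3 distinct
speeds and positive rates, and refuses negative fitted α or β (a cost
curve must rise with speed). Uopt = 1/β is stored exactly, not re-derived
numerically; COT = MO2/U (cm s⁻¹ → km h⁻¹, giving mg O₂ kg⁻¹ km⁻¹) has its
analytic minimum at Uopt, and the test suite confirms the identity by grid
search. Within a step the pipeline averages all QC-passing records per
speed (`per_speed_mo2`, with a `"last"` option) before fitting.

## Fast-start kinematics

The generator moves the center of mass along a circular arc of the true
turning radius, with per-frame speed ramping linearly over 5 frames to Vmax
and holding for ≥ 15 frames; latency is snapped to the 2-ms frame grid
because a camera cannot resolve sub-frame onsets. Analysis choices:

* motion onset: first post-stimulus frame whose displacement exceeds 3× the
  pre-stimulus displacement SD, floored at 0.2 mm — the floor keeps a
  noiseless synthetic fish from producing a zero threshold. No crossing is
  a flagged "no response", not an exception.
* velocity: central difference `(p[i+w] − p[i−w])/(2w)` on a 3-frame
  moving-average path. The default half-width is w = 1: at realistic
  escape magnitudes (≈1.4 m s⁻¹ on a ≈10-mm-radius turn at 500 fps) a wider
  stencil spans a large arc angle and biases chord speed low by several
  percent, while w = 1 keeps the discretization bias under 1 %. Both the
  smoothing window and w are parameters, not constants.
* turning radius: algebraic (Kåsa) least-squares circle through the frames
  in the first 20 ms after onset (the field reports no standard window;
  20 ms covers stage 1 of a C-start at these sizes). Collinear paths are a
  flagged "undefined radius" (straight escape).

All three metrics are invariant to rigid motions of the coordinate frame;
Vmax scales linearly under spatial rescaling; latency is quantized to
1000/fps ms. The per-frame speed plateau in the generator exists precisely
so the central-difference Vmax is recoverable; real escape responses peak
more sharply and their Vmax depends more on the smoothing choices.

## Geometric morphometrics

GPA centers each configuration, scales it to unit centroid size, rotates it
to the running consensus (SVD rotation, reflections excluded) and iterates
the consensus to `tol` (partial Procrustes: no further scaling in the
rotation step). The 17-landmark template is a stylized lateral fish
outline defined in `synth.FISH_TEMPLATE_17`; synthetic shape variation is a
fixed smooth thin-plate-spline displacement field scaled per specimen by a
known covariate, plus isotropic landmark noise.

Partial warps: the bending-energy matrix of the consensus (TPS kernel
r²·log r²) is eigendecomposed; its k−3 non-null eigenvectors, applied to
the x and y residual components, give 2(k−3) non-uniform scores. The
uniform (affine) component is the 2-D orthonormal complement of the
similarity directions inside the affine subspace. Residuals are first
projected into the shape tangent space (removing the residual scale and
rotation directions), so squared scores sum exactly to the squared tangent
residual per specimen — the Pythagorean identity the tests check at 1e-8.

Shape-on-covariate inference uses a Goodall-style pooled-SS statistic,
`F = SS_explained / (SS_residual/(n−2))`, with significance from covariate
permutations (observed permutation included in the tail count, so the
smallest attainable p is 1/(n_perm+1)). The classical parametric df
convention of legacy TPS software cannot be reconstructed unambiguously;
permutation inference is distribution-free and standard in current
geometric morphometrics, and n need not exceed the score dimension.
Semilandmarks are not supported.

Both peduncle ratios are provided — CPH (% of body length) and CPD/BD
(fraction of body depth) — because both denominators are in common use;
they are different numbers and are kept as separate fields.

## Population genetics

Sequences evolve by per-site independent K2P substitutions with ts/tv rate
ratio κ = 2 (matching the estimator's model); group ancestors diverge from
a root and tips from their ancestor, with branch lengths chosen so expected
within- and between-group pairwise distances hit their targets by path
additivity. The estimator counts transitions P and transversions Q under
pairwise deletion (gaps and any non-ACGT symbol drop the site for that pair
only) and applies the closed form; arguments of the logarithms ≤ 0 raise a
saturation error, and saturated pairs become NaN (with a warning) in
matrices rather than fabricated large distances. Ambiguity codes beyond N
are treated as missing — Sanger-grade cyt-b data rarely needs IUPAC
resolution. No alignment, tree building or haplotype networks: inputs are
assumed aligned.

## Statistics

*Correlations.* Pearson r with the exact two-sided p from
t = r·√((n−2)/(1−r²)) on n−2 df; |r| ≥ 1 maps to p = 0. No
multiple-testing correction is applied anywhere, by design parity with the
field workflow this package scripts.

*Factorial ANOVA.* Fixed-effects, sum-to-zero (deviation) coding, all
interactions by default. Columns are added term by term with an
incremental orthogonalization; a column linearly dependent on what precedes
it (the signature of a structurally missing cell) is dropped and reported
in `dropped_contrasts`, and a term losing *all* its columns raises an
inestimability error naming the missing cells. Each term is then tested by
full-vs-reduced model comparison against the full model's residual mean
square — on complete designs this is Type III (and collapses to the
classical decomposition when balanced, which the tests verify against a
closed-form oracle). In the five-site design the reach×stream interaction
retains 1 of its 2 contrasts. Speed enters the three-way analysis as a
fixed categorical factor even though the same fish contributes at every
speed; that pseudo-replication is inherited from the emulated workflow and
flagged here rather than remodelled (a mixed model is out of scope).

*Duncan's multiple range test.* Ranked group means; a stretch of p means is
homogeneous when its extremes differ by less than
q(1−(1−α)^(p−1); p, df)·√(MSE/n_h), or when it lies inside a homogeneous
stretch (the protection rule). MSE is the pooled within-group mean square;
n_h the harmonic mean of group sizes (the common convention for unequal
n). Letters are assigned to maximal homogeneous stretches, which are
contiguous in rank order, so the display is always a staircase. α is 0.05
throughout. The studentized-range quantile is cached per (span, df, α)
because scipy's `ppf` is expensive and the quantile is data-independent.

## Pipeline and reproducibility

`run_full_analysis` is plain sequential execution driven by one flat config
(`PipelineConfig` / YAML): every protocol constant — ΔV = 6 cm s⁻¹,
T = 30 min, 3.5 L, r² > 0.95, mass exponent 0.75, 500 fps, α = 0.05 — lives
there and nowhere else. Randomness flows from one `SeedSequence(seed)`
spawned per stage, so identical config+seed reproduces every numeric output
byte-for-byte (`run.log` timestamps and the provenance record, which embeds
the output path, are the only run-specific files). Failures abort with the
stage name attached.

Problem sizes in the test and acceptance suites — 31–35 fish, 11-point
power curves, 200-seed noise sweeps, 500–1000-replicate null simulations
with 99 permutations each, 100-dataset Duncan comparisons — were chosen as
the smallest sizes at which the Monte-Carlo standard errors are comfortably
inside the asserted bands.

## What passing tests do and do not show

The generators reproduce the *measurement models the analysis assumes*
(linear depletion, exponential cost curve, circular-arc escapes, TPS
deformations, K2P substitutions), so parameter-recovery tests certify the
estimators, not the models. Real data add background respiration drift,
gait transitions near Ucrit, sharply peaked escape velocity profiles,
digitizing error correlated along the body, rate variation across sites,
and fish that refuse to swim — none of which are simulated. Published
group-level values that depend on the original raw data (site means,
ANOVA tables, the 0–2.37 % divergence range) are not reproducible from
synthetic data and are not asserted; the one analytic anchor that survives
on printed numbers alone is the site-level Ucrit–Vmax correlation
(r = 0.367, n = 5 → p ≈ 0.543; the printed value 0.544 reflects rounding
of r itself, as r ∈ [0.3665, 0.3675] maps to p ∈ [0.5430, 0.5440]).
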