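# Methods

## Measurement model and correction

A spot's measured intensity is modelled as the true intensity times a
spatially varying multiplicative factor, `I(x,y) = CF(x,y) · I′(x,y)`.
Because all positive-control spots of one dilution are technical
replicates from a single lysate batch, their observed variability is a
direct survey of the spatial bias; the correction factor is the ratio of
the local (pseudo-)positive-control intensity to the slide's mean
positive-control intensity, `CF = PCI*/⟨PCI⟩`, and correction divides:
`I′ = I / CF`. The model assumes bias is multiplicative (signal
generation is proportional to bound reporter), smooth at the scale of the
anchor spacing (one subgrid, 11 spots), and shared by all spots
regardless of their content. Nothing is assumed about the relationship
between different samples' intensities.

## Anchors and the interpolation lattice

Each of the 96 positive-control dilution sets contributes one anchor.
The default policy takes the set's **median**-intensity valid spot — the
dilution most likely to fall in the assay's linear range — anchored at
that spot's own position; with an even number of valid spots the lower
median is used, so the anchor is always a physically printed spot. A
`fixed:k` policy (dilution step *k* of every set) is available for users
who prefer a deterministic position; on a clean monotone series the two
coincide at the middle dilution.

Bilinear interpolation needs anchors on a rectangular grid. Anchors are
therefore registered on a lattice keyed by subgrid row (12 lines) and
control-set column (8 lines in the default design); each lattice line's
coordinate is the **mean** absolute position of its member anchors, which
absorbs the ≤ ±2-spot jitter of median positions without breaking
rectangularity. The interpolant is exact at the registered lattice nodes
(knot property); for jitter-free slides the nodes coincide with the
anchor spots and an anchor corrected by its own surface lands exactly on
⟨PCI⟩.

Interior spots get the standard four-corner bilinear blend (linear in
each axis, bounded by the corner values). Spots outside the anchor hull —
the top 11 of 132 rows in the default layout, about 1/12 of the slide —
take the value at the **nearest covered location**; since the covered
region is an axis-aligned rectangle, the Euclidean-nearest point is the
per-axis clamp of the query, which is unique. Interpolation operates in
absolute spot-index space: on a uniform print grid, index space is an
affine image of physical coordinates, and bilinear interpolation is
invariant under axis-wise affine maps, so the results are identical.

A bicubic alternative evaluates an interpolating tensor-product spline
(scipy's `RectBivariateSpline`, `s=0`) through the same lattice. An
interpolating spline with not-a-knot-style end conditions was chosen over
a natural spline because it reproduces bicubic polynomial surfaces
exactly, giving a sharp correctness oracle; a natural spline's forced
zero boundary curvature would not. Lattices with fewer than 4 rows or
columns cannot support cubic pieces and fall back to bilinear with a
warning. The spline is a secondary method behind a flag; bilinear is the
default.

## Numerical choices

- **Clamping**: CF is clamped into `[0.1, 10]` by default. A dead region
  (near-zero pseudo-PCI) would otherwise explode corrected intensities;
  clamp events are counted and logged, and the unclamped surface is kept
  on the result for inspection.
- **Ties and degenerate inputs**: lower median on even counts; a control
  set with no valid positive spot is a hard error naming the set (the
  user should exclude it via the layout); an incomplete anchor lattice is
  an error rather than a silently irregular grid.
- **Invalid spots** (missing or flagged records) are carried with
  `valid = False`: excluded from anchor selection and all QC statistics,
  but still assigned a CF and corrected, so output tables keep the full
  grid shape.
- Statistics use the sample (n−1) standard deviation throughout;
  replicate counts are small (three biological replicates) where the
  choice matters.

## QC metrics and aggregation

`%CV = 100·σ/μ` per replicate group; replicates are only comparable
within one dilution step, so a group's %CV is computed per step and
averaged (unweighted), and the slide %CV is the unweighted mean over
groups — group-mean rather than pooled aggregation, which keeps a large
group from dominating. The slide pass flag compares the slide %CV with a
configurable cutoff (default 15%). Pearson ρ across duplicate slides is
computed on matched valid spot positions. Z′ and Welch's *t* compare
positive-control spots with buffer spots per dilution stratum and report
the mean across strata; pooling strata would inflate σ_p with the
16-fold dilution range — the same range-inflation artefact that makes a
pooled duplicate-slide ρ overstate reproducibility, which
`dilution_correlations` quantifies directly. QC can equally run on a
supplied concentration column instead of intensities; concentration
estimation itself is out of scope. All statistics are descriptive; no
p-value thresholds or multiplicity control are applied.

## Synthetic slides

The simulator emulates the default production design: positive-control
sets share one true dilution series (`control_level · 0.5^(step−1)`,
top level 10000 signal units), samples draw independent lognormal top
levels (meanlog = log 5000, sdlog = 1 — a wide biological spread),
buffer spots sit at a background of 200, and
`measured = truth · bias(row, col) · exp(N(0, σ_log))` with σ_log = 0.05
by default. Replicate studies print 100 conditions in biological
triplicate (≈300 samples, the scale of a typical perturbation study) with
lognormal replicate dispersion whose CV defaults to 10%, scattered over
the slide at random so spatial bias shows up as excess replicate
variance.

Bias fields: constant, linear gradient, radial Gaussian, low-frequency
sinusoid (the default ±30% amplitude, one period per axis — slow relative
to the anchor spacing), and a **cell-wise bilinear** field whose nodes sit
exactly at the default anchor positions. The last is the testing
backbone: a field that is bilinear within every anchor cell and constant
beyond the hull is recovered *exactly* by the bilinear normalizer, so
zero-noise recovery can be asserted to 1e-9 relative. Smooth fields are
normalized to unit mean over the slide; the cell-wise field is normalized
to unit mean over its lattice nodes instead, which makes the estimated
reference ⟨PCI⟩ exactly unbiased and the recovery identity exact rather
than up to a constant.

What the simulator does **not** model: antibody cross-reactivity,
saturation/dynamic-range ceilings, spot morphology and segmentation
error, additive background structure, or between-slide scale differences.
Passing tests therefore demonstrate that the estimator removes
multiplicative, smoothly varying bias under realistic noise — not that
real slides contain only such bias.

## Problem sizes and determinism

Stochastic properties are checked on full-size 5808-spot slides: 100
seeded slides for the held-out control %CV comparison and 50 seeded
duplicate pairs for the ρ and Z′ comparisons, with win-rate thresholds of
95% and 90% respectively. Every random draw flows from a single integer
seed through `numpy.random.SeedSequence`, so identical configuration and
seed reproduce slides bit for bit.

## Known limitations

- The correction is within-slide only; between-slide scaling and loading
  normalization are deliberately out of scope.
- Median-of-set anchoring assumes each control set's series is monotone
  enough that its median is meaningful; heavily saturated or dead sets
  should be excluded through the layout.
- The lattice-registration step assumes every subgrid contributes its
  full complement of control sets; partially printed slides need a custom
  layout declaration.
- Model-based alternatives (row/column fixed effects, per-spot regression
  normalization) are intentionally not implemented.
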