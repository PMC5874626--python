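# Methods

## Nitrogen mass balance

The budget treats each station × sectioning time point as a closed nitrogen
ledger over the upper 20 cm of soil.  Anaerobic NH₄⁺ production is measured
in homogenised, anoxic jar incubations per depth layer; the porewater
concentration slope (µM d⁻¹, ordinary least squares against incubation day)
is accepted only when its two-sided t-test gives p < α (default 0.05) and is
converted to a bulk volumetric rate by multiplying with porosity
(1 µM ≡ 1 nmol cm⁻³ of porewater).  Jar layers are 0–2, 2–5, 5–10 and
15–20 cm; the unincubated 10–15 cm layer is linearly interpolated between
its neighbours at the layer midpoints (7.5, 12.5, 17.5 cm — equally spaced
for this geometry, so the interpolation reduces to the mean; the general
midpoint formula is implemented because other geometries differ).  Areal
production is Σ rate × thickness, converted nmol cm⁻² d⁻¹ → mmol m⁻² d⁻¹
(×0.01).  A missing or non-significant required layer marks the whole
time point's budget *incomplete*; it is flagged and propagated, never
silently dropped.

Solute fluxes from closed-core incubations follow
(C_end − C_start)·V/(A·t); positive values are effluxes out of the soil and
negative values are uptake (a sign, not an error).  DIN is NH₄⁺ + NOx⁻.
Replicate cores are averaged per measurement day (SEM across cores); days
within the aggregation window — all measurements since the previous
sectioning, i.e. window (previous, current] — are combined with time
weights from the midpoints between consecutive days.  The matching of flux
campaigns to sectionings is a genuine design freedom; using all information
between snapshots was chosen over nearest-day matching because fluxes vary
smoothly between sectionings in this design.

Porewater inventories integrate concentration × porosity × thickness over
the six sectioning layers (0–1, 1–2, 2–5, 5–10, 10–15, 15–20 cm); the
accumulation rate is the inventory difference between consecutive
sectionings divided by the elapsed days, with the pre-flood profile as the
baseline for the first sectioning.

Potential denitrification is the residual
D_raw = production − DIN efflux − accumulation.  Negative residuals (DIN
release exceeding measured production, within error) are clamped to zero
and flagged `negligible_denitrification`; the raw value is always retained
for audit.  Potential NH₄⁺ oxidation is the clamped residual plus the NOx⁻
efflux, because denitrified nitrogen must first have been oxidised to NOx⁻.
The identity production − DIN efflux − accumulation − D_raw = 0 holds
bit-exactly (evaluated in that association order) for every computed budget.

## T-RFLP fragment pipeline

Peaks are gated to the closed interval [50, 550] bp (the sizing-standard
window).  Noise filtration is iterative, per sample: σ is the zero-mean RMS
of the currently unclassified peak areas (a sample-SD estimator is
available), every peak with area > 1.15·σ is promoted to signal, and the
pass repeats until a fixed point.  Peaks move one way only, so the loop
converges in ≤ n passes and is order-invariant.  Two structural properties
of this procedure are worth stating explicitly:

* for any factor ≥ 1, the fixed point always leaves at least one peak (the
  smallest survivor) classified as noise — exact recovery of noise-free data
  therefore requires disabling the filter, which `noise_factor = 0` does;
* the procedure is scale-free on the noise set, so whether baseline noise is
  removed depends only on the *shape* of the noise-area distribution: for
  heavy-tailed distributions (e.g. exponential) the threshold cascades
  downward and promotes most noise to signal, whereas any distribution with
  max/RMS < 1.15 under truncation (e.g. a uniform band with max/min ≤ 1.37)
  is removed essentially completely.  The synthetic generator therefore
  draws noise-peak areas from a narrow uniform band
  (0.75–1.0 × `noise_area_scale`), which the factor-1.15 filter removes at
  ≈99% — the residual ~1% reflects finite-sample RMS fluctuation, and such
  stray single-sample peaks are exactly what the downstream singleton filter
  removes.

Binning is single-linkage chaining on sorted sizes: a new OTU starts when
the gap to the previous observation exceeds 0.6 bp.  Chains can exceed
0.6 bp in total width; each OTU records its member-size range and its
area-weighted centroid.  Multiple peaks of one sample in one bin are summed
(area is the abundance proxy).  Rows are standardised to relative abundance,
then OTUs present in fewer than 2 samples (singletons) and OTUs whose mean
per-sample relative abundance is below 1% are removed.  "Total abundance"
is ambiguous between per-sample, mean and grand-total readings; the mean
reading is the default and the rule is configurable
(`abundance_rule="grand_total"`).  Rows are deliberately not re-normalised
after filtering, so removed mass stays visible.  The log transform is
ln(1 + 100·x) on relative fractions — zero-safe, monotone, percentage-scale;
the base is configurable.

## Community statistics

Bray–Curtis dissimilarities are computed for samples or OTU profiles
(scipy's implementation; a naive double-loop oracle guards it in the test
suite).  Hierarchical clustering is UPGMA via scipy's nearest-neighbour
chain; tie-breaks among equal merge heights follow that implementation and
are deterministic, but dendrogram shape under exact ties should not be
over-interpreted.

NMDS minimises Kruskal stress-1 with scikit-learn's non-metric SMACOF
solver, best of n seeded random restarts (default 20, k = 2, 300 iterations,
tolerance 1e-7); scores are centred and fully reproducible under a fixed
seed.  As with any NMDS, data consisting of a few discrete community types
can yield clumped, near-zero-stress configurations; this is a faithful rank
embedding of such data, not a solver failure, but stress values ≪ 0.01 on
rich data warrant a look at the score scatter.

PERMANOVA partitions tr(G), where G is the Gower-centred matrix of squared
dissimilarities, into sequential (Type I) terms in formula order via nested
hat matrices of the cumulative model designs; categorical factors enter as
dummy columns, numeric factors as centred covariates.  Pseudo-F uses the
residual mean square.  p-values use free row/column permutation: all n!
permutations are enumerated when n! ≤ 10,000 (p = #(F* ≥ F)/n!, identity
included, which makes p exactly the minimum attainable for perfectly
separated groups); otherwise random permutations with the +1 correction.
When a permutation fits perfectly (residual ≈ 0) its pseudo-F is treated as
infinite so that perfect fits tie rather than losing to float noise.
Restricted/strata permutation is not implemented.  Singleton groups are
allowed but flagged.

Environmental vector fitting regresses each numeric variable on the score
columns; R² is the coefficient of determination, the arrow is the unit
coefficient vector, and p comes from permuting the variable across samples.
Module detection applies UPGMA to Bray–Curtis distances between OTU
abundance profiles and cuts the tree into k flat clusters (default k = 4),
renumbering modules by first appearance along the sample ordering.

## qPCR quantification

The standard curve is OLS of Cq on log₁₀(copies) over a dilution series
(≥3 points spanning ≥2 decades; the default synthetic series is 10¹–10⁷
copies); amplification efficiency is 10^(−1/slope) − 1.  Duplicate Cq values
are averaged on the Cq scale and flagged when they differ by more than
0.5 Cq.  The normalisation chain is explicit —
copies/reaction × (elution volume / template volume) / (wet mass × (1 −
water content)) — with every factor an input column and no hidden constants.
Estimates below the lowest standard are reported but flagged *below
quantification*; the confidence interval propagates the duplicate spread
through the curve with a t interval (df = n−1) on the mean Cq.

## Synthetic scenarios

The generator emulates the study design: two stations with contrasting
organic matter ("UC" rich, "C" poor), a pre-flood baseline plus four
post-flood sectionings (days 7, 60, 120, 180), six porewater layers, four
jar layers, 3 replicate cores, 13 flux campaigns (weekly → biweekly →
monthly), 60 soil samples + 10 seawater samples for community profiling, and
five marker genes.  The nitrogen truth is built backwards from the target
denitrified fraction f: production P comes from per-layer volumetric rates
(the 10–15 cm truth is defined as the midpoint interpolation of its
neighbours, so depth integration is exact); the non-denitrified remainder
(1−f)·P is split 35% porewater accumulation / 65% DIN efflux, with a
time-increasing NOx⁻ share.  The budget identity P = DIN efflux +
accumulation + denitrified holds exactly in the truth tables by
construction.  Porewater NH₄⁺ profiles realise the implied inventory
trajectory with weights peaked at 5–15 cm; Cl⁻ profiles are
error-function-shaped diffusion fronts relaxing over time (descriptive
plumbing only — no transport physics is modelled, and consistency with the
budget identity, not diffusion, is the contract).

Communities are built from an OTU pool partitioned into core taxa, four
"boom and bust" modules with disjoint occupancy windows over
(time point × depth band), station-specific taxa and marine taxa (partially
invading soils after flooding); within a sample, abundances are Dirichlet
draws around the design weights (concentration 150).  Fragment centroids
are spread ≥2 bp apart over 60–540 bp; peaks get Gaussian size jitter
(sd 0.15 bp) and lognormal area noise; Poisson-count noise peaks (mean 25)
land uniformly on 50–550 bp.

Noise defaults are chosen once as realistic instrument precisions: 0.15 µM
additive on flux concentrations (flow-injection nutrient analysis), 1%
relative on porewater concentrations, 0.1 Cq replicate noise, lognormal
σ = 0.1 per peak area and 0.15 per sample total signal.  Jar series are
noise-free by default: the jar rate is fit-limited, not noise-limited, in
this design, and the regression gate's behaviour under noise is
characterised separately (type-I calibration at slope 0).  All randomness
derives from a single seed through named substreams (one per data type), so
regenerating one table never perturbs the others, and a fixed seed gives
byte-identical bundles.

What the generator does *not* emulate: spatial heterogeneity within a
layer, diffusive transport, non-linear jar kinetics, PCR amplification bias,
pseudo-T-RFs, or taxon-specific qPCR efficiencies.  Passing recovery tests
therefore demonstrate the correctness of the computational chain under the
stated error model, not robustness to every failure mode of real
measurements.

## Problem sizes and numerical choices

Recovery studies use the full study geometry (2 × 4 budget cells, 70
community samples); Monte-Carlo calibrations use 1000 replicates
(regression gate, PERMANOVA type-I at n = 8 with 99 permutations, qPCR CI
coverage) and 100–200 instances for oracle-agreement sweeps.  Exhaustive
PERMANOVA enumeration is capped at 10,000 permutations (n ≤ 7).
Significance gates use α = 0.05 two-sided throughout.  Degenerate inputs
fail loudly with the offending field or sample named: zero porosity, gapped
porewater profiles, zero-total samples, constant PERMANOVA factors,
inverted qPCR standards.  Analysis outputs are written with 6 significant
digits; simulated *input* data are written at full double precision so that
noise-free recovery round-trips through files losslessly.
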