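# Methods

## Neighborhood model

A tissue is a set of segmented cells with centroid coordinates in
micrometers and one mean intensity per marker.  Two cells are neighbors
when their center-to-center Euclidean distance is at most the
neighborhood radius `radius_um` (default 55 µm, boundary inclusive — the
radius is read as an attainable maximum).  The focal cell is never its
own neighbor; distinct cells at identical coordinates are legitimate
neighbors at distance 0 and are distinguished by id, never by distance.

**Border exclusion.**  A focal cell closer than `radius_um` to the ROI
boundary has a truncated neighborhood, so it is dropped from the focal
set; it remains available as a neighbor and as a nearest-of-type target
of retained cells, because truncation is a property of the focal
neighborhood, not of neighbor eligibility.  On a W×H rectangle the
retained set is exactly the inset rectangle [r, W−r]×[r, H−r]; for
polygon and circular ROIs the same rule uses distance to the boundary.
An ROI smaller than 2r in either dimension yields an empty focal set
with a warning, not an error.

**Per-focal metrics.**  Composition counts/fractions by phenotype over
the radius neighborhood (fractions sum to 1 when at least one neighbor
exists; empty neighborhoods are flagged and carry NaN fractions, never
silently dropped).  Nearest-of-type distance searches the whole ROI by
default — reported nearest-macrophage distances can exceed the
neighborhood radius, and nothing in the method caps them — with an
optional `within_radius` policy.  The mean k-nearest-of-type distance
(default k = 10) is missing when fewer than k targets exist; a partial
mean over the available targets would be biased low.  Lipid metrics use
two explicit denominators: lipid⁺ macrophage neighbors over all
neighbors, and over macrophage neighbors only (missing when there are
none).

**Aggregation.**  Metrics are computed per focal cell, then summarized
by region class either per-ROI-then-pooled (each ROI weighted equally)
or pooled over cells (large ROIs dominate).  Published neighborhood
analyses rarely state the level; both are first-class and the level is
recorded in every summary.  Fold changes are ratios of group means,
always reported with both orientations; group comparisons use the
two-sided unpaired t-test, Welch variant by default because the
equal-variance assumption is rarely defensible across tissue regions,
with the pooled variant behind a flag.  P-values are nominal — no
multiple-testing correction is applied at this stage.

## Phenotyping

Rules are an ordered list of (label, conjunction of marker predicates);
evaluation is first-match-wins, which encodes hierarchical panel
definitions (macrophage rules precede T-cell rules that require CD68−).
Positivity is strict `intensity > threshold` so a zero threshold is
well-defined (intensity 0 is negative).  Thresholds are per-marker,
per-dataset inputs; the package deliberately does not learn them
(no Otsu/GMM) because gating choices belong to the analyst.

The quantile gate takes the top and bottom fractions of a marker's
empirical distribution (default use case: top/bottom 10% to call
marker-high vs marker-low populations).  With distinct values the set
sizes are exactly ⌈frac·n⌉.  Ties at a gate boundary are all included
(deterministic, no arbitrary tie-break) with a warning; fully tied data
raise an error.  The high and low sets are kept disjoint — in the odd-n
corner case where both nominal sizes cannot hold simultaneously, the low
set yields and a warning is emitted.

## Coordinates and units

Image convention: origin top-left, x rightward, y downward, 0-based.
Coordinates are converted to micrometers at ingestion by a mandatory
`pixel_size_um` factor — segmentation exports do not record the scale
and nothing is silently assumed.  All downstream math is Euclidean, so
the axis convention is immaterial beyond consistency.

## Synthetic tissue generator

The generator produces a marked Poisson point pattern with the structure
the analysis is designed to detect: circular niches inside a rectangular
field; tumor cells uniform over the field at density λ_tumor, labeled
TRPC with probability `trpc_in_niche_fraction` inside niches and TSC
otherwise; macrophages at background density λ_TAM, multiplied by the
enrichment factor ρ inside niches (realized by superposition of an
excess Poisson field for ρ > 1, by thinning for ρ < 1 — distributionally
identical to sampling each region separately).  Counts are Poisson
(area × density) so density-based expectations are exact; a fixed-count
mode exists for deterministic tests.  Lipid flags are Bernoulli with
per-(type, region) probability; marker intensities are two-component
Gaussians (positive/negative population per marker, truncated at zero)
separated enough that threshold gating recovers the generating type
while remaining non-trivial.

Defaults (chosen once as the simulated study conditions): 1500×1000 µm
field; three non-overlapping niches of radius 200 µm (~25% of the
field); λ_tumor = 0.0025/µm², λ_TAM = 0.001/µm² — about 3500 cells/mm²,
a realistic solid-tissue density, giving ≈5000–6000 cells per field;
ρ = 2.5; `trpc_in_niche_fraction` = 0.9; lipid probabilities 0.746/0.30
for tumor cells in niche/background and 0.774/0.586 for macrophages,
values reported for resistant vs sensitive glioblastoma regions, so the
simulations run in a realistic regime.

Randomness is organized as keyed substreams of one user seed (a stream
per region × cell type for positions, plus dedicated streams for type
assignment, lipid flags, and each marker), drawn in a fixed documented
order; adding a cell type or marker never perturbs earlier draws, and
identical seeds give byte-identical tables.

`expected_metrics` provides closed forms for non-overlapping niches: the
lipid⁺ fraction per (type, region) equals its configured probability;
the niche/background macrophage density ratio equals ρ; the expected
macrophage neighbor fraction deep inside a niche is
ρλ_TAM/(λ_tumor + ρλ_TAM) and analogously outside.  Because a focal cell
near a niche edge mixes the two density regimes, the pipeline applies
the same exclusion logic used at image borders to *region* borders when
recovering these expectations: focal cells within one neighborhood
radius of a region boundary are tagged ambiguous and left out of region
summaries.  This was a design decision made on geometric grounds, and it
is what makes the deep-interior closed form the right comparison target.

**What the generator does not emulate** — segmentation error, marker
spillover/bleed-through, intensity spatial gradients, cell-size
variation, anisotropic or clustered-within-niche placement, and
holes/folds in tissue.  Passing recovery tests therefore demonstrate
correctness of the quantification given a faithful cell table, not
robustness to upstream imaging artifacts.

## Profiler QC module

Signal-to-background divides each probe count by the geometric mean of
the segment's IgG negative-control counts; within a segment the IgG
probes' own ratios consequently have geomean exactly 1.  A target is
excluded when its ratio stays at or below the background band (default
1.5) in all but fewer than `min_high_segments` (default 1) segments —
the published criterion is qualitative ("hovering around background"),
so both knobs are exposed and logged rather than hard-coded.  The four
normalization factors are the housekeeping geomean, IgG geomean, and
area and nuclei passed through verbatim.  Factor concordance is the
sample SD (n−1) of log₂(a/b) across segments — 0 for proportional
factors, invariant to rescaling either one.  Normalization divides by
the factor and multiplies back by the factor's across-segment geomean so
normalized counts keep the raw-count scale (switchable); recomputing the
factor on normalized counts gives a constant, which the tests check to
1e-9 relative.  Zero counts are refused by default; an explicit
pseudocount floors them when the caller opts in.  Whether geomeans are
computed before or after probe filtering is not standardized; the
default here is before (filtering affects downstream analysis, not the
background estimate), and the filtered ratio matrix can be passed
explicitly for the other choice.

## Numerical choices

- Neighbor queries use a k-d tree; unit and acceptance tests hold every
  query to exact agreement (pair sets, counts) or 1e-12 relative
  (distances) with exhaustive O(n²) scans on random instances up to
  2000 cells.
- Boundary comparisons are inclusive throughout (≤ radius, ≥ border
  distance), giving exact analytic counts on integer grids.
- Self-exclusion in nearest-of-type queries is by cell id, querying one
  extra tree neighbor, so coincident points are handled correctly.
- Group SEMs use the n−1 sample standard deviation; a single
  contributing unit yields SEM NaN rather than 0.
- Degenerate inputs fail loudly: empty gates, all-tied intensities,
  zero-variance t-tests, non-positive counts before logs, groups smaller
  than 2.

## Problem sizes in the validation suite

The oracle-equivalence checks run ~50 random instances up to 2000 cells;
enrichment recovery uses 20 seeds per ρ ∈ {1, 2.5, 5} on ~5,000–6,000-cell
tissues (the acceptance script uses 12 seeds per ρ); lipid-fraction
recovery uses a larger two-niche field sized to yield roughly 2000 cells
per tumor type; t-test calibration uses 200 null replicates at n = 20
per group.  These sizes give binomial/SEM tolerances that the tests
state explicitly next to each assertion.

## Known limitations

- ROI geometry supports rectangles, simple polygons and circles; no
  multi-polygon or holed regions.
- The neighborhood radius is global per analysis; no per-cell-type radii.
- No spatial statistics beyond neighborhood quantification (no Ripley's
  K, permutation enrichment nulls, or graph clustering) — deliberately
  out of scope.
- The DSP module stops at QC and normalization; mixed-effects
  differential expression on profiler data is out of scope.
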