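# Methods

## Coordinates and the region universe

All coordinates are BED convention: 0-based, half-open `[start, end)`.
Per-condition peak calls are concatenated and merged; intervals merge when
they overlap or are bookended (gap 0), so universe IDs (`chrom:start-end`)
are stable under small peak jitter.  Every input peak is fully contained in
exactly one universe region, and the universe is the common row space for
counting, annotation and module labels.  Blacklist filtering operates on
fragments (a fragment overlapping a blacklisted interval by ≥ 1 bp is
removed); region-level subtraction from the universe exists behind an
explicit call (`subtract_blacklist`) but is off in the pipeline, since the
standard filter is read-level.

## Cut sites and QC

The counting currency is the Tn5 insertion point: a fragment contributes
cut sites at `start` and `end − 1`.  The `+4/−5` offset (Tn5 inserts as a
dimer, its two transposition events 9 bp apart) can be applied at ingest
for unshifted fragment files; pre-shifted input is the default assumption.
Fragments longer than `max_fragment_length` (default 1000 bp) are dropped.
FRiP is the fraction of cut sites inside any universe region — the same
currency as the count matrix, so `column sum ≤ 2 × fragments` with equality
iff FRiP = 1.

TSS enrichment aggregates cut sites over ±1000 bp around every TSS
(minus-strand profiles reversed), smooths the profile with a 51 bp moving
average normalized for window coverage at the edges, and reports the
smoothed maximum over the mean of the outermost 100 positions per side.
Smoothing is part of the definition here: the unsmoothed maximum over
~2000 Poisson-noisy positions concentrates near 1.4 for a completely flat
library, whereas the smoothed score is 1 within ±0.1 at 10⁵ sites —
matching the behaviour expected of the score as a library-quality metric.
`smooth_bp=1` recovers the raw definition.

## The differential model

Counts are negative binomial, mean/dispersion parameterisation
`Var(y) = μ + αμ²`, with

```
log μ_rs = log s_s + β₀,r + β₁,r · x_s
```

for each pairwise comparison (x indicates the second condition; the
reported `log2_fold_change` is condition B relative to A).

* **Size factors** — median-of-ratios: per-region geometric-mean reference
  over samples (rows with any zero excluded), per-sample median of
  count/reference ratios, rescaled to geometric mean 1.
* **Two-pass normalization** — median-of-ratios assumes most regions are
  null.  The emulated study has ~half the universe differential with
  asymmetric (gain-dominated) signal, which biases single-pass factors and
  inflates the union-level false discovery rate to ~0.12.  The pipeline
  therefore re-estimates factors on the apparently-null regions of a first
  pass (no comparison reaching q < 0.3) and re-runs the tests; in
  simulation this restores union FDR to ~0.06–0.07 at ~0.97 recall.  With
  an oracle normalization the FDR is ~0.03, confirming the bias was in the
  factors, not the test.
* **Dispersion** — per-region method of moments on normalized counts:
  within-condition pooled variance s² and overall mean m give
  `α = max(floor, (s² − m)/m²)`, floor 10⁻⁸.  At 4–5 replicates per arm
  this estimate carries ~6–8 degrees of freedom, so each pairwise test
  shrinks it toward the cross-region median with prior weight 10
  (`moderate_dispersion`) — a single scalar prior, not a mean-dispersion
  trend, and no fold-change shrinkage anywhere.
* **Wald test** — IRLS with working weights `μ/(1 + αμ)`, vectorised
  across regions (all regions share the design matrix, so the 2×2 normal
  equations solve in closed form per region).  The statistic `β₁/SE` is
  referenced to a t distribution with residual-plus-prior degrees of
  freedom; with a normal reference the plug-in dispersion makes the test
  anticonservative at this sample size (null p < 0.05 fraction ~0.087
  versus ~0.048 with the t reference, at 5+5 replicates and α = 0.2).
  Regions with no counts in either group, or non-convergent fits, get
  p = NA and are excluded from the BH family.
* **Multiplicity** — Benjamini–Hochberg within each pairwise comparison;
  the differential set is the union over comparisons of regions with
  q below the threshold (default 0.05).  Union-level FDR is therefore not
  controlled at the per-comparison level by construction; the two-pass
  normalization keeps it near nominal in the emulated design.

## Modules

Differential regions are summarised as per-condition means of
`log2(count/size_factor + 1)` (a variance-stabilising choice for
clustering), row-z-scored (population SD; zero-variance rows zeroed and
flagged), and clustered by k-means (k-means++ initialisation, 10 seeded
restarts, best inertia).  Labels A, B, C, … are assigned by descending
cluster size, ties broken by smallest row index, so labelling is
deterministic given the seed.  k = 4 by default, matching the four
archetypes the generator plants.

## Category enrichment

Each universe region carries at most one exhaustion-state category
(a partition, ties resolved first-wins with a warning).  For module of size
n with k labelled regions against K labelled in the N-region universe:
`FE = (k/n)/(K/N)`, p = P(X ≥ k), X ~ Hypergeom(N, K, n).  K = 0 yields an
undefined (NaN) FE with p = 1.  The background population is the full
universe by default; `background="differential"` restricts it to the
clustered regions.

## Super-enhancer calling

Regulatory domains follow the basal-plus-extension rule: basal = 5 kb
upstream / 1 kb downstream of the TSS (strand-aware); each side extends to
the nearer of the 1 Mb cap and the closest *other* gene's basal boundary
(searched over all basals, not just TSS-neighbours — strand mixtures can
reorder basal intervals relative to TSS order).  Extension never shrinks
the basal domain; intergenic territory is generally shared by the two
flanking genes' extended domains, and a region (by midpoint containment)
counts for every domain containing it.

Genes with ≥ 1 assigned differential region are ranked by count
(descending, ties by gene ID), the curve scaled to the unit square
(`x = (rank−1)/(n−1)`, `y = count/max`), and the elbow taken as the point
of maximum perpendicular distance from the chord joining the endpoints
(ties → smallest index; a collinear curve is flagged and yields an empty
SE set).  SE-associated genes are those with strictly more regions than
the elbow gene.  Direction-specific analyses filter the differential set
by the sign of the fold change in a chosen comparison before assignment.

## The synthetic-data generator

The generator emulates a four-arm study — naive, baseline, one-year
treated, one-year untreated, 4 replicates per arm by default — on a toy
genome (2 × 10 Mb, 200 genes at ≥ 30 kb spacing, ~2,000 regions of
250–750 bp on a jittered grid, hence non-overlapping by construction).
Four module archetypes define signed log2 offsets across the arms, in
units of the effect size (default 2.0):

| module | naive | baseline | ART 1 yr | untreated 1 yr |
|--------|-------|----------|----------|----------------|
| A      | +1    | 0        | 0        | 0              |
| B      | 0     | +1       | 0        | +1             |
| C      | 0     | 0        | +1       | 0              |
| D      | 0     | +1       | +0.75    | +1             |

Module D's partial retention on therapy is set to 0.75: at 0.5 the planted
B–D separation after row normalization (≈ 0.87 z-units against ≈ 0.33
per-entry noise at 4 replicates, depth 50, α = 0.2) gives ~9%
Bayes-optimal confusion, making near-perfect recovery impossible for any
clusterer; 0.75 yields ≈ 1.4 z-units and ~2% irreducible confusion,
the separability the planted-recovery design requires.

Counts are NB with `mean = depth · baseline_r · 2^offset · mult_s`
(log-normal per-region baselines, sd 0.5; log-normal per-sample depth
multipliers, sd 0.3; Poisson when α = 0) — the same parameterisation the
test fits.  Fragments realise the same means: a `frip_target` fraction
(default 0.6) of each library falls entirely inside regions (region chosen
multinomially with per-sample gamma noise so implied counts are
over-dispersed), the rest entirely inside inter-region gaps; lengths follow
a sub-nucleosomal/mono-nucleosomal mixture capped at 1 kb.  Per-condition
peak files contain each region wherever its module is accessible (plus all
background regions), so the rebuilt universe reproduces the truth exactly.

Category planting targets the *measured* quantity: the module-B
late-exhaustion rate is set to `factor × universe rate` (default 3 × 0.10)
and the off-module rate absorbs the remainder, so the universe-background
fold enrichment is centred on the planted factor.  SE planting packs
`se_regions_per_gene` (default 30) small module-B regions inside each
chosen gene's basal domain — the only territory exclusive to that gene
under the extension rule; planting in shared intergenic space would
systematically inflate flanking genes.  The chord elbow separates planted
genes cleanly only when background per-gene counts are sparse (~0–3), so
the SE recovery study uses a direction-sparse configuration (module
proportions B = 0.02, C = 0.10 over 1,500 regions); the default dense
configuration is appropriate for the module/enrichment analyses.

A single master seed fixes every file byte-for-byte; truth (regions,
module labels, per-condition offsets, categories, SE genes, parameters)
serialises losslessly to JSON alongside each dataset.

### What the generator does not model

Nucleosome periodicity, GC and mappability bias, duplicate structure,
chromosome-scale covariance, subject-level pairing (subject IDs are
carried but not modelled in the design matrix), and real orthology
mapping (the category annotation is consumed as a given table).  Passing
tests certify the statistical machinery under the stated NB model, not
robustness to those real-data artefacts.

## Problem sizes and numerical choices

Simulation-based checks use 2,000 regions with 5+5 samples for
calibration, the default ~2,150-region four-arm study for module and
enrichment recovery, ten 1,500-region studies for SE recovery, and a
600-region study for the byte-level determinism check; each completes in
seconds on one CPU.  IRLS runs at most 100 iterations to tolerance 10⁻¹⁰
with the linear predictor clipped at ±50; k-means label ordering and all
seeds are explicit; BH is NaN-aware (NA excluded before m is set).
Degenerate inputs fail loudly: empty universes, empty clusters, curves
with fewer than three nonzero genes, zero TSS-flank background, and
fragment files missing for a declared sample are all named errors.

## Known limitations

The Wald t reference and scalar dispersion prior are calibrated for the
4–5-replicate regime the study design uses; very large designs would do as
well with the plain normal reference.  The union of per-comparison BH sets
does not control union-level FDR by construction (measured ~0.06–0.07
under the emulated design with two-pass normalization).  Elbow calling is
geometric, not inferential: it reports no uncertainty, and with a heavy
background tail it deliberately sits at the corner of the curve rather
than at any fixed quantile.
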