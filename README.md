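# charmod

Differential chromatin-accessibility analysis for ATAC-seq of sorted T-cell
populations: peak-universe construction, Tn5 cut-site counting and QC,
pairwise negative-binomial differential testing with accessibility-module
clustering, exhaustion-category enrichment, and super-enhancer-associated
gene calling.

## The problem

ATAC-seq on antigen-specific CD8 T cells sampled across disease and
treatment states (naive cells, cells at baseline during primary infection,
after a year of antiretroviral therapy, and after a year untreated) asks a
simple question of a large matrix: which open-chromatin regions change, in
which direction, and what do the coordinated changes mean?  `charmod`
implements the downstream analysis as a tested, reusable pipeline:

1. **Universe** — per-condition peak calls (narrowPeak/BED) are unioned and
   merged into a stable set of chromatin accessible regions (ChARs), the
   common row space for everything downstream.
2. **Counting & QC** — fragments are reduced to their two Tn5 insertion
   points (cut sites at `start` and `end − 1`; optional `+4/−5` shift at
   ingest); cut sites are counted per region per sample, and libraries are
   scored by FRiP and TSS enrichment.
3. **Differential testing** — counts are modelled as negative binomial,
   `Var(y) = μ + αμ²`, with median-of-ratios size factors,
   method-of-moments dispersion moderated toward the cross-region median,
   and a Wald test on the condition coefficient for every pair of
   conditions (`log μ_rs = log s_s + x_sᵀ β_r`).  Regions with
   Benjamini–Hochberg q < 0.05 in at least one comparison form the
   differential set.
4. **Modules** — per-condition means of `log2(normalized + 1)` are
   row-z-scored and k-means clustered (k = 4, labels A–D by descending
   size) into accessibility modules.
5. **Enrichment** — each module is scored for over-representation of
   murine exhaustion-state orthologs (naive / effector / memory / early /
   late exhaustion): fold enrichment `FE = (k/n)/(K/N)` with an upper-tail
   hypergeometric p-value.
6. **Super-enhancers** — differential regions are assigned to genes via
   basal-plus-extension regulatory domains (5 kb up / 1 kb down, extension
   to the neighbour's basal boundary, ≤ 1 Mb), genes ranked by region
   count, the curve unit-scaled, the elbow found as the maximum
   perpendicular distance from the endpoint chord, and genes strictly above
   the elbow count called SE-associated.

A fully deterministic synthetic-data generator (`charmod.simulate`) emulates
the four-arm study with planted modules, category enrichments and SE genes,
so every stage is testable end-to-end without any external data.

## Worked example

```python
from charmod import (SimulationParams, simulate_dataset, differential_analysis,
                     select_differential_union, condition_mean_rows,
                     row_normalize, kmeans_modules, enrichment_table,
                     CategoryAnnotation)

conds = ("naive", "baseline", "art_1yr", "untreated_1yr")
ds = simulate_dataset(SimulationParams(), seed=1)
pairwise, size_factors = differential_analysis(ds["counts"], ds["samples"],
                                               conditions=conds)
union = select_differential_union(pairwise, fdr_threshold=0.05)
print(f"differential regions: {len(union)} of {len(ds['universe'])}")

means = condition_mean_rows(ds["counts"], size_factors, ds["samples"],
                            union, conditions=conds)
normed, _ = row_normalize(means)
modules = kmeans_modules(normed, k=4, seed=0)
print(modules.cluster_sizes.to_string())
```

prints

```
differential regions: 1100 of 2025
module
A    499
B    238
C    201
D    162
```

— 1,100 of 2,025 regions are differential in at least one of the six
pairwise comparisons (the generator plants ~52%), split into four modules.
Scoring each module against the planted exhaustion-category annotation:

```python
truth = ds["truth"]
annotation = CategoryAnnotation(
    labels={r: c for r, c in zip(truth.region_ids(), truth.categories)
            if c != "none"},
    universe_size=len(truth.regions))
table = enrichment_table(modules, annotation)
print(table[table.category == "late_exhaustion"]
      [["cluster_label", "k", "n", "fold_enrichment", "p_value"]]
      .round(3).to_string(index=False))
```

```
cluster_label   k   n  fold_enrichment  p_value
            A 153 499            2.835    0.000
            B   8 238            0.311    1.000
            C  11 201            0.506    0.998
            D   8 162            0.457    0.998
```

Cluster A (the largest, corresponding to the planted
baseline/untreated-high module) carries late-exhaustion orthologs at 2.8×
the universe rate — the generator planted 3× — while the other modules are
depleted.

## Command line

```bash
charmod simulate --seed 1 --out data/          # synthetic study + truth.json
charmod run --data data/ --out results/        # all stages + manifest
charmod universe --peaks a.narrowPeak --peaks b.narrowPeak --out universe.bed
charmod count --universe universe.bed --fragments frags/ --samples samples.tsv --out counts.tsv
charmod qc | diff | modules | enrich | se | track ...
```

Every stage writes plain text (BED/TSV/JSON); `run` records a manifest with
config, input checksums, seed and per-stage timing, and reruns are
byte-identical.

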