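"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the four-arm study design — naive CD8 T cells,
antigen-specific cells at baseline (primary infection), after one year of
antiretroviral therapy, and after one year untreated — with 4-5 biological
replicates per arm.  It writes the same plain-text formats the analysis
consumes (per-condition narrowPeak, per-sample BED3 fragments, gene and
annotation TSVs) plus a truth record, so every downstream statistic can be
checked against what was planted.

Planted structure mirrors the four accessibility-module archetypes:

* module A  — most accessible in naive cells;
* module B  — accessible at baseline and in untreated infection, closed on
  therapy;
* module C  — opens after one year of therapy;
* module D  — accessible at baseline and untreated, and partially retained
  on therapy.

Counts follow a negative binomial with variance ``mu + alpha * mu**2`` —
the same mean/dispersion parameterisation the differential engine fits.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_CONDITIONS
from .counting import FragmentRecord, SampleTable
from .intervals import GenomicInterval, PeakSet, PeakUniverse
from .superenhancer import GeneModel, build_domains

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "make_genome_and_genes",
    "make_universe_and_modules",
    "plant_categories_and_se",
    "simulate_counts",
    "simulate_fragments",
    "simulate_dataset",
    "write_dataset",
]

#: log2 accessibility offsets per module across the four conditions
#: (naive, baseline, art_1yr, untreated_1yr), as multiples of the effect size.
MODULE_TEMPLATES = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "B": (0.0, 1.0, 0.0, 1.0),
    "C": (0.0, 0.0, 1.0, 0.0),
    "D": (0.0, 1.0, 0.75, 1.0),
    "background": (0.0, 0.0, 0.0, 0.0),
}


@dataclass
class SimulationParams:
    """Generator settings; defaults are the study conditions emulated.

    4 conditions x 4 replicates, a ~2,000-region universe on a small
    synthetic genome, moderate sequencing depth (mean 50 cut sites per
    accessible region), biological dispersion 0.2, and a 2.0 log2 effect
    size for planted differential regions.
    """

    n_chrom: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 200
    gene_min_spacing: int = 30_000
    n_regions: int = 2000
    region_min_width: int = 250
    region_max_width: int = 750
    module_proportions: dict = field(
        default_factory=lambda: {"A": 0.10, "B": 0.20, "C": 0.10, "D": 0.10}
    )
    n_per_condition: int = 4
    depth: float = 50.0
    alpha: float = 0.2
    lfc: float = 2.0
    baseline_sd: float = 0.5  # log-normal sd of per-region baseline
    size_factor_sd: float = 0.3  # log-normal sd of per-sample multipliers
    frip_target: float = 0.6
    n_fragments: int = 50_000
    category_rate: float = 0.10  # universe-wide late_exhaustion rate
    enrichment_factor: float = 3.0  # planted module-B enrichment
    other_category_rate: float = 0.05  # per remaining category, off-module
    se_gene_count: int = 5
    se_regions_per_gene: int = 30
    se_region_width: int = 120
    great_basal_up: int = 5000
    great_basal_down: int = 1000
    conditions: tuple = DEFAULT_CONDITIONS


@dataclass
class SyntheticTruth:
    """Everything that was planted, for checking pipeline output against."""

    params: SimulationParams
    seed: int
    chrom_sizes: dict
    genes: list  # (gene_id, chrom, tss, strand)
    regions: list  # (chrom, start, end)
    module_labels: list  # per region: A/B/C/D/background
    lfc_matrix: list  # per region: signed log2 offsets per condition
    categories: list  # per region: category or none
    se_genes: list

    def region_ids(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in self.regions]

    def to_json(self) -> str:
        d = asdict(self)
        d["params"]["conditions"] = list(d["params"]["conditions"])
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["params"]["conditions"] = tuple(d["params"]["conditions"])
        d["params"] = SimulationParams(**d["params"])
        d["genes"] = [tuple(g) for g in d["genes"]]
        d["regions"] = [tuple(r) for r in d["regions"]]
        d["lfc_matrix"] = [tuple(r) for r in d["lfc_matrix"]]
        return cls(**d)


def make_genome_and_genes(
    n_chrom: int,
    chrom_length: int,
    n_genes: int,
    min_spacing: int,
    seed: int,
) -> tuple[dict[str, int], list[GeneModel]]:
    """A toy genome with uniformly spaced genes of random strand.

    Gene TSSs are laid out per chromosome on a jittered regular grid so that
    every pair respects ``min_spacing``.
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_length for i in range(n_chrom)}
    genes: list[GeneModel] = []
    if n_genes == 0:
        return chrom_sizes, genes
    per_chrom = -(-n_genes // n_chrom)
    usable = chrom_length - 2 * min_spacing
    if usable <= 0 or usable / per_chrom < min_spacing:
        raise ValueError(
            f"{n_genes} genes with spacing {min_spacing} do not fit "
            f"{n_chrom} x {chrom_length} bp"
        )
    gene_idx = 0
    for chrom in chrom_sizes:
        slot = usable // per_chrom
        jitter_max = max(1, (slot - min_spacing) // 2)
        for j in range(per_chrom):
            if gene_idx >= n_genes:
                break
            tss = (
                min_spacing
                + j * slot
                + slot // 2
                + int(rng.integers(-jitter_max, jitter_max + 1))
            )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{gene_idx:04d}", chrom, tss, strand))
            gene_idx += 1
    return chrom_sizes, genes


def make_universe_and_modules(
    chrom_sizes: dict[str, int],
    n_regions: int,
    module_proportions: dict[str, float],
    min_width: int,
    max_width: int,
    seed: int,
    exclude: list[GenomicInterval] | None = None,
) -> tuple[list[GenomicInterval], list[str]]:
    """Non-overlapping accessible regions with module labels.

    Regions sit on a jittered grid (one per slot, so non-overlap holds by
    construction); slots intersecting ``exclude`` windows are skipped, which
    reserves space for explicitly planted regions.  Labels are drawn i.i.d.
    from the module proportions, remainder going to non-differential
    background.
    """
    rng = np.random.default_rng(seed)
    total = sum(module_proportions.values())
    if total > 1.0 + 1e-9:
        raise ValueError("module proportions must sum to <= 1")
    genome = sum(chrom_sizes.values())
    slot = genome // n_regions
    if slot < max_width + 2:
        raise ValueError("n_regions too large for genome: slots too narrow")
    regions: list[GenomicInterval] = []
    for chrom, length in chrom_sizes.items():
        n_slots = int(round(n_regions * length / genome))
        chrom_slot = length // max(n_slots, 1)
        for j in range(n_slots):
            width = int(rng.integers(min_width, max_width + 1))
            lo = j * chrom_slot + 1
            hi = min((j + 1) * chrom_slot, length) - width - 1
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            iv = GenomicInterval(chrom, start, start + width)
            if exclude and any(iv.overlaps(e) for e in exclude):
                continue
            regions.append(iv)
    labels_pool = list(module_proportions) + ["background"]
    probs = list(module_proportions.values()) + [1.0 - total]
    labels = [
        labels_pool[i]
        for i in rng.choice(len(labels_pool), size=len(regions), p=probs)
    ]
    return regions, labels


def plant_categories_and_se(
    regions: list[GenomicInterval],
    labels: list[str],
    genes: list[GeneModel],
    params: SimulationParams,
    seed: int,
) -> tuple[list[GenomicInterval], list[str], list[str], list[str]]:
    """Plant category enrichment in module B and SE gene region clusters.

    Category planting: module-B regions carry "late_exhaustion" at a rate
    chosen so the module's rate is ``enrichment_factor`` times the
    universe-wide rate (``category_rate``); the off-module rate absorbs the
    remainder.  Remaining categories are sprinkled uniformly off-module at
    ``other_category_rate`` each.

    SE planting: ``se_gene_count`` genes receive ``se_regions_per_gene``
    extra module-B regions packed inside their basal regulatory domain
    (exclusive to the gene under the basal-plus-extension rule), roughly ten
    times the largest background per-gene region count at default settings.

    Returns the augmented (regions, labels, categories, se_gene_ids).
    """
    rng = np.random.default_rng(seed)
    if params.enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")

    # --- SE clusters first (they add module-B regions) -------------------
    se_genes: list[str] = []
    new_regions = list(regions)
    new_labels = list(labels)
    if params.se_gene_count > 0:
        if params.se_gene_count > len(genes):
            raise ValueError("more SE genes requested than genes available")
        pick = rng.choice(len(genes), size=params.se_gene_count, replace=False)
        domains = {
            d.gene_id: d
            for d in build_domains(
                genes, params.great_basal_up, params.great_basal_down
            )
        }
        gap = 20
        step = params.se_region_width + gap
        for gi in sorted(pick):
            gene = genes[gi]
            basal = domains[gene.gene_id].basal
            capacity = (len(basal) - gap) // step
            if capacity < params.se_regions_per_gene:
                raise ValueError(
                    f"basal domain of {gene.gene_id} fits only {capacity} "
                    f"planted regions < {params.se_regions_per_gene}"
                )
            for j in range(params.se_regions_per_gene):
                start = basal.start + gap + j * step
                new_regions.append(
                    GenomicInterval(
                        gene.chrom, start, start + params.se_region_width
                    )
                )
                new_labels.append("B")
            se_genes.append(gene.gene_id)

    # --- category labels --------------------------------------------------
    n = len(new_regions)
    is_b = np.array([lab == "B" for lab in new_labels])
    n_b = int(is_b.sum())
    p_bar = params.category_rate
    q_module = params.enrichment_factor * p_bar
    if q_module > 1:
        raise ValueError(
            f"infeasible enrichment: factor x rate = {q_module:.2f} > 1; "
            f"feasible factor <= {1 / p_bar:.2f}"
        )
    if n_b < n:
        p_other = (p_bar * n - q_module * n_b) / (n - n_b)
    else:
        p_other = 0.0
    if p_other < 0:
        raise ValueError(
            "infeasible enrichment: module too large for requested factor; "
            f"feasible factor <= {n / max(n_b, 1):.2f}"
        )
    categories = ["none"] * n
    u = rng.random(n)
    other_cats = ["naive", "effector", "memory", "early_exhaustion"]
    for i in range(n):
        p_late = q_module if is_b[i] else p_other
        if u[i] < p_late:
            categories[i] = "late_exhaustion"
        else:
            # remaining categories, planted without module preference
            v = rng.random()
            cum = 0.0
            for cat in other_cats:
                cum += params.other_category_rate
                if v < cum:
                    categories[i] = cat
                    break
    return new_regions, new_labels, categories, se_genes


def _lfc_matrix(labels: list[str], lfc: float) -> np.ndarray:
    return np.array(
        [[t * lfc for t in MODULE_TEMPLATES[lab]] for lab in labels]
    )


def simulate_counts(
    truth: SyntheticTruth,
    seed: int,
) -> tuple[pd.DataFrame, SampleTable]:
    """Negative-binomial cut-site counts under the planted truth.

    mean(r, s) = depth * baseline_r * 2**lfc(r, condition(s)) * mult_s with
    log-normal per-region baselines and per-sample size multipliers; counts
    are NB with the truth's dispersion (Poisson when alpha = 0).
    """
    p = truth.params
    rng = np.random.default_rng(seed)
    n_regions = len(truth.regions)
    conditions = list(p.conditions)
    sample_rows = []
    for c, condition in enumerate(conditions):
        for rep in range(p.n_per_condition):
            sample_rows.append(
                {
                    "sample_id": f"{condition}_rep{rep + 1}",
                    "condition": condition,
                    "subject_id": f"subj_{condition[:3]}{rep + 1}",
                }
            )
    samples = SampleTable(pd.DataFrame(sample_rows))
    baseline = np.exp(rng.normal(0.0, p.baseline_sd, size=n_regions))
    mult = np.exp(rng.normal(0.0, p.size_factor_sd, size=len(sample_rows)))
    lfc = np.array(truth.lfc_matrix)
    cond_index = np.array(
        [conditions.index(r["condition"]) for r in sample_rows]
    )
    mu = (
        p.depth
        * baseline[:, None]
        * np.power(2.0, lfc[:, cond_index])
        * mult[None, :]
    )
    if p.alpha < 1e-6:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / p.alpha
        counts = rng.negative_binomial(shape, shape / (shape + mu))
    return (
        pd.DataFrame(
            counts, index=truth.region_ids(), columns=samples.sample_ids
        ),
        samples,
    )


def _fragment_lengths(rng: np.random.Generator, size: int, cap: int) -> np.ndarray:
    """Sub-nucleosomal / mono-nucleosomal length mixture, capped."""
    short = rng.normal(80.0, 20.0, size=size)
    mono = rng.normal(200.0, 30.0, size=size)
    pick = rng.random(size) < 0.65
    lengths = np.where(pick, short, mono)
    return np.clip(np.round(lengths), 30, cap).astype(np.int64)


def simulate_fragments(
    truth: SyntheticTruth,
    sample_table: SampleTable,
    seed: int,
) -> dict[str, list[FragmentRecord]]:
    """Per-sample fragment lists realising the planted accessibility.

    A ``frip_target`` fraction of each library's fragments falls entirely
    inside universe regions — chosen per region in proportion to that
    sample's condition-specific accessibility, with per-sample gamma noise
    so the implied counts are over-dispersed — and the remainder entirely
    inside inter-region background.
    """
    p = truth.params
    rng = np.random.default_rng(seed)
    if not (0 < p.frip_target < 1):
        raise ValueError("frip_target must lie in (0, 1)")
    regions = [GenomicInterval(c, s, e) for c, s, e in truth.regions]
    lfc = np.array(truth.lfc_matrix)
    conditions = list(p.conditions)
    baseline = np.exp(rng.normal(0.0, p.baseline_sd, size=len(regions)))

    # background gaps per chromosome (space between consecutive regions)
    gaps: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in sorted(regions, key=lambda r: (r.chrom, r.start)):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, length in truth.chrom_sizes.items():
        prev = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start - prev > 2000:
                gaps.append((chrom, prev + 1, iv.start - 1))
            prev = iv.end
        if length - prev > 2000:
            gaps.append((chrom, prev + 1, length - 1))
    gap_lengths = np.array([g[2] - g[1] for g in gaps], dtype=np.float64)
    gap_probs = gap_lengths / gap_lengths.sum()

    out: dict[str, list[FragmentRecord]] = {}
    for _, row in sample_table.df.iterrows():
        c = conditions.index(row["condition"])
        weights = baseline * np.power(2.0, lfc[:, c])
        if p.alpha >= 1e-6:
            weights = weights * rng.gamma(
                1.0 / p.alpha, p.alpha, size=len(regions)
            )
        weights = weights / weights.sum()
        n_in = int(rng.binomial(p.n_fragments, p.frip_target))
        n_bg = p.n_fragments - n_in
        frags: list[FragmentRecord] = []
        # in-peak fragments, fully inside their region
        region_idx = rng.choice(len(regions), size=n_in, p=weights)
        lengths = _fragment_lengths(rng, n_in, 1000)
        for ri, length in zip(region_idx, lengths):
            iv = regions[ri]
            length = min(int(length), len(iv))
            start = int(rng.integers(iv.start, iv.end - length + 1))
            frags.append(FragmentRecord(iv.chrom, start, start + length))
        # background fragments, fully inside a gap
        gap_idx = rng.choice(len(gaps), size=n_bg, p=gap_probs)
        lengths = _fragment_lengths(rng, n_bg, 1000)
        for gi, length in zip(gap_idx, lengths):
            chrom, g_start, g_end = gaps[gi]
            length = min(int(length), g_end - g_start - 1)
            start = int(rng.integers(g_start, g_end - length))
            frags.append(FragmentRecord(chrom, start, start + length))
        out[row["sample_id"]] = frags
    return out


def simulate_dataset(
    params: SimulationParams | None = None,
    seed: int = 0,
    with_fragments: bool = False,
) -> dict:
    """Generate a complete dataset with planted truth.

    Returns a dict with keys ``truth``, ``counts``, ``samples``,
    ``universe``, ``genes``, ``peaksets`` and (optionally) ``fragments``.
    Derived seeds are drawn from one master ``seed`` so the whole dataset is
    reproducible from a single integer.
    """
    p = params or SimulationParams()
    master = np.random.default_rng(seed)
    sub = [int(s) for s in master.integers(0, 2**31 - 1, size=8)]
    chrom_sizes, genes = make_genome_and_genes(
        p.n_chrom, p.chrom_length, p.n_genes, p.gene_min_spacing, sub[0]
    )
    # reserve basal windows of future SE genes before placing grid regions
    exclude: list[GenomicInterval] = []
    if p.se_gene_count > 0 and genes:
        domains = build_domains(genes, p.great_basal_up, p.great_basal_down)
        exclude = [d.basal for d in domains]
    regions, labels = make_universe_and_modules(
        chrom_sizes,
        p.n_regions,
        p.module_proportions,
        p.region_min_width,
        p.region_max_width,
        sub[1],
        exclude=exclude,
    )
    regions, labels, categories, se_genes = plant_categories_and_se(
        regions, labels, genes, p, sub[2]
    )
    order = sorted(range(len(regions)), key=lambda i: (regions[i].chrom, regions[i].start))
    regions = [regions[i] for i in order]
    labels = [labels[i] for i in order]
    categories = [categories[i] for i in order]
    truth = SyntheticTruth(
        params=p,
        seed=seed,
        chrom_sizes=chrom_sizes,
        genes=[(g.gene_id, g.chrom, g.tss, g.strand) for g in genes],
        regions=[(r.chrom, r.start, r.end) for r in regions],
        module_labels=labels,
        lfc_matrix=_lfc_matrix(labels, p.lfc).tolist(),
        categories=categories,
        se_genes=se_genes,
    )
    counts, samples = simulate_counts(truth, sub[3])
    universe = PeakUniverse(regions)
    # per-condition peak sets: a module's regions appear as peaks wherever
    # the module is accessible; background regions appear in every condition
    peaksets = []
    lfc = np.array(truth.lfc_matrix)
    for c, condition in enumerate(p.conditions):
        ivs = [
            regions[i]
            for i in range(len(regions))
            if labels[i] == "background" or lfc[i, c] > 0
        ]
        peaksets.append(PeakSet(condition_label=condition, intervals=ivs))
    out = {
        "truth": truth,
        "counts": counts,
        "samples": samples,
        "universe": universe,
        "genes": genes,
        "peaksets": peaksets,
    }
    if with_fragments:
        out["fragments"] = simulate_fragments(truth, samples, sub[4])
    return out


def write_dataset(dataset: dict, outdir: str, gzip_fragments: bool = False) -> None:
    """Write a simulated dataset in the formats the pipeline reads.

    genome.tsv, genes.tsv, samples.tsv, per-condition ``peaks_<cond>.narrowPeak``,
    per-sample ``fragments_<sample>.bed[.gz]``, annotation.tsv, truth.json,
    counts.tsv.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth: SyntheticTruth = dataset["truth"]
    with open(out / "genome.tsv", "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in truth.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    pd.DataFrame(
        truth.genes, columns=["gene_id", "chrom", "tss", "strand"]
    ).to_csv(out / "genes.tsv", sep="\t", index=False)
    dataset["samples"].df.to_csv(out / "samples.tsv", sep="\t", index=False)
    for ps in dataset["peaksets"]:
        path = out / f"peaks_{ps.condition_label}.narrowPeak"
        with open(path, "w") as fh:
            for i, iv in enumerate(ps.intervals):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i}\t0\t.\t"
                    f"0.0\t-1\t-1\t{len(iv) // 2}\n"
                )
    with open(out / "annotation.tsv", "w") as fh:
        for (chrom, start, end), cat in zip(truth.regions, truth.categories):
            fh.write(f"{chrom}\t{start}\t{end}\t{cat}\n")
    if "fragments" in dataset:
        for sample_id, frags in dataset["fragments"].items():
            suffix = ".bed.gz" if gzip_fragments else ".bed"
            path = out / f"fragments_{sample_id}{suffix}"
            opener = gzip.open if gzip_fragments else open
            with opener(path, "wt") as fh:
                for frag in frags:
                    fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\n")
    dataset["counts"].rename_axis("region_id").to_csv(
        out / "counts.tsv", sep="\t"
    )
    (out / "truth.json").write_text(truth.to_json())
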