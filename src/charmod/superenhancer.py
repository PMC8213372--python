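"""Super-enhancer-associated gene calling from differential region counts.

Differential regions are assigned to genes through basal-plus-extension
regulatory domains (basal window 5 kb upstream / 1 kb downstream of the TSS,
strand-aware; extension toward each neighbour's basal boundary up to 1 Mb).
Genes are ranked by the number of assigned regions, the ranked curve is
scaled to the unit square, and the elbow is the point of maximum
perpendicular distance from the chord joining the curve's endpoints.  Genes
with strictly more regions than the elbow gene are called SE-associated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import FragmentRecord, cutsite_arrays
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "read_genes",
    "RegulatoryDomain",
    "build_domains",
    "assign_regions",
    "rank_and_scale",
    "find_elbow",
    "call_se_genes",
    "ElbowResult",
    "se_analysis",
    "locus_track",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene, reduced to its canonical TSS."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")


def read_genes(path: str) -> list[GeneModel]:
    """Read a gene TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene_ids (one TSS per gene)")
    return [
        GeneModel(r.gene_id, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples(index=False)
    ]


@dataclass
class RegulatoryDomain:
    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval


def build_domains(
    genes: list[GeneModel],
    basal_up: int = 5000,
    basal_down: int = 1000,
    extension_max: int = 1_000_000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains.

    The basal domain spans ``basal_up`` bp upstream and ``basal_down`` bp
    downstream of the TSS (strand-aware).  Each side then extends to the
    nearer of the extension cap and the adjacent gene's basal boundary;
    extension can never shrink the basal domain.  Coordinates clip at 0 and,
    if ``chrom_sizes`` is given, at the chromosome end.
    """
    domains: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, chrom_genes in by_chrom.items():
        chrom_genes = sorted(chrom_genes, key=lambda g: g.tss)
        chrom_end = chrom_sizes.get(chrom) if chrom_sizes else None
        basals = []
        for g in chrom_genes:
            if g.strand == "+":
                b_start, b_end = g.tss - basal_up, g.tss + basal_down
            else:
                b_start, b_end = g.tss - basal_down, g.tss + basal_up
            b_start = max(0, b_start)
            if chrom_end is not None:
                b_end = min(b_end, chrom_end)
            basals.append((b_start, b_end))
        all_starts = np.sort(np.array([b[0] for b in basals], dtype=np.int64))
        all_ends = np.sort(np.array([b[1] for b in basals], dtype=np.int64))
        for i, g in enumerate(chrom_genes):
            b_start, b_end = basals[i]
            # nearest other-gene basal boundary on each side; strand mixes
            # can reorder basals relative to TSS order, so search all basals
            j = int(np.searchsorted(all_ends, b_start, side="right")) - 1
            left_limit = int(all_ends[j]) if j >= 0 else 0
            j = int(np.searchsorted(all_starts, b_end, side="left"))
            right_limit = (
                int(all_starts[j])
                if j < len(all_starts)
                else (chrom_end if chrom_end is not None else b_end + extension_max)
            )
            e_start = min(b_start, max(left_limit, b_start - extension_max, 0))
            e_end = max(b_end, min(right_limit, b_end + extension_max))
            if chrom_end is not None:
                e_end = min(max(e_end, b_end), chrom_end)
            domains.append(
                RegulatoryDomain(
                    g.gene_id,
                    GenomicInterval(chrom, b_start, b_end, name=g.gene_id),
                    GenomicInterval(chrom, e_start, e_end, name=g.gene_id),
                )
            )
    return domains


def assign_regions(
    regions: list[GenomicInterval],
    domains: list[RegulatoryDomain],
) -> pd.Series:
    """Differential regions per gene, by midpoint containment.

    A region is assigned to every gene whose extended domain contains the
    region midpoint (multi-assignment allowed).  Zero-count genes are kept.
    """
    counts = {d.gene_id: 0 for d in domains}
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.extended.chrom, []).append(d)
    for region in regions:
        mid = region.midpoint
        for d in by_chrom.get(region.chrom, ()):
            if d.extended.start <= mid < d.extended.end:
                counts[d.gene_id] += 1
    return pd.Series(counts, name="n_regions").rename_axis("gene_id")


def rank_and_scale(counts: pd.Series) -> pd.DataFrame:
    """Rank nonzero genes by descending count and scale the curve to [0,1].

    Ties in count break by gene_id lexicographically.  x = (rank-1)/(n-1),
    y = count / max_count.  Genes with zero regions are dropped before
    ranking (the curve starts above zero by construction).
    """
    nonzero = counts[counts > 0]
    if len(nonzero) < 3:
        raise ValueError(
            f"only {len(nonzero)} genes with >= 1 region: "
            "curve too short for elbow detection"
        )
    df = nonzero.rename("n_regions").rename_axis("gene_id").reset_index()
    df = df.sort_values(
        ["n_regions", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    n = len(df)
    df["rank"] = np.arange(1, n + 1)
    df["scaled_x"] = (df["rank"] - 1) / (n - 1)
    df["scaled_y"] = df["n_regions"] / df["n_regions"].max()
    return df


def find_elbow(scaled_x: np.ndarray, scaled_y: np.ndarray) -> tuple[int, bool]:
    """Chord-distance elbow: index of maximum perpendicular distance.

    The chord joins the first and last scaled points; the elbow is the point
    farthest from it (ties -> smallest index).  A collinear curve (maximum
    distance 0) is flagged; by convention the elbow is then index 0 and the
    SE set is empty.  Returns (elbow_index, collinear_flag).
    """
    x = np.asarray(scaled_x, dtype=np.float64)
    y = np.asarray(scaled_y, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need >= 3 points for elbow detection")
    if np.any(np.diff(y) > 1e-12):
        raise ValueError("scaled y must be non-increasing")
    x0, y0 = x[0], y[0]
    x1, y1 = x[-1], y[-1]
    # distance from (x,y) to the line through (x0,y0)-(x1,y1)
    norm = np.hypot(x1 - x0, y1 - y0)
    dist = np.abs((x1 - x0) * (y0 - y) - (x0 - x) * (y1 - y0)) / norm
    if dist.max() <= 1e-12:
        return 0, True
    return int(np.argmax(dist)), False


def call_se_genes(ranked: pd.DataFrame, elbow_index: int) -> list[str]:
    """Genes with strictly more regions than the gene at the elbow."""
    elbow_count = ranked["n_regions"].iloc[elbow_index]
    mask = ranked["n_regions"] > elbow_count
    return ranked.loc[mask, "gene_id"].tolist()


@dataclass
class ElbowResult:
    """Ranked/scaled curve with the detected elbow and SE gene calls."""

    ranked: pd.DataFrame  # gene_id, n_regions, rank, scaled_x, scaled_y
    elbow_index: int
    elbow_count: int
    collinear: bool
    se_genes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.ranked.copy()
        out["is_se"] = out["gene_id"].isin(set(self.se_genes))
        return out


def se_analysis(
    regions: list[GenomicInterval],
    genes: list[GeneModel],
    basal_up: int = 5000,
    basal_down: int = 1000,
    extension_max: int = 1_000_000,
    chrom_sizes: dict[str, int] | None = None,
) -> ElbowResult:
    """End-to-end SE calling: domains -> assignment -> rank -> elbow -> calls."""
    domains = build_domains(
        genes, basal_up, basal_down, extension_max, chrom_sizes
    )
    counts = assign_regions(regions, domains)
    ranked = rank_and_scale(counts)
    elbow_index, collinear = find_elbow(
        ranked["scaled_x"].to_numpy(), ranked["scaled_y"].to_numpy()
    )
    if collinear:
        logger.warning("ranked curve is collinear; no SE genes called")
        se_genes: list[str] = []
    else:
        se_genes = call_se_genes(ranked, elbow_index)
    return ElbowResult(
        ranked=ranked,
        elbow_index=elbow_index,
        elbow_count=int(ranked["n_regions"].iloc[elbow_index]),
        collinear=collinear,
        se_genes=se_genes,
    )


def locus_track(
    fragments: list[FragmentRecord],
    view: GenomicInterval,
    bin_width: int = 1,
) -> pd.DataFrame:
    """Binned cut-site pileup over a genomic view, bedGraph-ready.

    Returns a DataFrame with chrom/start/end/count per bin; the total count
    in view (the number displayed beside a browser track) is the column sum.
    """
    if len(view) == 0:
        raise ValueError("empty view interval")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    positions = cutsite_arrays(fragments).get(view.chrom)
    n_bins = -(-len(view) // bin_width)
    hist = np.zeros(n_bins, dtype=np.int64)
    if positions is not None:
        in_view = positions[(positions >= view.start) & (positions < view.end)]
        if in_view.size:
            hist = np.bincount(
                (in_view - view.start) // bin_width, minlength=n_bins
            )
    starts = view.start + bin_width * np.arange(n_bins)
    ends = np.minimum(starts + bin_width, view.end)
    return pd.DataFrame(
        {"chrom": view.chrom, "start": starts, "end": ends, "count": hist}
    )
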