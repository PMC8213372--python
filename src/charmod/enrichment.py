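"""Hypergeometric enrichment of accessibility modules in exhaustion categories.

Each universe region can carry one label from the murine exhaustion-state
chromatin atlas (naive, effector, memory, early_exhaustion, late_exhaustion)
after orthologous mapping, or "none".  A module of n regions containing k
labelled regions, against K labelled regions in the N-region universe, has
fold enrichment FE = (k/n) / (K/N) and upper-tail hypergeometric p-value
P(X >= k) for X ~ Hypergeometric(N, K, n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .differential import ModuleAssignment
from .intervals import PeakUniverse

logger = logging.getLogger(__name__)

CATEGORIES = (
    "naive",
    "effector",
    "memory",
    "early_exhaustion",
    "late_exhaustion",
)

__all__ = [
    "CATEGORIES",
    "CategoryAnnotation",
    "load_category_annotation",
    "EnrichmentResult",
    "fold_enrichment",
    "enrichment_table",
]


@dataclass
class CategoryAnnotation:
    """region_id -> exhaustion-state category (each region at most one)."""

    labels: dict[str, str]
    universe_size: int

    def category_total(self, category: str) -> int:
        return sum(1 for c in self.labels.values() if c == category)

    def regions_of(self, category: str) -> set[str]:
        return {r for r, c in self.labels.items() if c == category}


def load_category_annotation(
    path: str, universe: PeakUniverse
) -> CategoryAnnotation:
    """Load a region -> category TSV and attach it to universe regions.

    Accepts either (region_id, category) or (chrom, start, end, category)
    rows; coordinate rows are matched by midpoint containment.  Unmatched
    rows are logged and dropped; more than 50% unmatched raises (a likely
    coordinate-convention mismatch).  Duplicate assignments keep the first
    listed with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] == 2:
        df.columns = ["region_id", "category"]
        coord_mode = False
    elif df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = ["chrom", "start", "end", "category"]
        coord_mode = True
    else:
        raise ValueError(
            f"{path}: expected 2 (region_id, category) or >= 4 "
            "(chrom, start, end, category) columns"
        )
    valid = set(CATEGORIES) | {"none"}
    bad = sorted(set(df["category"]) - valid)
    if bad:
        raise ValueError(f"{path}: unknown categories {bad}")

    known_ids = set(universe.region_ids)
    labels: dict[str, str] = {}
    n_unmatched = 0
    for row in df.itertuples(index=False):
        if coord_mode:
            mid = (int(row.start) + int(row.end)) // 2
            idx = universe.query_point(row.chrom, mid)
            if idx is None:
                n_unmatched += 1
                logger.debug(
                    "annotation %s:%s-%s midpoint in no region; dropped",
                    row.chrom, row.start, row.end,
                )
                continue
            region_id = universe.region_ids[idx]
        else:
            region_id = row.region_id
            if region_id not in known_ids:
                n_unmatched += 1
                continue
        if region_id in labels:
            logger.warning(
                "region %s annotated more than once; keeping first (%s)",
                region_id, labels[region_id],
            )
            continue
        if row.category != "none":
            labels[region_id] = row.category
    if len(df) and n_unmatched / len(df) > 0.5:
        raise ValueError(
            f"{path}: {n_unmatched}/{len(df)} annotation rows unmatched; "
            "check the coordinate convention (expected 0-based half-open)"
        )
    if n_unmatched:
        logger.info("%s: dropped %d unmatched annotation rows", path, n_unmatched)
    return CategoryAnnotation(labels=labels, universe_size=len(universe))


@dataclass
class EnrichmentResult:
    cluster_label: str
    category: str
    k: int  # labelled regions inside the cluster
    n: int  # cluster size
    K: int  # labelled regions in the universe
    N: int  # universe size
    fold_enrichment: float  # (k/n) / (K/N); NaN when K == 0
    p_value: float  # upper tail P(X >= k)


def fold_enrichment(
    cluster_label: str,
    cluster_regions: set[str],
    annotation: CategoryAnnotation,
    category: str,
) -> EnrichmentResult:
    """Hypergeometric fold enrichment of one cluster in one category."""
    if not cluster_regions:
        raise ValueError("empty cluster")
    n = len(cluster_regions)
    N = annotation.universe_size
    category_regions = annotation.regions_of(category)
    K = len(category_regions)
    k = len(cluster_regions & category_regions)
    if K == 0:
        return EnrichmentResult(
            cluster_label, category, k, n, K, N, float("nan"), 1.0
        )
    fe = (k / n) / (K / N)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(cluster_label, category, k, n, K, N, fe, p)


def enrichment_table(
    modules: ModuleAssignment,
    annotation: CategoryAnnotation,
    background: str = "universe",
) -> pd.DataFrame:
    """One enrichment row per (module x category), cluster-major order.

    ``background`` selects the reference population: the full region universe
    (default) or only the differential regions that were clustered.
    """
    if background not in ("universe", "differential"):
        raise ValueError("background must be 'universe' or 'differential'")
    if background == "differential":
        diff_ids = set(modules.labels.index)
        annotation = CategoryAnnotation(
            labels={r: c for r, c in annotation.labels.items() if r in diff_ids},
            universe_size=len(diff_ids),
        )
    rows = []
    for label in sorted(modules.labels.unique()):
        cluster = set(modules.regions_in(label))
        for category in CATEGORIES:
            res = fold_enrichment(label, cluster, annotation, category)
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
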