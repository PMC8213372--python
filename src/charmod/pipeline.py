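"""End-to-end pipeline orchestration with a run manifest.

Stages run in dependency order — universe, counts, QC, differential,
modules, enrichment, super-enhancers — each writing plain-text outputs
(BED/TSV/JSON) so any stage can be re-run standalone and diffed.  The
manifest records the config snapshot, input checksums, master seed, stage
timings and output checksums; re-running on identical inputs reproduces
identical stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import counting, differential, enrichment, intervals, superenhancer
from .config import PipelineConfig, validate_config
from .counting import SampleTable

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "file_checksum"]

STAGES = ("universe", "count", "qc", "diff", "modules", "enrich", "se")


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logging(outdir: Path, level: int = logging.INFO) -> None:
    root = logging.getLogger("charmod")
    root.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        root.addHandler(sh)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(fmt)
    root.addHandler(fh)


def run_pipeline(
    peak_files: list[str],
    fragment_files: dict[str, str],
    sample_table_path: str,
    outdir: str,
    genes_path: str | None = None,
    annotation_path: str | None = None,
    tss_path: str | None = None,
    config: PipelineConfig | dict | str | None = None,
    apply_shift: bool = False,
    se_direction: tuple[str, str] | None = None,
) -> dict:
    """Run the full analysis; returns in-memory results per stage.

    ``se_direction`` is an ordered condition pair (A, B): the SE stage uses
    differential regions more accessible in A than in B (log2FC of B vs A
    negative, q below threshold).  Defaults to (baseline, art_1yr).
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)

    inputs = list(peak_files) + list(fragment_files.values()) + [sample_table_path]
    for optional in (genes_path, annotation_path, tss_path):
        if optional:
            inputs.append(optional)
    missing = [p for p in inputs if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    if annotation_path is None:
        logger.info("no annotation file: enrichment stage will be skipped")
    if genes_path is None:
        logger.info("no gene file: SE stage will be skipped")

    manifest: dict = {
        "config": cfg.to_dict(),
        "inputs": {str(p): file_checksum(p) for p in inputs},
        "seed": cfg.random_seed,
        "timing_s": {},
        "outputs": {},
    }
    results: dict = {}

    def _finish(stage: str, t0: float, paths: list[Path]) -> None:
        manifest["timing_s"][stage] = round(time.perf_counter() - t0, 3)
        for p in paths:
            manifest["outputs"][p.name] = file_checksum(p)
        logger.info("stage %s done (%.2fs)", stage, manifest["timing_s"][stage])

    # --- universe ---------------------------------------------------------
    t0 = time.perf_counter()
    peaksets = []
    for path in peak_files:
        dialect = "narrowPeak" if str(path).endswith(("narrowPeak", "narrowPeak.gz")) else "bed3"
        ps = intervals.read_bed(path, dialect=dialect)
        ps.condition_label = Path(path).stem
        peaksets.append(ps)
    universe = intervals.build_universe(peaksets)
    universe_bed = out / "universe.bed"
    intervals.write_bed(universe.regions, universe_bed)
    results["universe"] = universe
    _finish("universe", t0, [universe_bed])

    # --- counts -----------------------------------------------------------
    t0 = time.perf_counter()
    samples = SampleTable.read_tsv(sample_table_path)
    counts = counting.count_matrix(
        fragment_files,
        universe,
        samples,
        max_fragment_length=cfg.max_fragment_length,
        apply_shift=apply_shift,
    )
    counts_path = out / "counts.tsv"
    counts.rename_axis("region_id").to_csv(counts_path, sep="\t")
    results["counts"] = counts
    results["samples"] = samples
    _finish("count", t0, [counts_path])

    # --- qc ---------------------------------------------------------------
    t0 = time.perf_counter()
    tss = None
    if tss_path:
        tss_df = pd.read_csv(tss_path, sep="\t", dtype={"chrom": str})
        tss = [
            (r.chrom, int(r.pos), r.strand) for r in tss_df.itertuples(index=False)
        ]
    qc = counting.qc_report(
        fragment_files,
        universe,
        tss_positions=tss,
        max_fragment_length=cfg.max_fragment_length,
        apply_shift=apply_shift,
        window=cfg.tss_window,
        flank=cfg.tss_flank,
    )
    qc_path = out / "qc.tsv"
    qc.to_csv(qc_path, sep="\t", index=False)
    results["qc"] = qc
    _finish("qc", t0, [qc_path])

    # --- differential -----------------------------------------------------
    t0 = time.perf_counter()
    observed = [c for c in cfg.conditions if c in set(samples.df["condition"])]
    pairwise, size_factors = differential.differential_analysis(
        counts, samples, conditions=tuple(observed),
        dispersion_floor=cfg.dispersion_floor,
    )
    diff_paths = []
    for (a, b), df in pairwise.items():
        p = out / f"diff_{a}_vs_{b}.tsv"
        df.to_csv(p, sep="\t")
        diff_paths.append(p)
    union = differential.select_differential_union(pairwise, cfg.fdr_threshold)
    union_bed = out / "differential_union.bed"
    id_to_region = dict(zip(universe.region_ids, universe.regions))
    intervals.write_bed([id_to_region[r] for r in union], union_bed)
    results["size_factors"] = size_factors
    results["pairwise"] = pairwise
    results["differential_union"] = union
    _finish("diff", t0, diff_paths + [union_bed])

    # --- modules ----------------------------------------------------------
    t0 = time.perf_counter()
    if not union:
        raise RuntimeError(
            "stage modules failed: no differential regions at "
            f"FDR < {cfg.fdr_threshold}"
        )
    cond_means = differential.condition_mean_rows(
        counts, size_factors, samples, union, conditions=tuple(observed)
    )
    row_norm, flagged = differential.row_normalize(cond_means)
    modules = differential.kmeans_modules(
        row_norm, k=cfg.k_clusters, seed=cfg.random_seed, restarts=cfg.kmeans_restarts
    )
    modules_path = out / "modules.tsv"
    modules.labels.rename_axis("region_id").to_csv(modules_path, sep="\t")
    matrix_path = out / "row_normalized.tsv"
    row_norm.rename_axis("region_id").to_csv(matrix_path, sep="\t")
    results["modules"] = modules
    _finish("modules", t0, [modules_path, matrix_path])

    # --- enrichment -------------------------------------------------------
    if annotation_path:
        t0 = time.perf_counter()
        annotation = enrichment.load_category_annotation(annotation_path, universe)
        enr = enrichment.enrichment_table(modules, annotation)
        enr_path = out / "enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False)
        results["enrichment"] = enr
        _finish("enrich", t0, [enr_path])

    # --- super-enhancers --------------------------------------------------
    if genes_path:
        t0 = time.perf_counter()
        genes = superenhancer.read_genes(genes_path)
        if se_direction is None:
            se_direction = ("baseline", "art_1yr")
        a, b = se_direction
        key = (a, b) if (a, b) in pairwise else (b, a)
        if key not in pairwise:
            raise RuntimeError(
                f"stage se failed: no pairwise result for conditions {a}/{b}"
            )
        df = pairwise[key]
        sign = -1.0 if key == (a, b) else 1.0
        sig = df[(df["q_value"] < cfg.fdr_threshold).fillna(False)]
        chosen = sig.index[np.sign(sig["log2_fold_change"]) == sign]
        se_regions = [id_to_region[r] for r in chosen]
        elbow = superenhancer.se_analysis(
            se_regions,
            genes,
            basal_up=cfg.great_basal_up,
            basal_down=cfg.great_basal_down,
            extension_max=cfg.great_extension_max,
        )
        se_path = out / "se_genes.tsv"
        elbow.to_frame().to_csv(se_path, sep="\t", index=False)
        results["se"] = elbow
        _finish("se", t0, [se_path])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return results
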