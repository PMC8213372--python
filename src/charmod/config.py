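"""Pipeline configuration.

All numeric settings of the analysis live here so that every stage reads
its thresholds from one validated object.  Defaults follow the analysis
conventions used throughout the package: FDR 0.05 for differential region
selection, k = 4 accessibility modules, GREAT-default regulatory domains
(5 kb upstream / 1 kb downstream basal, 1 Mb maximum extension), a 1000 bp
maximum fragment length, and an ENCODE-style TSS enrichment window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any, Mapping

import yaml

#: canonical condition labels of the four-arm study design:
#: naive CD8 T cells, antigen-specific cells at baseline (primary infection),
#: after one year of antiretroviral therapy, and after one year untreated.
DEFAULT_CONDITIONS = ("naive", "baseline", "art_1yr", "untreated_1yr")


@dataclass
class PipelineConfig:
    """Validated numeric settings for every pipeline stage.

    Attributes
    ----------
    fdr_threshold:
        Benjamini-Hochberg q-value cutoff selecting differential regions
        within each pairwise comparison.
    k_clusters:
        Number of k-means accessibility modules (labels ``A``, ``B``, ...).
    dispersion_floor:
        Lower bound on the per-region negative-binomial dispersion.
    kmeans_restarts:
        Independent k-means++ starts; the best inertia wins.
    random_seed:
        Master seed for every stochastic step.
    max_fragment_length:
        Fragments longer than this are discarded at ingest (bp).
    tss_window, tss_flank:
        Half-window around each TSS and background flank width for the
        TSS enrichment score (bp).
    great_basal_up, great_basal_down, great_extension_max:
        Basal-plus-extension regulatory-domain rule (bp, strand-aware).
    """

    fdr_threshold: float = 0.05
    k_clusters: int = 4
    dispersion_floor: float = 1e-8
    kmeans_restarts: int = 10
    random_seed: int = 0
    max_fragment_length: int = 1000
    tss_window: int = 1000
    tss_flank: int = 100
    great_basal_up: int = 5000
    great_basal_down: int = 1000
    great_extension_max: int = 1_000_000
    conditions: tuple = DEFAULT_CONDITIONS

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError(
                f"fdr_threshold must lie in (0, 1), got {self.fdr_threshold}"
            )
        for name in (
            "k_clusters",
            "kmeans_restarts",
            "max_fragment_length",
            "tss_window",
            "tss_flank",
            "great_basal_up",
            "great_basal_down",
            "great_extension_max",
        ):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.dispersion_floor <= 0:
            raise ValueError(
                f"dispersion_floor must be positive, got {self.dispersion_floor}"
            )
        if self.random_seed < 0:
            raise ValueError(f"random_seed must be >= 0, got {self.random_seed}")
        self.conditions = tuple(self.conditions)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d


def validate_config(source: Mapping[str, Any] | str | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a mapping or a YAML file path.

    Missing keys take their defaults; unknown keys are rejected by name;
    out-of-range values raise with the violated bound.
    """
    if source is None:
        return PipelineConfig()
    if isinstance(source, str):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {source!r} must contain a mapping")
    else:
        data = dict(source)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return PipelineConfig(**data)
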