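"""Configuration dataclasses for the synthetic generator and the pipeline.

Every tunable of the analysis lives in :class:`PipelineConfig`; its defaults
are the published constants of the method (minimum 20 samples per series,
ANOVA alpha 0.01 with a top-3000 fallback, TE 90th-percentile abundance
floor, top-0.1% edge fraction with positive correlations only, core
universality cutoff 10, power-law tail cutoffs 50/500, module-similarity
threshold 10 with a 10-neighbor cap).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigurationError


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {msg}")


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic collection of expression series.

    The generator plants latent-factor coexpression modules: *core* modules
    active in most series (ribosome/photosystem-like machinery) and
    *specific* modules active in only a few, tissue-aligned series, on top
    of uncorrelated noise genes, low-abundance genes (absent calls, below
    the TE abundance floor) and TE rows.
    """

    n_series: int = 15
    samples_per_series: int = 24
    n_replicate_groups: int = 6
    n_core_modules: int = 3
    core_module_size: int = 25
    core_presence: int = 12          # series each core module is active in
    n_specific_modules: int = 10
    specific_module_size: int = 25
    specific_presence: tuple[int, int] = (1, 2)  # presence cycles over this range
    module_signal: float = 0.95      # latent-factor loading, in (0, 1]
    core_background_signal: float = 0.2  # residual core-module loading in non-active series
    noise_sd: float = 0.3            # per-gene residual noise sd (factor units)
    group_effect: float = 0.7        # fraction of factor variance between replicate groups
    n_noise_genes: int = 1500
    n_low_abundance_genes: int = 150
    n_te_rows: int = 200
    n_tissues: int = 3
    n_undersized_series: int = 0     # extra series failing the min-sample filter
    undersized_samples: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.specific_presence = tuple(self.specific_presence)  # type: ignore[arg-type]
        for name in ("n_series", "samples_per_series", "n_replicate_groups",
                     "n_core_modules", "core_module_size", "core_presence",
                     "n_specific_modules", "specific_module_size",
                     "n_noise_genes", "n_low_abundance_genes", "n_te_rows",
                     "n_tissues", "n_undersized_series", "undersized_samples"):
            v = getattr(self, name)
            _require(isinstance(v, int) and v >= 0, name, f"must be a non-negative integer, got {v!r}")
        _require(self.n_series >= 1, "n_series", "must be >= 1")
        _require(self.n_replicate_groups >= 2, "n_replicate_groups", "must be >= 2")
        _require(self.samples_per_series >= 2 * self.n_replicate_groups,
                 "samples_per_series",
                 f"must be >= 2 * n_replicate_groups = {2 * self.n_replicate_groups}")
        _require(0.0 < self.module_signal <= 1.0, "module_signal", "must be in (0, 1]")
        _require(0.0 <= self.core_background_signal < self.module_signal,
                 "core_background_signal", "must be in [0, module_signal)")
        _require(self.noise_sd > 0, "noise_sd", "must be positive")
        _require(0.0 <= self.group_effect < 1.0, "group_effect", "must be in [0, 1)")
        _require(self.core_presence <= self.n_series, "core_presence",
                 "cannot exceed n_series")
        _require(len(self.specific_presence) == 2
                 and 1 <= self.specific_presence[0] <= self.specific_presence[1]
                 <= self.n_series,
                 "specific_presence", "must be (lo, hi) with 1 <= lo <= hi <= n_series")
        _require(self.n_te_rows >= 1, "n_te_rows",
                 "at least one TE row is required for the abundance floor")
        _require(self.n_tissues >= 1, "n_tissues", "must be >= 1")

    @property
    def n_genes(self) -> int:
        """Total gene rows (module + noise + low-abundance; TE rows excluded)."""
        return (self.n_core_modules * self.core_module_size
                + self.n_specific_modules * self.specific_module_size
                + self.n_noise_genes + self.n_low_abundance_genes)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their published defaults."""

    # preprocess
    min_samples: int = 20
    anova_alpha: float = 0.01
    fallback_n: int = 3000
    te_quantile: float = 0.90
    te_percentile_scope: str = "per_sample"  # "per_sample" | "dataset"
    # netbuild
    edge_fraction: float = 0.001
    positive_only: bool = True
    drop_nonpositive_first: bool = False
    # pancore
    core_u: int = 10
    powerlaw_tail_core: int = 50
    powerlaw_tail_pan: int = 500
    use_transitivity: bool = False   # global transitivity instead of average local clustering
    n_perm_overlap: int = 200
    # enrichment
    enrichment_alpha: float = 0.05
    broad_term_method: str = "min_p"  # "min_p" | "max_fraction"
    broad_max_fraction: float = 0.2
    background_scope: str = "network"  # "network" | "genome"
    # similarity
    n_perm_preservation: int = 100
    similarity_threshold: float = 10.0
    max_neighbors: int = 10
    n_perm_label: int = 999
    min_module_genes: int = 5
    max_module_genes: int = 150
    # orchestration
    seed: int = 0
    input_manifest: str | None = None    # read a collection instead of simulating
    reference_edges_path: str | None = None
    annotations_path: str | None = None
    hierarchy_path: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        _require(self.min_samples >= 0, "min_samples", "must be non-negative")
        _require(0 < self.anova_alpha < 1, "anova_alpha", "must be in (0, 1)")
        _require(self.fallback_n >= 0, "fallback_n", "must be non-negative")
        _require(0 < self.te_quantile < 1, "te_quantile", "must be in (0, 1)")
        _require(self.te_percentile_scope in ("per_sample", "dataset"),
                 "te_percentile_scope", "must be 'per_sample' or 'dataset'")
        _require(0 < self.edge_fraction <= 1, "edge_fraction", "must be in (0, 1]")
        _require(self.core_u >= 1, "core_u", "must be >= 1")
        _require(self.broad_term_method in ("min_p", "max_fraction"),
                 "broad_term_method", "must be 'min_p' or 'max_fraction'")
        _require(self.background_scope in ("network", "genome"),
                 "background_scope", "must be 'network' or 'genome'")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["synthetic"]["specific_presence"] = list(
            d["synthetic"]["specific_presence"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fanned out from the root seed."""
        offsets = {"synthetic": 1, "netbuild": 2, "pancore": 3, "modules": 4,
                   "enrichment": 5, "similarity": 6, "overlap": 7, "label": 8}
        if stage not in offsets:
            raise ConfigurationError(f"unknown stage {stage!r}")
        return (int(self.seed) * 1000 + offsets[stage]) % (2**31 - 1)
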