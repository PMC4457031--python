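"""Structured run configuration.

Every stage's thresholds live here with the study defaults: marker QC at
call rate 0.90 / MAF 0.05 / HWE 1e-6, association alpha 0.05 with
Bonferroni over informative markers, variant-site depth bounds [6, 70]
with 5-bp spacing and quality 20, panel segregation frequency 0.1, DEG
calling at FDR <= 0.001 with |log2 ratio| >= 1, consensus top fraction
0.20, and the human-variant damaging/conservation thresholds.

Unknown keys in a config document are rejected so that typos never
silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not math.isfinite(value) or not (lo <= value <= hi):
        raise ValueError(f"{name}={value!r} out of bounds [{lo}, {hi}]")


@dataclass
class QcParams:
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    hwe_individuals: str = "all"  # "all" | "founders" | "f2"

    def validate(self) -> None:
        _check_range("qc.call_rate_min", self.call_rate_min, 0.0, 1.0)
        _check_range("qc.maf_min", self.maf_min, 0.0, 0.5)
        _check_range("qc.hwe_p_min", self.hwe_p_min, 0.0, 1.0)
        if self.hwe_individuals not in ("all", "founders", "f2"):
            raise ValueError(f"qc.hwe_individuals={self.hwe_individuals!r} unknown")


@dataclass
class AssocParams:
    alpha: float = 0.05
    method: str = "trend"  # "trend" (dosage regression) | "welch" (hom vs hom)
    max_unknown_frac: float = 0.5
    posterior_threshold: float = 0.95
    hmm_error_rate: float = 0.01
    cm_per_mb: float = 1.0

    def validate(self) -> None:
        _check_range("assoc.alpha", self.alpha, 0.0, 1.0)
        if self.method not in ("trend", "welch"):
            raise ValueError(f"assoc.method={self.method!r} unknown")
        _check_range("assoc.max_unknown_frac", self.max_unknown_frac, 0.0, 1.0)
        _check_range("assoc.posterior_threshold", self.posterior_threshold, 0.5, 1.0)
        _check_range("assoc.hmm_error_rate", self.hmm_error_rate, 0.0, 0.5)
        _check_range("assoc.cm_per_mb", self.cm_per_mb, 1e-6, 1e3)


@dataclass
class FinemapParams:
    min_markers: int = 2
    bridge_markers: int = 2
    matching: str = "missing_compatible"  # | "strict"
    boundary: str = "inner"  # | "midpoint"

    def validate(self) -> None:
        if self.min_markers < 1:
            raise ValueError("finemap.min_markers must be >= 1")
        if self.bridge_markers < 0:
            raise ValueError("finemap.bridge_markers must be >= 0")
        if self.matching not in ("missing_compatible", "strict"):
            raise ValueError(f"finemap.matching={self.matching!r} unknown")
        if self.boundary not in ("inner", "midpoint"):
            raise ValueError(f"finemap.boundary={self.boundary!r} unknown")


@dataclass
class VariantParams:
    depth_min: int = 6
    depth_max: int = 70
    min_spacing_bp: int = 5
    quality_min: float = 20.0
    seg_freq_threshold: float = 0.1
    panel_screen_order: str = "after_cascade"  # | "before_cascade"

    def validate(self) -> None:
        if not (0 <= self.depth_min <= self.depth_max):
            raise ValueError("variants.depth bounds must satisfy 0 <= min <= max")
        if self.min_spacing_bp < 0:
            raise ValueError("variants.min_spacing_bp must be >= 0")
        _check_range("variants.quality_min", self.quality_min, 0.0, 1e6)
        _check_range("variants.seg_freq_threshold", self.seg_freq_threshold, 0.0, 1.0)
        if self.panel_screen_order not in ("after_cascade", "before_cascade"):
            raise ValueError(f"variants.panel_screen_order={self.panel_screen_order!r} unknown")


@dataclass
class DegParams:
    fdr_max: float = 0.001
    min_abs_log2: float = 1.0
    two_sided: str = "doubled_tail"  # | "minlike"

    def validate(self) -> None:
        _check_range("deg.fdr_max", self.fdr_max, 0.0, 1.0)
        _check_range("deg.min_abs_log2", self.min_abs_log2, 0.0, 64.0)
        if self.two_sided not in ("doubled_tail", "minlike"):
            raise ValueError(f"deg.two_sided={self.two_sided!r} unknown")


@dataclass
class ConsensusParams:
    fraction: float = 0.20

    def validate(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("consensus.fraction must be in (0, 1]")


@dataclass
class HumanFilterParams:
    damaging_min: float = 0.85
    conservation_min: float = 1.0
    required_absent_dbs: tuple[str, ...] = ("thousand_genomes", "dbsnp", "evs")

    def validate(self) -> None:
        _check_range("human.damaging_min", self.damaging_min, 0.0, 1.0)
        _check_range("human.conservation_min", self.conservation_min, 0.0, 1.0)


_BLOCKS = {
    "qc": QcParams,
    "assoc": AssocParams,
    "finemap": FinemapParams,
    "variants": VariantParams,
    "deg": DegParams,
    "consensus": ConsensusParams,
    "human": HumanFilterParams,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    qc: QcParams = field(default_factory=QcParams)
    assoc: AssocParams = field(default_factory=AssocParams)
    finemap: FinemapParams = field(default_factory=FinemapParams)
    variants: VariantParams = field(default_factory=VariantParams)
    deg: DegParams = field(default_factory=DegParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    human: HumanFilterParams = field(default_factory=HumanFilterParams)
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        for name in _BLOCKS:
            getattr(self, name).validate()

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "PipelineConfig":
        doc = dict(doc or {})
        kwargs: dict[str, Any] = {}
        if "seed" in doc:
            kwargs["seed"] = doc.pop("seed")
        if "paths" in doc:
            kwargs["paths"] = dict(doc.pop("paths"))
        for name, block_cls in _BLOCKS.items():
            if name in doc:
                block_doc = dict(doc.pop(name) or {})
                known = {f.name for f in dataclasses.fields(block_cls)}
                unknown = set(block_doc) - known
                if unknown:
                    raise ValueError(f"unknown keys in config block {name!r}: {sorted(unknown)}")
                if "required_absent_dbs" in block_doc:
                    block_doc["required_absent_dbs"] = tuple(block_doc["required_absent_dbs"])
                kwargs[name] = block_cls(**block_doc)
        if doc:
            raise ValueError(f"unknown top-level config keys: {sorted(doc)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ValueError("config document must be a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"seed": self.seed, "paths": dict(self.paths)}
        for name in _BLOCKS:
            block = dataclasses.asdict(getattr(self, name))
            if "required_absent_dbs" in block:
                block["required_absent_dbs"] = list(block["required_absent_dbs"])
            out[name] = block
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
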