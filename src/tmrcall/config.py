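"""Run configuration: YAML round-trip of every pipeline parameter.

A single config object carries all algorithm defaults (coverage mask 10
reads, 30 complete pairs per correlation, 5 kb search-region pads,
smoothing factor 0.75 with 10 flanking CpGs, thresholds at +/- log10(0.05),
minimum 5 CpGs per region, mappability cutoff 1.0, 1000 permutations) plus
the seed that governs every stochastic stage.  The serialized form is
echoed into run outputs so results are reproducible from the files alone.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .caller import CallerConfig, SmoothingParams, Thresholds

__all__ = ["RunConfig", "load_run_config", "dump_run_config"]


@dataclass
class RunConfig:
    # inputs (optional: the library API can be used without files)
    sample_sheet: Optional[str] = None
    methylome_dialect: str = "beta"
    counts: Optional[str] = None
    gtf: Optional[str] = None
    ctss_bed: Optional[str] = None
    mappability: Optional[str] = None
    # algorithm parameters
    min_reads: int = 10
    min_samples: int = 30
    upstream_pad: int = 5000
    downstream_pad: int = 5000
    smoothing_factor: float = 0.75
    n_flank: int = 10
    negative_threshold: float = math.log10(0.05)
    positive_threshold: float = -math.log10(0.05)
    min_cpgs: int = 5
    mappability_min_score: float = 1.0
    mappability_mode: str = "full_containment"
    cage_min_tags: int = 10
    cage_tolerance_bp: int = 0
    n_perm: int = 1000
    # reproducibility
    seed: int = 0
    out_dir: str = "tmrcall_out"

    def caller_config(self) -> CallerConfig:
        return CallerConfig(
            min_reads=self.min_reads,
            min_samples=self.min_samples,
            upstream_pad=self.upstream_pad,
            downstream_pad=self.downstream_pad,
            smoothing=SmoothingParams(self.smoothing_factor, self.n_flank),
            thresholds=Thresholds(self.negative_threshold, self.positive_threshold),
            min_cpgs=self.min_cpgs,
            mappability_min_score=self.mappability_min_score,
            mappability_mode=self.mappability_mode,
        )

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def header(self, version: str) -> str:
        return f"tmrcall v{version} config={self.config_hash()} seed={self.seed}"


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def dump_run_config(config: RunConfig, path) -> None:
    with open(path, "wt") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
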