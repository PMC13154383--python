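"""Run configuration with the study's filtering thresholds as defaults.

All thresholds are strict inequalities where the source protocol phrases them
that way: contigs must be *longer than* ``min_length_bp``, detection requires
breadth *greater than* ``breadth_threshold``, taxonomy requires *more than*
half of annotated genes, and MAG quality classes use strict completion /
contamination cut-offs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger("halovir")


class ConfigError(ValueError):
    """Invalid or out-of-range run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds and knobs, defaulting to the protocol values."""

    #: consensus: keep contigs strictly longer than this (bp)
    min_length_bp: int = 10_000
    #: consensus: minimum number of distinct predictors calling a contig
    min_tools: int = 2
    #: vOTU clustering: minimum average nucleotide identity
    ani_min: float = 0.95
    #: vOTU clustering: minimum aligned fraction of the shorter sequence
    af_min: float = 0.85
    #: detection: minimum coverage breadth (strict) for a vOTU in a sample
    breadth_threshold: float = 0.75
    #: taxonomy: strict majority fraction of annotated genes
    majority_fraction: float = 0.5
    #: temporal model selection: k range searched
    k_min: int = 1
    k_max: int = 20
    #: permutation count for ANOSIM / PERMANOVA / envfit
    n_permutations: int = 9_999
    #: community distance for the multivariate tests
    distance: str = "clr_euclidean"  # or "braycurtis"
    #: taxonomy votes over the representative's genes only, or pooled members
    pool_member_genes: bool = False
    #: delimiter separating a contig base name from a predictor trim suffix
    trim_delimiter: str = "||"
    #: seed for every stochastic stage (NMDS restarts, permutations, PAM)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length_bp < 0 or self.min_tools < 1:
            raise ConfigError("min_length_bp must be >= 0 and min_tools >= 1")
        for name in ("ani_min", "af_min", "breadth_threshold", "majority_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 1 <= self.k_min <= self.k_max:
            raise ConfigError("need 1 <= k_min <= k_max")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be positive")
        if self.distance not in ("clr_euclidean", "braycurtis"):
            raise ConfigError(f"unknown distance {self.distance!r}")

    def log_defaults(self) -> None:
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a JSON run configuration; absent keys fall back to defaults.

    Unknown keys are rejected so typos cannot silently revert a threshold to
    its default.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = json.loads(text) if text.strip() else {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a JSON object")
    data.update(overrides)
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.log_defaults()
    return cfg
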