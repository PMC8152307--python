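"""Run configuration: one flat document holding every pipeline knob.

A :class:`RunConfig` can be loaded from a YAML or JSON file and overridden
field-by-field (the CLI maps flags onto :meth:`RunConfig.replace`). The seed
is global: every stage that uses randomness derives its own sub-seeds from
it, so a fixed config reproduces the whole pipeline bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

NORMALIZATION_METHODS = ("tmm", "median_of_ratios", "none")


@dataclass(frozen=True)
class RunConfig:
    """Global settings for a network-inference run.

    Parameters
    ----------
    seed : global random seed; all stage-level randomness derives from it.
    n_trees : trees per random forest (both inference and permutation refits).
    n_permutations : target-profile shuffles per tested target (B).
    density : prior network connectivity density in (0, 1).
    fdr_threshold : BH-adjusted p-value cutoff for the final network.
    correlation_threshold : Spearman correlation above which regulators are
        grouped into one meta-regulator, in (0, 1].
    low_count_threshold : minimum total count (summed over samples) a gene
        must reach to be kept; ``None`` means 10 x n_samples at run time.
    normalization_method : "tmm", "median_of_ratios" or "none".
    log_transform : feed log2(1 + x) of the normalized values to the random
        forests. On count-scale data, variance-based splitting is dominated
        by the few highest-expression samples; the log stabilises it.
        Regulator grouping (Spearman) is unaffected either way.
    """

    seed: int = 42
    n_trees: int = 1000
    n_permutations: int = 100
    density: float = 0.03
    fdr_threshold: float = 0.05
    correlation_threshold: float = 0.9
    low_count_threshold: float | None = None
    normalization_method: str = "tmm"
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be a positive integer")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be a positive integer")
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must lie in (0, 1]")
        if self.low_count_threshold is not None and self.low_count_threshold < 0:
            raise ValueError("low_count_threshold must be non-negative")
        if self.normalization_method not in NORMALIZATION_METHODS:
            raise ValueError(
                f"normalization_method must be one of {NORMALIZATION_METHODS}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from a flat YAML or JSON document."""
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **overrides) -> "RunConfig":
        """New config with the given fields overridden (None values ignored)."""
        overrides = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **overrides)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
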