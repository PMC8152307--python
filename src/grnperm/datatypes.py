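"""Core containers passed between pipeline stages.

All containers are thin dataclasses around pandas objects with invariant
checks at construction time. Expression matrices are genes x samples; edge
tables are pandas DataFrames with one row per directed regulator->target
edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: separator used to build meta-regulator identifiers out of member IDs
META_SEPARATOR = "-"

#: columns of a tested edge table, in output order
EDGE_COLUMNS = ["regulator", "target", "importance", "pvalue", "fdr"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise ValueError(f"duplicate {what} IDs: {sorted(map(str, dups))}")


@dataclass
class CountMatrix:
    """Gene x sample expression matrix (raw counts or normalized values)."""

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if self.values.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 samples")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                "negative expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        state = "normalized" if self.normalized else "raw"
        return f"CountMatrix({self.n_genes} genes x {self.n_samples} samples, {state})"


@dataclass(frozen=True)
class RegulatorSet:
    """Genes allowed to have outgoing edges (transcription factors)."""

    regulator_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "regulator_ids", frozenset(self.regulator_ids))

    def intersect(self, genes: Sequence[str]) -> list[str]:
        """Regulators present in an expression matrix, sorted for determinism."""
        return sorted(self.regulator_ids.intersection(genes))

    def __len__(self) -> int:
        return len(self.regulator_ids)

    def __contains__(self, item: str) -> bool:
        return item in self.regulator_ids


@dataclass
class SizeFactors:
    """Per-sample library scaling factors."""

    factors: pd.Series  # indexed by sample ID
    method: str  # "tmm" | "median_of_ratios"

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be strictly positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.factors.index)


@dataclass
class RegulatorGrouping:
    """Partition of the regulator set into groups of rank-correlated TFs.

    ``groups`` maps a meta-regulator ID (member IDs joined lexicographically
    by :data:`META_SEPARATOR`) to its member list; singletons map to
    themselves. ``meta_profiles`` holds one merged expression profile per
    meta-regulator (mean of member profiles), meta-regulators x samples.
    """

    groups: dict[str, list[str]]
    meta_profiles: pd.DataFrame

    def __post_init__(self) -> None:
        members = [m for ms in self.groups.values() for m in ms]
        _check_unique(members, "regulator (grouping must partition)")
        if set(self.meta_profiles.index) != set(self.groups):
            raise ValueError("meta_profiles rows must match group keys")

    @property
    def meta_ids(self) -> list[str]:
        return list(self.meta_profiles.index)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def members(self, meta_id: str) -> list[str]:
        return list(self.groups[meta_id])

    def group_of(self, gene: str) -> str | None:
        """Meta-regulator whose group contains ``gene``, or None."""
        for meta, ms in self.groups.items():
            if gene in ms:
                return meta
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"meta_regulator": meta, "member": m}
            for meta in sorted(self.groups)
            for m in sorted(self.groups[meta])
        ]
        return pd.DataFrame(rows, columns=["meta_regulator", "member"])


@dataclass
class ImportanceMatrix:
    """Random-forest importances w[regulator, target] (GENIE3 weights)."""

    w: pd.DataFrame  # meta-regulators x targets
    grouping: RegulatorGrouping | None = None

    def __post_init__(self) -> None:
        if (self.w.to_numpy() < 0).any():
            raise ValueError("importances must be non-negative")

    @property
    def regulators(self) -> list[str]:
        return list(self.w.index)

    @property
    def targets(self) -> list[str]:
        return list(self.w.columns)


@dataclass
class WeightedNetwork:
    """Density-thresholded prior network (edges ranked by importance)."""

    edges: pd.DataFrame  # columns: regulator, target, importance
    density: float
    grouping: RegulatorGrouping | None = None

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))


@dataclass
class NullDistribution:
    """Permutation null importances for one target: B draws per regulator."""

    target: str
    draws: pd.DataFrame  # B rows x regulators

    def __post_init__(self) -> None:
        if len(self.draws) < 1:
            raise ValueError("need at least one permutation draw")
        if (self.draws.to_numpy() < 0).any():
            raise ValueError("null importances must be non-negative")

    @property
    def n_permutations(self) -> int:
        return len(self.draws)

    @property
    def regulators(self) -> list[str]:
        return list(self.draws.columns)


@dataclass
class TestedNetwork:
    """Prior edges with permutation p-values and BH-adjusted q-values.

    ``edges`` holds every tested prior edge; the final network is the subset
    with ``fdr <= fdr_threshold`` (:attr:`final_edges`). When testing was
    skipped, pvalue/fdr are NaN and all edges are final.
    """

    edges: pd.DataFrame  # columns EDGE_COLUMNS
    fdr_threshold: float
    n_permutations: int
    grouping: RegulatorGrouping | None = None

    def __post_init__(self) -> None:
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns {missing}")
        p = self.edges["pvalue"].to_numpy(dtype=float)
        finite = p[~np.isnan(p)]
        if ((finite <= 0) | (finite > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def tested(self) -> bool:
        # 0 permutations marks a skipped test stage (pvalues are NaN);
        # -1 marks an edge table read from disk with B unknown but p present
        return self.n_permutations != 0

    @property
    def final_edges(self) -> pd.DataFrame:
        if not self.tested:
            return self.edges
        return self.edges[self.edges["fdr"] <= self.fdr_threshold]

    @property
    def n_edges(self) -> int:
        return len(self.final_edges)

    def nodes(self) -> list[str]:
        e = self.final_edges
        return sorted(set(e["regulator"]) | set(e["target"]))


@dataclass(frozen=True)
class GoldStandard:
    """Externally validated regulator->target pairs (evaluation only)."""

    validated_pairs: frozenset[tuple[str, str]]
    informative_regulators: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "validated_pairs", frozenset(self.validated_pairs))
        object.__setattr__(
            self, "informative_regulators", frozenset(self.informative_regulators)
        )
        stray = {r for r, _ in self.validated_pairs} - self.informative_regulators
        if stray:
            raise ValueError(
                f"validated pairs reference regulators without validation info: {sorted(stray)}"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.validated_pairs)


@dataclass
class CommunityPartition:
    """Louvain module assignment for every network node."""

    labels: dict[str, int]
    modularity: float

    def __post_init__(self) -> None:
        if not -0.5 - 1e-12 <= self.modularity <= 1 + 1e-12:
            raise ValueError("modularity out of [-0.5, 1]")

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> list[str]:
        return sorted(g for g, c in self.labels.items() if c == label)


@dataclass
class SyntheticDataset:
    """Simulated counts with a planted regulator->target truth network."""

    counts: CountMatrix
    regulators: RegulatorSet
    truth: GoldStandard
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        stray = {r for r, _ in self.truth.validated_pairs} - set(
            self.regulators.regulator_ids
        )
        if stray:
            raise ValueError(f"truth pairs use unknown regulators: {sorted(stray)}")
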