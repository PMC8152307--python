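"""Model/Results facade over the inference pipeline.

:class:`GRNModel` bundles an expression matrix, a regulator list and a
:class:`~grnperm.config.RunConfig`; :meth:`GRNModel.fit` runs normalization,
regulator grouping, random-forest importance estimation, density-based edge
selection and permutation testing, and returns a :class:`GRNResults` holding
every intermediate product plus diagnostics, a text ``summary()``, topology
and community helpers, plotting, and exporters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, io
from .benchmark import precision as _precision
from .config import RunConfig
from .datatypes import (
    CountMatrix,
    GoldStandard,
    ImportanceMatrix,
    RegulatorGrouping,
    RegulatorSet,
    SizeFactors,
    TestedNetwork,
    WeightedNetwork,
)
from .inference import (
    group_correlated_regulators,
    infer_importances,
    select_edges_by_density,
)
from .normalization import log_transform, normalize
from .testing import TestingDiagnostics, refine_network, testing_diagnostics

__all__ = ["GRNModel", "GRNResults"]


class GRNModel:
    """Gene-regulatory-network model for one expression dataset.

    Parameters
    ----------
    counts : CountMatrix
        Raw (or already normalized) gene x sample expression.
    regulators : RegulatorSet or iterable of str
        Genes allowed outgoing edges; only those present in ``counts`` are
        used.
    config : RunConfig, optional
        All pipeline settings, including the global seed.
    """

    def __init__(self, counts, regulators, config: RunConfig | None = None):
        if not isinstance(counts, CountMatrix):
            counts = CountMatrix(values=pd.DataFrame(counts))
        if not isinstance(regulators, RegulatorSet):
            regulators = RegulatorSet(frozenset(regulators))
        if not regulators.regulator_ids:
            raise ValueError("regulator set is empty")
        self.counts = counts
        self.regulators = regulators
        self.config = config or RunConfig()

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        regulators_path: str | Path,
        config: RunConfig | None = None,
    ) -> "GRNModel":
        """Build a model from an expression table and a regulator list file."""
        return cls(
            io.read_expression_matrix(counts_path),
            RegulatorSet(io.read_regulators(regulators_path)),
            config=config,
        )

    def fit(self, skip_testing: bool = False, null_trees: int | None = None) -> "GRNResults":
        """Run the full pipeline and return the results object."""
        cfg = self.config
        if self.counts.normalized:
            normalized, factors = self.counts, None
        else:
            normalized, factors = normalize(
                self.counts,
                method=cfg.normalization_method,
                low_count_threshold=cfg.low_count_threshold,
            )
        rf_input = log_transform(normalized) if cfg.log_transform else normalized
        grouping = group_correlated_regulators(
            rf_input, self.regulators, rho=cfg.correlation_threshold
        )
        importances = infer_importances(
            rf_input, grouping, n_trees=cfg.n_trees, seed=cfg.seed
        )
        prior = select_edges_by_density(importances, cfg.density)
        tested = refine_network(
            prior,
            rf_input,
            grouping,
            B=cfg.n_permutations,
            n_trees=cfg.n_trees,
            fdr_threshold=cfg.fdr_threshold,
            seed=cfg.seed,
            skip_testing=skip_testing,
            null_trees=null_trees,
        )
        return GRNResults(
            model=self,
            normalized=normalized,
            size_factors=factors,
            grouping=grouping,
            importances=importances,
            prior=prior,
            network=tested,
        )


class GRNResults:
    """Fitted network with estimates, significance and diagnostics."""

    def __init__(
        self,
        model: GRNModel,
        normalized: CountMatrix,
        size_factors: SizeFactors | None,
        grouping: RegulatorGrouping,
        importances: ImportanceMatrix,
        prior: WeightedNetwork,
        network: TestedNetwork,
    ):
        self.model = model
        self.normalized = normalized
        self.size_factors = size_factors
        self.grouping = grouping
        self.importances = importances
        self.prior = prior
        self.network = network

    # -- tables ---------------------------------------------------------
    @property
    def edges(self) -> pd.DataFrame:
        """Final network edge table (regulator, target, importance, pvalue, fdr)."""
        return self.network.final_edges.reset_index(drop=True)

    def degree_table(self) -> pd.DataFrame:
        return analysis.degree_statistics(self.network)

    def communities(self, seed: int | None = None, weighted: bool = True):
        seed = self.model.config.seed if seed is None else seed
        return analysis.detect_communities(self.network, seed=seed, weighted=weighted)

    def module_profiles(self, partition=None) -> pd.DataFrame:
        partition = partition or self.communities()
        return analysis.module_profiles(self.network, partition, self.normalized)

    def diagnostics(self) -> TestingDiagnostics:
        return testing_diagnostics(self.network)

    def precision(self, gold: GoldStandard) -> float | None:
        return _precision(self.network, gold, self.grouping)

    # -- export ---------------------------------------------------------
    def to_edge_csv(self, path: str | Path, final_only: bool = True) -> None:
        io.write_network(self.network, path, format="edge_csv", final_only=final_only)

    def to_graphml(self, path: str | Path, final_only: bool = True) -> None:
        io.write_network(self.network, path, format="graphml", final_only=final_only)

    def node_table(self, seed: int | None = None) -> pd.DataFrame:
        """Per-node degrees and community labels (gene, in/out degree, community)."""
        table = self.degree_table()
        labels = self.communities(seed=seed).labels
        table["community"] = [labels[g] for g in table["gene"]]
        return table

    # -- plotting -------------------------------------------------------
    def plot_pvalue_histogram(self, ax=None, bins: int = 20):
        """Histogram of edge p-values (decision support for the FDR cut)."""
        import matplotlib.pyplot as plt

        diag = testing_diagnostics(self.network, bins=bins)
        if ax is None:
            _, ax = plt.subplots()
        centers = 0.5 * (diag.hist_edges[:-1] + diag.hist_edges[1:])
        ax.bar(centers, diag.hist_counts, width=np.diff(diag.hist_edges), edgecolor="k")
        ax.set_xlabel("empirical p-value")
        ax.set_ylabel("edges")
        return ax

    def plot_edges_vs_fdr(self, ax=None):
        """Final edge count as a function of the FDR cutoff."""
        import matplotlib.pyplot as plt

        diag = testing_diagnostics(self.network)
        if ax is None:
            _, ax = plt.subplots()
        ax.step(diag.fdr_grid, diag.n_edges, where="post")
        ax.axvline(self.network.fdr_threshold, ls="--", color="grey")
        ax.set_xlabel("FDR cutoff")
        ax.set_ylabel("edges kept")
        return ax

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        """Plain-text run summary (settings, sizes, top hubs)."""
        cfg = self.model.config
        net = self.network
        lines = [
            "Gene regulatory network inference results",
            "=" * 41,
            f"genes: {self.normalized.n_genes}   samples: {self.normalized.n_samples}",
            f"regulators: {sum(len(m) for m in self.grouping.groups.values())} "
            f"in {self.grouping.n_groups} groups "
            f"(Spearman > {cfg.correlation_threshold})",
            f"forest: {cfg.n_trees} trees, seed {cfg.seed}",
            f"prior network: density {self.prior.density} -> {self.prior.n_edges} edges",
        ]
        if net.tested:
            lines.append(
                f"testing: B={net.n_permutations} permutations, "
                f"FDR <= {net.fdr_threshold} -> {len(net.final_edges)} edges kept"
            )
        else:
            lines.append("testing: skipped (all prior edges kept)")
        table = self.degree_table().head(5)
        lines.append("top hubs (total degree):")
        for row in table.itertuples(index=False):
            lines.append(
                f"  {row.rank}. {row.gene} (in {row.in_degree}, out {row.out_degree})"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GRNResults: {len(self.network.final_edges)} edges over "
            f"{len(self.network.nodes())} nodes>"
        )
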