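"""Permutation-based significance testing of prior-network edges.

For every target gene in the prior network, the target's expression profile
is shuffled across samples B times; after each shuffle the same random-forest
specification used for inference is refitted, yielding one null importance
draw for every regulator of that target simultaneously. The empirical
p-value of an edge is the right-tail extremeness of its observed importance
within the null draws, with the standard add-one correction so p is never 0:

    p = (1 + #{b : null_b >= observed}) / (1 + B)

Benjamini-Hochberg adjustment is then applied jointly across all prior
edges, and the final network keeps the edges with adjusted p at or below the
FDR threshold.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._forest import forest_importances
from .datatypes import (
    CountMatrix,
    NullDistribution,
    RegulatorGrouping,
    TestedNetwork,
    WeightedNetwork,
)

__all__ = [
    "permutation_null",
    "empirical_pvalue",
    "bh_adjust",
    "refine_network",
    "testing_diagnostics",
    "TestingDiagnostics",
]

#: refuse permutation runs costing more than this many tree fits per target
DEFAULT_TREE_BUDGET = 10_000_000


def _null_rng(seed: int, target: str) -> np.random.Generator:
    # distinct stream per (seed, target); crc32 keeps entropy below 2**32
    return np.random.default_rng([int(seed), zlib.crc32(target.encode("utf-8")), 0x9E37])


def permutation_null(
    expr: CountMatrix,
    grouping: RegulatorGrouping,
    target: str,
    B: int = 100,
    n_trees: int = 1000,
    seed: int = 42,
    max_budget: int = DEFAULT_TREE_BUDGET,
) -> NullDistribution:
    """Null importance distribution of every regulator for one target.

    Each of the B shuffles permutes only the target's expression vector
    (predictors untouched), refits the inference forest, and records all
    regulators' importances — one shuffle is one joint null draw. Shuffles
    are drawn uniformly with replacement from the n! permutations; the
    identity permutation is not excluded.
    """
    if target not in expr.values.index:
        raise KeyError(f"target {target!r} not in the expression matrix")
    if B < 1:
        raise ValueError("need at least one permutation")
    if B * n_trees > max_budget:
        raise ValueError(
            f"permutation budget B*n_trees = {B * n_trees} exceeds {max_budget}; "
            "reduce B or the number of trees (a smaller null forest is fine)"
        )
    own = None
    for meta, members in grouping.groups.items():
        if target in members:
            own = meta
    predictors = [m for m in grouping.meta_ids if m != own]
    if not predictors:
        raise ValueError("no eligible predictors for this target")
    X = grouping.meta_profiles.loc[predictors, expr.sample_ids].to_numpy(dtype=float).T

    y = expr.values.loc[target].to_numpy(dtype=float)
    sd = y.std()
    draws = np.zeros((B, len(predictors)))
    if sd > 0:
        y = (y - y.mean()) / sd
        rng = _null_rng(seed, target)
        for b in range(B):
            perm = rng.permutation(y.shape[0])
            forest_seed = int(rng.integers(0, 2**31))
            draws[b] = forest_importances(X, y[perm], n_trees=n_trees, seed=forest_seed)
    # sd == 0: the observed importances were flagged to 0; every shuffle of a
    # constant vector is identical, so all null draws equal that 0 as well.
    return NullDistribution(target=target, draws=pd.DataFrame(draws, columns=predictors))


def empirical_pvalue(observed: float, nulls: np.ndarray) -> float:
    """Right-tail empirical p-value of an observed importance.

    p = (1 + #{null >= observed}) / (1 + B); ties count toward the tail and
    the add-one guard keeps p strictly positive, so p is in (0, 1].
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.count_nonzero(nulls >= observed)) / (1 + nulls.size))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending; adjusted_i = min over j >= i of m * p_(j) / j, capped at
    1; map back to the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def refine_network(
    prior: WeightedNetwork,
    expr: CountMatrix,
    grouping: RegulatorGrouping,
    B: int = 100,
    n_trees: int = 1000,
    fdr_threshold: float = 0.05,
    seed: int = 42,
    skip_testing: bool = False,
    null_trees: int | None = None,
    max_budget: int = DEFAULT_TREE_BUDGET,
) -> TestedNetwork:
    """Test every prior edge by permutation and keep those passing the FDR cut.

    One permutation batch per distinct target serves all of that target's
    prior edges; BH adjustment is applied jointly across all prior edges.
    ``null_trees`` lets the null forests use fewer trees than inference.
    With ``skip_testing`` the prior is returned untested (p-values NaN, all
    edges final).
    """
    if prior.n_edges == 0:
        raise ValueError("prior network is empty")
    edges = prior.edges.copy().reset_index(drop=True)
    if skip_testing:
        edges["pvalue"] = np.nan
        edges["fdr"] = np.nan
        return TestedNetwork(
            edges=edges, fdr_threshold=fdr_threshold, n_permutations=0,
            grouping=grouping,
        )
    if null_trees is None:
        null_trees = n_trees
    pvals = np.empty(len(edges))
    for target, idx in sorted(edges.groupby("target").groups.items()):
        nulls = permutation_null(
            expr, grouping, target, B=B, n_trees=null_trees, seed=seed,
            max_budget=max_budget,
        )
        for i in idx:
            reg = edges.at[i, "regulator"]
            pvals[i] = empirical_pvalue(
                edges.at[i, "importance"], nulls.draws[reg].to_numpy()
            )
    edges["pvalue"] = pvals
    edges["fdr"] = bh_adjust(pvals)
    return TestedNetwork(
        edges=edges, fdr_threshold=fdr_threshold, n_permutations=B, grouping=grouping
    )


@dataclass
class TestingDiagnostics:
    """Decision-support summaries of a tested network.

    ``hist_counts``/``hist_edges``: p-value histogram over (0, 1];
    ``fdr_grid``/``n_edges``: surviving-edge counts as a function of the FDR
    cutoff (non-decreasing in the cutoff).
    """

    hist_counts: np.ndarray
    hist_edges: np.ndarray
    fdr_grid: np.ndarray
    n_edges: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.fdr_grid, "n_edges": self.n_edges})


def testing_diagnostics(
    tested: TestedNetwork, bins: int = 20, grid: np.ndarray | None = None
) -> TestingDiagnostics:
    """P-value histogram and edge count versus FDR cutoff for a tested network."""
    if len(tested.edges) == 0:
        raise ValueError("tested network is empty")
    if not tested.tested:
        raise ValueError("network was not tested; no p-values to summarise")
    p = tested.edges["pvalue"].to_numpy(dtype=float)
    fdr = tested.edges["fdr"].to_numpy(dtype=float)
    counts, edges = np.histogram(p, bins=bins, range=(0.0, 1.0))
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    n_edges = np.array([(fdr <= c).sum() for c in grid])
    return TestingDiagnostics(
        hist_counts=counts, hist_edges=edges, fdr_grid=grid, n_edges=n_edges
    )
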