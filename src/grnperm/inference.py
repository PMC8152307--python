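"""GENIE3-style network inference: regulator grouping, random-forest
importances, and density-based prior edge selection.

For each target gene a random-forest regression predicts its (unit-variance
standardized) expression from the profiles of all meta-regulators not
containing the target; the impurity-reduction importance of each predictor is
the weight of the corresponding regulator->target edge. Highly
rank-correlated regulators are merged beforehand into meta-regulators
(connected components at a Spearman threshold, profile = member mean), which
stabilises the regression when regulators are nearly collinear. The prior
network keeps the top ``density`` fraction of all possible edges.
"""

from __future__ import annotations

import warnings
import zlib

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.stats import spearmanr

from ._forest import forest_importances
from .datatypes import (
    META_SEPARATOR,
    CountMatrix,
    ImportanceMatrix,
    RegulatorGrouping,
    RegulatorSet,
    WeightedNetwork,
)

__all__ = [
    "group_correlated_regulators",
    "infer_importances",
    "select_edges_by_density",
    "possible_edge_count",
]


def target_subseed(seed: int, target: str) -> int:
    """Stable per-target sub-seed: base seed plus a hash of the target ID."""
    return (int(seed) + zlib.crc32(target.encode("utf-8"))) % (2**31)


def group_correlated_regulators(
    expr: CountMatrix, regs: RegulatorSet, rho: float = 0.9
) -> RegulatorGrouping:
    """Merge regulators whose expression profiles are rank-correlated above ``rho``.

    An undirected graph joins two regulators when their Spearman correlation
    across all samples exceeds ``rho`` (strictly); connected components become
    meta-regulators whose profile is the arithmetic mean of member profiles.
    The meta-regulator ID is the lexicographically sorted member IDs joined by
    ``"-"``.
    """
    if rho <= 0:
        raise ValueError("correlation threshold must be positive")
    if rho > 1:
        raise ValueError("correlation threshold cannot exceed 1")
    members = regs.intersect(expr.gene_ids)
    if not members:
        raise ValueError("no regulator is present in the expression matrix")
    profiles = expr.values.loc[members]

    n = len(members)
    adj = np.zeros((n, n), dtype=bool)
    if n > 1:
        corr = spearmanr(profiles.to_numpy().T).statistic
        corr = np.atleast_2d(corr)
        with np.errstate(invalid="ignore"):
            adj = np.nan_to_num(corr, nan=0.0) > rho
        np.fill_diagonal(adj, False)
    _, labels = connected_components(adj, directed=False)

    groups: dict[str, list[str]] = {}
    rows = {}
    for comp in np.unique(labels):
        comp_members = sorted(np.array(members)[labels == comp])
        meta_id = META_SEPARATOR.join(comp_members)
        groups[meta_id] = comp_members
        rows[meta_id] = profiles.loc[comp_members].mean(axis=0)
    meta_profiles = pd.DataFrame(rows).T.loc[sorted(groups)]
    meta_profiles.columns = expr.sample_ids
    return RegulatorGrouping(groups=groups, meta_profiles=meta_profiles)


def infer_importances(
    expr: CountMatrix,
    grouping: RegulatorGrouping,
    n_trees: int = 1000,
    seed: int = 42,
) -> ImportanceMatrix:
    """Random-forest importance of every meta-regulator for every gene.

    Per target: the response is the target's expression standardized to unit
    variance; predictors are all meta-regulator profiles except any group
    containing the target; the forest uses ``n_trees`` fully grown trees with
    mtry = floor(sqrt(#predictors)). Importances of a regulator for its own
    member genes stay 0. Deterministic given (seed, n_trees): each target's
    forest is seeded by ``seed`` plus a stable hash of the target ID.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples to fit random forests")
    if grouping.n_groups < 2:
        raise ValueError("need at least 2 meta-regulators for inference")
    meta_ids = grouping.meta_ids
    member_of = {m: meta for meta, ms in grouping.groups.items() for m in ms}
    X_all = grouping.meta_profiles.loc[meta_ids, expr.sample_ids].to_numpy(dtype=float).T
    targets = expr.gene_ids
    w = pd.DataFrame(0.0, index=meta_ids, columns=targets)

    meta_pos = {m: i for i, m in enumerate(meta_ids)}
    for target in targets:
        y = expr.values.loc[target].to_numpy(dtype=float)
        sd = y.std()
        if sd == 0:
            warnings.warn(f"target {target!r} has zero variance; importances set to 0")
            continue
        y = (y - y.mean()) / sd
        own = member_of.get(target)
        cols = [i for m, i in meta_pos.items() if m != own]
        if len(cols) < 1:
            continue
        imp = forest_importances(
            X_all[:, cols], y, n_trees=n_trees, seed=target_subseed(seed, target)
        )
        w.loc[np.array(meta_ids)[cols], target] = imp
    return ImportanceMatrix(w=w, grouping=grouping)


def possible_edge_count(w: ImportanceMatrix) -> int:
    """Number of candidate regulator->target pairs (self pairs excluded).

    Counts ordered (meta-regulator, gene) pairs minus the pairs where the
    gene is a member of the meta-regulator's group.
    """
    grouping = w.grouping
    n_self = 0
    targets = set(w.targets)
    if grouping is not None:
        n_self = sum(
            1 for meta in w.regulators for g in grouping.groups.get(meta, []) if g in targets
        )
    else:
        n_self = sum(1 for r in w.regulators if r in targets)
    return len(w.regulators) * len(w.targets) - n_self


def select_edges_by_density(w: ImportanceMatrix, density: float) -> WeightedNetwork:
    """Keep the strongest edges down to the requested connectivity density.

    Exactly ``round(density * n_possible)`` pairs are kept, ranked by
    importance descending with ties broken by (regulator ID, target ID)
    lexicographic order. Pairs where the target belongs to the regulator's
    own group are never eligible.
    """
    if not 0 < density < 1:
        raise ValueError("density must lie in (0, 1)")
    n_possible = possible_edge_count(w)
    k = round(density * n_possible)
    if k < 1:
        raise ValueError(
            f"density {density} yields 0 edges out of {n_possible} candidates"
        )
    grouping = w.grouping
    long = w.w.stack()
    long.index.names = ["regulator", "target"]
    df = long.rename("importance").reset_index()
    if grouping is not None:
        self_pair = [
            t in grouping.groups.get(r, (r,))
            for r, t in zip(df["regulator"], df["target"])
        ]
    else:
        self_pair = (df["regulator"] == df["target"]).tolist()
    df = df[~np.array(self_pair)]
    df = df.sort_values(
        ["importance", "regulator", "target"], ascending=[False, True, True]
    ).head(k)
    return WeightedNetwork(
        edges=df.reset_index(drop=True), density=density, grouping=grouping
    )
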