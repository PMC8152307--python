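"""Synthetic expression data with a planted regulator->target truth network.

The generator emulates the kind of multi-condition expression compendium the
pipeline is designed for: independent regulator activities per sample, target
genes driven by a saturating (Hill-type) response to their planted
regulators, log-normal baselines, and per-sample sequencing-depth multipliers
that the normalization stage must undo. Values are continuous ("TPM-like"),
so the noiseless limit is an exactly monotone function of the regulators —
convenient for closed-form checks. ``effect_size=0`` yields the pure-null
generator used for p-value calibration.

Default scale: 20 regulators, 200 targets, 24 samples — a desk-scale stand-in
for a 24-condition perturbation compendium.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datatypes import CountMatrix, GoldStandard, RegulatorSet, SyntheticDataset

__all__ = [
    "simulate_truth",
    "simulate_expression",
    "simulate_dataset",
    "simulate_correlated_regulator_pair",
    "DEFAULTS",
]

#: study-condition defaults for the planted-signal simulator
DEFAULTS = dict(
    n_regulators=20,
    n_targets=200,
    n_samples=24,
    edges_per_target=2,
    effect_size=3.0,
    noise_sd=0.2,
)

#: mean log10 baseline expression and its spread across genes
_BASELINE_LOG_MEAN = np.log(100.0)
_BASELINE_LOG_SD = 1.0
#: library size columns are scaled to before depth multipliers
_LIBRARY_SIZE = 1e6


def _regulator_ids(n: int) -> list[str]:
    return [f"R{i:03d}" for i in range(1, n + 1)]


def _target_ids(n: int) -> list[str]:
    return [f"T{i:04d}" for i in range(1, n + 1)]


def simulate_truth(
    n_regulators: int, n_targets: int, edges_per_target: int, seed: int = 42
) -> GoldStandard:
    """Plant a sparse truth network: each target gets ``edges_per_target``
    distinct regulators drawn uniformly and independently."""
    if not 1 <= edges_per_target <= n_regulators:
        raise ValueError("edges_per_target must lie in [1, n_regulators]")
    if n_regulators < 1 or n_targets < 1:
        raise ValueError("need at least one regulator and one target")
    rng = np.random.default_rng(seed)
    regs = _regulator_ids(n_regulators)
    pairs = set()
    for tgt in _target_ids(n_targets):
        chosen = rng.choice(n_regulators, size=edges_per_target, replace=False)
        pairs.update((regs[j], tgt) for j in chosen)
    return GoldStandard(
        validated_pairs=frozenset(pairs), informative_regulators=frozenset(regs)
    )


def _hill(z: np.ndarray) -> np.ndarray:
    """Centered saturating response: Hill function of exp(z) with coefficient 2.

    exp(2z)/(exp(2z)+1) - 1/2, a strictly increasing sigmoid in (-1/2, 1/2).
    """
    return 1.0 / (1.0 + np.exp(-2.0 * z)) - 0.5


def simulate_expression(
    truth: GoldStandard,
    n_samples: int = 24,
    effect_size: float = 3.0,
    noise_sd: float = 0.2,
    seed: int = 42,
) -> SyntheticDataset:
    """Expression matrix realizing a planted truth network.

    Regulator log-activities are i.i.d. standard normal per sample; a
    target's log-expression is ``effect_size`` times the sum of Hill-type
    transforms of its regulators' activities plus Gaussian noise of sd
    ``noise_sd``. Log-normal gene baselines are added, columns are scaled to
    a common library size, then per-sample depth multipliers drawn
    log-uniformly in [0.5, 2] are applied so that normalization has real work
    to do. ``effect_size=0`` gives targets independent of regulators.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    regs = sorted(truth.informative_regulators)
    targets = sorted({t for _, t in truth.validated_pairs})
    parents: dict[str, list[str]] = {t: [] for t in targets}
    for r, t in sorted(truth.validated_pairs):
        parents[t].append(r)

    z = pd.DataFrame(
        rng.standard_normal((len(regs), n_samples)),
        index=regs,
        columns=[f"S{j:02d}" for j in range(1, n_samples + 1)],
    )
    log_expr = {r: z.loc[r].to_numpy() for r in regs}
    for t in targets:
        signal = effect_size * np.sum(
            [_hill(z.loc[r].to_numpy()) for r in parents[t]], axis=0
        )
        log_expr[t] = signal + noise_sd * rng.standard_normal(n_samples)

    genes = regs + targets
    baseline = _BASELINE_LOG_MEAN + _BASELINE_LOG_SD * rng.standard_normal(len(genes))
    mat = np.exp(
        np.array([log_expr[g] for g in genes]) + baseline[:, None]
    )
    # one global constant brings libraries to a realistic scale; the only
    # per-sample distortion is then the depth multiplier, which normalization
    # is expected to undo
    mat *= _LIBRARY_SIZE / mat.sum(axis=0).mean()
    depth = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_samples))
    mat *= depth[None, :]

    counts = CountMatrix(
        values=pd.DataFrame(mat, index=genes, columns=z.columns), normalized=False
    )
    params = dict(
        n_regulators=len(regs),
        n_targets=len(targets),
        n_samples=n_samples,
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=seed,
        depth_multipliers=depth,
    )
    return SyntheticDataset(
        counts=counts,
        regulators=RegulatorSet(frozenset(regs)),
        truth=truth,
        params=params,
    )


def simulate_dataset(
    n_regulators: int = DEFAULTS["n_regulators"],
    n_targets: int = DEFAULTS["n_targets"],
    n_samples: int = DEFAULTS["n_samples"],
    edges_per_target: int = DEFAULTS["edges_per_target"],
    effect_size: float = DEFAULTS["effect_size"],
    noise_sd: float = DEFAULTS["noise_sd"],
    seed: int = 42,
) -> SyntheticDataset:
    """One-call generator: plant a truth network, then realize expression."""
    truth = simulate_truth(n_regulators, n_targets, edges_per_target, seed=seed)
    ds = simulate_expression(
        truth,
        n_samples=n_samples,
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=seed + 1,
    )
    ds.params["edges_per_target"] = edges_per_target
    return ds


def simulate_correlated_regulator_pair(
    base: SyntheticDataset, rho_target: float = 0.9, seed: int = 42
) -> SyntheticDataset:
    """Add a near-duplicate of one regulator to exercise regulator grouping.

    The duplicate's counts are the source regulator's row with small
    log-normal jitter, shrunk until the Spearman correlation exceeds
    ``rho_target``; the source's truth pairs are copied to the duplicate
    (either member regulates the shared targets).
    """
    if rho_target >= 1:
        raise ValueError("rho_target must be < 1 (perfect correlation unreachable)")
    if rho_target <= 0:
        raise ValueError("rho_target must be positive")
    rng = np.random.default_rng(seed)
    source = sorted(base.regulators.regulator_ids)[0]
    dup = f"{source}dup"
    if dup in base.counts.gene_ids:
        raise ValueError(f"duplicate regulator {dup!r} already present")
    row = base.counts.values.loc[source].to_numpy(dtype=float)
    jitter = rng.standard_normal(row.size)
    sd = 0.5
    for _ in range(60):
        candidate = row * np.exp(sd * jitter)
        if spearmanr(candidate, row).statistic > rho_target:
            break
        sd *= 0.5
    else:
        raise RuntimeError(f"could not reach Spearman > {rho_target}")

    values = pd.concat(
        [base.counts.values, pd.DataFrame([candidate], index=[dup],
                                          columns=base.counts.sample_ids)]
    )
    counts = CountMatrix(values=values, normalized=base.counts.normalized)
    new_pairs = set(base.truth.validated_pairs)
    new_pairs.update((dup, t) for r, t in base.truth.validated_pairs if r == source)
    truth = GoldStandard(
        validated_pairs=frozenset(new_pairs),
        informative_regulators=frozenset(base.truth.informative_regulators | {dup}),
    )
    params = dict(base.params, duplicate_of=source, rho_target=rho_target)
    return SyntheticDataset(
        counts=counts,
        regulators=RegulatorSet(frozenset(base.regulators.regulator_ids | {dup})),
        truth=truth,
        params=params,
    )
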