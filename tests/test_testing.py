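import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnperm.inference import infer_importances, select_edges_by_density
from grnperm.testing import bh_adjust, empirical_pvalue, permutation_null, refine_network
from grnperm.testing import testing_diagnostics as compute_diagnostics


class TestEmpiricalPvalue:
    def test_observed_above_all_nulls(self):
        nulls = np.linspace(0, 0.5, 99)
        assert empirical_pvalue(0.9, nulls) == pytest.approx(1 / 100)

    def test_observed_tied_with_every_null(self):
        assert empirical_pvalue(0.3, np.full(4, 0.3)) == 1.0

    def test_hand_counted_middle_case(self):
        assert empirical_pvalue(0.25, np.array([0.1, 0.2, 0.3, 0.4])) == pytest.approx(
            3 / 5
        )

    def test_empty_nulls_error(self):
        with pytest.raises(ValueError):
            empirical_pvalue(0.5, np.array([]))

    @given(st.integers(1, 200), st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_always_in_unit_interval(self, b, seed):
        rng = np.random.default_rng(seed)
        nulls = rng.uniform(size=b)
        p = empirical_pvalue(float(rng.uniform()), nulls)
        assert 0 < p <= 1
        assert p >= 1 / (b + 1)


def _bh_bruteforce(p):
    """Literal step-up: adj_i = min_{j : p_j >= p_i-rank} (m p_(j) / j), capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        adj[order[i]] = min(1.0, min(m * sorted_p[j] / (j + 1) for j in range(i, m)))
    return adj


class TestBHAdjust:
    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.7]), [0.7])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 80))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), _bh_bruteforce(p), atol=1e-15)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestPermutationNull:
    def test_single_permutation_gives_length_one_arrays(
        self, planted_rf, planted_grouping
    ):
        nulls = permutation_null(
            planted_rf, planted_grouping, "T0001", B=1, n_trees=20, seed=0
        )
        assert nulls.n_permutations == 1
        assert nulls.draws.shape == (1, planted_grouping.n_groups)

    def test_constant_target_yields_degenerate_null(self, planted_grouping, planted_rf):
        from grnperm import CountMatrix

        values = planted_rf.values.copy()
        values.loc["T0001"] = 7.0
        cm = CountMatrix(values, normalized=True)
        nulls = permutation_null(cm, planted_grouping, "T0001", B=5, n_trees=20, seed=0)
        assert (nulls.draws.to_numpy() == 0).all()

    def test_budget_cap_enforced(self, planted_rf, planted_grouping):
        with pytest.raises(ValueError, match="budget"):
            permutation_null(
                planted_rf,
                planted_grouping,
                "T0001",
                B=1000,
                n_trees=1000,
                seed=0,
                max_budget=10_000,
            )

    def test_observed_within_null_span_on_null_data(self, rng):
        """Independent-target case: observed importances are unexceptional."""
        from grnperm import CountMatrix, RegulatorSet
        from grnperm.inference import group_correlated_regulators

        genes = [f"R{i}" for i in range(8)] + ["tgt"]
        cm = CountMatrix(
            pd.DataFrame(
                rng.uniform(1, 10, size=(9, 24)), index=genes,
                columns=[f"s{j}" for j in range(24)],
            ),
            normalized=True,
        )
        g = group_correlated_regulators(cm, RegulatorSet(frozenset(genes[:-1])), 0.95)
        w = infer_importances(cm, g, n_trees=100, seed=1)
        nulls = permutation_null(cm, g, "tgt", B=200, n_trees=100, seed=2)
        inside = 0
        for reg in nulls.regulators:
            obs = w.w.loc[reg, "tgt"]
            lo, hi = nulls.draws[reg].min(), nulls.draws[reg].max()
            inside += lo <= obs <= hi
        assert inside / len(nulls.regulators) >= 0.95


@pytest.fixture(scope="module")
def tested_small(planted_rf, planted_grouping):
    w = infer_importances(planted_rf, planted_grouping, n_trees=100, seed=9)
    prior = select_edges_by_density(w, 0.08)
    tested = refine_network(
        prior, planted_rf, planted_grouping,
        B=49, n_trees=100, fdr_threshold=0.05, seed=9,
    )
    return prior, tested


class TestRefineNetwork:
    def test_fdr_one_keeps_whole_prior(self, tested_small):
        prior, tested = tested_small
        relaxed = tested.edges[tested.edges["fdr"] <= 1.0]
        assert len(relaxed) == prior.n_edges
        assert set(zip(relaxed["regulator"], relaxed["target"])) == prior.edge_set()

    def test_bh_applied_jointly_over_prior_edges(self, tested_small):
        _, tested = tested_small
        np.testing.assert_allclose(
            tested.edges["fdr"], bh_adjust(tested.edges["pvalue"]), atol=1e-15
        )

    def test_threshold_monotonicity(self, tested_small):
        _, tested = tested_small
        kept_strict = set(
            map(tuple, tested.edges[tested.edges["fdr"] <= 0.01][["regulator", "target"]].to_numpy())
        )
        kept_loose = set(
            map(tuple, tested.edges[tested.edges["fdr"] <= 0.2][["regulator", "target"]].to_numpy())
        )
        assert kept_strict <= kept_loose

    def test_skip_testing_returns_untested_prior(
        self, planted_rf, planted_grouping, tested_small
    ):
        prior, _ = tested_small
        skipped = refine_network(
            prior, planted_rf, planted_grouping, skip_testing=True
        )
        assert not skipped.tested
        assert len(skipped.final_edges) == prior.n_edges
        assert skipped.edges["pvalue"].isna().all()

    def test_bit_reproducible_given_seed(
        self, planted_rf, planted_grouping, tested_small
    ):
        prior, tested = tested_small
        again = refine_network(
            prior, planted_rf, planted_grouping,
            B=49, n_trees=100, fdr_threshold=0.05, seed=9,
        )
        pd.testing.assert_frame_equal(tested.edges, again.edges)

    def test_planted_edges_retained_decoys_removed(self):
        """A prior of strong planted edges plus arbitrary decoy pairs: testing
        keeps every planted edge and removes at least half the decoys."""
        from grnperm import WeightedNetwork
        from grnperm.normalization import log_transform, normalize
        from grnperm.inference import group_correlated_regulators
        from grnperm.synthetic import simulate_dataset

        ds = simulate_dataset(
            n_regulators=10, n_targets=40, n_samples=24, edges_per_target=1, seed=21
        )
        norm, _ = normalize(ds.counts, method="tmm", low_count_threshold=0)
        rf = log_transform(norm)
        grouping = group_correlated_regulators(rf, ds.regulators, 0.9)
        w = infer_importances(rf, grouping, n_trees=100, seed=21)
        truth = sorted(ds.truth.validated_pairs)
        rng = np.random.default_rng(0)
        regs = sorted(ds.regulators.regulator_ids)
        decoys = []
        for reg, tgt in truth:  # one wrong-regulator decoy per target
            wrong = regs[(regs.index(reg) + 1 + rng.integers(8)) % len(regs)]
            decoys.append((wrong, tgt))
        edges = pd.DataFrame(
            [(r, t, w.w.loc[r, t]) for r, t in truth + decoys],
            columns=["regulator", "target", "importance"],
        ).sort_values("importance", ascending=False, ignore_index=True)
        prior = WeightedNetwork(edges=edges, density=0.05, grouping=grouping)
        tested = refine_network(
            prior, rf, grouping, B=99, n_trees=100, fdr_threshold=0.05, seed=4
        )
        final = set(zip(tested.final_edges["regulator"], tested.final_edges["target"]))
        assert set(truth) <= final
        removed = [d for d in decoys if d not in final]
        assert len(removed) / len(decoys) >= 0.5


class TestDiagnostics:
    def test_curve_monotone_and_total_at_one(self, tested_small):
        _, tested = tested_small
        diag = compute_diagnostics(tested)
        assert (np.diff(diag.n_edges) >= 0).all()
        assert diag.n_edges[-1] == len(tested.edges)
        assert diag.hist_counts.sum() == len(tested.edges)

    def test_curve_matches_bruteforce_refilter(self, tested_small, rng):
        _, tested = tested_small
        cutoffs = rng.uniform(0, 1, 5)
        diag = compute_diagnostics(tested, grid=cutoffs)
        for c, n in zip(diag.fdr_grid, diag.n_edges):
            assert n == (tested.edges["fdr"] <= c).sum()
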