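"""Gain-loss CTMC: transition kernel, pruning likelihood, marginals, fitting."""

import numpy as np
import pandas as pd
import pytest

from defenseflux import simulate
from defenseflux.gainloss import (
    DegenerateDataError,
    GainLossModel,
    GainLossParams,
    fit_gain_loss,
    reconstruct_marginals,
    transition_matrix,
)
from defenseflux.tree import read_newick

from conftest import enumeration_likelihood_and_marginals, random_tree, trait_matrix


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        assert np.allclose(transition_matrix(0.7, 1.3, 0.0), np.eye(2))

    def test_long_time_reaches_stationary(self):
        p = transition_matrix(1.0, 1.0, 50.0)
        assert np.allclose(p, 0.5, atol=1e-12)

    def test_closed_form_value(self):
        # g = l = 1, t = ln 2: P01 = 0.5 * (1 - e^{-2 ln 2}) = 0.375
        p = transition_matrix(1.0, 1.0, np.log(2.0))
        assert p[0, 1] == pytest.approx(0.375, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(1.0, 1.0, -0.1)

    def test_rows_sum_to_one_on_grid(self):
        for g in (1e-4, 0.3, 2.0, 50.0):
            for l in (1e-4, 0.7, 5.0):
                for t in (0.0, 1e-6, 0.1, 1.0, 100.0):
                    p = transition_matrix(g, l, t)
                    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
                    assert (p >= 0).all()


class TestLogLikelihood:
    def test_single_tip_observed_with_certain_prior(self):
        tree = read_newick("(A:1.0,B:1.0);")
        mat = trait_matrix(tree, {"T": np.array([1, 1])})
        model = GainLossModel(tree, mat, root_prior=1.0)
        # loss -> 0: present stays present, P(data) -> 1
        ll = model.loglike(GainLossParams(1.0, 1e-6, 1.0))
        assert ll == pytest.approx(0.0, abs=1e-4)

    def test_nothing_to_gain_likelihood_one(self):
        tree = read_newick("((A:1,B:1):0.5,C:2);")
        mat = trait_matrix(tree, {"T": np.zeros(3, dtype=int)})
        model = GainLossModel(tree, mat, root_prior=0.0)
        ll = model.loglike(GainLossParams(1e-6, 1.0, 0.0))
        assert ll == pytest.approx(0.0, abs=1e-4)

    def test_matches_enumeration_on_random_small_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            tree = random_tree(rng, int(rng.integers(3, 7)))
            tips = rng.integers(0, 2, tree.n_tips)
            g, l = rng.uniform(0.05, 3.0, size=2)
            pi = rng.uniform(0.0, 1.0)
            mat = trait_matrix(tree, {"T": tips})
            model = GainLossModel(tree, mat, root_prior=pi)
            ll = model.loglike(GainLossParams(g, l, pi))
            total, _ = enumeration_likelihood_and_marginals(tree, tips, g, l, pi)
            assert ll == pytest.approx(np.log(total), abs=1e-9)

    def test_invariant_under_tip_relabeling(self):
        rng = np.random.default_rng(5)
        tree = random_tree(rng, 6)
        tips = np.array([0, 1, 1, 0, 1, 0])
        mat = trait_matrix(tree, {"T": tips})
        params = GainLossParams(0.4, 0.9, 0.3)
        ll = GainLossModel(tree, mat, root_prior=0.3).loglike(params)
        # rename tips but keep the (tree position, state) pairing
        from defenseflux.tree import PhyloTree

        new_names = iter("UVWXYZ")
        labels = [None if lab is None else next(new_names) for lab in tree.labels]
        tree2 = PhyloTree(tree.parent, tree.lengths, labels)
        mat2 = pd.DataFrame({"T": tips}, index=tree2.tip_labels)
        ll2 = GainLossModel(tree2, mat2, root_prior=0.3).loglike(params)
        assert ll2 == pytest.approx(ll, abs=1e-12)

    def test_missing_tip_state_is_input_error(self, three_tip):
        mat = pd.DataFrame({"T": [1, 0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="missing"):
            GainLossModel(three_tip, mat)


class TestMarginals:
    def test_constant_present_trait_gives_confident_internal_nodes(self):
        rng = np.random.default_rng(1)
        tree = random_tree(rng, 4)
        mat = trait_matrix(tree, {"T": np.ones(4, dtype=int)})
        probs = reconstruct_marginals(tree, mat, GainLossParams(1.0, 0.01, 0.99))
        internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
        assert (probs.loc[internal, "T"] > 0.99).all()

    def test_two_tip_symmetry_gives_half_at_root(self):
        tree = read_newick("(A:1.0,B:1.0);")
        mat = trait_matrix(tree, {"T": np.array([1, 0])})
        probs = reconstruct_marginals(tree, mat, GainLossParams(1.0, 1.0, 0.5))
        assert probs.loc[0, "T"] == pytest.approx(0.5, abs=1e-12)

    def test_tips_keep_observed_states_exactly(self):
        rng = np.random.default_rng(2)
        tree = random_tree(rng, 6)
        tips = rng.integers(0, 2, 6)
        mat = trait_matrix(tree, {"T": tips})
        probs = reconstruct_marginals(tree, mat, GainLossParams(0.5, 0.5, 0.5))
        assert np.array_equal(probs.loc[tree.tip_ids, "T"].to_numpy(), tips)

    def test_matches_enumeration_posteriors(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            tree = random_tree(rng, int(rng.integers(3, 7)))
            tips = rng.integers(0, 2, tree.n_tips)
            g, l = rng.uniform(0.05, 3.0, size=2)
            pi = rng.uniform(0.0, 1.0)
            mat = trait_matrix(tree, {"T": tips})
            probs = reconstruct_marginals(tree, mat, GainLossParams(g, l, pi))
            _, marg = enumeration_likelihood_and_marginals(tree, tips, g, l, pi)
            for v, expected in marg.items():
                assert probs.loc[v, "T"] == pytest.approx(expected, abs=1e-9)


class TestFit:
    def test_recovers_simulation_rates_within_quarter(self):
        cfg = simulate.SimulationConfig(
            n_tips=200, n_accessory_ogs=500, seed=11, effect_multiplier=1.0,
            n_defense_systems=1, base_gain_rate=0.5, og_loss_rate=1.0, islands=(),
        )
        ds = simulate.simulate_dataset(cfg)
        res = fit_gain_loss(ds.tree, ds.matrix)
        assert res.gain_rate == pytest.approx(0.5, rel=0.25)
        assert res.loss_rate == pytest.approx(1.0, rel=0.25)
        assert res.converged

    def test_all_constant_matrix_is_degenerate(self, three_tip):
        mat = trait_matrix(three_tip, {"T1": np.ones(3), "T2": np.ones(3)})
        with pytest.raises(DegenerateDataError):
            fit_gain_loss(three_tip, mat)

    def test_symmetric_data_gives_equal_rates(self):
        tree = simulate.simulate_tree(100, seed=3)
        rng = np.random.default_rng(5)
        cols = {}
        for j in range(80):
            s = simulate.simulate_binary_trait(tree, 1.0, 1.0, 0.5, rng)
            cols[f"A{j}"] = s[tree.tip_ids]
            cols[f"B{j}"] = 1 - s[tree.tip_ids]
        res = fit_gain_loss(tree, trait_matrix(tree, cols))
        assert res.gain_rate == pytest.approx(res.loss_rate, rel=1e-3)

    def test_recovery_error_shrinks_with_tree_size(self):
        med = {}
        for n in (100, 400):
            errs = []
            for s in range(2):
                cfg = simulate.SimulationConfig(
                    n_tips=n, n_accessory_ogs=300, seed=40 + s, effect_multiplier=1.0,
                    n_defense_systems=1, base_gain_rate=0.5, og_loss_rate=1.0, islands=(),
                )
                ds = simulate.simulate_dataset(cfg)
                res = fit_gain_loss(ds.tree, ds.matrix)
                errs.append(
                    max(abs(res.gain_rate - 0.5) / 0.5, abs(res.loss_rate - 1.0) / 1.0)
                )
            med[n] = np.median(errs)
        assert med[400] < med[100]

    def test_serialized_states_round_trip(self, tmp_path):
        cfg = simulate.SimulationConfig(
            n_tips=20, n_accessory_ogs=10, seed=6, n_defense_systems=1, islands=(),
        )
        ds = simulate.simulate_dataset(cfg)
        res = fit_gain_loss(ds.tree, ds.matrix)
        out = tmp_path / "states.tsv"
        res.to_tsv(out)
        tidy = pd.read_csv(out, sep="\t")
        assert set(tidy.columns) == {"trait_id", "node_id", "probability"}
        wide = tidy.pivot(index="node_id", columns="trait_id", values="probability")
        direct = res.ancestral_probabilities()
        assert np.allclose(wide[direct.columns].to_numpy(), direct.to_numpy(), atol=1e-6)
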