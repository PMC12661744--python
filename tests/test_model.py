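"""Model specification, sampler correctness, convergence diagnostics."""

import json
from dataclasses import replace

import numpy as np
import pytest

from nmasplit import (
    MCMCSettings,
    PriorSpec,
    gelman_rubin,
    run_all_nodes,
    run_node_split,
    specify_model,
)
from nmasplit.geometry import SplitNode, build_network, enumerate_split_nodes
from nmasplit.model import _NodeSplitSampler

from conftest import REFERENCE_DIR, make_dataset


def ess(draws_by_chain: np.ndarray) -> float:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        return float(az.ess(draws_by_chain))


def mcse(pooled: np.ndarray, n_chains: int = 3) -> float:
    by_chain = pooled.reshape(n_chains, -1)
    return float(pooled.std(ddof=1) / np.sqrt(ess(by_chain)))


class TestSpecifyModel:
    def test_triangle_split_structure(self, triangle_dataset):
        node = SplitNode(("A", "B"), 2, False)
        spec = specify_model(triangle_dataset, node)
        # theta = (d[B], d[C], d_dir); reference A
        assert spec.n_params == 3
        assert spec.reference == "A"
        assert spec.direct_coord == 2
        assert spec.x_coord == -1 and spec.y_coord == 0  # d_ind = d[B] - 0
        # the two A-B studies load only on d_dir
        direct_rows = spec.X[:, 2] == 1.0
        assert direct_rows.sum() == 2
        assert np.all(spec.X[direct_rows][:, :2] == 0.0)
        # B-C studies load d[B] with -1 (baseline B) and d[C] with +1
        assert "d_dir" in spec.describe() or "free d_dir" in spec.describe()

    def test_two_arm_only_rows_are_signed_indicators(self, triangle_dataset):
        node = SplitNode(("B", "C"), 2, False)
        spec = specify_model(triangle_dataset, node)
        assert np.all(np.isin(spec.X, (-1.0, 0.0, 1.0)))
        assert np.all(spec.k_by_study == 1)

    def test_multiarm_block_dimensions(self, multiarm_plus_edge_dataset):
        node = SplitNode(("A", "B"), 1, True)
        spec = specify_model(multiarm_plus_edge_dataset, node)
        assert sorted(spec.k_by_study.tolist()) == [1, 2]
        # the three-arm study stays on the consistency side: no d_dir load
        three_arm_rows = spec.X[np.repeat(spec.k_by_study, spec.k_by_study) == 2]
        assert np.all(three_arm_rows[:, spec.direct_coord] == 0.0)

    def test_unsplittable_node_rejected(self, multiarm_plus_edge_dataset):
        with pytest.raises(ValueError, match="not splittable"):
            specify_model(
                multiarm_plus_edge_dataset, SplitNode(("A", "C"), 1, True)
            )


class TestPriorStructure:
    def test_multiarm_quadratic_form_matches_dense_inverse(
        self, multiarm_plus_edge_dataset
    ):
        # the sampler's O(k) quadratic form must equal r' Sigma^-1 r tau^2
        # for Sigma = tau^2/2 (I + J), checked against a dense inverse
        node = SplitNode(("A", "B"), 1, True)
        spec = specify_model(multiarm_plus_edge_dataset, node)
        rng = np.random.default_rng(0)
        sampler = _NodeSplitSampler(spec, PriorSpec(), rng)
        resid = rng.standard_normal(len(spec.nb_events))
        got = sampler._prior_quad_by_study(resid)
        expected = []
        for i, sl in enumerate(sampler.block):
            k = spec.k_by_study[i]
            sigma = 0.5 * (np.eye(k) + np.ones((k, k)))  # tau^2 factored out
            r = resid[sl]
            expected.append(r @ np.linalg.inv(sigma) @ r)
        assert np.allclose(got, expected, atol=1e-10)

    def test_prior_spec_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(effect_prior_sd=0.0)
        with pytest.raises(ValueError):
            PriorSpec(tau2_family="gamma")
        with pytest.raises(ValueError):
            PriorSpec(tau2_family="halfnormal", tau2_params=(1.0, 2.0))
        spec = PriorSpec.empirical("pharma_vs_placebo", "semi_objective")
        assert spec.tau2_params == (-2.56, 1.74)

    def test_mcmc_settings_validation(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_chains=1)
        with pytest.raises(ValueError):
            MCMCSettings(burn_in=30_000)
        with pytest.raises(ValueError):
            MCMCSettings(thin=0)
        assert MCMCSettings().n_kept == 1800


class TestGelmanRubin:
    def test_converged_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = [rng.standard_normal(10_000) for _ in range(3)]
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(2)
        chains = [rng.standard_normal(500), 10 + rng.standard_normal(500)]
        assert gelman_rubin(chains) > 5.0

    def test_matches_textbook_formula_oracle(self):
        x = np.arange(40, dtype=float).reshape(2, 20) ** 1.3  # fixed array
        m, n = x.shape
        within = np.mean([np.var(c, ddof=1) for c in x])
        means = x.mean(axis=1)
        b_over_n = np.var(means, ddof=1)
        oracle = np.sqrt(((n - 1) / n * within + b_over_n) / within)
        assert gelman_rubin(list(x)) == pytest.approx(oracle, abs=1e-12)

    def test_split_variant_detects_drift(self):
        trend = np.linspace(0, 5, 2000)
        rng = np.random.default_rng(3)
        chains = [trend + 0.1 * rng.standard_normal(2000) for _ in range(2)]
        assert gelman_rubin(chains, method="classic") < 1.05
        assert gelman_rubin(chains, method="split") > 1.5

    def test_error_contracts(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.zeros(100)])
        with pytest.raises(ValueError):
            gelman_rubin([np.zeros(100), np.zeros(50)])
        with pytest.raises(ValueError):
            gelman_rubin([np.zeros(5), np.zeros(5)])


class TestRunNodeSplit:
    def test_null_recovery_on_consistent_fixture(
        self, reference_dataset, quick_mcmc
    ):
        node = SplitNode(("A", "B"), 2, False)
        res = run_node_split(reference_dataset, node, mcmc=quick_mcmc)
        assert res.inconsistency_factor.q025 < 0 < res.inconsistency_factor.q975
        assert res.converged and res.max_rhat < 1.1
        # IF is the per-draw difference, so its mean matches the difference
        # of means up to floating error
        assert res.inconsistency_factor.mean == pytest.approx(
            res.direct.mean - res.indirect.mean, abs=1e-10
        )
        assert res.kld is not None and res.kld.index >= 0

    def test_deterministic_given_seed(self, reference_dataset, quick_mcmc):
        node = SplitNode(("A", "B"), 2, False)
        a = run_node_split(reference_dataset, node, mcmc=quick_mcmc)
        b = run_node_split(reference_dataset, node, mcmc=quick_mcmc)
        assert a == b

    def test_seed_to_seed_agreement_within_mc_error(
        self, reference_dataset, quick_mcmc
    ):
        node = SplitNode(("A", "B"), 2, False)
        a = run_node_split(reference_dataset, node, mcmc=quick_mcmc,
                           keep_draws=True)
        b = run_node_split(
            reference_dataset, node, mcmc=replace(quick_mcmc, seed=987),
            keep_draws=True,
        )
        for name, attr in [("if_", "inconsistency_factor"), ("tau", "tau")]:
            tol = 3 * np.hypot(mcse(a.draws[name]), mcse(b.draws[name]))
            diff = abs(getattr(a, attr).mean - getattr(b, attr).mean)
            assert diff < tol, (name, diff, tol)

    def test_agrees_with_recorded_jags_reference(self, reference_dataset):
        """Independent cross-check: same model, same priors, JAGS sampler.

        The reference posteriors (frozen from an rjags run of
        tests/reference/jags_nodesplit.R at the default chain geometry)
        must agree with this sampler within 3 combined Monte-Carlo SEs.
        """
        ref = json.loads((REFERENCE_DIR / "jags_reference.json").read_text())
        node = SplitNode(("A", "B"), 2, False)
        res = run_node_split(
            reference_dataset, node, mcmc=MCMCSettings(seed=31), keep_draws=True
        )
        pairs = [("direct", "ddir"), ("indirect", "dind"), ("if_", "IF"),
                 ("tau", "tau")]
        attr = {"direct": "direct", "indirect": "indirect",
                "if_": "inconsistency_factor", "tau": "tau"}
        for mine, theirs in pairs:
            tol = 3 * np.hypot(ref[theirs]["ts_se"], mcse(res.draws[mine]))
            diff = abs(getattr(res, attr[mine]).mean - ref[theirs]["mean"])
            assert diff < tol, (theirs, diff, tol)
            assert getattr(res, attr[mine]).sd == pytest.approx(
                ref[theirs]["sd"], rel=0.15
            )

    def test_label_invariance_flips_if_sign(self, reference_dataset, quick_mcmc):
        # swapping the A and B labels reverses the comparison direction:
        # |IF| and the index are unchanged within Monte-Carlo error
        node = SplitNode(("A", "B"), 2, False)
        a = run_node_split(reference_dataset, node, mcmc=quick_mcmc,
                           keep_draws=True)
        df = reference_dataset.frame
        swap = {"A": "B", "B": "A", "C": "C"}
        ds2 = make_dataset(
            [(r.study, swap[r.treatment], r.events, r.sample_size)
             for r in df.itertuples(index=False)]
        )
        b = run_node_split(ds2, node, mcmc=quick_mcmc, keep_draws=True)
        tol = 3 * np.hypot(mcse(a.draws["if_"]), mcse(b.draws["if_"]))
        assert abs(
            a.inconsistency_factor.mean + b.inconsistency_factor.mean
        ) < tol
        assert a.kld.index == pytest.approx(b.kld.index, abs=0.2)


class TestRunAllNodes:
    def test_triangle_yields_three_results(self, triangle_dataset):
        mcmc = MCMCSettings(n_chains=2, n_iter=1500, burn_in=500, thin=2, seed=5)
        results = run_all_nodes(triangle_dataset, mcmc=mcmc)
        assert [r.node.comparison for r in results] == [
            ("A", "B"), ("A", "C"), ("B", "C")
        ]
        assert all(r.kld is not None for r in results)

    def test_star_yields_empty_with_warning(self, star_dataset, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="nmasplit"):
            assert run_all_nodes(star_dataset) == []
        assert "no split nodes" in caplog.text

    def test_rerun_is_bitwise_identical(self, triangle_dataset, tmp_path):
        from nmasplit import write_results_table

        mcmc = MCMCSettings(n_chains=2, n_iter=1500, burn_in=500, thin=2, seed=5)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_results_table(run_all_nodes(triangle_dataset, mcmc=mcmc), p1)
        write_results_table(run_all_nodes(triangle_dataset, mcmc=mcmc), p2)
        assert p1.read_bytes() == p2.read_bytes()
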