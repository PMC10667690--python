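"""Mixed-model engine: design building, EM-REML, Henderson solutions,
heritability and reliability, checked against independent dense oracles."""

import numpy as np
import pandas as pd
import pytest

from agscreen import (
    InputDataError,
    MixedModel,
    VarianceComponents,
    build_design,
    heritability,
    reliability,
    reml_fit,
    solve_mme,
)
from agscreen.lmm import reml_loglik_dense
from agscreen.phenotypes import plots_to_traits
from agscreen.simulate import TrialSimulator

from conftest import small_config, toy_trait_table


def random_instance(rng, with_kinship=True, max_obs=30):
    """A small random mixed-model instance with an optional marker kinship."""
    n_g = int(rng.integers(3, 9))
    n_obs = int(rng.integers(n_g + 4, max_obs + 1))
    X = np.column_stack([np.ones(n_obs), rng.normal(size=(n_obs, 2))])
    Z = np.zeros((n_obs, n_g))
    assign = np.concatenate(
        [np.arange(n_g), rng.integers(0, n_g, n_obs - n_g)]
    )
    Z[np.arange(n_obs), assign] = 1.0
    K = None
    W = None
    if with_kinship:
        m = int(rng.integers(20, 201))
        W = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n_g, m)).astype(float)
        p = W.mean(axis=0) / 2.0
        W = W - 2.0 * p
        denom = 2.0 * np.sum(p * (1.0 - p))
        K = W @ W.T / denom
        W = (W, denom)
    y = rng.normal(size=n_obs)
    s2g = float(rng.uniform(0.5, 4.0))
    s2e = float(rng.uniform(0.5, 2.0))
    return X, Z, y, K, W, s2g, s2e


def gls_oracle(X, Z, y, K, s2g, s2e):
    """Direct dense GLS / conditional-expectation computation via V."""
    Kmat = np.eye(Z.shape[1]) if K is None else K
    V = s2g * Z @ Kmat @ Z.T + s2e * np.eye(len(y))
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = s2g * Kmat @ Z.T @ Vi @ (y - X @ beta)
    return beta, u


class TestBuildDesign:
    def test_dimension_arithmetic_without_blocks(self):
        table = toy_trait_table(n_genotypes=3, n_reps=2)
        d = build_design(table, scope="sea")
        assert d.X.shape == (6, 2)  # intercept + one replication contrast
        assert d.Z.shape == (6, 3)

    def test_block_labels_reused_across_replications_get_distinct_columns(self):
        table = toy_trait_table(n_genotypes=4, n_reps=2, blocks=True)
        d = build_design(table, scope="sea")
        block_cols = [n for n in d.fixed_names if n.startswith("block")]
        # blocks b1/b2 reused in r1 and r2: one dropped level per replication
        assert len(block_cols) == 2
        assert {"block[r1:b2]", "block[r2:b2]"} == set(block_cols)

    def test_mea_has_single_environment_contrast(self):
        rows = []
        for cond in ("anaerobic", "aerobic"):
            for r in ("r1", "r2"):
                for g in ("g1", "g2", "g3"):
                    rows.append(("e1", cond, r, None, g, "t", 1.0))
        table = pd.DataFrame(rows, columns=[
            "experiment", "condition", "replication", "block",
            "genotype", "trait", "value"])
        d = build_design(table, scope="mea")
        env_cols = [n for n in d.fixed_names if n.startswith("condition")]
        assert len(env_cols) == 1

    def test_missing_responses_dropped_and_counted(self):
        table = toy_trait_table(n_genotypes=4, n_reps=2)
        table.loc[table.index[2], "value"] = np.nan
        d = build_design(table, scope="sea")
        assert d.n_dropped == 1
        assert len(d.y) == 7

    def test_mixed_conditions_rejected_for_sea(self):
        table = toy_trait_table(4, 2)
        table.loc[table.index[:2], "condition"] = "aerobic"
        with pytest.raises(InputDataError):
            build_design(table, scope="sea")


class TestREML:
    def test_optimum_beats_random_grid(self):
        # independent dense-V restricted likelihood as objective oracle
        rng = np.random.default_rng(5)
        X, Z, y, K, _, s2g, s2e = random_instance(rng, with_kinship=False)
        y = (Z @ rng.normal(0, 2.0, Z.shape[1])) + rng.normal(0, 1.0, len(y)) + X @ [5.0, 1.0, -1.0]
        vc = reml_fit(X, Z, y, K=None)
        Kmat = np.eye(Z.shape[1])
        best = reml_loglik_dense(
            X, y, vc.sigma2_g * Z @ Kmat @ Z.T + vc.sigma2_e * np.eye(len(y))
        )
        for _ in range(100):
            g, e = rng.uniform(0.01, 10.0, 2)
            ll = reml_loglik_dense(X, y, g * Z @ Kmat @ Z.T + e * np.eye(len(y)))
            assert best >= ll - 1e-6

    def test_variance_recovery_in_balanced_trial(self):
        # true sigma2_g = 4, sigma2_e = 1; 200 genotypes x 2 replications
        errs_g, errs_e = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            u = rng.normal(0, 2.0, 200)
            rows = []
            for r in ("r1", "r2"):
                for i in range(200):
                    rows.append(("e1", "anaerobic", r, None, f"g{i:03d}",
                                 "t", 10.0 + u[i] + rng.normal(0, 1.0)))
            table = pd.DataFrame(rows, columns=[
                "experiment", "condition", "replication", "block",
                "genotype", "trait", "value"])
            d = build_design(table, scope="sea")
            vc = reml_fit(d.X, d.Z, d.y)
            errs_g.append(vc.sigma2_g)
            errs_e.append(vc.sigma2_e)
        assert np.mean(errs_g) == pytest.approx(4.0, rel=0.25)
        assert np.mean(errs_e) == pytest.approx(1.0, rel=0.25)

    def test_constant_response_hits_boundary_with_flag(self):
        table = toy_trait_table(4, 2, values=[7.0] * 8)
        d = build_design(table, scope="sea")
        vc = reml_fit(d.X, d.Z, d.y)
        assert vc.boundary
        assert vc.sigma2_g <= 1e-9

    def test_loglik_trace_nondecreasing(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            X, Z, y, K, _, _, _ = random_instance(rng)
            y = y + Z @ rng.normal(0, 1.5, Z.shape[1])
            vc = reml_fit(X, Z, y, K=K)
            trace = np.asarray(vc.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-8 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_shift_invariance(self):
        rng = np.random.default_rng(23)
        X, Z, y, K, _, _, _ = random_instance(rng, with_kinship=False)
        vc0 = reml_fit(X, Z, y)
        vc1 = reml_fit(X, Z, y + 100.0)
        assert vc1.sigma2_g == pytest.approx(vc0.sigma2_g, abs=1e-6, rel=1e-6)
        assert vc1.sigma2_e == pytest.approx(vc0.sigma2_e, abs=1e-6, rel=1e-6)
        fixed = VarianceComponents(sigma2_g=vc0.sigma2_g, sigma2_e=vc0.sigma2_e)
        _, u0, _, _ = solve_mme(X, Z, y, None, fixed)
        _, u1, _, _ = solve_mme(X, Z, y + 100.0, None, fixed)
        np.testing.assert_allclose(u1, u0, atol=1e-8)


class TestSolveMME:
    def test_matches_dense_gls_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X, Z, y, K, _, s2g, s2e = random_instance(rng)
            vc = VarianceComponents(sigma2_g=s2g, sigma2_e=s2e)
            beta, u, _, _ = solve_mme(X, Z, y, K, vc)
            beta_o, u_o = gls_oracle(X, Z, y, K, s2g, s2e)
            np.testing.assert_allclose(beta, beta_o, atol=1e-8)
            np.testing.assert_allclose(u, u_o, atol=1e-8)

    def test_balanced_closed_form_blups(self):
        table = toy_trait_table(3, 2, seed=2)
        d = build_design(table, scope="sea")
        vc = VarianceComponents(sigma2_g=4.0, sigma2_e=1.0)
        _, u, _, _ = solve_mme(d.X, d.Z, d.y, None, vc)
        means = np.array([d.y[d.Z[:, j] == 1].mean() for j in range(3)])
        shrink = 2 * 4.0 / (2 * 4.0 + 1.0)
        np.testing.assert_allclose(u, shrink * (means - means.mean()), atol=1e-10)

    def test_infinite_shrinkage_sends_blups_to_zero(self):
        table = toy_trait_table(3, 2, seed=4)
        d = build_design(table, scope="sea")
        vc = VarianceComponents(sigma2_g=1e-12, sigma2_e=1.0)
        _, u, _, _ = solve_mme(d.X, d.Z, d.y, None, vc)
        np.testing.assert_allclose(u, 0.0, atol=1e-6)

    def test_shrinkage_monotone_in_lambda(self):
        table = toy_trait_table(5, 2, seed=6)
        d = build_design(table, scope="sea")
        prev = None
        for s2g in (8.0, 4.0, 2.0, 1.0, 0.5):  # lambda = 1/s2g increases
            vc = VarianceComponents(sigma2_g=s2g, sigma2_e=1.0)
            _, u, _, _ = solve_mme(d.X, d.Z, d.y, None, vc)
            if prev is not None:
                assert np.all(np.abs(u) <= np.abs(prev) + 1e-12)
            prev = u

    def test_pev_bounded_by_genetic_variance(self):
        rng = np.random.default_rng(31)
        X, Z, y, _, _, s2g, s2e = random_instance(rng, with_kinship=False)
        vc = VarianceComponents(sigma2_g=s2g, sigma2_e=s2e)
        _, _, pev, _ = solve_mme(X, Z, y, None, vc)
        assert np.all(pev <= s2g + 1e-10)


class TestHeritabilityReliability:
    def test_heritability_simple_ratios(self):
        assert heritability(VarianceComponents(2.0, 2.0)) == pytest.approx(0.5)
        assert heritability(VarianceComponents(0.0, 3.0)) == pytest.approx(0.0)

    def test_heritability_undefined_at_double_boundary(self):
        vc = VarianceComponents(sigma2_g=1e-10, sigma2_e=1e-10, boundary=True)
        assert np.isnan(heritability(vc))

    def test_reliability_noiseless_limit(self):
        # as sigma2_e -> 0 the only residual uncertainty is the level split
        # between intercept and genotype mean, worth sigma2_g / q, so the
        # reliability of every observed genotype approaches 1 - 1/q
        q = 100
        table = toy_trait_table(q, 2, seed=9)
        d = build_design(table, scope="sea")
        vc = VarianceComponents(sigma2_g=4.0, sigma2_e=1e-9)
        _, _, pev, _ = solve_mme(d.X, d.Z, d.y, None, vc)
        rel = reliability(pev, vc.sigma2_g)
        np.testing.assert_allclose(rel, 1.0 - 1.0 / q, atol=1e-6)

    def test_unobserved_genotype_has_zero_reliability(self):
        table = toy_trait_table(3, 2, seed=10)
        d = build_design(table, scope="sea",
                         genotype_ids=["g01", "g02", "g03", "g99"])
        vc = VarianceComponents(sigma2_g=4.0, sigma2_e=1.0)
        _, u, pev, _ = solve_mme(d.X, d.Z, d.y, None, vc)
        rel = reliability(pev, vc.sigma2_g)
        assert u[3] == pytest.approx(0.0, abs=1e-10)
        assert rel[3] == pytest.approx(0.0, abs=1e-10)

    def test_balanced_reliability_approaches_closed_form(self):
        # with many genotypes the intercept contribution to the PEV is O(1/q)
        table = toy_trait_table(80, 2, seed=12)
        d = build_design(table, scope="sea")
        vc = VarianceComponents(sigma2_g=4.0, sigma2_e=1.0)
        _, _, pev, _ = solve_mme(d.X, d.Z, d.y, None, vc)
        rel = reliability(pev, vc.sigma2_g)
        closed = 2 * 4.0 / (2 * 4.0 + 1.0)
        np.testing.assert_allclose(rel, closed, atol=0.05)

    def test_zero_genetic_variance_reports_zero_reliability(self):
        rel = reliability(np.array([0.5, 0.2]), 0.0)
        np.testing.assert_allclose(rel, 0.0)


class TestMixedModelEstimator:
    def test_recovers_configured_heritability_on_synthetic_trial(self):
        cfg = small_config(n_entries=60, n_checks=4, check_reps_within_replication=3,
                           blocks_per_replication=6, plots_per_block=12,
                           rng_seed=19)
        table = plots_to_traits(TrialSimulator(cfg).run().plots)
        sub = table[(table.condition == "anaerobic") & (table.trait == "germ14_pct")]
        model = MixedModel(scope="across").fit(sub)
        assert model.converged_
        assert 0.3 < model.heritability_ < 0.95
        assert abs(model.blups_.mean()) < 2.0  # shrunken around zero
        assert model.n_obs_ == len(sub)

    def test_random_blocks_switch_adds_component(self):
        table = toy_trait_table(12, 2, seed=30, blocks=True)
        model = MixedModel(scope="sea", blocks="random").fit(table)
        assert model.varcomp_.sigma2_blocks is not None
        assert model.block_blups_ is not None

    def test_sklearn_param_interface(self):
        model = MixedModel(scope="mea", max_iter=123)
        params = model.get_params()
        assert params["scope"] == "mea" and params["max_iter"] == 123
        model.set_params(scope="sea")
        assert model.scope == "sea"
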