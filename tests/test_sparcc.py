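import numpy as np
import pandas as pd
import pytest

from phona.exceptions import DataError
from phona.io_tables import OtuTable
from phona.sparcc import (
    AssociationResult,
    basis_variances,
    bootstrap_pvalues,
    dirichlet_fractions,
    filter_associations,
    logratio_variances,
    sparcc_correlations,
)
from phona.synthdata import SynthConfig, generate_counts

from conftest import make_table


def brute_force_sparcc(fractions: np.ndarray) -> np.ndarray:
    """Naive loop implementation of the basis-variance system and the
    correlation formula, independent of the module's vectorised path."""
    n, p = fractions.shape
    logf = np.log(fractions)
    T = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i != j:
                T[i, j] = np.var(logf[:, i] - logf[:, j], ddof=1)
    M = np.zeros((p, p))
    t = np.zeros(p)
    for i in range(p):
        for j in range(p):
            if i == j:
                M[i, i] = p - 1
            else:
                M[i, j] = 1.0
                t[i] += T[i, j]
    omega2 = np.linalg.solve(M, t)
    degenerate = omega2 <= 0  # convention: zero such OTUs' correlations
    w = np.sqrt(np.clip(omega2, 1e-12, None))
    rho = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            rho[i, j] = (omega2[i] + omega2[j] - T[i, j]) / (2 * w[i] * w[j])
    rho = np.clip(rho, -1.0, 1.0)
    rho[degenerate, :] = 0.0
    rho[:, degenerate] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho


class TestDirichletFractions:
    def test_zero_row_resolved_by_prior(self):
        t = make_table([[0, 0], [1, 1]])
        f = dirichlet_fractions(t, seed=0)
        assert (f > 0).all()
        np.testing.assert_allclose(f.sum(axis=1), 1.0)

    def test_huge_counts_pin_the_posterior(self):
        t = make_table([[10**6, 10**6], [10**6, 10**6]])
        f = dirichlet_fractions(t, seed=1)
        np.testing.assert_allclose(f, 0.5, atol=0.01)

    def test_posterior_mean_is_counts_plus_one(self):
        # row (3, 1): Dirichlet mean (4/6, 2/6)
        t = make_table(np.tile([3, 1], (10_000, 1)))
        f = dirichlet_fractions(t, seed=2)
        np.testing.assert_allclose(f.mean(axis=0), [4 / 6, 2 / 6], atol=0.01)


class TestLogratioVariances:
    def test_proportional_columns_have_zero_variance(self):
        f = np.array([[0.2, 0.4, 0.4], [0.1, 0.2, 0.7], [0.3, 0.6, 0.1]])
        T = logratio_variances(f)
        assert T[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_otu_case(self):
        # log-ratios {0, 1, 2} -> unbiased variance 1
        f = np.column_stack([np.exp([0.0, 1.0, 2.0]), np.ones(3)])
        f = f / f.sum(axis=1, keepdims=True)
        T = logratio_variances(f)
        assert T[0, 1] == pytest.approx(1.0, rel=1e-10)

    def test_sample_order_irrelevant(self):
        rng = np.random.default_rng(3)
        f = rng.dirichlet(np.ones(5), size=8)
        T = logratio_variances(f)
        Tp = logratio_variances(f[::-1])
        np.testing.assert_allclose(T, Tp, atol=1e-12)

    def test_needs_two_samples(self):
        with pytest.raises(DataError):
            logratio_variances(np.array([[0.5, 0.5]]))


class TestBasisVariances:
    def test_symmetric_closed_form(self):
        # all off-diagonal T = 2v solves to omega^2 = v for every OTU
        v = 0.7
        p = 6
        T = np.full((p, p), 2 * v)
        np.fill_diagonal(T, 0.0)
        omega2 = basis_variances(T)
        np.testing.assert_allclose(omega2, v, rtol=1e-10)

    def test_zero_T_gives_zero_variances(self):
        omega2 = basis_variances(np.zeros((5, 5)))
        assert np.all(np.abs(omega2) <= 1e-9)

    def test_solution_satisfies_the_linear_system(self):
        rng = np.random.default_rng(4)
        T = rng.uniform(0.1, 2.0, size=(6, 6))
        T = (T + T.T) / 2
        np.fill_diagonal(T, 0.0)
        omega2 = basis_variances(T)
        for i in range(6):
            lhs = sum(omega2[i] + omega2[j] for j in range(6) if j != i)
            assert lhs == pytest.approx(T[i].sum(), rel=1e-8)

    def test_too_few_otus_is_an_error(self):
        with pytest.raises(DataError, match="4"):
            basis_variances(np.zeros((3, 3)))


class TestSparccCorrelations:
    def test_matches_brute_force_oracle_on_shared_draw(self):
        cfg = SynthConfig(n_samples=50, n_otus=5, depth=2000,
                          correlations=[(0, 1, 0.6)], seed=13)
        table, _ = generate_counts(cfg)
        seed = 99
        expected = brute_force_sparcc(
            dirichlet_fractions(table, np.random.default_rng(seed)))
        got = sparcc_correlations(table, n_iterations=1,
                                  n_exclusion_rounds=0, seed=seed).rho
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-8)

    def test_symmetry_and_unit_diagonal(self):
        cfg = SynthConfig(n_samples=30, n_otus=6, depth=500, seed=5)
        table, _ = generate_counts(cfg)
        rho = sparcc_correlations(table, n_iterations=3, seed=6).rho.to_numpy()
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        assert np.abs(rho).max() <= 1.0

    def test_planted_pair_recovered(self):
        cfg = SynthConfig(n_samples=200, n_otus=22, depth=5000,
                          correlations=[(0, 1, 0.8)], seed=42)
        table, _ = generate_counts(cfg)
        rho = sparcc_correlations(table, seed=1).rho.to_numpy()
        assert 0.6 <= rho[0, 1] <= 0.95

    def test_independent_basis_gives_small_correlations(self):
        cfg = SynthConfig(n_samples=500, n_otus=10, depth=5000, seed=3)
        table, _ = generate_counts(cfg)
        rho = sparcc_correlations(table, seed=4).rho.to_numpy()
        off = np.abs(rho[np.triu_indices(10, 1)])
        assert off.mean() < 0.15

    def test_input_size_contracts(self):
        with pytest.raises(DataError):
            sparcc_correlations(make_table(np.ones((10, 3), dtype=int)))
        with pytest.raises(DataError):
            sparcc_correlations(make_table(np.ones((2, 6), dtype=int)))


class TestBootstrapPvalues:
    def test_minimum_p_is_add_one_bound(self):
        cfg = SynthConfig(n_samples=40, n_otus=5, depth=1000,
                          correlations=[(0, 1, 0.9)], seed=8)
        table, _ = generate_counts(cfg)
        rho = sparcc_correlations(table, n_iterations=3, seed=9).rho
        pv = bootstrap_pvalues(table, rho, n_bootstraps=50, seed=10)
        arr = pv.to_numpy()[np.triu_indices(5, 1)]
        assert arr.min() >= 1 / 51 - 1e-12
        assert arr.max() <= 1.0

    def test_larger_observed_rho_never_raises_p(self):
        # same seed -> same bootstrap null sample; scaling |rho_obs| up can
        # only shrink the exceedance count
        cfg = SynthConfig(n_samples=30, n_otus=6, depth=800, seed=11)
        table, _ = generate_counts(cfg)
        rho = sparcc_correlations(table, n_iterations=2, seed=12).rho
        p_lo = bootstrap_pvalues(table, rho * 0.5, n_bootstraps=40, seed=13)
        p_hi = bootstrap_pvalues(table, rho, n_bootstraps=40, seed=13)
        assert (p_hi.to_numpy() <= p_lo.to_numpy() + 1e-12).all()

    def test_rejects_zero_bootstraps(self):
        cfg = SynthConfig(n_samples=10, n_otus=5, depth=100, seed=1)
        table, _ = generate_counts(cfg)
        with pytest.raises(DataError):
            bootstrap_pvalues(table, np.eye(5), n_bootstraps=0)


class TestFilterAssociations:
    @staticmethod
    def _result(rho, pvals):
        ids = [f"o{i}" for i in range(rho.shape[0])]
        return AssociationResult(
            rho=pd.DataFrame(rho, index=ids, columns=ids),
            pvals=pd.DataFrame(pvals, index=ids, columns=ids),
            n_iterations=1, n_bootstraps=1)

    def test_boundary_rho_is_excluded(self):
        rho = np.eye(2)
        rho[0, 1] = rho[1, 0] = 0.5
        edges = filter_associations(self._result(rho, np.full((2, 2), 0.001)),
                                    min_abs_rho=0.5, alpha=0.05)
        assert len(edges) == 0

    def test_enumerated_four_otu_case(self):
        # qualifying pairs: (0,1) rho=0.8 p=0.01 and (2,3) rho=-0.6 p=0.02;
        # (0,2) fails on p, (1,3) fails on |rho|
        rho = np.eye(4)
        pv = np.ones((4, 4))
        for i, j, r, p in [(0, 1, 0.8, 0.01), (2, 3, -0.6, 0.02),
                           (0, 2, 0.7, 0.20), (1, 3, 0.4, 0.01)]:
            rho[i, j] = rho[j, i] = r
            pv[i, j] = pv[j, i] = p
        edges = filter_associations(self._result(rho, pv))
        assert len(edges) == 2
        signs = {(r.source, r.target): r.sign for r in edges.itertuples()}
        assert signs == {("o0", "o1"): "positive", ("o2", "o3"): "negative"}
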