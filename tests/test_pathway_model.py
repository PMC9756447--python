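import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pathmix import (
    ConfigError,
    ContractError,
    DegenerateInputError,
    IncidenceMatrix,
    NumericalError,
    Pathway,
    PathwayCollection,
    adjust_pvalues,
    build_covariance,
    fit_pathway_model,
    jaccard,
    partition_variance,
    pathway_pvalues,
    solve_mme,
)
from pathmix.pathway_model import PathwayCovariance, VariancePartition

from conftest import gls_blup_oracle, mme_dense_oracle, random_instance


def vp_for(sigma_y2, ratio=0.3):
    return VariancePartition(sigma_y2, ratio, ratio * sigma_y2, (1 - ratio) * sigma_y2)


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"A", "B", "C"}, {"A", "B", "C"}, 1.0),
            ({"A", "B"}, {"C", "D"}, 0.0),
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),  # M=2 shared, N=4 total
            ({"A"} | {f"x{i}" for i in range(9)}, {"A"} | {f"y{i}" for i in range(9)}, 1 / 19),
        ],
    )
    def test_shared_over_total(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_empty_set_is_domain_error(self):
        with pytest.raises(DegenerateInputError):
            jaccard(set(), {"A"})

    gene_sets = st.sets(st.sampled_from([f"g{i}" for i in range(12)]), min_size=1)

    @given(a=gene_sets, b=gene_sets)
    @settings(deadline=None)
    def test_symmetric_bounded_and_one_iff_equal(self, a, b):
        j = jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard(b, a)
        assert (j == 1.0) == (a == b)


class TestCovariance:
    def test_single_pathway(self):
        pw = PathwayCollection([Pathway("p", "", frozenset({"A"}))])
        assert build_covariance(pw).matrix.tolist() == [[1.0]]

    def test_disjoint_pathways_give_identity(self):
        pw = PathwayCollection(
            [Pathway("p1", "", frozenset({"A"})), Pathway("p2", "", frozenset({"B"}))]
        )
        assert np.array_equal(build_covariance(pw).matrix, np.eye(2))

    def test_duplicate_gene_sets_warn_and_get_jitter(self):
        pw = PathwayCollection(
            [Pathway("p1", "", frozenset({"A", "B"})), Pathway("p2", "", frozenset({"A", "B"}))]
        )
        with pytest.warns(UserWarning, match="identical gene sets"):
            V = build_covariance(pw, jitter=1e-8)
        assert V.jitter_applied == 1e-8
        assert V.matrix[0, 1] == 1.0

    def test_random_families_are_psd_with_unit_diagonal(self, rng):
        genes = [f"g{i}" for i in range(40)]
        for _ in range(100):
            p = int(rng.integers(2, 10))
            pw = PathwayCollection(
                Pathway(
                    f"p{j}",
                    "",
                    frozenset(rng.choice(genes, size=int(rng.integers(2, 15)), replace=False)),
                )
                for j in range(p)
            )
            V = build_covariance(pw).matrix
            assert np.array_equal(V, V.T)
            assert np.allclose(np.diag(V), 1.0)
            assert V.min() >= 0.0 and V.max() <= 1.0 + 1e-15
            assert np.linalg.eigvalsh(V).min() >= -1e-8


class TestVariancePartition:
    def test_fixed_ratio_split(self):
        vp = partition_variance([0.0, 2.0], ratio_t=0.3)
        assert vp.sigma_y2 == pytest.approx(2.0)
        assert vp.sigma_t2 == pytest.approx(0.6)
        assert vp.sigma_e2 == pytest.approx(1.4)
        assert vp.sigma_t2 + vp.sigma_e2 == pytest.approx(vp.sigma_y2)

    def test_unbiased_denominator(self, rng):
        y = rng.normal(size=50)
        assert partition_variance(y).sigma_y2 == pytest.approx(np.var(y, ddof=1))

    def test_constant_y_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            partition_variance([1.0, 1.0, 1.0])

    def test_ratio_bounds(self):
        with pytest.raises(ConfigError):
            partition_variance([0.0, 1.0], ratio_t=1.0)


class TestSolveMme:
    def test_two_gene_worked_example(self):
        Z = IncidenceMatrix(np.eye(2), ("gA", "gB"), ("p1", "p2"))
        V = PathwayCovariance(np.eye(2), ("p1", "p2"))
        vp = vp_for(0.5)  # var of (1, 2) -> sigma_t2=0.15, sigma_e2=0.35
        fit = solve_mme([1.0, 2.0], Z, V, vp)
        assert fit.mu_hat == pytest.approx(1.5, abs=1e-12)
        assert fit.t_hat == pytest.approx([-0.15, 0.15], abs=1e-12)

    def test_constant_y_gives_zero_effects(self):
        Z = IncidenceMatrix(np.eye(3), tuple("abc"), tuple("xyz"))
        V = PathwayCovariance(np.eye(3), tuple("xyz"))
        fit = solve_mme([2.0, 2.0, 2.0], Z, V, vp_for(1.0))
        assert fit.mu_hat == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(fit.t_hat, 0.0, atol=1e-12)

    def test_matches_dense_inverse_oracle(self, rng):
        for _ in range(20):
            y, inc, pathways = random_instance(rng, max_genes=8 * 3, max_pathways=3)
            V = build_covariance(pathways)
            vp = partition_variance(y)
            fit = solve_mme(y, inc, V, vp)
            mu_o, t_o = mme_dense_oracle(y, inc.matrix, V.matrix, vp.sigma_t2, vp.sigma_e2)
            assert fit.mu_hat == pytest.approx(mu_o, rel=1e-10)
            assert fit.t_hat == pytest.approx(t_o, rel=1e-10, abs=1e-12)

    def test_matches_gls_blup_closed_form(self, rng):
        for _ in range(20):
            y, inc, pathways = random_instance(rng)
            V = build_covariance(pathways)
            vp = partition_variance(y)
            fit = solve_mme(y, inc, V, vp)
            mu_o, t_o = gls_blup_oracle(y, inc.matrix, V.matrix, vp.sigma_t2, vp.sigma_e2)
            assert fit.mu_hat == pytest.approx(mu_o, rel=1e-8)
            assert fit.t_hat == pytest.approx(t_o, rel=1e-8, abs=1e-12)

    def test_shrinkage_closed_form_with_identity_design(self, rng):
        # with V = I and Z = I: t_i = (sigma_t^2 / sigma_y^2) (y_i - mu)
        n = 6
        y = np.abs(rng.normal(1, 0.4, n))
        Z = IncidenceMatrix(np.eye(n), tuple(f"g{i}" for i in range(n)), tuple(f"p{i}" for i in range(n)))
        V = PathwayCovariance(np.eye(n), Z.pathway_ids)
        vp = partition_variance(y, 0.3)
        fit = solve_mme(y, Z, V, vp)
        assert fit.t_hat == pytest.approx(0.3 * (y - fit.mu_hat), rel=1e-10)

    def test_shrinkage_vanishes_as_ratio_to_zero(self, rng):
        y, inc, pathways = random_instance(rng)
        V = build_covariance(pathways)
        prev = np.inf
        for ratio in (0.3, 0.03, 0.003, 3e-5):
            fit = solve_mme(y, inc, V, partition_variance(y, ratio))
            peak = np.abs(fit.t_hat).max()
            assert peak < prev
            prev = peak
        assert prev < 1e-4

    def test_location_shift_moves_only_mu(self, rng):
        y, inc, pathways = random_instance(rng)
        V = build_covariance(pathways)
        vp = partition_variance(y)
        fit = solve_mme(y, inc, V, vp)
        shifted = solve_mme(y + 7.5, inc, V, vp)
        assert shifted.mu_hat == pytest.approx(fit.mu_hat + 7.5, rel=1e-10)
        assert shifted.t_hat == pytest.approx(fit.t_hat, rel=1e-8, abs=1e-12)
        p0 = pathway_pvalues(fit.t_hat, vp)
        p1 = pathway_pvalues(shifted.t_hat, vp)
        assert p1 == pytest.approx(p0, rel=1e-8)

    def test_singular_covariance_names_duplicates(self):
        Z = IncidenceMatrix(np.eye(2), ("a", "b"), ("p1", "p2"))
        V = PathwayCovariance(np.ones((2, 2)), ("p1", "p2"))  # duplicate sets, no jitter
        with pytest.raises(NumericalError, match="p1"):
            solve_mme([1.0, 2.0], Z, V, vp_for(1.0))

    def test_dimension_mismatch_is_contract_error(self):
        Z = IncidenceMatrix(np.eye(2), ("a", "b"), ("p1", "p2"))
        V = PathwayCovariance(np.eye(2), ("p1", "p2"))
        with pytest.raises(ContractError):
            solve_mme([1.0, 2.0, 3.0], Z, V, vp_for(1.0))


class TestPvalues:
    def test_known_quantiles(self):
        vp = vp_for(1.0)  # sigma_t = sqrt(0.3)
        t = np.array([0.0, vp.sigma_t, -vp.sigma_t])
        p = pathway_pvalues(t, vp)
        assert p[0] == pytest.approx(0.5)
        assert p[1] == pytest.approx(1 - stats.norm.cdf(1))  # ~0.15866
        assert p[2] == pytest.approx(stats.norm.cdf(1))  # ~0.84134, never significant

    @given(st.lists(st.integers(-300, 300), min_size=2, max_size=10, unique=True))
    @settings(deadline=None)
    def test_strictly_decreasing_in_t(self, t_vals):
        vp = vp_for(1.0)
        t = np.sort(np.array(t_vals, dtype=float)) / 100.0
        p = pathway_pvalues(t, vp)
        assert np.all(np.diff(p) < 0)

    def test_bh_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        # step-up by enumeration: min over j>=i of p_(j) * m / j = 0.04 for all
        assert adjust_pvalues(p, "bh") == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_none_is_identity_and_single_bh_unchanged(self):
        p = np.array([0.2, 0.7])
        assert adjust_pvalues(p, "none") == pytest.approx(p)
        assert adjust_pvalues([0.123], "bh") == pytest.approx([0.123])

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            adjust_pvalues([0.5], "bonferroni")


def test_fit_pathway_model_end_to_end(rng):
    y, inc, pathways = random_instance(rng)
    fit = fit_pathway_model(y, inc, pathways)
    assert len(fit.t_hat) == len(fit.pvalues) == len(pathways)
    assert np.all((fit.pvalues > 0) & (fit.pvalues < 1))
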