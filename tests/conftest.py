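import numpy as np
import pytest

from pathmix import (
    IncidenceMatrix,
    Pathway,
    PathwayCollection,
    SimulationConfig,
    assign_snps_to_genes,
    build_incidence,
    fit_pathway_model,
    recovery_report,
    select_top_snp_per_gene,
    simulate_gene_sets,
    simulate_summary_stats,
)


def gls_blup_oracle(y, Z, V, sigma_t2, sigma_e2):
    """Independent closed-form GLS/BLUP solution via the full n x n inverse.

    mu = (1' S^-1 1)^-1 1' S^-1 y and t = G Z' S^-1 (y - 1 mu) with
    S = Z G Z' + I sigma_e^2, G = V sigma_t2 — no mixed-model equations.
    """
    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    n = len(y)
    G = V * sigma_t2
    S = Z @ G @ Z.T + sigma_e2 * np.eye(n)
    Si = np.linalg.inv(S)
    ones = np.ones(n)
    mu = (ones @ Si @ y) / (ones @ Si @ ones)
    t = G @ Z.T @ Si @ (y - mu)
    return mu, t


def mme_dense_oracle(y, Z, V, sigma_t2, sigma_e2):
    """Brute-force solve of the full mixed-model-equation system via np.linalg.inv."""
    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    n, p = Z.shape
    X = np.ones((n, 1))
    Rinv = np.eye(n) / sigma_e2
    Ginv = np.linalg.inv(V * sigma_t2)
    C = np.block(
        [[X.T @ Rinv @ X, X.T @ Rinv @ Z], [Z.T @ Rinv @ X, Z.T @ Rinv @ Z + Ginv]]
    )
    rhs = np.concatenate([X.T @ Rinv @ y, Z.T @ Rinv @ y])
    sol = np.linalg.inv(C) @ rhs
    return sol[0], sol[1:]


def random_instance(rng, max_genes=30, max_pathways=8):
    """A random small model instance: y, incidence, pathway collection."""
    p = int(rng.integers(2, max_pathways + 1))
    n = int(rng.integers(p + 2, max_genes + 1))
    universe = [f"G{i}" for i in range(n)]
    # ensure each gene sits in >= 1 pathway and each pathway gets >= 1 gene
    sets = [set() for _ in range(p)]
    for i, g in enumerate(universe):
        sets[i % p].add(g)
        for j in range(p):
            if rng.random() < 0.3:
                sets[j].add(g)
    pathways = PathwayCollection(
        Pathway(f"p{j}", "", frozenset(sets[j])) for j in range(p)
    )
    Z = np.zeros((n, p))
    for i, g in enumerate(universe):
        for j in range(p):
            if g in sets[j]:
                Z[i, j] = 1.0
    inc = IncidenceMatrix(Z, tuple(universe), tuple(pathways.ids))
    y = np.abs(rng.normal(1.0, 0.3, size=n))
    return y, inc, pathways


def simulate_and_fit(config: SimulationConfig):
    """Full in-memory pipeline on one simulated dataset; returns (fit, truth, report)."""
    pathways = simulate_gene_sets(config)
    records, gene_models, truth = simulate_summary_stats(config, pathways)
    assignments = assign_snps_to_genes(records, gene_models)
    gene_effects = select_top_snp_per_gene(records, assignments)
    gene_effects, retained, Z = build_incidence(gene_effects, pathways)
    fit = fit_pathway_model([g.y for g in gene_effects], Z, retained,
                            ratio_t=config.ratio_t)
    return fit, truth, recovery_report(fit, truth)


@pytest.fixture
def two_pathway_collection():
    return PathwayCollection(
        [
            Pathway("p1", "first", frozenset({"A", "B", "C"})),
            Pathway("p2", "second", frozenset({"B", "C", "D"})),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20220473)
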