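"""Synthetic summary statistics with known pathway structure.

The generator draws data from the same model the estimator assumes:
pathway effects t ~ N(0, V sigma_t^2) (with a configurable fraction forced
to zero), per-gene residuals e ~ N(0, I sigma_e^2), and a gene-level value
mu + (Z t)_g + e_g. Each gene's designated top SNP carries that value as its
effect magnitude with a random sign; additional decoy SNPs carry strictly
smaller magnitudes, so gene-level collapsing provably recovers the designated
SNP. Gene models are laid out as non-overlapping intervals on one synthetic
chromosome and everything can be emitted through the io_formats writers, so
the simulator doubles as an end-to-end fixture factory.

It deliberately does not emulate LD, allele frequencies, or genotype-level
noise — the upstream GWAS is outside the model being tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .annotation import IncidenceMatrix
from .errors import ConfigError, ContractError
from .io_formats import (
    GeneModel,
    Pathway,
    PathwayCollection,
    SummaryStatRecord,
    write_bed,
    write_gmt,
    write_summary_stats,
)
from .pathway_model import ModelFit, build_covariance

logger = logging.getLogger(__name__)

_GENE_SPAN = 2_000  # bp allotted per gene on the synthetic chromosome
_GENE_LEN = 1_000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    ``genes_per_pathway`` and ``snps_per_gene`` accept either a single count
    or an inclusive ``(low, high)`` range sampled per pathway/gene.
    ``overlap_fraction`` makes consecutive pathways share
    ``round(overlap_fraction * size)`` genes so V has non-trivial
    off-diagonals. ``mu`` and ``sigma_y2_target`` set the mean and variance
    of the gene-level values: the defaults (1.0 and 0.09) give a coefficient
    of variation of 0.3, keeping essentially all values positive so the
    absolute-value transform is benign. ``null_fraction`` forces that share
    of pathways to a true effect of exactly zero.
    """

    n_pathways: int = 40
    genes_per_pathway: int | tuple[int, int] = 25
    overlap_fraction: float = 0.1
    snps_per_gene: int | tuple[int, int] = 3
    mu: float = 1.0
    sigma_y2_target: float = 0.09
    ratio_t: float = 0.3
    null_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ConfigError("n_pathways must be >= 1")
        for name in ("genes_per_pathway", "snps_per_gene"):
            v = getattr(self, name)
            lo, hi = (v, v) if isinstance(v, int) else v
            if lo < 1 or hi < lo:
                raise ConfigError(f"{name} must be a positive count or (low, high) range")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ConfigError("overlap_fraction must be in [0, 1)")
        if self.sigma_y2_target <= 0:
            raise ConfigError("sigma_y2_target must be positive")
        if not (0.0 < self.ratio_t < 1.0):
            raise ConfigError("ratio_t must be in (0, 1)")
        if not (0.0 <= self.null_fraction <= 1.0):
            raise ConfigError("null_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated dataset, aligned with the emitted files."""

    mu: float
    t: np.ndarray
    pathway_ids: tuple[str, ...]
    null_mask: np.ndarray
    y: np.ndarray
    gene_ids: tuple[str, ...]
    gene_to_pathways: dict[str, frozenset[str]]
    V: np.ndarray


def _draw_count(value: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(value, int):
        return value
    lo, hi = value
    return int(rng.integers(lo, hi + 1))


def simulate_gene_sets(config: SimulationConfig) -> PathwayCollection:
    """Generate pathways where consecutive sets share a fixed gene fraction.

    Pathway k reuses the last ``round(overlap_fraction * size)`` genes of
    pathway k-1 and fills the rest with fresh genes. Deterministic under the
    config seed (gene-set structure uses its own random stream, so the same
    sets are produced regardless of how the effect stream is consumed).
    """
    rng = np.random.default_rng([config.seed % (2**31), 11])
    pathways: list[Pathway] = []
    next_gene = 0
    prev: list[str] = []
    for k in range(config.n_pathways):
        size = _draw_count(config.genes_per_pathway, rng)
        n_shared = round(config.overlap_fraction * size) if k > 0 else 0
        n_shared = min(n_shared, len(prev))
        if n_shared >= size:
            raise ConfigError(
                f"overlap_fraction {config.overlap_fraction} leaves no unique genes "
                f"in pathway of size {size}"
            )
        shared = prev[-n_shared:] if n_shared else []
        fresh = [f"G{next_gene + i:06d}" for i in range(size - n_shared)]
        next_gene += len(fresh)
        members = shared + fresh
        pathways.append(Pathway(f"pw{k:04d}", f"synthetic pathway {k}", frozenset(members)))
        prev = members
    return PathwayCollection(pathways)


def simulate_summary_stats(
    config: SimulationConfig, pathways: PathwayCollection
) -> tuple[list[SummaryStatRecord], list[GeneModel], SimulationTruth]:
    """Draw SNP-level summary statistics under the generative pathway model.

    Returns the SNP records (top SNP plus decoys per gene, random signs),
    the gene models on one synthetic chromosome, and the ground truth.
    """
    rng = np.random.default_rng([config.seed % (2**31), 23])
    gene_ids = _ordered_genes(pathways)
    membership = pathways.gene_to_pathways()
    n_genes, n_pw = len(gene_ids), len(pathways)

    V = build_covariance(pathways).matrix
    sigma_t2 = config.ratio_t * config.sigma_y2_target
    sigma_e2 = (1.0 - config.ratio_t) * config.sigma_y2_target

    # pathway effects: correlated draw, then null pathways forced to zero
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n_pw))
    t = np.sqrt(sigma_t2) * (L @ rng.standard_normal(n_pw))
    n_null = round(config.null_fraction * n_pw)
    null_idx = rng.choice(n_pw, size=n_null, replace=False) if n_null else np.array([], dtype=int)
    null_mask = np.zeros(n_pw, dtype=bool)
    null_mask[null_idx] = True
    t[null_mask] = 0.0

    col = {pid: j for j, pid in enumerate(pathways.ids)}
    e = np.sqrt(sigma_e2) * rng.standard_normal(n_genes)
    zt = np.array(
        [sum(t[col[pid]] for pid in membership[g]) for g in gene_ids]
    )
    gene_values = config.mu + zt + e
    y_true = np.abs(gene_values)

    records: list[SummaryStatRecord] = []
    gene_models: list[GeneModel] = []
    chrom = "1"
    for i, g in enumerate(gene_ids):
        start = 1 + i * _GENE_SPAN
        end = start + _GENE_LEN - 1
        gene_models.append(GeneModel(g, chrom, start, end))
        n_snps = _draw_count(config.snps_per_gene, rng)
        positions = start + rng.choice(_GENE_LEN, size=n_snps, replace=False)
        top_mag = y_true[i]
        mags = np.concatenate(
            [[top_mag], top_mag * rng.uniform(0.2, 0.9, size=n_snps - 1)]
        )
        signs = rng.choice([-1.0, 1.0], size=n_snps)
        se = float(np.sqrt(sigma_e2))
        for j in range(n_snps):
            effect = float(signs[j] * mags[j])
            pval = float(np.clip(2.0 * stats.norm.sf(abs(effect) / se), 1e-300, 1.0))
            records.append(
                SummaryStatRecord(
                    snp_id=f"snp_{g}_{j}",
                    chrom=chrom,
                    pos=int(positions[j]),
                    effect=effect,
                    se=se,
                    pvalue=pval,
                )
            )

    truth = SimulationTruth(
        mu=config.mu,
        t=t,
        pathway_ids=tuple(pathways.ids),
        null_mask=null_mask,
        y=y_true,
        gene_ids=tuple(gene_ids),
        gene_to_pathways={g: frozenset(membership[g]) for g in gene_ids},
        V=V,
    )
    logger.info(
        "simulated %d SNPs in %d genes across %d pathways (%d null)",
        len(records),
        n_genes,
        n_pw,
        int(null_mask.sum()),
    )
    return records, gene_models, truth


def _ordered_genes(pathways: PathwayCollection) -> list[str]:
    """All member genes in deterministic first-appearance order (sorted within a set)."""
    seen: dict[str, None] = {}
    for p in pathways:
        for g in sorted(p.genes):
            seen.setdefault(g)
    return list(seen)


def write_dataset(
    records: Sequence[SummaryStatRecord],
    gene_models: Sequence[GeneModel],
    pathways: PathwayCollection,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit a simulated dataset in the exact formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary_stats": outdir / "summary_stats.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "gene_models": outdir / "gene_models.bed",
    }
    write_summary_stats(records, paths["summary_stats"])
    write_gmt(pathways, paths["gene_sets"])
    write_bed(gene_models, paths["gene_models"])
    return paths


def recovery_report(
    fit: ModelFit, truth: SimulationTruth, alpha: float = 0.05
) -> dict[str, float]:
    """How well the fit recovered the simulated pathway effects.

    Reports Pearson and Spearman correlation of t_hat with the true t, the
    RMSE of t_hat, the empirical type-I error rate at ``alpha`` among
    true-null pathways, and power among true-non-null pathways; rates over
    an empty group are reported as NaN.
    """
    idx = {pid: i for i, pid in enumerate(truth.pathway_ids)}
    missing = [pid for pid in fit.pathway_ids if pid not in idx]
    if missing:
        raise ContractError(f"fit pathways not in truth: {missing[:3]}")
    order = [idx[pid] for pid in fit.pathway_ids]
    t_true = truth.t[order]
    null = truth.null_mask[order]
    t_hat = np.asarray(fit.t_hat)
    if fit.pvalues is None:
        raise ContractError("fit has no p-values; run the significance step first")
    sig = np.asarray(fit.pvalues) <= alpha

    # correlation is undefined for a constant truth vector (e.g. all-null)
    defined = len(t_hat) > 1 and np.ptp(t_true) > 0 and np.ptp(t_hat) > 0
    pearson = float(stats.pearsonr(t_hat, t_true)[0]) if defined else float("nan")
    spearman = float(stats.spearmanr(t_hat, t_true)[0]) if defined else float("nan")
    return {
        "pearson": pearson,
        "spearman": spearman,
        "rmse": float(np.sqrt(np.mean((t_hat - t_true) ** 2))),
        "type1_rate": float(sig[null].mean()) if null.any() else float("nan"),
        "power": float(sig[~null].mean()) if (~null).any() else float("nan"),
    }
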