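"""SNP-to-gene assignment and gene-level collapsing.

Each gene enters the model through a single representative SNP: among all
SNPs assigned to a gene, the one with the strongest effect is kept and the
gene-level response is the absolute value of its estimated additive effect.
This module builds that response vector and the binary gene-by-pathway
incidence matrix Z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .errors import ConfigError, ContractError, DegenerateInputError, FormatError
from .io_formats import GeneModel, PathwayCollection, SummaryStatRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpGeneAssignment:
    """One (SNP, gene) pair; a SNP inside overlapping genes yields several."""

    snp_id: str
    gene_id: str


@dataclass(frozen=True)
class GeneEffect:
    """Per-gene element of the response vector y.

    ``y`` is the absolute effect of the selected (strongest) SNP; ``chrom``
    and ``pos`` locate that SNP. ``pathways`` is filled by
    :func:`build_incidence`.
    """

    gene_id: str
    snp_id: str
    chrom: str
    pos: int
    y: float
    pathways: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.y < 0:
            raise ValueError(f"y must be non-negative, got {self.y}")


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary matrix Z: rows follow gene order, columns follow pathway order."""

    matrix: np.ndarray
    gene_ids: tuple[str, ...]
    pathway_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n, p = self.matrix.shape
        if n != len(self.gene_ids) or p != len(self.pathway_ids):
            raise ContractError("incidence matrix shape does not match label lists")


def assign_snps_to_genes(
    records: Sequence[SummaryStatRecord],
    genes: Sequence[GeneModel],
    flank_bp: int = 0,
) -> list[SnpGeneAssignment]:
    """Assign each SNP to every gene whose (flank-extended) interval covers it.

    SNP s maps to gene g iff the chromosomes match and
    ``start - flank_bp <= pos <= end + flank_bp``. SNPs covering no gene
    yield no assignment; a SNP inside overlapping genes yields one
    assignment per gene. Output is ordered by input record, then gene id.
    """
    if flank_bp < 0:
        raise ConfigError(f"flank_bp must be non-negative, got {flank_bp}")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; [start-f, end+f] inclusive -> end+f+1
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - flank_bp, g.end + flank_bp + 1, g.gene_id
        )
    out: list[SnpGeneAssignment] = []
    for rec in records:
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree.at(rec.pos))
        out.extend(SnpGeneAssignment(rec.snp_id, gid) for gid in hits)
    logger.info(
        "assigned %d SNP-gene pairs (%d SNPs, %d genes, flank %d bp)",
        len(out),
        len(records),
        len(genes),
        flank_bp,
    )
    return out


def read_snp_gene_map(path: str | Path) -> list[SnpGeneAssignment]:
    """Read a two-column TSV (snp_id, gene_id) bypassing positional assignment."""
    out: list[SnpGeneAssignment] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["snp_id", "gene_id"]:
            raise FormatError(
                f"snp-gene map must start with columns snp_id, gene_id; got {header[:2]}",
                line=1,
            )
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError("snp-gene map line needs 2 fields", line=line_no)
            pair = (fields[0], fields[1])
            if pair in seen:
                raise FormatError(f"duplicate pair {pair}", line=line_no)
            seen.add(pair)
            out.append(SnpGeneAssignment(*pair))
    return out


def select_top_snp_per_gene(
    records: Sequence[SummaryStatRecord],
    assignments: Sequence[SnpGeneAssignment],
    criterion: str = "max_abs_effect",
) -> list[GeneEffect]:
    """Collapse each gene to its single strongest SNP.

    Under ``max_abs_effect`` the SNP with the largest \\|effect\\| wins; ties
    are broken by smaller p-value (when present), then lexicographic snp_id,
    so the result is invariant to input order. Under ``min_pvalue`` the
    smallest p-value wins (ties by larger \\|effect\\|, then snp_id); this
    criterion requires a p-value on every assigned SNP. The gene-level
    response is y = \\|effect\\| of the winner. Output is sorted by gene id.
    """
    if criterion not in {"max_abs_effect", "min_pvalue"}:
        raise ConfigError(f"unknown selection criterion {criterion!r}")
    by_snp: dict[str, SummaryStatRecord] = {r.snp_id: r for r in records}
    per_gene: dict[str, list[SummaryStatRecord]] = {}
    for a in assignments:
        rec = by_snp.get(a.snp_id)
        if rec is None:
            raise ContractError(f"assignment references unknown SNP {a.snp_id!r}")
        per_gene.setdefault(a.gene_id, []).append(rec)

    if criterion == "min_pvalue":
        missing = [
            r.snp_id for recs in per_gene.values() for r in recs if r.pvalue is None
        ]
        if missing:
            raise ConfigError(
                "criterion min_pvalue requires p-values on all assigned SNPs; "
                f"missing for e.g. {sorted(set(missing))[:3]}"
            )

    def sort_key(r: SummaryStatRecord):
        if criterion == "max_abs_effect":
            p = r.pvalue if r.pvalue is not None else float("inf")
            return (-abs(r.effect), p, r.snp_id)
        return (r.pvalue, -abs(r.effect), r.snp_id)

    out = []
    for gene_id in sorted(per_gene):
        winner = min(per_gene[gene_id], key=sort_key)
        out.append(
            GeneEffect(
                gene_id=gene_id,
                snp_id=winner.snp_id,
                chrom=winner.chrom,
                pos=winner.pos,
                y=abs(winner.effect),
            )
        )
    logger.info("collapsed %d genes from %d assignments", len(out), len(assignments))
    return out


def build_incidence(
    gene_effects: Sequence[GeneEffect],
    pathways: PathwayCollection,
    keep_unmapped: bool = False,
) -> tuple[list[GeneEffect], PathwayCollection, IncidenceMatrix]:
    """Fill pathway memberships and build the incidence matrix Z.

    Genes belonging to no pathway are dropped by default (they cannot inform
    the pathway effects and would only enter the mean); ``keep_unmapped``
    retains them with an all-zero row. Pathways with zero observed genes are
    dropped from the matrix and logged. Returns the filtered gene effects
    (with ``pathways`` filled), the retained pathway collection, and Z.
    """
    membership = pathways.gene_to_pathways()

    filled: list[GeneEffect] = []
    for ge in gene_effects:
        pids = frozenset(membership.get(ge.gene_id, set()))
        if not pids and not keep_unmapped:
            continue
        filled.append(replace(ge, pathways=pids))
    if not any(ge.pathways for ge in filled):
        raise DegenerateInputError(
            "no overlap between summary statistics and gene sets: "
            "zero collapsed genes are members of any pathway"
        )
    n_dropped_genes = len(gene_effects) - len(filled)
    if n_dropped_genes:
        logger.info("dropped %d genes belonging to no pathway", n_dropped_genes)

    observed = {pid for ge in filled for pid in ge.pathways}
    retained = pathways.subset([pid for pid in pathways.ids if pid in observed])
    dropped = [pid for pid in pathways.ids if pid not in observed]
    if dropped:
        logger.info(
            "dropped %d pathways with zero observed genes: %s%s",
            len(dropped),
            ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )

    col = {pid: j for j, pid in enumerate(retained.ids)}
    Z = np.zeros((len(filled), len(retained)), dtype=float)
    for i, ge in enumerate(filled):
        for pid in ge.pathways:
            Z[i, col[pid]] = 1.0
    incidence = IncidenceMatrix(
        matrix=Z,
        gene_ids=tuple(ge.gene_id for ge in filled),
        pathway_ids=tuple(retained.ids),
    )
    logger.info(
        "incidence matrix: %d genes x %d pathways (%d pathways dropped)",
        *Z.shape,
        len(dropped),
    )
    return filled, retained, incidence
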