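"""Readers and writers for every external file the pipeline touches.

Supported formats
-----------------
* delimited summary-statistic tables (any delimiter pandas can sniff, with a
  header row and a configurable column mapping),
* GMT gene-set files (``pathway_id <TAB> description <TAB> gene1 ...``),
* gene models as GFF3 (1-based inclusive) or BED (0-based half-open,
  converted on read),
* the two tab-delimited result tables (per-pathway and per-gene).

Internal genomic convention is 1-based inclusive coordinates; strand is
carried but ignored for overlap. Numbers in result tables are printed with
six significant digits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

#: default column names for summary-statistic tables; override via ``column_map``
DEFAULT_COLUMN_MAP = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect": "effect",
    "se": "se",
    "pvalue": "pvalue",
}

#: significant digits used when printing floats to result tables
FLOAT_PRECISION = 6


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.{FLOAT_PRECISION}g}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's estimated additive effect with genomic coordinates.

    ``effect`` is on the trait scale as reported by the upstream GWAS; the
    model later consumes its absolute value. ``se`` and ``pvalue`` are
    optional and only required by the ``min_pvalue`` selection criterion.
    """

    snp_id: str
    chrom: str
    pos: int
    effect: float
    se: float | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not math.isfinite(self.effect):
            raise ValueError(f"effect must be finite, got {self.effect}")
        if self.se is not None and not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue must be in (0, 1], got {self.pvalue}")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] for {self.gene_id}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")


@dataclass(frozen=True)
class Pathway:
    """A named gene set (KEGG map or any GMT-defined set)."""

    pathway_id: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id} has an empty gene set")


class PathwayCollection:
    """An ordered collection of named gene sets.

    Order is deterministic (file order on read) and defines the column order
    of the incidence matrix and of the pathway covariance.
    """

    def __init__(self, pathways: Iterable[Pathway]):
        self._pathways: list[Pathway] = list(pathways)
        ids = [p.pathway_id for p in self._pathways]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate pathway ids: {', '.join(dupes)}")
        self._by_id = {p.pathway_id: p for p in self._pathways}

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self._pathways)

    def __getitem__(self, key: int | str) -> Pathway:
        if isinstance(key, str):
            return self._by_id[key]
        return self._pathways[key]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCollection):
            return NotImplemented
        return self._pathways == other._pathways

    @property
    def ids(self) -> list[str]:
        return [p.pathway_id for p in self._pathways]

    def gene_to_pathways(self) -> dict[str, set[str]]:
        """Map each gene id to the set of pathway ids containing it."""
        out: dict[str, set[str]] = {}
        for p in self._pathways:
            for g in p.genes:
                out.setdefault(g, set()).add(p.pathway_id)
        return out

    def subset(self, pathway_ids: Sequence[str]) -> "PathwayCollection":
        """A new collection restricted to ``pathway_ids``, keeping this order."""
        keep = set(pathway_ids)
        return PathwayCollection(p for p in self._pathways if p.pathway_id in keep)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    lenient: bool = False,
) -> list[SummaryStatRecord]:
    """Read a delimited summary-statistic table into records, in file order.

    ``column_map`` maps the internal field names (``snp_id``, ``chrom``,
    ``pos``, ``effect`` and optionally ``se``, ``pvalue``) to the column
    names actually present in the file; unspecified fields fall back to
    :data:`DEFAULT_COLUMN_MAP`. Rows with a non-finite or unparseable effect
    are rejected: by default the reader fails fast with the line number,
    under ``lenient=True`` it skips the row with a logged warning.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMN_MAP)
        if unknown:
            raise ConfigError(f"unknown column-map keys: {sorted(unknown)}")
        cmap.update(column_map)

    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for fld in ("snp_id", "chrom", "pos", "effect"):
        if cmap[fld] not in df.columns:
            raise ConfigError(
                f"summary-statistic file {path} is missing mapped column "
                f"{cmap[fld]!r} (field {fld!r}); present: {list(df.columns)}"
            )
    has_se = cmap["se"] in df.columns
    has_p = cmap["pvalue"] in df.columns

    records: list[SummaryStatRecord] = []
    n_rejected = 0
    # header occupies line 1, so data row i (0-based) sits on line i + 2
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        row_d = dict(zip(df.columns, row))
        try:
            pos = int(row_d[cmap["pos"]])
            effect = float(row_d[cmap["effect"]])
            se = float(row_d[cmap["se"]]) if has_se and _present(row_d[cmap["se"]]) else None
            pval = (
                float(row_d[cmap["pvalue"]])
                if has_p and _present(row_d[cmap["pvalue"]])
                else None
            )
            records.append(
                SummaryStatRecord(
                    snp_id=str(row_d[cmap["snp_id"]]),
                    chrom=str(row_d[cmap["chrom"]]),
                    pos=pos,
                    effect=effect,
                    se=se,
                    pvalue=pval,
                )
            )
        except (TypeError, ValueError) as exc:
            n_rejected += 1
            if not lenient:
                raise FormatError(f"cannot parse summary-statistic row: {exc}", line=line)
            logger.warning("skipping summary-statistic row (line %d): %s", line, exc)
    logger.info(
        "read %d summary-statistic records from %s (%d rejected)",
        len(records),
        path,
        n_rejected,
    )
    return records


def _present(value: object) -> bool:
    return value is not None and not (isinstance(value, float) and math.isnan(value)) and str(value) not in {"", "NA", "nan", "NaN"}


def write_summary_stats(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    """Write records as a tab-delimited table with the default column names."""
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\teffect\tse\tpvalue\n")
        for r in records:
            fh.write(
                f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.effect!r}\t"
                f"{'NA' if r.se is None else repr(r.se)}\t"
                f"{'NA' if r.pvalue is None else repr(r.pvalue)}\n"
            )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file: ``pathway_id <TAB> description <TAB> gene1 <TAB> ...``.

    Duplicate gene ids within one set are de-duplicated; an empty gene list
    or a duplicate pathway id is a format error.
    """
    pathways: list[Pathway] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line has {len(fields)} fields, need at least 3", line=line_no
                )
            pid, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"pathway {pid} has no genes", line=line_no)
            pathways.append(Pathway(pid, desc, frozenset(genes)))
    collection = PathwayCollection(pathways)
    logger.info("read %d gene sets from %s", len(collection), path)
    return collection


def write_gmt(pathways: PathwayCollection, path: str | Path) -> None:
    """Write a collection to GMT; genes sorted within each set for determinism."""
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.description, *sorted(p.genes)]) + "\n")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 or BED.

    ``format`` is ``"gff3"`` or ``"bed"``; if omitted it is inferred from the
    file extension. BED's 0-based half-open coordinates are converted to the
    1-based inclusive internal convention on read, so ``chr1 99 200 g1``
    becomes ``[100, 200]``.
    """
    fmt = format or _infer_format(path)
    if fmt == "bed":
        genes = _read_bed(path)
    elif fmt == "gff3":
        genes = _read_gff3(path)
    else:
        raise ConfigError(f"unknown gene-model format {fmt!r} (expected gff3 or bed)")
    seen: dict[str, int] = {}
    for g in genes:
        seen[g.gene_id] = seen.get(g.gene_id, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise FormatError(f"duplicate gene ids in {path}: {', '.join(dupes[:5])}")
    logger.info("read %d gene models from %s (%s)", len(genes), path, fmt)
    return genes


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return "bed"
    if suffix in {".gff", ".gff3"}:
        return "gff3"
    raise ConfigError(f"cannot infer gene-model format from extension {suffix!r}")


def _read_bed(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError("BED line needs >= 4 fields (name required)", line=line_no)
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
            # 0-based half-open -> 1-based inclusive; start == end yields a 1-bp gene
            genes.append(GeneModel(name, chrom, start + 1, max(end, start + 1), strand))
    return genes


def _read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if "ID" not in feat.attributes:
            raise FormatError(f"gene feature at {feat.seqid}:{feat.start} lacks an ID attribute")
        strand = feat.strand if feat.strand in {"+", "-"} else "."
        genes.append(GeneModel(feat.attributes["ID"][0], feat.seqid, feat.start, feat.end, strand))
    return genes


def write_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as 4/6-column BED (internal 1-based -> BED 0-based)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_results(fit, gene_effects, out_prefix: str | Path, alpha: float = 0.05) -> tuple[Path, Path]:
    """Write the per-pathway and per-gene result tables.

    The pathway table (``<prefix>.pathways.tsv``) lists each retained pathway
    with its observed gene count, predicted effect, p-value, and a
    significance flag at ``alpha`` (comparison is ``<=``), sorted by p-value
    ascending with ties broken by pathway id. The gene table
    (``<prefix>.genes.tsv``) lists each collapsed gene with its selected SNP
    and response value. Floats are printed with six significant digits.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    pathway_path = out_prefix.with_name(out_prefix.name + ".pathways.tsv")
    gene_path = out_prefix.with_name(out_prefix.name + ".genes.tsv")

    n_obs = {pid: 0 for pid in fit.pathway_ids}
    for ge in gene_effects:
        for pid in ge.pathways:
            if pid in n_obs:
                n_obs[pid] += 1

    rows = sorted(
        zip(fit.pathway_ids, fit.t_hat, fit.pvalues),
        key=lambda r: (r[2], r[0]),
    )
    with open(pathway_path, "w") as fh:
        fh.write("pathway_id\tn_genes_observed\tt_hat\tpvalue\tsignificant\n")
        for pid, t, p in rows:
            fh.write(f"{pid}\t{n_obs[pid]}\t{_fmt(t)}\t{_fmt(p)}\t{int(p <= alpha)}\n")

    with open(gene_path, "w") as fh:
        fh.write("gene_id\tsnp_id\tchrom\tpos\ty\tpathways\n")
        for ge in gene_effects:
            fh.write(
                f"{ge.gene_id}\t{ge.snp_id}\t{ge.chrom}\t{ge.pos}\t{_fmt(ge.y)}\t"
                f"{','.join(sorted(ge.pathways))}\n"
            )
    logger.info("wrote %s and %s", pathway_path, gene_path)
    return pathway_path, gene_path
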