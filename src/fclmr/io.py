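"""Readers and writers for the standard formats the pipeline touches.

GTF is 1-based inclusive on disk and converted to the package's internal
0-based half-open convention on read (delegated to pyranges, which performs
the same conversion); BED is already 0-based half-open and passes through
natively. Ortholog tables, expression matrices and sample metadata are TSV;
gene sets are GMT.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .types import (
    CODING,
    LNCRNA,
    ExpressionMatrix,
    GeneModel,
    OrthologMap,
    PathwayDB,
    check_unique_ids,
)

logger = logging.getLogger(__name__)

#: Mapping from annotation-dialect biotype labels to internal biotypes.
DEFAULT_BIOTYPE_RULE: dict[str, str] = {
    "protein_coding": CODING,
    "coding": CODING,
    "lncRNA": LNCRNA,
    "lincRNA": LNCRNA,
    "lnc_RNA": LNCRNA,
    "antisense": LNCRNA,
}

_HEADER_TOKENS = ("gene", "id", "human", "mouse", "ortholog", "symbol", "ensembl")


def _validate_gtf_lines(path: Path) -> int:
    """Cheap structural pass so malformed lines fail with a line number.

    Returns the number of data lines."""
    n_data = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated GTF fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"{path}: line {lineno}: end ({end}) < start ({start})")
            n_data += 1
    return n_data


def _collapse_gene(rows: pd.DataFrame, gene_id: str, species: str, biotype: str) -> GeneModel:
    chroms = rows["Chromosome"].unique()
    if len(chroms) > 1:
        raise ValueError(f"gene {gene_id!r} spans multiple chromosomes: {list(chroms)}")
    strands = rows["Strand"].unique() if "Strand" in rows else ["."]
    strand = strands[0] if len(strands) == 1 and strands[0] in ("+", "-") else "."
    return GeneModel(
        gene_id=gene_id,
        species=species,
        chrom=str(chroms[0]),
        start=int(rows["Start"].min()),
        end=int(rows["End"].max()),
        strand=strand,
        biotype=biotype,
    )


def read_annotation(
    path: str | Path,
    format: str = "gtf",
    biotype_rule: Mapping[str, str] | None = None,
    species: str = "unknown",
) -> list[GeneModel]:
    """Read a GTF or BED annotation into gene-level models.

    Multi-transcript genes are collapsed to the union interval of all their
    records. Records whose biotype label is absent from ``biotype_rule`` are
    skipped with a logged warning (annotation dialects disagree on
    vocabulary, so the mapping is explicit and configurable).

    Parameters
    ----------
    path
        Annotation file.
    format
        ``"gtf"`` (1-based inclusive; converted) or ``"bed"`` (BED6+1 with
        the biotype label in column 7; passed through natively).
    biotype_rule
        label → {"coding", "lncRNA"} mapping; defaults to
        :data:`DEFAULT_BIOTYPE_RULE`.
    species
        Species tag stamped on every gene.
    """
    import pyranges as pr  # deferred: heavy import

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rule = dict(biotype_rule) if biotype_rule is not None else dict(DEFAULT_BIOTYPE_RULE)

    genes: list[GeneModel] = []
    if format == "gtf":
        if _validate_gtf_lines(path) == 0:
            return []
        df = pr.read_gtf(str(path)).df
        if df.empty:
            return []
        if "gene_id" not in df.columns:
            raise ValueError(f"{path}: GTF records carry no gene_id attribute")
        label_col = next(
            (c for c in ("gene_biotype", "gene_type", "biotype") if c in df.columns), None
        )
        if label_col is None:
            raise ValueError(f"{path}: no biotype attribute (gene_biotype/gene_type) found")
        for gene_id, rows in df.groupby("gene_id", sort=True):
            label = rows[label_col].iloc[0]
            if label not in rule:
                logger.warning("skipping gene %s: unknown biotype label %r", gene_id, label)
                continue
            genes.append(_collapse_gene(rows, str(gene_id), species, rule[label]))
    elif format == "bed":
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        except pd.errors.EmptyDataError:
            return []
        if df.shape[1] < 7:
            raise ValueError(f"{path}: BED needs >= 7 columns (BED6 + biotype label)")
        for i, row in df.iterrows():
            label = row[6]
            if label not in rule:
                logger.warning("skipping gene %s: unknown biotype label %r", row[3], label)
                continue
            start, end = int(row[1]), int(row[2])
            if end <= start:
                raise ValueError(f"{path}: row {i + 1}: end ({end}) <= start ({start})")
            genes.append(
                GeneModel(
                    gene_id=str(row[3]),
                    species=species,
                    chrom=str(row[0]),
                    start=start,
                    end=end,
                    strand=row[5] if row[5] in ("+", "-") else ".",
                    biotype=rule[label],
                )
            )
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    check_unique_ids(genes)
    return genes


def write_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    """BED6+1: chrom, start, end, gene_id, score 0, strand, biotype label."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{g.biotype}\n")


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "fclmr") -> None:
    """One gene-level GTF record per gene (0-based half-open → 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            label = "protein_coding" if g.biotype == CODING else "lncRNA"
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{label}";'
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{strand}\t.\t{attrs}\n"
            )


def read_ortholog_table(path: str | Path) -> OrthologMap:
    """Two-column TSV of (species A id, species B id); optional header.

    A header row is recognised when both fields of the first non-comment
    line contain a common column-name token (gene/id/human/mouse/...).
    Duplicate rows collapse; one-to-many relations are retained.
    """
    path = Path(path)
    omap = OrthologMap()
    with open(path) as fh:
        first_data_seen = False
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: row {lineno}: expected two non-empty id fields")
            a, b = fields[0].strip(), fields[1].strip()
            if not first_data_seen:
                first_data_seen = True
                lowered = (a.lower(), b.lower())
                if all(any(tok in f for tok in _HEADER_TOKENS) for f in lowered):
                    continue  # header row
            omap.add(a, b)
    return omap


def write_ortholog_table(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id_a\tgene_id_b\n")
        for a, b in omap.pairs():
            fh.write(f"{a}\t{b}\n")


def read_expression(values_path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Genes × samples TSV plus a sample-metadata TSV.

    The metadata file needs columns ``sample_id``, ``compartment``,
    ``condition`` and ``replicate``; every matrix column must have a
    metadata row, and all abundances must be nonnegative.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ValueError(f"{metadata_path}: metadata lacks a sample_id column")
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values, meta)


def write_expression(expr: ExpressionMatrix, values_path: str | Path, metadata_path: str | Path) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="gene_id", float_format="%.6g")
    expr.sample_meta.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_gene_sets(path: str | Path) -> PathwayDB:
    """Standard GMT: name, description, then member gene ids.

    Members are de-duplicated per pathway; a pathway with zero members is
    skipped with a warning; a duplicated pathway name is an error.
    """
    db = PathwayDB()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: GMT needs name and description fields")
            name, description = fields[0], fields[1]
            members = [m for m in fields[2:] if m.strip()]
            if not members:
                logger.warning("skipping pathway %s (line %d): no members", name, lineno)
                continue
            if name in db:
                raise ValueError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            db.add(name, description, members)
    return db


def write_gene_sets(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in db.pathway_ids():
            members = "\t".join(sorted(db.members(pid)))
            fh.write(f"{pid}\t{db.name(pid)}\t{members}\n")
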