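"""Readers and writers for the external formats shared by every pipeline stage.

Coordinate conventions used throughout the package:

* genomic coordinates are 1-based and inclusive on both ends (GFF3 native);
* gene order along a contig is a 0-based, gap-free ``index`` assigned by
  ascending start coordinate — the PUL caller operates on these indices only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

__all__ = [
    "Gene",
    "GenomeMeta",
    "GFF3ParseError",
    "HitTableError",
    "read_gff3",
    "read_hits_table",
    "read_genome_meta",
    "write_genome_meta",
    "read_newick",
    "write_newick",
]

#: annotation categories a gene label may carry
CATEGORIES = (
    "GH", "PL", "CE", "CBM", "GT",
    "SULFATASE", "PEPTIDASE", "SUSC", "SUSD", "TRANSPORTER", "OTHER",
)


class GFF3ParseError(ValueError):
    """Raised for malformed GFF3 input; the message names the offending line."""


class HitTableError(ValueError):
    """Raised for malformed homology-search tables."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene with its rank along the contig and its labels.

    ``labels`` is a frozenset of ``(category, family)`` pairs, e.g.
    ``("GH", "GH16_3")`` or ``("SUSC", "TIGR04056")``; a gene may carry zero
    or several labels.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    index: int
    start: int
    end: int
    strand: str = "+"
    labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid span {self.start}..{self.end} "
                "(need end >= start >= 1)"
            )

    @property
    def categories(self) -> frozenset:
        return frozenset(cat for cat, _ in self.labels)

    def with_labels(self, labels: Iterable[tuple]) -> "Gene":
        return replace(self, labels=frozenset(labels))


@dataclass(frozen=True)
class GenomeMeta:
    """Assembly-level metadata (completeness/contamination as estimated
    upstream, e.g. by CheckM; consumed, never recomputed here)."""

    genome_id: str
    completeness: float
    contamination: float
    size_bp: int
    gc: float
    genus_id: str
    source: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness <= 100.0):
            raise ValueError(f"{self.genome_id}: completeness out of [0,100]")
        if not (0.0 <= self.contamination <= 100.0):
            raise ValueError(f"{self.genome_id}: contamination out of [0,100]")
        if self.size_bp <= 0:
            raise ValueError(f"{self.genome_id}: size_bp must be positive")

    @property
    def quality(self) -> float:
        """dRep-style quality score: completeness − 5 × contamination."""
        return self.completeness - 5.0 * self.contamination


# ---------------------------------------------------------------------------
# GFF3

_GFF3_STRANDS = {"+", "-", ".", "?"}


def read_gff3(path, genome_id: str | None = None,
              feature_types: Sequence[str] = ("CDS", "gene")) -> list[Gene]:
    """Parse CDS/gene features from a GFF3 file into :class:`Gene` records.

    Genes are sorted by contig then start; per-contig 0-based indices are
    assigned after sorting. Coordinates stay 1-based inclusive. ``genome_id``
    defaults to the file stem.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    raw: list[tuple] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GFF3ParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}..{end_s!r}"
                ) from None
            if start < 1 or end < start:
                raise GFF3ParseError(
                    f"{path}:{lineno}: invalid span {start}..{end}"
                )
            if strand not in _GFF3_STRANDS:
                raise GFF3ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            m = re.search(r"(?:^|;)ID=([^;]+)", attrs)
            if not m:
                raise GFF3ParseError(f"{path}:{lineno}: feature has no ID attribute")
            gene_id = m.group(1)
            if gene_id in seen_ids:
                raise GFF3ParseError(
                    f"{path}:{lineno}: duplicate gene_id {gene_id!r}"
                )
            seen_ids.add(gene_id)
            raw.append((seqid, start, end, strand if strand in "+-" else "+", gene_id))

    raw.sort(key=lambda r: (r[0], r[1], r[2]))
    genes: list[Gene] = []
    idx = 0
    prev_contig = None
    for seqid, start, end, strand, gene_id in raw:
        if seqid != prev_contig:
            idx = 0
            prev_contig = seqid
        genes.append(Gene(gene_id=gene_id, genome_id=gid, contig_id=seqid,
                          index=idx, start=start, end=end, strand=strand))
        idx += 1
    return genes


def write_gff3(genes: Sequence[Gene], path) -> None:
    """Write genes back out as GFF3 CDS features (round-trip partner of
    :func:`read_gff3` on the retained fields)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start)):
            fh.write(
                f"{g.contig_id}\tmagniche\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Homology-search hit tables

#: standard BLAST/DIAMOND outfmt-6 column order; an optional 13th column
#: (qcovhsp) carries query coverage as DIAMOND emits it.
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def read_hits_table(path, dialect: str, source: str):
    """Read a tabular homology-search result into a list of hits.

    ``dialect`` is ``"blast6"`` (12 columns, optional 13th qcovhsp column)
    or ``"hmmer_tbl"`` (6 columns: gene_id, profile, evalue, score, and two
    ignored columns — a reduced domtblout). ``source`` tags every hit with
    the database it came from (see :mod:`magniche.annotation_merge`).
    """
    from .annotation_merge import Hit, SOURCES  # local import, avoids a cycle

    if source not in SOURCES:
        raise HitTableError(f"unknown hit source {source!r}")
    if dialect not in ("blast6", "hmmer_tbl"):
        raise HitTableError(f"unknown hit-table dialect {dialect!r}")

    hits: list = []
    bad_rows: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "blast6":
                if len(fields) not in (12, 13):
                    raise HitTableError(
                        f"{path}:{lineno}: blast6 needs 12 (or 13) columns, "
                        f"got {len(fields)}: {line!r}"
                    )
                try:
                    evalue = float(fields[10])
                    pident = float(fields[2])
                    score = float(fields[11])
                    qcov = float(fields[12]) if len(fields) == 13 else None
                except ValueError:
                    bad_rows.append(f"line {lineno}")
                    continue
                hits.append(Hit(gene_id=fields[0], source=source,
                                family=fields[1], evalue=evalue,
                                pct_identity=pident, query_cover=qcov,
                                score=score))
            else:
                if len(fields) < 4:
                    raise HitTableError(
                        f"{path}:{lineno}: hmmer_tbl needs >=4 columns, "
                        f"got {len(fields)}: {line!r}"
                    )
                try:
                    evalue = float(fields[2])
                    score = float(fields[3])
                except ValueError:
                    bad_rows.append(f"line {lineno}")
                    continue
                hits.append(Hit(gene_id=fields[0], source=source,
                                family=fields[1], evalue=evalue, score=score))
    if bad_rows:
        raise HitTableError(
            f"{path}: {len(bad_rows)} row(s) with non-numeric values "
            f"({', '.join(bad_rows[:5])}{'...' if len(bad_rows) > 5 else ''})"
        )
    return hits


# ---------------------------------------------------------------------------
# Genome metadata TSV

_META_COLUMNS = ["genome_id", "completeness", "contamination",
                 "size_bp", "gc", "genus_id", "source"]


def read_genome_meta(path) -> list[GenomeMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "genus_id": str})
    missing = [c for c in _META_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata TSV missing columns {missing}")
    metas = []
    for row in df.itertuples(index=False):
        metas.append(GenomeMeta(
            genome_id=row.genome_id,
            completeness=float(row.completeness),
            contamination=float(row.contamination),
            size_bp=int(row.size_bp),
            gc=float(row.gc),
            genus_id=row.genus_id,
            source=str(getattr(row, "source", "")),
        ))
    return metas


def write_genome_meta(metas: Sequence[GenomeMeta], path) -> None:
    pd.DataFrame(
        [(m.genome_id, m.completeness, m.contamination, m.size_bp,
          m.gc, m.genus_id, m.source) for m in metas],
        columns=_META_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)


def read_newick(source) -> dendropy.Tree:
    """Read one newick tree from a path or a newick string.

    Leaf labels must be unique; unrooted trees are preserved as read.
    """
    try:
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            tree = dendropy.Tree.get(path=str(source), schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(data=str(source), schema="newick",
                                     preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate leaf labels in tree: {e}") from e
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({x for x in labels if labels.count(x) > 1})
    if dupes:
        raise ValueError(f"duplicate leaf labels in tree: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)
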