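"""Multi-database annotation consensus: threshold filtering and label merging.

Raw homology hits from seven search channels (dbCAN HMMs, CAZy blastp,
SulfAtlas blastp, the Pfam sulfatase HMM, MEROPS blastp, TIGRFAM
TonB-dependent-transporter HMMs and the Pfam SusD HMMs) are filtered with
per-database E-value / identity / coverage thresholds and merged into a
labelled gene table. CAZyme labels (GH/PL/CE/CBM, plus GT) require the dbCAN
and CAZy calls to agree at the family level; all other categories accept a
single surviving line of evidence.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_core import Gene

__all__ = [
    "Hit",
    "ThresholdConfig",
    "GeneTable",
    "AnnotationError",
    "filter_hits",
    "assign_labels",
    "build_gene_table",
]

#: recognised hit sources (databases)
SOURCES = (
    "DBCAN_HMM",
    "CAZY_BLAST",
    "SULFATLAS_BLAST",
    "PFAM_SULF_HMM",
    "MEROPS_BLAST",
    "TIGRFAM_TBDT_HMM",
    "PFAM_SUSD_HMM",
)

#: CAZyme category is the leading letters of the family name (GH16_3 -> GH)
_CAZY_CAT_RE = re.compile(r"^(GH|PL|CE|CBM|GT)\d")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Hit:
    """One row of a homology search result, tagged with its database."""

    gene_id: str
    source: str
    family: str
    evalue: float
    pct_identity: float | None = None
    query_cover: float | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown hit source {self.source!r}")
        if self.evalue < 0:
            raise ValueError(f"{self.gene_id}: negative E-value")
        for name, v in (("pct_identity", self.pct_identity),
                        ("query_cover", self.query_cover)):
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.gene_id}: {name} out of [0,100]")


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-database acceptance thresholds.

    Defaults are the search settings used for flavobacterial MAG
    annotation: dbCAN HMMs at 1e-5; CAZy blastp at 1e-20 with >=30 %
    identity and >=40 % query coverage; SulfAtlas and MEROPS blastp at
    1e-4; the Pfam sulfatase HMM at 1e-5; TIGRFAM TBDT HMMs at 1e-10; the
    Pfam SusD HMMs at 1e-5. ``sulfatase_mode`` controls whether one
    ("either", default) or both ("both") sulfatase evidence channels are
    required for a SULFATASE label.
    """

    evalue_ceilings: Mapping[str, float] = field(default_factory=lambda: {
        "DBCAN_HMM": 1e-5,
        "CAZY_BLAST": 1e-20,
        "SULFATLAS_BLAST": 1e-4,
        "PFAM_SULF_HMM": 1e-5,
        "MEROPS_BLAST": 1e-4,
        "TIGRFAM_TBDT_HMM": 1e-10,
        "PFAM_SUSD_HMM": 1e-5,
    })
    cazy_min_identity: float = 30.0
    cazy_min_coverage: float = 40.0
    sulfatase_mode: str = "either"

    def __post_init__(self) -> None:
        if self.sulfatase_mode not in ("either", "both"):
            raise ValueError("sulfatase_mode must be 'either' or 'both'")


def family_base(family: str) -> str:
    """Strip a dbCAN subfamily suffix: GH16_3 -> GH16 (first '_' onwards)."""
    return family.split("_", 1)[0]


def cazyme_category(family: str) -> str | None:
    m = _CAZY_CAT_RE.match(family)
    return m.group(1) if m else None


def filter_hits(hits: Iterable[Hit], config: ThresholdConfig | None = None) -> list[Hit]:
    """Keep hits passing their database's thresholds; input order preserved.

    A hit survives iff its E-value is at or below the per-source ceiling
    and, for CAZy blastp, identity >= 30 and query coverage >= 40 (both
    fields required). Idempotent by construction.
    """
    config = config or ThresholdConfig()
    out = []
    for h in hits:
        ceiling = config.evalue_ceilings[h.source]
        if h.evalue > ceiling:
            continue
        if h.source == "CAZY_BLAST":
            if h.pct_identity is None or h.query_cover is None:
                raise AnnotationError(
                    f"CAZY_BLAST hit for gene {h.gene_id} lacks identity or "
                    "query-coverage fields required by the filter"
                )
            if h.pct_identity < config.cazy_min_identity:
                continue
            if h.query_cover < config.cazy_min_coverage:
                continue
        out.append(h)
    return out


def _best(hits: Sequence[Hit]) -> Hit:
    # lowest E-value; ties -> higher score, then lexicographic family
    return min(hits, key=lambda h: (h.evalue,
                                    -(h.score if h.score is not None else 0.0),
                                    h.family))


def assign_labels(gene_hits: Iterable[Hit],
                  config: ThresholdConfig | None = None) -> set[tuple]:
    """Merge one gene's surviving hits into a set of (category, family) labels.

    * CAZyme (GH/PL/CE/CBM/GT): emitted only when the best dbCAN and best
      CAZy families agree after stripping the dbCAN subfamily suffix; the
      dbCAN (subfamily) form is reported.
    * SULFATASE: SulfAtlas or Pfam evidence per ``sulfatase_mode``.
    * PEPTIDASE / SUSC / SUSD: any surviving MEROPS / TIGRFAM / Pfam-SusD hit.

    Absence of evidence yields an empty set, never an error.
    """
    config = config or ThresholdConfig()
    by_source: dict[str, list[Hit]] = defaultdict(list)
    for h in gene_hits:
        by_source[h.source].append(h)

    labels: set[tuple] = set()

    if by_source.get("DBCAN_HMM") and by_source.get("CAZY_BLAST"):
        dbcan = _best(by_source["DBCAN_HMM"])
        cazy = _best(by_source["CAZY_BLAST"])
        if family_base(dbcan.family) == family_base(cazy.family):
            cat = cazyme_category(dbcan.family)
            if cat is not None:
                labels.add((cat, dbcan.family))

    sulf_atlas = by_source.get("SULFATLAS_BLAST", [])
    sulf_pfam = by_source.get("PFAM_SULF_HMM", [])
    sulf_ok = (bool(sulf_atlas) and bool(sulf_pfam)) \
        if config.sulfatase_mode == "both" else bool(sulf_atlas or sulf_pfam)
    if sulf_ok:
        fam = _best(sulf_atlas).family if sulf_atlas else _best(sulf_pfam).family
        labels.add(("SULFATASE", fam))

    if by_source.get("MEROPS_BLAST"):
        labels.add(("PEPTIDASE", _best(by_source["MEROPS_BLAST"]).family))
    if by_source.get("TIGRFAM_TBDT_HMM"):
        labels.add(("SUSC", _best(by_source["TIGRFAM_TBDT_HMM"]).family))
    if by_source.get("PFAM_SUSD_HMM"):
        labels.add(("SUSD", _best(by_source["PFAM_SUSD_HMM"]).family))

    return labels


class GeneTable:
    """Ordered, labelled genes of one (or several concatenated) genomes.

    The central substrate for PUL calling, family profiling and the
    per-Mbp density metrics.
    """

    def __init__(self, genes: Sequence[Gene]):
        self.genes: list[Gene] = sorted(
            genes, key=lambda g: (g.genome_id, g.contig_id, g.index))
        self._by_contig: dict[tuple, list[Gene]] = defaultdict(list)
        for g in self.genes:
            self._by_contig[(g.genome_id, g.contig_id)].append(g)
        for key, glist in self._by_contig.items():
            if [g.index for g in glist] != list(range(len(glist))):
                raise ValueError(
                    f"contig {key}: gene indices are not consecutive from 0")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def genome_ids(self) -> list[str]:
        return sorted({g.genome_id for g in self.genes})

    def contigs(self) -> list[tuple]:
        return sorted(self._by_contig)

    def contig_genes(self, genome_id: str, contig_id: str) -> list[Gene]:
        return self._by_contig[(genome_id, contig_id)]

    def category_counts(self) -> pd.Series:
        counts: dict[str, int] = defaultdict(int)
        for g in self.genes:
            for cat in g.categories:
                counts[cat] += 1
        return pd.Series(counts, dtype=int).sort_index()

    def family_counts(self, categories: Iterable[str] | None = None) -> pd.DataFrame:
        """Genome × family count matrix over the selected label categories."""
        cats = set(categories) if categories is not None else None
        rows: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
        for g in self.genes:
            for cat, fam in g.labels:
                if cats is None or cat in cats:
                    rows[g.genome_id][fam] += 1
        df = pd.DataFrame(rows).T.fillna(0).astype(int)
        return df.reindex(sorted(df.index)).reindex(sorted(df.columns), axis=1)

    # -- TSV round trip -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            pairs = sorted(g.labels)
            rows.append((g.genome_id, g.contig_id, g.index, g.gene_id,
                         g.start, g.end, g.strand,
                         ";".join(c for c, _ in pairs),
                         ";".join(f for _, f in pairs)))
        return pd.DataFrame(rows, columns=[
            "genome_id", "contig_id", "index", "gene_id", "start", "end",
            "strand", "categories", "families"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        genes = []
        for row in df.itertuples(index=False):
            cats = row.categories.split(";") if row.categories else []
            fams = row.families.split(";") if row.families else []
            genes.append(Gene(
                gene_id=row.gene_id, genome_id=row.genome_id,
                contig_id=row.contig_id, index=int(row.index),
                start=int(row.start), end=int(row.end), strand=row.strand,
                labels=frozenset(zip(cats, fams))))
        return cls(genes)


def build_gene_table(genes: Sequence[Gene], hits: Iterable[Hit],
                     config: ThresholdConfig | None = None,
                     transporters: Mapping[str, str] | None = None,
                     ) -> GeneTable:
    """Filter hits, merge evidence per gene and attach labels to genes.

    Every hit must reference a known gene; orphan gene ids raise an error
    listing them. ``transporters`` optionally maps gene_id to a free-text
    transporter name taken from a generic annotation source; these become
    TRANSPORTER labels directly, bypassing the hit-table thresholds.
    """
    config = config or ThresholdConfig()
    known = {g.gene_id for g in genes}
    surviving = filter_hits(hits, config)
    orphans = sorted({h.gene_id for h in surviving} - known)
    if orphans:
        raise AnnotationError(
            f"hits reference {len(orphans)} unknown gene_id(s): "
            f"{orphans[:10]}{'...' if len(orphans) > 10 else ''}")
    per_gene: dict[str, list[Hit]] = defaultdict(list)
    for h in surviving:
        per_gene[h.gene_id].append(h)
    transporters = transporters or {}
    labelled = []
    for g in genes:
        labels = assign_labels(per_gene.get(g.gene_id, ()), config)
        if g.gene_id in transporters:
            labels.add(("TRANSPORTER", transporters[g.gene_id]))
        labelled.append(g.with_labels(labels))
    return GeneTable(labelled)
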