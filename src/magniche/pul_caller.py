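"""Polysaccharide utilisation locus (PUL) detection on a labelled gene table.

A PUL candidate is a maximal chain of substrate-utilisation genes
(GH/PL/CE/CBM, sulfatases, SusC, SusD by default) in which every two
consecutive substrate genes are separated by at most ``max_gap`` intervening
non-substrate genes (default 6). A chain is called

* **canonical** when it contains at least one adjacent SusC/SusD gene pair
  together with >= ``min_degradative`` degradative CAZymes (GH/PL/CE), or
* **non-canonical** when it contains >= ``min_chain`` substrate genes
  (default 3) without such a pair;

otherwise no locus is reported. Substrate targets are predicted from
family-content archetypes (alginate, laminarin, α-fucan) in a fixed
priority order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotation_merge import GeneTable, family_base

__all__ = [
    "PULParams",
    "PULCall",
    "SubstrateArchetype",
    "DEFAULT_ARCHETYPES",
    "find_suscd_pairs",
    "build_chains",
    "call_puls",
    "call_puls_from_labels",
    "predict_substrate",
]


@dataclass(frozen=True)
class PULParams:
    """Tunable rule parameters for locus detection.

    ``max_gap`` is the maximum number of intervening non-substrate genes
    between consecutive substrate genes of a chain; ``min_chain`` the
    substrate-gene count needed for a non-canonical call; ``min_degradative``
    the degradative-CAZyme count needed (with a SusC/SusD pair) for a
    canonical call.
    """

    max_gap: int = 6
    min_chain: int = 3
    min_degradative: int = 2
    degradative_categories: frozenset = frozenset({"GH", "PL", "CE"})
    substrate_categories: frozenset = frozenset(
        {"GH", "PL", "CE", "CBM", "SULFATASE", "SUSC", "SUSD"})

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_chain < 1:
            raise ValueError("min_chain must be >= 1")


@dataclass(frozen=True)
class PULCall:
    """A detected locus: an inclusive index span on one contig."""

    genome_id: str
    contig_id: str
    first_index: int
    last_index: int
    pul_class: str  # "canonical" | "noncanonical"
    member_gene_ids: tuple
    n_suscd_pairs: int
    n_degradative: int
    substrate: Optional[str] = None


@dataclass(frozen=True)
class SubstrateArchetype:
    """A family-content signature mapping a locus to a predicted substrate.

    Each requirement is ``(families, min_genes)``: at least ``min_genes``
    member genes whose family (compared at base-family level, subfamily
    suffixes stripped) is in ``families``. The token ``"category:X"``
    matches on label category instead (used for sulfatases).
    """

    substrate: str
    requirements: tuple

    def matches(self, labels: Sequence[frozenset]) -> bool:
        for families, min_genes in self.requirements:
            n = 0
            for gene_labels in labels:
                hit = False
                for cat, fam in gene_labels:
                    for token in families:
                        if token.startswith("category:"):
                            if cat == token.split(":", 1)[1]:
                                hit = True
                        elif "_" in token:
                            if fam == token:  # explicit subfamily signature
                                hit = True
                        elif family_base(fam) == token:
                            hit = True
                if hit:
                    n += 1
            if n < min_genes:
                return False
        return True


#: default archetypes, checked in order (priority alginate > laminarin > α-fucan)
DEFAULT_ARCHETYPES = (
    SubstrateArchetype("alginate", ((frozenset({"PL6", "PL7", "PL17"}), 2),)),
    SubstrateArchetype("laminarin", ((frozenset({"GH16_3"}), 1),
                                     (frozenset({"GH3"}), 1))),
    SubstrateArchetype("alpha-fucan", ((frozenset({"GH29"}), 1),
                                       (frozenset({"category:SULFATASE"}), 2))),
)


# ---------------------------------------------------------------------------
# label-level core (fast path shared by the gene-level API)


def _flags(labels: Sequence[frozenset], params: PULParams):
    sub, deg, susc, susd = [], [], [], []
    for gene_labels in labels:
        cats = {c for c, _ in gene_labels}
        sub.append(bool(cats & params.substrate_categories))
        deg.append(bool(cats & params.degradative_categories))
        susc.append("SUSC" in cats)
        susd.append("SUSD" in cats)
    return sub, deg, susc, susd


def _greedy_pairs(susc: Sequence[bool], susd: Sequence[bool],
                  lo: int, hi: int) -> list[tuple]:
    """Left-to-right greedy adjacent SusC/SusD pairing on [lo, hi]."""
    pairs = []
    i = lo
    while i < hi:
        if (susc[i] and susd[i + 1]) or (susd[i] and susc[i + 1]):
            pairs.append((i, i + 1))
            i += 2
        else:
            i += 1
    return pairs


def _chain_spans(sub: Sequence[bool], max_gap: int) -> list[tuple]:
    positions = [i for i, s in enumerate(sub) if s]
    spans = []
    if not positions:
        return spans
    first = prev = positions[0]
    for p in positions[1:]:
        if p - prev - 1 <= max_gap:
            prev = p
        else:
            spans.append((first, prev))
            first = prev = p
    spans.append((first, prev))
    return spans


def call_puls_from_labels(labels: Sequence[frozenset],
                          params: PULParams | None = None) -> list[tuple]:
    """Core detection on a bare label sequence (one contig).

    Returns ``(first, last, pul_class, n_pairs, n_degradative)`` tuples in
    index order. The gene-level :func:`call_puls` delegates here.
    """
    params = params or PULParams()
    sub, deg, susc, susd = _flags(labels, params)
    calls = []
    for first, last in _chain_spans(sub, params.max_gap):
        n_pairs = len(_greedy_pairs(susc, susd, first, last))
        n_deg = sum(deg[first:last + 1])
        n_sub = sum(sub[first:last + 1])
        if n_pairs >= 1 and n_deg >= params.min_degradative:
            calls.append((first, last, "canonical", n_pairs, n_deg))
        elif n_sub >= params.min_chain:
            calls.append((first, last, "noncanonical", n_pairs, n_deg))
    return calls


# ---------------------------------------------------------------------------
# gene-table API


def find_suscd_pairs(gene_table: GeneTable, genome_id: str,
                     contig_id: str) -> list[tuple]:
    """Adjacent SusC/SusD gene pairs (either order) on one contig, paired
    greedily left to right so each gene joins at most one pair."""
    genes = gene_table.contig_genes(genome_id, contig_id)
    susc = ["SUSC" in g.categories for g in genes]
    susd = ["SUSD" in g.categories for g in genes]
    return _greedy_pairs(susc, susd, 0, len(genes) - 1)


def build_chains(gene_table: GeneTable, genome_id: str, contig_id: str,
                 params: PULParams | None = None) -> list[tuple]:
    """Maximal substrate-gene chains on one contig as inclusive index spans,
    trimmed to start and end on substrate genes."""
    params = params or PULParams()
    genes = gene_table.contig_genes(genome_id, contig_id)
    sub = [bool(g.categories & params.substrate_categories) for g in genes]
    return _chain_spans(sub, params.max_gap)


def predict_substrate(member_labels: Sequence[frozenset],
                      archetypes: Iterable[SubstrateArchetype] = DEFAULT_ARCHETYPES,
                      ) -> Optional[str]:
    """First matching archetype's substrate, or None when none match."""
    for arch in archetypes:
        if arch.matches(member_labels):
            return arch.substrate
    return None


def call_puls(gene_table: GeneTable, params: PULParams | None = None,
              archetypes: Iterable[SubstrateArchetype] = DEFAULT_ARCHETYPES,
              ) -> list[PULCall]:
    """Detect PULs on every contig of a labelled gene table."""
    params = params or PULParams()
    archetypes = tuple(archetypes)
    calls: list[PULCall] = []
    for genome_id, contig_id in gene_table.contigs():
        genes = gene_table.contig_genes(genome_id, contig_id)
        labels = [g.labels for g in genes]
        for first, last, cls, n_pairs, n_deg in call_puls_from_labels(labels, params):
            members = genes[first:last + 1]
            calls.append(PULCall(
                genome_id=genome_id, contig_id=contig_id,
                first_index=first, last_index=last, pul_class=cls,
                member_gene_ids=tuple(g.gene_id for g in members),
                n_suscd_pairs=n_pairs, n_degradative=n_deg,
                substrate=predict_substrate([g.labels for g in members],
                                            archetypes)))
    return calls


def puls_to_frame(calls: Sequence[PULCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.genome_id, c.contig_id, c.first_index, c.last_index, c.pul_class,
          c.n_suscd_pairs, c.n_degradative, c.substrate or "",
          ";".join(c.member_gene_ids)) for c in calls],
        columns=["genome_id", "contig_id", "first_index", "last_index",
                 "pul_class", "n_suscd_pairs", "n_degradative", "substrate",
                 "member_gene_ids"])
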