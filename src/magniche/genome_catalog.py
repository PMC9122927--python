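"""Species dereplication, per-genus genome selection and gene-family sharing.

Genomes are collapsed into species-level clusters at 95 % average nucleotide
identity (ANI) by a greedy, quality-ordered procedure (quality = completeness
− 5 × contamination, the dRep convention). Genus-level comparisons use the
three most complete genomes per genus and presence/absence of gene families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import mean, median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import GenomeMeta

__all__ = [
    "ANIMatrix",
    "SpeciesCluster",
    "greedy_dereplicate",
    "select_top_complete",
    "conserved_families",
    "partition_shared_families",
    "cluster_identity_summary",
]


class ANIMatrix:
    """Symmetric pairwise identity matrix (percent), diagonal fixed at 100.

    Missing comparisons (NaN) are legal and treated as below any clustering
    threshold — all-vs-all ANI tools omit distant pairs.
    """

    def __init__(self, df: pd.DataFrame):
        if list(df.index) != list(df.columns):
            raise ValueError("ANI matrix must have identical row/column ids")
        values = df.to_numpy(dtype=float)
        both = ~np.isnan(values) & ~np.isnan(values.T)
        if not np.allclose(values[both & both.T].reshape(-1),
                           values.T[both & both.T].reshape(-1), atol=1e-6):
            raise ValueError("ANI matrix is not symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmax(values) > 100.0 + 1e-9 or np.nanmin(values) < 0.0:
                raise ValueError("ANI values must lie in [0,100]")
        np.fill_diagonal(values, 100.0)
        self.df = pd.DataFrame(values, index=df.index, columns=df.columns)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.index)

    def identity(self, a: str, b: str) -> float:
        """Pairwise identity; NaN for missing comparisons."""
        return float(self.df.at[a, b])

    @classmethod
    def from_tsv(cls, path) -> "ANIMatrix":
        """Read either a square matrix TSV (ids as header/index) or a long
        three-column (query, reference, ani) table."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[1] == 2 and \
                set(map(str, df.columns)) != set(map(str, df.index)):  # long form
            long = pd.read_csv(path, sep="\t")
            long.columns = ["a", "b", "ani"]
            ids = sorted(set(long["a"]) | set(long["b"]))
            sq = pd.DataFrame(np.nan, index=ids, columns=ids)
            for a, b, v in long.itertuples(index=False):
                sq.at[a, b] = v
                sq.at[b, a] = v
            return cls(sq)
        df.columns = [str(c) for c in df.columns]
        df.index = [str(i) for i in df.index]
        return cls(df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class SpeciesCluster:
    representative: str
    members: tuple

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be among members")


def greedy_dereplicate(ani: ANIMatrix, metas: Sequence[GenomeMeta],
                       threshold: float = 95.0) -> list[SpeciesCluster]:
    """Greedy species clustering at an inclusive ANI threshold.

    Genomes are ranked by quality (completeness − 5 × contamination; ties
    broken by larger size, then id); the best unassigned genome seeds a
    cluster and absorbs every unassigned genome with identity >= threshold.
    Representatives are therefore pairwise below threshold.
    """
    ids = set(ani.genome_ids)
    missing = [m.genome_id for m in metas if m.genome_id not in ids]
    if missing:
        raise ValueError(f"genomes missing from ANI matrix: {missing}")
    order = sorted(metas, key=lambda m: (-m.quality, -m.size_bp, m.genome_id))
    unassigned = [m.genome_id for m in order]
    clusters: list[SpeciesCluster] = []
    while unassigned:
        rep = unassigned.pop(0)
        members = [rep]
        rest = []
        for g in unassigned:
            ident = ani.identity(rep, g)
            if not np.isnan(ident) and ident >= threshold:
                members.append(g)
            else:
                rest.append(g)
        unassigned = rest
        clusters.append(SpeciesCluster(representative=rep,
                                       members=tuple(sorted(members))))
    return clusters


def select_top_complete(metas: Sequence[GenomeMeta], genus_id: str,
                        n: int = 3) -> list[str]:
    """The n most complete genomes of a genus (ties: lower contamination,
    then larger size). Fewer than n genomes are returned whole, with a
    warning."""
    pool = [m for m in metas if m.genus_id == genus_id]
    if not pool:
        raise ValueError(f"unknown genus {genus_id!r}")
    pool.sort(key=lambda m: (-m.completeness, m.contamination,
                             -m.size_bp, m.genome_id))
    if len(pool) < n:
        warnings.warn(
            f"genus {genus_id}: only {len(pool)} genome(s) available "
            f"(requested {n})", stacklevel=2)
    return [m.genome_id for m in pool[:n]]


def conserved_families(profiles: pd.DataFrame,
                       genome_ids: Sequence[str]) -> set[str]:
    """Families present (count >= 1) in every listed genome — the
    presence-set intersection."""
    if len(genome_ids) == 0:
        raise ValueError("genome id list is empty")
    sub = profiles.loc[list(genome_ids)]
    present = (sub > 0).all(axis=0)
    return set(present.index[present])


def partition_shared_families(presence: Mapping[str, set]) -> dict:
    """Partition the union of per-genus family sets into universal
    (all genera), unique (exactly one) and shared (1 < k < all; mapped to
    their genus count)."""
    if len(presence) < 2:
        raise ValueError("need at least two genera")
    n = len(presence)
    union: set[str] = set().union(*presence.values())
    counts = {fam: sum(fam in s for s in presence.values()) for fam in union}
    return {
        "universal": {f for f, k in counts.items() if k == n},
        "unique": {f for f, k in counts.items() if k == 1},
        "shared": {f: k for f, k in counts.items() if 1 < k < n},
    }


def _stats(values: list[float]) -> dict:
    return {"min": min(values), "median": median(values), "mean": mean(values)}


def cluster_identity_summary(matrix: pd.DataFrame,
                             clusters: Sequence[SpeciesCluster | Sequence[str]],
                             ) -> dict:
    """Within- and between-cluster identity summaries over unordered pairs.

    Returns ``{"intra": {representative_or_index: stats_or_None}, "inter":
    stats_or_None}``; singleton clusters report intra statistics as None
    (absent, not zero). Works for any symmetric identity matrix — 16S
    similarity, AAI or ANI.
    """
    member_lists: list[tuple[str, list[str]]] = []
    for i, c in enumerate(clusters):
        if isinstance(c, SpeciesCluster):
            member_lists.append((c.representative, list(c.members)))
        else:
            member_lists.append((str(i), list(c)))
    intra: dict[str, dict | None] = {}
    assigned: dict[str, int] = {}
    for ci, (key, members) in enumerate(member_lists):
        for m in members:
            assigned[m] = ci
        vals = [float(matrix.at[a, b])
                for i, a in enumerate(members) for b in members[i + 1:]]
        intra[key] = _stats(vals) if vals else None
    all_members = list(assigned)
    inter_vals = [float(matrix.at[a, b])
                  for i, a in enumerate(all_members)
                  for b in all_members[i + 1:]
                  if assigned[a] != assigned[b]]
    return {"intra": intra, "inter": _stats(inter_vals) if inter_vals else None}


def family_profile(gene_tables: Iterable, categories: Sequence[str] | None = None,
                   ) -> pd.DataFrame:
    """Concatenate per-genome family counts into one genome × family matrix."""
    frames = [gt.family_counts(categories) for gt in gene_tables]
    df = pd.concat(frames).fillna(0).astype(int)
    df = df.groupby(level=0).sum()
    return df.reindex(sorted(df.columns), axis=1)
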