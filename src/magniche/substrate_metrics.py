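"""Per-Mbp gene-category densities, genus-level summaries and GH:X ratios.

Densities are genes per megabase of assembly; genus summaries are unweighted
means over the three most complete genomes of the genus, with display
rounding (densities and PUL counts to integers, sizes to two decimals, GC to
integers) applied only at formatting time. Substrate-preference ratios are
written "1:x" with x = other/GH rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .genome_catalog import select_top_complete
from .io_core import GenomeMeta

__all__ = [
    "density_per_mbp",
    "ratio_to_gh",
    "GenusSummary",
    "genus_summary",
    "genus_table",
    "NS5_REFERENCE_TABLE",
]

#: fixed column order for the genus summary table
GENUS_TABLE_COLUMNS = [
    "genus_id", "completeness", "contamination", "size_mbp", "gc",
    "GH_per_mbp", "CAZyme_per_mbp", "peptidase_per_mbp", "sulfatase_per_mbp",
    "TBDT_per_mbp", "SusC_per_mbp", "SusD_per_mbp", "PULs",
    "GH:peptidase", "GH:sulfatase", "GH:TBDT",
]

#: Published genus-level values for the four NS5 marine group genera
#: (per-Mbp integer densities and the ratio strings printed alongside them);
#: shipped as reference data for the worked reproduction example.
NS5_REFERENCE_TABLE = pd.DataFrame(
    [
        ("NS5_A", 81.4, 0.3, 1.17, 30, 5, 7, 8, 8, 7, 2, 3, 0,
         "1:1.6", "1:1.6", "1:1.4"),
        ("NS5_B", 97.3, 0.5, 1.82, 30, 9, 12, 8, 13, 8, 2, 2, 2,
         "1:0.9", "1:1.4", "1:0.9"),
        ("NS5_D", 99.1, 1.4, 2.02, 37, 9, 12, 7, 9, 9, 4, 4, 3,
         "1:0.8", "1:1", "1:1"),
        ("NS5_F", 97.0, 0.1, 2.05, 36, 7, 10, 7, 4, 9, 2, 3, 2,
         "1:1", "1:0.6", "1:1.3"),
    ],
    columns=GENUS_TABLE_COLUMNS,
).set_index("genus_id")


def density_per_mbp(count: int, size_bp: int) -> float:
    """Gene count normalised to genes per Mbp of assembly."""
    if size_bp <= 0:
        raise ValueError("size_bp must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / (size_bp / 1_000_000)


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def ratio_to_gh(gh_density: float, other_density: float) -> str:
    """Format other/GH as a "1:x" preference ratio.

    x is rounded half-up to one decimal and a trailing ".0" is dropped
    (8/5 -> "1:1.6", 9/9 -> "1:1"). A zero GH density makes the ratio
    undefined, reported as "NA".
    """
    if gh_density == 0:
        return "NA"
    x = _round_half_up(other_density / gh_density, 1)
    return f"1:{int(x)}" if x == int(x) else f"1:{x}"


@dataclass(frozen=True)
class GenusSummary:
    """Unrounded genus-level means; :meth:`format_row` applies the display
    rounding used in the summary table."""

    genus_id: str
    genome_ids: tuple
    completeness: float
    contamination: float
    size_mbp: float
    gc: float
    densities: Mapping[str, float]  # category -> mean density per Mbp
    pul_count: float

    def ratio(self, other_category: str, from_rounded: bool = False) -> str:
        gh = self.densities.get("GH", 0.0)
        other = self.densities.get(other_category, 0.0)
        if from_rounded:
            gh, other = _round_half_up(gh), _round_half_up(other)
        return ratio_to_gh(gh, other)

    def format_row(self, ratios_from_rounded: bool = False) -> dict:
        row = {
            "genus_id": self.genus_id,
            "completeness": _round_half_up(self.completeness, 1),
            "contamination": _round_half_up(self.contamination, 1),
            "size_mbp": _round_half_up(self.size_mbp, 2),
            "gc": int(_round_half_up(self.gc)),
        }
        for col, cat in [("GH_per_mbp", "GH"), ("CAZyme_per_mbp", "CAZYME"),
                         ("peptidase_per_mbp", "PEPTIDASE"),
                         ("sulfatase_per_mbp", "SULFATASE"),
                         ("TBDT_per_mbp", "SUSC"), ("SusC_per_mbp", "SUSC"),
                         ("SusD_per_mbp", "SUSD")]:
            row[col] = int(_round_half_up(self.densities.get(cat, 0.0)))
        row["PULs"] = int(_round_half_up(self.pul_count))
        row["GH:peptidase"] = self.ratio("PEPTIDASE", ratios_from_rounded)
        row["GH:sulfatase"] = self.ratio("SULFATASE", ratios_from_rounded)
        row["GH:TBDT"] = self.ratio("SUSC", ratios_from_rounded)
        return row


def genus_summary(metas: Sequence[GenomeMeta],
                  densities: pd.DataFrame,
                  pul_counts: Mapping[str, int],
                  genus_id: str,
                  top_n: int = 3) -> GenusSummary:
    """Average genomic statistics and category densities over the ``top_n``
    most complete genomes of a genus.

    ``densities`` is a genome × category table of per-Mbp densities (see
    :func:`density_per_mbp`); ``pul_counts`` maps genome_id to its detected
    locus count. Densities are averaged per genome, never pooled.
    """
    chosen = select_top_complete(metas, genus_id, n=top_n)
    by_id = {m.genome_id: m for m in metas}
    sel = [by_id[g] for g in chosen]
    dens = densities.loc[chosen].mean(axis=0)
    return GenusSummary(
        genus_id=genus_id,
        genome_ids=tuple(chosen),
        completeness=sum(m.completeness for m in sel) / len(sel),
        contamination=sum(m.contamination for m in sel) / len(sel),
        size_mbp=sum(m.size_bp for m in sel) / len(sel) / 1e6,
        gc=sum(m.gc for m in sel) / len(sel),
        densities=dens.to_dict(),
        pul_count=sum(pul_counts.get(g, 0) for g in chosen) / len(chosen),
    )


def genus_table(metas: Sequence[GenomeMeta], densities: pd.DataFrame,
                pul_counts: Mapping[str, int], top_n: int = 3,
                ratios_from_rounded: bool = False) -> pd.DataFrame:
    """One formatted summary row per genus, in the fixed column order."""
    genera = sorted({m.genus_id for m in metas})
    rows = [genus_summary(metas, densities, pul_counts, g, top_n)
            .format_row(ratios_from_rounded) for g in genera]
    return pd.DataFrame(rows, columns=GENUS_TABLE_COLUMNS).set_index("genus_id")


def category_densities(gene_table, metas: Sequence[GenomeMeta],
                       ) -> pd.DataFrame:
    """Genome × category per-Mbp density table from a labelled gene table.

    The CAZYME pseudo-category sums GH+PL+CE+CBM+GT; TBDT density is the
    SUSC column (TonB-dependent transporters are what the SusC channel
    detects).
    """
    sizes = {m.genome_id: m.size_bp for m in metas}
    counts: dict[str, dict[str, int]] = {}
    for g in gene_table.genes:
        per = counts.setdefault(g.genome_id, {})
        for cat in g.categories:
            per[cat] = per.get(cat, 0) + 1
    rows = {}
    cazyme_cats = ("GH", "PL", "CE", "CBM", "GT")
    for genome_id in sizes:
        per = counts.get(genome_id, {})
        row = {cat: density_per_mbp(n, sizes[genome_id])
               for cat, n in per.items()}
        row["CAZYME"] = density_per_mbp(
            sum(per.get(c, 0) for c in cazyme_cats), sizes[genome_id])
        rows[genome_id] = row
    return pd.DataFrame(rows).T.fillna(0.0).sort_index()
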