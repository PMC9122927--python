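"""Read-recruitment abundance statistics and environmental correlation.

Mapped-read counts are normalised to RPKM (reads per kilobase of genome per
million sample reads); per-base depth vectors yield breadth of coverage and
the truncated average depth (TAD — the mean after discarding the extreme
low and high tails, 10 % per tail by default, i.e. TAD80). A presence
cut-off of 0.25 RPKM (inclusive) flags records rather than deleting them.
Environmental associations use Pearson correlation of RPKM against
log10-transformed parameter values. Oligotype recruitment at the 100 %
identity threshold is implemented as exact substring matching on both
strands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "AbundanceRecord",
    "CorrelationResult",
    "compute_rpkm",
    "compute_depth_stats",
    "build_records",
    "filter_by_rpkm",
    "aggregate_genus",
    "correlate_env",
    "recruit_oligotypes",
]

DEFAULT_MIN_RPKM = 0.25
DEFAULT_TRIM_FRACTION = 0.10

#: environmental parameters carried by an EnvTable sample row
ENV_PARAMETERS = ("depth_m", "temperature", "salinity", "oxygen",
                  "chlorophyll_a", "nitrite", "nitrate_nitrite",
                  "phosphate", "silicate")


@dataclass
class AbundanceRecord:
    sample_id: str
    genome_id: str
    rpkm: float
    breadth: Optional[float] = None  # percent of positions with depth >= 1
    tad: Optional[float] = None
    passes_threshold: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    parameter: str
    r: Optional[float]
    p_value: Optional[float]
    n: int
    reason: Optional[str] = None  # set when the correlation is undefined


def compute_rpkm(mapped_reads: int, genome_len_bp: int, total_reads: int) -> float:
    """reads / (genome length in kb × sample reads in millions)."""
    if genome_len_bp <= 0:
        raise ValueError("genome_len_bp must be positive")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return mapped_reads / ((genome_len_bp / 1000.0) * (total_reads / 1_000_000.0))


def compute_depth_stats(depth, trim_fraction: float = DEFAULT_TRIM_FRACTION,
                        ) -> tuple[float, float]:
    """(breadth %, TAD) of a per-base depth vector.

    Breadth is the percentage of positions with depth >= 1. TAD removes
    floor(trim_fraction × n) lowest and the same number of highest values
    before averaging; trim_fraction 0 gives the plain mean.
    """
    d = np.asarray(depth, dtype=float)
    if d.size == 0:
        raise ValueError("depth vector is empty")
    if not (0.0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    if (d < 0).any():
        raise ValueError("negative depth values")
    breadth = 100.0 * float((d >= 1).sum()) / d.size
    k = math.floor(trim_fraction * d.size)
    trimmed = np.sort(d)[k:d.size - k] if k else np.sort(d)
    return breadth, float(trimmed.mean())


def build_records(mappings: pd.DataFrame,
                  genome_lengths: Mapping[str, int],
                  depths: Mapping[tuple, Sequence[float]] | None = None,
                  min_rpkm: float = DEFAULT_MIN_RPKM,
                  trim_fraction: float = DEFAULT_TRIM_FRACTION,
                  ) -> list[AbundanceRecord]:
    """Turn a mapping summary table (sample_id, genome_id, mapped_reads,
    total_reads) plus optional per-(sample, genome) depth vectors into
    threshold-flagged abundance records."""
    records = []
    for row in mappings.itertuples(index=False):
        rpkm = compute_rpkm(int(row.mapped_reads),
                            genome_lengths[row.genome_id],
                            int(row.total_reads))
        breadth = tad = None
        if depths is not None and (row.sample_id, row.genome_id) in depths:
            breadth, tad = compute_depth_stats(
                depths[(row.sample_id, row.genome_id)], trim_fraction)
        records.append(AbundanceRecord(
            sample_id=str(row.sample_id), genome_id=str(row.genome_id),
            rpkm=rpkm, breadth=breadth, tad=tad))
    return filter_by_rpkm(records, min_rpkm)


def filter_by_rpkm(records: Sequence[AbundanceRecord],
                   min_rpkm: float = DEFAULT_MIN_RPKM) -> list[AbundanceRecord]:
    """Set ``passes_threshold`` (inclusive at the cut-off); records are
    flagged, never dropped."""
    for r in records:
        r.passes_threshold = r.rpkm >= min_rpkm
    return list(records)


def aggregate_genus(records: Sequence[AbundanceRecord],
                    genus_of: Mapping[str, str],
                    passing_only: bool = False) -> pd.DataFrame:
    """Sum species RPKM into genus RPKM per sample.

    By default all records are summed regardless of the threshold flag;
    ``passing_only`` restricts the sum to flagged records.
    """
    unmapped = sorted({r.genome_id for r in records} - set(genus_of))
    if unmapped:
        raise ValueError(f"genomes without genus assignment: {unmapped}")
    rows = [(r.sample_id, genus_of[r.genome_id], r.rpkm)
            for r in records if (r.passes_threshold or not passing_only)]
    df = pd.DataFrame(rows, columns=["sample_id", "genus_id", "rpkm"])
    return (df.groupby(["sample_id", "genus_id"], as_index=False)["rpkm"]
              .sum())


def correlate_env(records: Sequence[AbundanceRecord],
                  env: pd.DataFrame, parameter: str,
                  min_rpkm: float = DEFAULT_MIN_RPKM) -> CorrelationResult:
    """Pearson correlation of RPKM vs log10(parameter) over passing samples.

    Samples with non-positive or missing parameter values are excluded from
    the log transform. A constant series (or n < 3) leaves the correlation
    undefined; the result then carries a reason instead of r/p.
    """
    if parameter not in env.columns:
        raise ValueError(f"unknown environmental parameter {parameter!r}")
    values = env[parameter]
    xs, ys = [], []
    for r in records:
        if r.rpkm < min_rpkm or r.sample_id not in env.index:
            continue
        v = values.get(r.sample_id)
        if v is None or pd.isna(v) or v <= 0:
            continue
        xs.append(math.log10(float(v)))
        ys.append(r.rpkm)
    n = len(xs)
    if n < 3:
        return CorrelationResult(parameter, None, None, n,
                                 reason="fewer than 3 usable samples")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return CorrelationResult(parameter, None, None, n,
                                 reason="constant series")
    r_val, p_val = stats.pearsonr(ys, xs)
    return CorrelationResult(parameter, float(r_val), float(p_val), n)


def recruit_oligotypes(oligotype_fasta, reference_fasta,
                       identity_threshold: float = 100.0) -> pd.DataFrame:
    """Exact (100 % identity) oligotype-to-reference recruitment.

    An oligotype matches a reference when it occurs verbatim as a substring
    of the reference sequence or of its reverse complement. Only the exact
    mode is implemented; sub-100 % thresholds need a read mapper.
    Returns a table (oligotype_id, genome_id, matched, position, strand)
    with 0-based forward-strand positions (-1 when unmatched).
    """
    if identity_threshold != 100.0:
        raise ValueError(
            "only the 100% identity (exact substring) mode is supported; "
            "use an external read mapper for lower thresholds")
    oligos = list(SeqIO.parse(str(oligotype_fasta), "fasta"))
    refs = list(SeqIO.parse(str(reference_fasta), "fasta"))
    rows = []
    for ref in refs:
        fwd = str(ref.seq).upper()
        rev = str(Seq(fwd).reverse_complement())
        for ol in oligos:
            q = str(ol.seq).upper()
            pos = fwd.find(q)
            strand = "+"
            if pos < 0:
                rc_pos = rev.find(q)
                if rc_pos >= 0:
                    # report the forward-strand coordinate of the match start
                    pos = len(fwd) - rc_pos - len(q)
                    strand = "-"
            rows.append((ol.id, ref.id, pos >= 0, pos if pos >= 0 else -1,
                         strand if pos >= 0 else ""))
    return pd.DataFrame(rows, columns=["oligotype_id", "genome_id",
                                       "matched", "position", "strand"])
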