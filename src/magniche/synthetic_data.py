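"""Synthetic input bundles with known ground truth for every pipeline stage.

The generator emulates the study conditions the pipeline was designed for:
a set of marine flavobacterial MAGs organised into genera and species
(genome sizes ~1.2–2.1 Mbp), multi-database annotation hit tables with
controllable inter-source agreement and decoy hits placed just outside the
acceptance thresholds, planted canonical/non-canonical PULs following the
conserved archetypes (alginate, laminarin, α-fucan), block-structured ANI
matrices (within-species >= 95 %), read-recruitment mapping summaries with
planted RPKM and depth profiles, environmental covariates with planted
log-linear responses, and tree sets sharing planted stable clades.

Gene *sequences* are not simulated: annotation is label-level, and no stage
downstream of the consumed search tables needs residues except oligotype
matching, which gets random sequences with planted substrings. Background
substrate genes are rejection-placed so they can never extend or create a
chain, making planted PUL truth exact — a generator guarantee, not a
property of real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_merge import Hit, ThresholdConfig, family_base
from .io_core import Gene, GenomeMeta, write_genome_meta, write_gff3
from .genome_catalog import ANIMatrix

__all__ = [
    "SimConfig",
    "NoiseParams",
    "GenomeBundle",
    "MappingBundle",
    "simulate_genome_set",
    "simulate_hit_tables",
    "simulate_ani_matrix",
    "simulate_mapping",
    "simulate_tree_set",
    "simulate_family_profiles",
    "write_hit_tables",
]


@dataclass(frozen=True)
class NoiseParams:
    """Annotation noise: per-source false-negative (dropout) rates, and a
    decoy rate emitting hits placed just outside the thresholds (E-value a
    ``decoy_margin`` factor above the ceiling, or identity/coverage below
    the floors) which a correct filter must remove."""

    false_negative: Mapping[str, float] = field(default_factory=dict)
    decoy_rate: float = 0.0
    decoy_margin: float = 10.0

    def fn(self, source: str) -> float:
        return float(self.false_negative.get(source, 0.0))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the generator.

    4 genera × 3 species × 2 genomes, genome sizes 1.17–2.05 Mbp, two
    planted PULs per genome cycling through the conserved archetypes, a 2 %
    background annotation rate, within-species ANI 96–99 %, within-genus
    80–94 %, between-genus 70–79 %, 20 samples of 10⁶ reads each, and six
    input trees over 12 taxa sharing two planted stable clades.
    """

    seed: int = 0
    n_genera: int = 4
    species_per_genus: int = 3
    genomes_per_species: int = 2
    genome_size_bp: tuple = (1_170_000, 2_050_000)
    contigs_per_genome: tuple = (3, 6)
    mean_gene_footprint_bp: int = 1200
    puls_per_genome: int = 2
    background_label_rate: float = 0.02
    noise: NoiseParams = field(default_factory=NoiseParams)
    ani_within_species: tuple = (96.0, 99.0)
    ani_within_genus: tuple = (80.0, 94.0)
    ani_between_genus: tuple = (70.0, 79.0)
    n_samples: int = 20
    total_reads: int = 1_000_000
    read_len: int = 100
    depth_bins: int = 2000
    depth_overdispersion: float = 0.3
    env_slope: float = 2.0
    env_intercept: float = 0.5
    env_noise_sd: float = 0.05
    n_trees: int = 6
    n_taxa: int = 12
    tree_perturbation: float = 1.0
    pul_isolation_gap: int = 7  # > max_gap: blocks accidental chain fusion

    def species_layout(self) -> list[tuple]:
        """(genome_id, species_id, genus_id) triples for the configured set."""
        out = []
        for g in range(self.n_genera):
            genus = f"genus_{chr(ord('A') + g)}"
            for s in range(self.species_per_genus):
                species = f"{genus}_sp{s + 1}"
                for k in range(self.genomes_per_species):
                    out.append((f"{species}_mag{k + 1}", species, genus))
        return out


# --- planted PUL archetype templates (label list, class, substrate) --------

_TEMPLATES = (
    ("alginate", "canonical",
     (("SUSC", "TIGR04056"), ("SUSD", "PF12741"), ("SUSC", "TIGR04056"),
      ("SUSD", "PF12741"), ("PL", "PL6"), ("PL", "PL7"), ("PL", "PL17"))),
    ("laminarin", "canonical",
     (("SUSC", "TIGR04056"), ("SUSD", "PF12741"), ("GH", "GH16_3"),
      ("GH", "GH16_3"), ("GH", "GH3"), ("GH", "GH109"))),
    ("alpha-fucan", "noncanonical",
     (("GH", "GH29"), ("GH", "GH29"), ("SULFATASE", "S1_15"),
      ("SULFATASE", "S1_16"), ("GH", "GH33"))),
    (None, "noncanonical",
     (("GH", "GH13_31"), ("CE", "CE4"), ("GH", "GH2"))),
)

_SUBSTRATE_CATS = {"GH", "PL", "CE", "CBM", "SULFATASE", "SUSC", "SUSD"}

#: background label pool (category, family) with sampling weights
_BACKGROUND_POOL = (
    (("PEPTIDASE", "M1"), 0.25), (("PEPTIDASE", "S8"), 0.15),
    (("GT", "GT2"), 0.15), (("TRANSPORTER", "AmtB"), 0.1),
    (("GH", "GH23"), 0.1), (("SUSC", "TIGR01783"), 0.05),
    (("SULFATASE", "S1_4"), 0.05), (("CBM", "CBM50"), 0.05),
    (("CE", "CE11"), 0.05), (("GH", "GH73"), 0.05),
)


@dataclass
class GenomeBundle:
    """A simulated genome set plus its ground truth."""

    config: SimConfig
    genes: list  # list[Gene], all genomes, unlabelled
    metas: list  # list[GenomeMeta]
    truth_labels: dict  # gene_id -> frozenset[(category, family)]
    truth_puls: pd.DataFrame  # genome/contig/first/last/class/substrate
    species_of: dict
    genus_of: dict

    @property
    def genome_lengths(self) -> dict:
        return {m.genome_id: m.size_bp for m in self.metas}

    @property
    def transporter_annotations(self) -> dict:
        """gene_id -> transporter name, the generic-annotation channel
        (TRANSPORTER labels never travel through the hit tables)."""
        return {gid: fam for gid, labels in self.truth_labels.items()
                for cat, fam in labels if cat == "TRANSPORTER"}

    def labelled_gene_table(self):
        """Gene table carrying the *truth* labels (bypasses annotation)."""
        from .annotation_merge import GeneTable
        return GeneTable([g.with_labels(self.truth_labels[g.gene_id])
                          for g in self.genes])

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        truth = outdir / "truth"
        truth.mkdir(exist_ok=True)
        by_genome: dict[str, list] = {}
        for g in self.genes:
            by_genome.setdefault(g.genome_id, []).append(g)
        for genome_id, genes in by_genome.items():
            write_gff3(genes, outdir / f"{genome_id}.gff3")
        write_genome_meta(self.metas, outdir / "genome_meta.tsv")
        rows = [(gid, ";".join(f"{c}:{f}" for c, f in sorted(labels)))
                for gid, labels in sorted(self.truth_labels.items())]
        pd.DataFrame(rows, columns=["gene_id", "labels"]).to_csv(
            truth / "labels.tsv", sep="\t", index=False)
        self.truth_puls.to_csv(truth / "puls.tsv", sep="\t", index=False)


def _plant_positions(rng, n_genes: int, span: int, blocked: list,
                     isolation: int) -> int | None:
    """A start index for a planted locus keeping ``isolation`` genes clear
    of every previously blocked interval, or None when impossible."""
    candidates = []
    for start in range(0, n_genes - span + 1):
        lo, hi = start - isolation, start + span - 1 + isolation
        if all(b_hi < lo or b_lo > hi for b_lo, b_hi in blocked):
            candidates.append(start)
    if not candidates:
        return None
    return int(rng.choice(candidates))


def simulate_genome_set(config: SimConfig | None = None,
                        seed: int | None = None) -> GenomeBundle:
    """Simulate genomes, coordinates, truth labels and planted PULs.

    Deterministic given (config, seed). Planted loci satisfy the caller's
    rules by construction; background substrate genes are isolated by at
    least ``pul_isolation_gap`` genes from any other substrate gene so the
    truth PUL table is exact.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes: list[Gene] = []
    metas: list[GenomeMeta] = []
    truth_labels: dict[str, frozenset] = {}
    pul_rows = []
    species_of: dict[str, str] = {}
    genus_of: dict[str, str] = {}

    layout = config.species_layout()
    for genome_idx, (genome_id, species_id, genus_id) in enumerate(layout):
        species_of[genome_id] = species_id
        genus_of[genome_id] = genus_id
        target = int(rng.integers(config.genome_size_bp[0],
                                  config.genome_size_bp[1] + 1))
        n_contigs = int(rng.integers(config.contigs_per_genome[0],
                                     config.contigs_per_genome[1] + 1))
        n_genes = max(target // config.mean_gene_footprint_bp, 20 * n_contigs)
        # split genes across contigs (roughly even, rng-jittered)
        weights = rng.dirichlet(np.full(n_contigs, 8.0))
        per_contig = np.maximum((weights * n_genes).astype(int), 12)

        genome_genes: list[Gene] = []
        genome_size = 0
        contig_gene_lists = []
        for c in range(n_contigs):
            contig_id = f"{genome_id}_ctg{c + 1}"
            pos = 1
            contig_genes = []
            for i in range(int(per_contig[c])):
                gene_len = int(rng.integers(600, 1501))
                gap = int(rng.integers(20, 201))
                start = pos
                end = start + gene_len - 1
                pos = end + 1 + gap
                strand = "+" if rng.random() < 0.5 else "-"
                gid = f"{genome_id}_g{c + 1:02d}_{i:04d}"
                contig_genes.append(Gene(
                    gene_id=gid, genome_id=genome_id, contig_id=contig_id,
                    index=i, start=start, end=end, strand=strand))
            genome_size += contig_genes[-1].end + 100
            contig_gene_lists.append(contig_genes)
            genome_genes.extend(contig_genes)

        # ---- plant PULs -------------------------------------------------
        genus_idx = ord(genus_id[-1]) - ord("A")
        blocked_per_contig: dict[int, list] = {c: [] for c in range(n_contigs)}
        for p in range(config.puls_per_genome):
            substrate, pul_class, template = _TEMPLATES[
                (genus_idx + p) % len(_TEMPLATES)]
            span = len(template)
            placed = False
            for c in rng.permutation(n_contigs):
                c = int(c)
                contig_genes = contig_gene_lists[c]
                start = _plant_positions(rng, len(contig_genes), span,
                                         blocked_per_contig[c],
                                         config.pul_isolation_gap)
                if start is None:
                    continue
                blocked_per_contig[c].append((start, start + span - 1))
                for off, label in enumerate(template):
                    gid = contig_genes[start + off].gene_id
                    truth_labels[gid] = frozenset({label})
                pul_rows.append((genome_id, contig_genes[0].contig_id,
                                 start, start + span - 1, pul_class,
                                 substrate or ""))
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"infeasible config: cannot place a {span}-gene locus "
                    f"in genome {genome_id}")

        # ---- background labels (isolated) -------------------------------
        pool_labels = [lab for lab, _ in _BACKGROUND_POOL]
        pool_w = np.array([w for _, w in _BACKGROUND_POOL])
        pool_w = pool_w / pool_w.sum()
        for c, contig_genes in enumerate(contig_gene_lists):
            substrate_idx = set()
            for b_lo, b_hi in blocked_per_contig[c]:
                substrate_idx.update(range(b_lo, b_hi + 1))
            for g in contig_genes:
                if g.gene_id in truth_labels:
                    continue
                if rng.random() >= config.background_label_rate:
                    continue
                cat, fam = pool_labels[int(rng.choice(len(pool_labels),
                                                      p=pool_w))]
                if cat in _SUBSTRATE_CATS:
                    iso = config.pul_isolation_gap
                    near = range(g.index - iso, g.index + iso + 1)
                    if any(i in substrate_idx for i in near):
                        continue  # rejection keeps chains impossible
                    substrate_idx.add(g.index)
                truth_labels[g.gene_id] = frozenset({(cat, fam)})

        for g in genome_genes:
            truth_labels.setdefault(g.gene_id, frozenset())
        genes.extend(genome_genes)
        metas.append(GenomeMeta(
            genome_id=genome_id,
            completeness=float(np.round(rng.uniform(80.0, 99.9), 1)),
            contamination=float(np.round(rng.uniform(0.0, 3.0), 1)),
            size_bp=genome_size,
            gc=float(np.round(rng.uniform(29.0, 38.0), 1)),
            genus_id=genus_id,
            source="simulated"))

    truth_puls = pd.DataFrame(
        pul_rows, columns=["genome_id", "contig_id", "first_index",
                           "last_index", "pul_class", "substrate"])
    return GenomeBundle(config=config, genes=genes, metas=metas,
                        truth_labels=truth_labels, truth_puls=truth_puls,
                        species_of=species_of, genus_of=genus_of)


# ---------------------------------------------------------------------------
# hit tables


def _supporting_hits(cat: str, fam: str, gene_id: str, rng) -> list[Hit]:
    """Hits that, after filtering and merging, reproduce one truth label."""
    if cat in ("GH", "PL", "CE", "CBM", "GT"):
        return [
            Hit(gene_id, "DBCAN_HMM", fam,
                evalue=10.0 ** -rng.uniform(10, 50),
                score=float(rng.uniform(50, 500))),
            Hit(gene_id, "CAZY_BLAST", family_base(fam),
                evalue=10.0 ** -rng.uniform(25, 60),
                pct_identity=float(rng.uniform(35, 95)),
                query_cover=float(rng.uniform(50, 100)),
                score=float(rng.uniform(100, 900))),
        ]
    if cat == "SULFATASE":
        return [
            Hit(gene_id, "SULFATLAS_BLAST", fam,
                evalue=10.0 ** -rng.uniform(8, 40),
                pct_identity=float(rng.uniform(35, 95)),
                query_cover=float(rng.uniform(50, 100)),
                score=float(rng.uniform(100, 900))),
            Hit(gene_id, "PFAM_SULF_HMM", "PF00884",
                evalue=10.0 ** -rng.uniform(8, 40),
                score=float(rng.uniform(50, 400))),
        ]
    if cat == "PEPTIDASE":
        return [Hit(gene_id, "MEROPS_BLAST", fam,
                    evalue=10.0 ** -rng.uniform(6, 40),
                    pct_identity=float(rng.uniform(35, 95)),
                    query_cover=float(rng.uniform(50, 100)),
                    score=float(rng.uniform(100, 900)))]
    if cat == "SUSC":
        return [Hit(gene_id, "TIGRFAM_TBDT_HMM", fam,
                    evalue=10.0 ** -rng.uniform(12, 60),
                    score=float(rng.uniform(100, 800)))]
    if cat == "SUSD":
        return [Hit(gene_id, "PFAM_SUSD_HMM", fam,
                    evalue=10.0 ** -rng.uniform(7, 40),
                    score=float(rng.uniform(50, 400)))]
    return []  # TRANSPORTER/OTHER bypass the hit-table machinery


def _decoy_hit(gene_id: str, config: ThresholdConfig, noise: NoiseParams,
               rng) -> Hit:
    sources = ("DBCAN_HMM", "CAZY_BLAST", "MEROPS_BLAST",
               "TIGRFAM_TBDT_HMM", "PFAM_SUSD_HMM")
    source = sources[int(rng.choice(len(sources)))]
    fams = {"DBCAN_HMM": "GH5", "CAZY_BLAST": "GH5", "MEROPS_BLAST": "C26",
            "TIGRFAM_TBDT_HMM": "TIGR01352", "PFAM_SUSD_HMM": "PF07980"}
    ceiling = config.evalue_ceilings[source]
    if source == "CAZY_BLAST" and rng.random() < 0.5:
        # passes the E-value gate but fails identity or coverage
        low_ident = rng.random() < 0.5
        return Hit(gene_id, source, fams[source],
                   evalue=ceiling / 100.0,
                   pct_identity=15.0 if low_ident else 80.0,
                   query_cover=90.0 if low_ident else 20.0,
                   score=200.0)
    kwargs = {}
    if source in ("CAZY_BLAST", "MEROPS_BLAST"):
        kwargs = dict(pct_identity=80.0, query_cover=90.0)
    return Hit(gene_id, source, fams[source],
               evalue=ceiling * noise.decoy_margin, score=20.0, **kwargs)


def simulate_hit_tables(bundle: GenomeBundle,
                        noise: NoiseParams | None = None,
                        seed: int | None = None,
                        config: ThresholdConfig | None = None,
                        ) -> dict[str, list[Hit]]:
    """Per-source hit lists that the annotation stage must merge back into
    the truth labels.

    Noise-free, the round trip is exact. Per-source dropout removes single
    evidence lines (so CAZyme dropout on either channel breaks the
    agreement rule); decoys are emitted just outside the thresholds.
    """
    noise = noise or bundle.config.noise
    config = config or ThresholdConfig()
    rng = np.random.default_rng(bundle.config.seed + 101 if seed is None else seed)
    by_source: dict[str, list[Hit]] = {}
    for g in bundle.genes:
        for cat, fam in sorted(bundle.truth_labels[g.gene_id]):
            for hit in _supporting_hits(cat, fam, g.gene_id, rng):
                if rng.random() < noise.fn(hit.source):
                    continue
                by_source.setdefault(hit.source, []).append(hit)
        if noise.decoy_rate > 0 and rng.random() < noise.decoy_rate:
            d = _decoy_hit(g.gene_id, config, noise, rng)
            by_source.setdefault(d.source, []).append(d)
    return by_source


def write_hit_tables(hits_by_source: Mapping[str, Sequence[Hit]],
                     outdir) -> dict[str, Path]:
    """Write per-source TSVs in their native dialect (blast6 with a 13th
    qcovhsp column for blastp sources, reduced hmmer tabular for HMM
    sources); returns source -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for source, hits in sorted(hits_by_source.items()):
        path = outdir / f"hits_{source.lower()}.tsv"
        with open(path, "w") as fh:
            for h in hits:
                if source.endswith("_BLAST"):
                    fh.write("\t".join(map(str, (
                        h.gene_id, h.family, h.pct_identity or 0.0, 100, 5, 1,
                        1, 100, 1, 100, h.evalue, h.score or 0.0,
                        h.query_cover if h.query_cover is not None else 100.0,
                    ))) + "\n")
                else:
                    fh.write(f"{h.gene_id}\t{h.family}\t{h.evalue}\t"
                             f"{h.score or 0.0}\t-\t-\n")
        paths[source] = path
    return paths


# ---------------------------------------------------------------------------
# ANI matrix


def simulate_ani_matrix(bundle: GenomeBundle, seed: int | None = None,
                        ) -> tuple[ANIMatrix, list[frozenset]]:
    """Block-structured ANI matrix plus the planted species clusters."""
    cfg = bundle.config
    rng = np.random.default_rng(cfg.seed + 202 if seed is None else seed)
    ids = sorted(bundle.species_of)
    n = len(ids)
    m = np.full((n, n), np.nan)
    for i in range(n):
        m[i, i] = 100.0
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            if bundle.species_of[a] == bundle.species_of[b]:
                lo, hi = cfg.ani_within_species
            elif bundle.genus_of[a] == bundle.genus_of[b]:
                lo, hi = cfg.ani_within_genus
            else:
                lo, hi = cfg.ani_between_genus
            v = float(rng.uniform(lo, hi))
            m[i, j] = m[j, i] = v
    truth: dict[str, set] = {}
    for gid, sp in bundle.species_of.items():
        truth.setdefault(sp, set()).add(gid)
    clusters = [frozenset(v) for _, v in sorted(truth.items())]
    return ANIMatrix(pd.DataFrame(m, index=ids, columns=ids)), clusters


# ---------------------------------------------------------------------------
# read-recruitment mapping, depth and environment


@dataclass
class MappingBundle:
    mappings: pd.DataFrame  # sample_id, genome_id, mapped_reads, total_reads
    depths: dict  # (sample_id, genome_id) -> np.ndarray
    env: pd.DataFrame  # indexed by sample_id
    planted_rpkm: pd.DataFrame  # sample_id, genome_id, rpkm
    responder: str  # genome with the planted log-linear temperature response


def simulate_mapping(bundle: GenomeBundle, seed: int | None = None,
                     ) -> MappingBundle:
    """Mapping summaries, depth profiles and environmental covariates.

    Mapped-read counts are Poisson draws whose expectation matches the
    planted RPKM; depth profiles are gamma-Poisson (overdispersed) around
    the mean depth implied by the mapped reads; one designated genome
    responds log-linearly to temperature (slope ``env_slope``) for the
    correlation-recovery tests. Depth profiles have ``depth_bins``
    positions (a fixed-resolution per-base subsample).
    """
    cfg = bundle.config
    rng = np.random.default_rng(cfg.seed + 303 if seed is None else seed)
    genome_ids = sorted(bundle.genome_lengths)
    lengths = bundle.genome_lengths
    responder = genome_ids[0]

    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    env = pd.DataFrame({
        "depth_m": rng.uniform(5, 300, cfg.n_samples),
        "temperature": rng.uniform(0.5, 30.0, cfg.n_samples),
        "salinity": rng.uniform(32.0, 38.5, cfg.n_samples),
        "oxygen": rng.uniform(150.0, 350.0, cfg.n_samples),
        "chlorophyll_a": rng.uniform(0.01, 2.0, cfg.n_samples),
        "nitrite": rng.uniform(0.01, 1.0, cfg.n_samples),
        "nitrate_nitrite": rng.uniform(0.05, 20.0, cfg.n_samples),
        "phosphate": rng.uniform(0.01, 2.5, cfg.n_samples),
        "silicate": rng.uniform(0.5, 50.0, cfg.n_samples),
    }, index=pd.Index(samples, name="sample_id"))

    map_rows, planted_rows = [], []
    depths: dict[tuple, np.ndarray] = {}
    for s in samples:
        temp = float(env.at[s, "temperature"])
        for gid in genome_ids:
            if gid == responder:
                rpkm = max(0.0, cfg.env_intercept
                           + cfg.env_slope * np.log10(temp)
                           + rng.normal(0.0, cfg.env_noise_sd))
            else:
                rpkm = float(rng.uniform(0.0, 3.0))
            expected = rpkm * (lengths[gid] / 1000.0) * (cfg.total_reads / 1e6)
            mapped = int(rng.poisson(expected))
            map_rows.append((s, gid, mapped, cfg.total_reads))
            planted_rows.append((s, gid, rpkm))
            mean_depth = mapped * cfg.read_len / lengths[gid]
            od = cfg.depth_overdispersion
            if od > 0:
                lam = rng.gamma(shape=1.0 / od, scale=mean_depth * od,
                                size=cfg.depth_bins) if mean_depth > 0 \
                    else np.zeros(cfg.depth_bins)
            else:
                lam = np.full(cfg.depth_bins, mean_depth)
            depths[(s, gid)] = rng.poisson(lam).astype(float)

    return MappingBundle(
        mappings=pd.DataFrame(map_rows, columns=[
            "sample_id", "genome_id", "mapped_reads", "total_reads"]),
        depths=depths, env=env,
        planted_rpkm=pd.DataFrame(planted_rows, columns=[
            "sample_id", "genome_id", "rpkm"]),
        responder=responder)


# ---------------------------------------------------------------------------
# tree sets


def _random_rooted(units: list[str], rng) -> str:
    """Random rooted binary newick over pre-rendered unit strings."""
    units = list(units)
    rng.shuffle(units)
    while len(units) > 1:
        i, j = sorted(rng.choice(len(units), size=2, replace=False))
        b = units.pop(int(j))
        a = units.pop(int(i))
        units.append(f"({a},{b})")
    return units[0]


def simulate_tree_set(config: SimConfig | None = None,
                      seed: int | None = None) -> tuple[list, set]:
    """Newick tree strings sharing planted stable clades.

    Two clades (with fixed internal structure, so their internal splits are
    stable too) are present in every tree; the arrangement of the remaining
    taxa is re-randomised per tree when ``tree_perturbation`` > 0. Returns
    (newick strings, truth bipartitions as canonical frozensets).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed + 404 if seed is None else seed)
    if config.n_taxa < 10:
        raise ValueError("need at least 10 taxa for the planted-clade layout")
    taxa = [f"T{i + 1:02d}" for i in range(config.n_taxa)]
    clade1 = taxa[3:6]      # (T04,(T05,T06))
    clade2 = taxa[-4:]      # ((Tn-3,Tn-2),(Tn-1,Tn))
    unit1 = f"({clade1[0]},({clade1[1]},{clade1[2]}))"
    unit2 = f"(({clade2[0]},{clade2[1]}),({clade2[2]},{clade2[3]}))"
    singles = [t for t in taxa if t not in clade1 + clade2]
    truth = {frozenset(clade1), frozenset(clade1[1:]),
             frozenset(clade2), frozenset(clade2[:2]), frozenset(clade2[2:])}

    units = singles + [unit1, unit2]
    base = _random_rooted(list(units), np.random.default_rng(
        rng.integers(2 ** 31))) + ";"
    trees = []
    for _ in range(config.n_trees):
        if config.tree_perturbation > 0 and rng.random() < config.tree_perturbation:
            trees.append(_random_rooted(list(units), rng) + ";")
        else:
            trees.append(base)
    return trees, truth


# ---------------------------------------------------------------------------
# genus-signature family profiles (for the ordination/clustering checks)


def simulate_family_profiles(n_genera: int = 4, genomes_per_genus: int = 6,
                             n_shared_families: int = 20,
                             signature_families: int = 8,
                             signature_mean: float = 6.0,
                             background_mean: float = 1.0,
                             seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Genome × family count profiles where genus identity drives the
    signal: each genus gets its own high-count family block on top of a
    shared low-count background (Poisson noise). Returns (profiles,
    genome -> genus labels)."""
    rng = np.random.default_rng(seed)
    families = [f"BG{i:02d}" for i in range(n_shared_families)]
    for g in range(n_genera):
        families += [f"SIG{g}_{i:02d}" for i in range(signature_families)]
    rows, labels = {}, {}
    for g in range(n_genera):
        genus = f"genus_{chr(ord('A') + g)}"
        for k in range(genomes_per_genus):
            genome = f"{genus}_mag{k + 1}"
            labels[genome] = genus
            means = np.full(len(families), background_mean)
            lo = n_shared_families + g * signature_families
            means[lo:lo + signature_families] = signature_mean
            rows[genome] = rng.poisson(means)
    profiles = pd.DataFrame(rows, index=families).T.sort_index()
    return profiles, labels
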