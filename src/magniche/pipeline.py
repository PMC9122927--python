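"""End-to-end orchestration of the analysis stages on one input bundle.

Stage order: annotate -> call-puls -> dereplicate -> conserved families ->
genus metrics -> abundance/correlation -> composition (Bray-Curtis, hclust,
NMDS) -> consensus tree. A manifest (parameters, seed, record counts,
output checksums) is written alongside the outputs; identical configs
reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import build_records, correlate_env
from .annotation_merge import ThresholdConfig, build_gene_table
from .composition_analysis import bray_curtis, hierarchical_cluster, nmds
from .genome_catalog import (conserved_families, family_profile,
                             greedy_dereplicate, select_top_complete)
from .phylo_utils import consensus_tree
from .pul_caller import PULParams, call_puls, puls_to_frame
from .substrate_metrics import category_densities, genus_table
from .synthetic_data import (SimConfig, simulate_ani_matrix,
                             simulate_genome_set, simulate_hit_tables,
                             simulate_mapping, simulate_tree_set)

__all__ = ["run_pipeline"]

COMPOSITION_CATEGORIES = ("GH", "PL", "CE", "CBM", "GT", "SULFATASE",
                          "PEPTIDASE", "SUSC")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(outdir, sim_config: SimConfig | None = None,
                 thresholds: ThresholdConfig | None = None,
                 pul_params: PULParams | None = None,
                 ani_threshold: float = 95.0,
                 min_rpkm: float = 0.25,
                 trim_fraction: float = 0.10,
                 nmds_seed: int = 42) -> dict:
    """Simulate a full input bundle and run every stage over it.

    Returns the manifest dict (also written to ``manifest.json``). Stage
    outputs are TSV/newick files under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_config = sim_config or SimConfig()
    thresholds = thresholds or ThresholdConfig()
    pul_params = pul_params or PULParams()
    manifest: dict = {
        "version": __version__,
        "seed": sim_config.seed,
        "parameters": {
            "ani_threshold": ani_threshold,
            "min_rpkm": min_rpkm,
            "trim_fraction": trim_fraction,
            "max_gap": pul_params.max_gap,
            "min_chain": pul_params.min_chain,
            "min_degradative": pul_params.min_degradative,
            "nmds_seed": nmds_seed,
        },
        "stages": {},
    }

    # simulate
    bundle = simulate_genome_set(sim_config)
    bundle.write(outdir / "inputs")
    hits = simulate_hit_tables(bundle)
    manifest["stages"]["simulate"] = {
        "genomes": len(bundle.metas), "genes": len(bundle.genes)}

    # annotate
    gene_table = build_gene_table(
        bundle.genes, [h for hs in hits.values() for h in hs], thresholds,
        transporters=bundle.transporter_annotations)
    gene_table.to_tsv(outdir / "gene_table.tsv")
    manifest["stages"]["annotate"] = {
        "labelled_genes": int(sum(bool(g.labels) for g in gene_table.genes))}

    # call PULs
    calls = call_puls(gene_table, pul_params)
    puls_to_frame(calls).to_csv(outdir / "puls.tsv", sep="\t", index=False)
    manifest["stages"]["call_puls"] = {
        "puls": len(calls),
        "canonical": sum(c.pul_class == "canonical" for c in calls)}

    # dereplicate
    ani, _truth = simulate_ani_matrix(bundle)
    ani.to_tsv(outdir / "ani_matrix.tsv")
    clusters = greedy_dereplicate(ani, bundle.metas, threshold=ani_threshold)
    pd.DataFrame(
        [(c.representative, ";".join(c.members)) for c in clusters],
        columns=["representative", "members"],
    ).to_csv(outdir / "species_clusters.tsv", sep="\t", index=False)
    manifest["stages"]["dereplicate"] = {"clusters": len(clusters)}

    # conserved families per genus
    profiles = family_profile([gene_table])
    genera = sorted({m.genus_id for m in bundle.metas})
    conserved_rows = []
    for genus in genera:
        top = select_top_complete(bundle.metas, genus, n=3)
        for fam in sorted(conserved_families(profiles, top)):
            conserved_rows.append((genus, fam))
    pd.DataFrame(conserved_rows, columns=["genus_id", "family"]).to_csv(
        outdir / "conserved_families.tsv", sep="\t", index=False)
    manifest["stages"]["conserved"] = {"rows": len(conserved_rows)}

    # genus metrics summary table
    densities = category_densities(gene_table, bundle.metas)
    pul_counts = {m.genome_id: sum(c.genome_id == m.genome_id for c in calls)
                  for m in bundle.metas}
    table = genus_table(bundle.metas, densities, pul_counts)
    table.to_csv(outdir / "genus_summary.tsv", sep="\t")
    manifest["stages"]["metrics"] = {"genera": len(table)}

    # abundance + environmental correlation
    mapping = simulate_mapping(bundle)
    records = build_records(mapping.mappings, bundle.genome_lengths,
                            mapping.depths, min_rpkm=min_rpkm,
                            trim_fraction=trim_fraction)
    pd.DataFrame(
        [(r.sample_id, r.genome_id, r.rpkm, r.breadth, r.tad,
          r.passes_threshold) for r in records],
        columns=["sample_id", "genome_id", "rpkm", "breadth", "tad",
                 "passes_threshold"],
    ).to_csv(outdir / "abundance.tsv", sep="\t", index=False)
    responder_records = [r for r in records if r.genome_id == mapping.responder]
    corr = correlate_env(responder_records, mapping.env, "temperature",
                         min_rpkm=min_rpkm)
    pd.DataFrame([(corr.parameter, corr.r, corr.p_value, corr.n,
                   corr.reason or "")],
                 columns=["parameter", "r", "p_value", "n", "reason"]).to_csv(
        outdir / "env_correlation.tsv", sep="\t", index=False)
    manifest["stages"]["abundance"] = {
        "records": len(records),
        "passing": sum(r.passes_threshold for r in records)}

    # composition
    bc = bray_curtis(profiles)
    bc.to_csv(outdir / "bray_curtis.tsv", sep="\t")
    dendro = hierarchical_cluster(bc)
    (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    ordination = nmds(bc, k=2, seed=nmds_seed)
    frame = ordination.to_frame()
    with open(outdir / "nmds.tsv", "w") as fh:
        fh.write(f"# stress\t{ordination.stress:.6f}\n")
        frame.to_csv(fh, sep="\t")
    manifest["stages"]["compare"] = {"stress": round(ordination.stress, 6)}

    # consensus tree
    trees, _clades = simulate_tree_set(sim_config)
    cons = consensus_tree(trees, mode="strict")
    cons.write(path=str(outdir / "consensus.nwk"), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)
    manifest["stages"]["consensus"] = {"input_trees": len(trees)}

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*"))
        if p.is_file() and p.name != "manifest.json"}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
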