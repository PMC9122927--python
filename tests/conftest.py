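import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from magniche.io_core import Gene
from magniche.synthetic_data import SimConfig, simulate_genome_set


def gene(i, labels=(), contig="ctg1", genome="G1"):
    """Shorthand: a gene at index i with the given (category, family) labels."""
    return Gene(gene_id=f"{genome}_{contig}_g{i}", genome_id=genome,
                contig_id=contig, index=i, start=1 + i * 1000,
                end=900 + i * 1000, labels=frozenset(labels))


def label_row(categories):
    """Map bare category names to (category, family) label sets using a
    representative family per category."""
    fam = {"GH": "GH16_3", "PL": "PL7", "CE": "CE4", "CBM": "CBM50",
           "GT": "GT2", "SULFATASE": "S1_15", "PEPTIDASE": "M1",
           "SUSC": "TIGR04056", "SUSD": "PF12741", "OTHER": None}
    out = []
    for cats in categories:
        if isinstance(cats, str):
            cats = [cats] if cats != "OTHER" else []
        out.append(frozenset((c, fam[c]) for c in cats))
    return out


@pytest.fixture(scope="session")
def small_config():
    """A reduced genome set for fast stage-level tests."""
    return SimConfig(seed=11, n_genera=2, species_per_genus=2,
                     genomes_per_species=1,
                     genome_size_bp=(120_000, 200_000),
                     contigs_per_genome=(2, 3), n_samples=6,
                     depth_bins=500)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_genome_set(small_config)
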