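import itertools

import pytest

from magniche.annotation_merge import (AnnotationError, Hit, ThresholdConfig,
                                       assign_labels, build_gene_table,
                                       filter_hits)
from magniche.synthetic_data import (NoiseParams, SimConfig,
                                     simulate_genome_set,
                                     simulate_hit_tables)

from conftest import gene


def hit(source, family, evalue, ident=None, cover=None, score=100.0, gid="g1"):
    return Hit(gene_id=gid, source=source, family=family, evalue=evalue,
               pct_identity=ident, query_cover=cover, score=score)


class TestFilter:
    @pytest.mark.parametrize("source,ceiling", [
        ("DBCAN_HMM", 1e-5), ("CAZY_BLAST", 1e-20), ("SULFATLAS_BLAST", 1e-4),
        ("PFAM_SULF_HMM", 1e-5), ("MEROPS_BLAST", 1e-4),
        ("TIGRFAM_TBDT_HMM", 1e-10), ("PFAM_SUSD_HMM", 1e-5)])
    def test_evalue_ceiling_per_source(self, source, ceiling):
        passing = hit(source, "F", ceiling, ident=50.0, cover=80.0)
        failing = hit(source, "F", ceiling * 10, ident=50.0, cover=80.0)
        kept = filter_hits([passing, failing])
        assert kept == [passing]

    def test_dbcan_just_above_ceiling_removed(self):
        assert filter_hits([hit("DBCAN_HMM", "GH16", 1e-4)]) == []

    @pytest.mark.parametrize("ident,cover,kept", [
        (25.0, 80.0, False),   # identity below 30
        (80.0, 39.0, False),   # coverage below 40
        (30.0, 40.0, True),    # both floors inclusive
    ])
    def test_cazy_identity_and_coverage_floors(self, ident, cover, kept):
        h = hit("CAZY_BLAST", "GH16", 1e-25, ident=ident, cover=cover)
        assert (filter_hits([h]) == [h]) is kept

    def test_cazy_missing_fields_error_names_gene(self):
        h = hit("CAZY_BLAST", "GH16", 1e-25, gid="orphan_gene")
        with pytest.raises(AnnotationError, match="orphan_gene"):
            filter_hits([h])

    def test_empty_and_order_preserving(self):
        assert filter_hits([]) == []
        hits = [hit("MEROPS_BLAST", f"M{i}", 1e-6) for i in range(5)]
        assert filter_hits(hits) == hits

    def test_idempotent(self):
        hits = [hit("DBCAN_HMM", "GH16_3", 1e-8),
                hit("DBCAN_HMM", "GH16_3", 1e-3),
                hit("CAZY_BLAST", "GH16", 1e-25, 60.0, 90.0)]
        once = filter_hits(hits)
        assert filter_hits(once) == once


class TestAssignLabels:
    def test_subfamily_agreement_reports_dbcan_form(self):
        labels = assign_labels([hit("DBCAN_HMM", "GH16_3", 1e-8),
                                hit("CAZY_BLAST", "GH16", 1e-25, 60.0, 90.0)])
        assert labels == {("GH", "GH16_3")}

    def test_family_disagreement_blocks_cazyme_label(self):
        labels = assign_labels([hit("DBCAN_HMM", "GH16", 1e-8),
                                hit("CAZY_BLAST", "GH18", 1e-25, 60.0, 90.0)])
        assert labels == set()

    def test_single_source_cazyme_blocked_but_merops_labels(self):
        assert assign_labels([hit("DBCAN_HMM", "PL7", 1e-8)]) == set()
        labels = assign_labels([hit("DBCAN_HMM", "PL7", 1e-8),
                                hit("MEROPS_BLAST", "M1", 1e-6)])
        assert labels == {("PEPTIDASE", "M1")}

    def test_rule_table_over_all_source_subsets(self):
        """Enumerate every subset of the seven evidence channels against a
        hand-written truth matrix of expected label categories."""
        evidence = {
            "DBCAN_HMM": hit("DBCAN_HMM", "GH16_3", 1e-8),
            "CAZY_BLAST": hit("CAZY_BLAST", "GH16", 1e-25, 60.0, 90.0),
            "SULFATLAS_BLAST": hit("SULFATLAS_BLAST", "S1_15", 1e-6),
            "PFAM_SULF_HMM": hit("PFAM_SULF_HMM", "PF00884", 1e-8),
            "MEROPS_BLAST": hit("MEROPS_BLAST", "M1", 1e-6),
            "TIGRFAM_TBDT_HMM": hit("TIGRFAM_TBDT_HMM", "TIGR04056", 1e-15),
            "PFAM_SUSD_HMM": hit("PFAM_SUSD_HMM", "PF12741", 1e-8),
        }
        for subset_len in range(len(evidence) + 1):
            for subset in itertools.combinations(sorted(evidence), subset_len):
                expected = set()
                if "DBCAN_HMM" in subset and "CAZY_BLAST" in subset:
                    expected.add("GH")
                if "SULFATLAS_BLAST" in subset or "PFAM_SULF_HMM" in subset:
                    expected.add("SULFATASE")
                if "MEROPS_BLAST" in subset:
                    expected.add("PEPTIDASE")
                if "TIGRFAM_TBDT_HMM" in subset:
                    expected.add("SUSC")
                if "PFAM_SUSD_HMM" in subset:
                    expected.add("SUSD")
                got = {c for c, _ in
                       assign_labels([evidence[s] for s in subset])}
                assert got == expected, subset

    def test_sulfatase_both_mode(self):
        config = ThresholdConfig(sulfatase_mode="both")
        only_atlas = [hit("SULFATLAS_BLAST", "S1_15", 1e-6)]
        assert assign_labels(only_atlas, config) == set()
        both = only_atlas + [hit("PFAM_SULF_HMM", "PF00884", 1e-8)]
        assert assign_labels(both, config) == {("SULFATASE", "S1_15")}

    def test_best_hit_tie_breaking(self):
        """Lowest E-value wins; ties go to higher score then family name."""
        hits = [hit("MEROPS_BLAST", "M9", 1e-6, score=50.0),
                hit("MEROPS_BLAST", "M1", 1e-8, score=10.0)]
        assert assign_labels(hits) == {("PEPTIDASE", "M1")}
        tied = [hit("MEROPS_BLAST", "M9", 1e-8, score=90.0),
                hit("MEROPS_BLAST", "M1", 1e-8, score=10.0)]
        assert assign_labels(tied) == {("PEPTIDASE", "M9")}

    def test_monotone_in_evidence(self):
        """Adding a surviving hit never removes an existing label."""
        base = [hit("MEROPS_BLAST", "M1", 1e-6),
                hit("TIGRFAM_TBDT_HMM", "TIGR04056", 1e-15)]
        extras = [hit("PFAM_SUSD_HMM", "PF12741", 1e-8),
                  hit("SULFATLAS_BLAST", "S1_15", 1e-6),
                  hit("DBCAN_HMM", "GH3", 1e-8),
                  hit("CAZY_BLAST", "GH3", 1e-25, 60.0, 90.0)]
        current = list(base)
        labels = assign_labels(current)
        for extra in extras:
            current.append(extra)
            grown = assign_labels(current)
            assert labels <= grown
            labels = grown


class TestBuildGeneTable:
    def test_labels_attach_to_the_right_gene(self):
        genes = [gene(0), gene(1), gene(2)]
        hits = [hit("TIGRFAM_TBDT_HMM", "TIGR04056", 1e-15,
                    gid=genes[2].gene_id)]
        table = build_gene_table(genes, hits)
        assert [g.categories for g in table.genes] == [
            frozenset(), frozenset(), frozenset({"SUSC"})]

    def test_no_hits_all_empty(self):
        table = build_gene_table([gene(0), gene(1)], [])
        assert all(not g.labels for g in table.genes)

    def test_orphan_hits_rejected(self):
        with pytest.raises(AnnotationError, match="ghost"):
            build_gene_table([gene(0)],
                             [hit("MEROPS_BLAST", "M1", 1e-6, gid="ghost")])

    def test_transporter_channel_bypasses_thresholds(self):
        genes = [gene(0), gene(1)]
        table = build_gene_table(genes, [],
                                 transporters={genes[0].gene_id: "AmtB"})
        assert table.genes[0].labels == frozenset({("TRANSPORTER", "AmtB")})

    def test_noise_free_truth_recovery(self, small_bundle):
        hits = simulate_hit_tables(small_bundle)
        table = build_gene_table(
            small_bundle.genes, [h for hs in hits.values() for h in hs],
            transporters=small_bundle.transporter_annotations)
        for g in table.genes:
            assert g.labels == small_bundle.truth_labels[g.gene_id]

    def test_category_counts_match_planted(self, small_bundle):
        hits = simulate_hit_tables(small_bundle)
        table = build_gene_table(
            small_bundle.genes, [h for hs in hits.values() for h in hs],
            transporters=small_bundle.transporter_annotations)
        planted = {}
        for labels in small_bundle.truth_labels.values():
            for cat, _ in labels:
                planted[cat] = planted.get(cat, 0) + 1
        assert table.category_counts().to_dict() == planted

    def test_decoys_produce_no_labels(self, small_config):
        bundle = simulate_genome_set(small_config)
        noise = NoiseParams(false_negative={s: 1.0 for s in (
            "DBCAN_HMM", "CAZY_BLAST", "SULFATLAS_BLAST", "PFAM_SULF_HMM",
            "MEROPS_BLAST", "TIGRFAM_TBDT_HMM", "PFAM_SUSD_HMM")},
            decoy_rate=0.5)
        hits = simulate_hit_tables(bundle, noise=noise)
        table = build_gene_table(bundle.genes,
                                 [h for hs in hits.values() for h in hs])
        assert all(not g.labels for g in table.genes)

    def test_cazy_dropout_kills_cazyme_labels_only(self, small_bundle):
        noise = NoiseParams(false_negative={"CAZY_BLAST": 1.0})
        hits = simulate_hit_tables(small_bundle, noise=noise)
        table = build_gene_table(small_bundle.genes,
                                 [h for hs in hits.values() for h in hs])
        counts = table.category_counts()
        for cat in ("GH", "PL", "CE", "CBM", "GT"):
            assert counts.get(cat, 0) == 0
        truth_susc = sum(1 for l in small_bundle.truth_labels.values()
                         if any(c == "SUSC" for c, _ in l))
        assert counts.get("SUSC", 0) == truth_susc
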