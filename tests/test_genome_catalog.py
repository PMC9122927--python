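import itertools

import numpy as np
import pandas as pd
import pytest

from magniche.genome_catalog import (ANIMatrix, SpeciesCluster,
                                     cluster_identity_summary,
                                     conserved_families, greedy_dereplicate,
                                     partition_shared_families,
                                     select_top_complete)
from magniche.io_core import GenomeMeta
from magniche.synthetic_data import SimConfig, simulate_ani_matrix, simulate_genome_set


def meta(gid, completeness=95.0, contamination=0.5, size=2_000_000,
         genus="genus_A"):
    return GenomeMeta(gid, completeness, contamination, size, 35.0, genus)


def ani_from(pairs, ids):
    df = pd.DataFrame(np.nan, index=ids, columns=ids)
    for i in ids:
        df.at[i, i] = 100.0
    for (a, b), v in pairs.items():
        df.at[a, b] = df.at[b, a] = v
    return ANIMatrix(df)


class TestANIMatrix:
    def test_asymmetry_rejected(self):
        df = pd.DataFrame([[100.0, 96.0], [91.0, 100.0]],
                          index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="symmetric"):
            ANIMatrix(df)

    def test_square_tsv_round_trip(self, tmp_path):
        m = ani_from({("A", "B"): 96.5}, ["A", "B"])
        m.to_tsv(tmp_path / "ani.tsv")
        back = ANIMatrix.from_tsv(tmp_path / "ani.tsv")
        assert back.identity("A", "B") == pytest.approx(96.5)

    def test_long_tsv(self, tmp_path):
        (tmp_path / "ani.tsv").write_text(
            "query\treference\tani\nA\tB\t97.2\nA\tC\t80.0\n")
        m = ANIMatrix.from_tsv(tmp_path / "ani.tsv")
        assert m.identity("A", "B") == pytest.approx(97.2)
        assert np.isnan(m.identity("B", "C"))  # missing comparison


class TestDereplicate:
    def test_hand_worked_greedy(self):
        """A absorbs B (ANI 96), C stays alone (90/91 < 95)."""
        metas = [meta("A", 99.0), meta("B", 95.0), meta("C", 90.0)]
        m = ani_from({("A", "B"): 96, ("A", "C"): 90, ("B", "C"): 91},
                     ["A", "B", "C"])
        clusters = greedy_dereplicate(m, metas)
        assert [(c.representative, set(c.members)) for c in clusters] == [
            ("A", {"A", "B"}), ("C", {"C"})]

    def test_all_below_threshold_singletons(self):
        metas = [meta(g) for g in "ABC"]
        m = ani_from({(a, b): 80.0 for a, b in itertools.combinations("ABC", 2)},
                     list("ABC"))
        assert len(greedy_dereplicate(m, metas)) == 3

    def test_boundary_95_is_inclusive(self):
        metas = [meta("A", 99.0), meta("B", 90.0)]
        m = ani_from({("A", "B"): 95.0}, ["A", "B"])
        clusters = greedy_dereplicate(m, metas)
        assert len(clusters) == 1 and set(clusters[0].members) == {"A", "B"}

    def test_missing_genome_in_matrix_rejected(self):
        m = ani_from({}, ["A"])
        with pytest.raises(ValueError, match="missing"):
            greedy_dereplicate(m, [meta("A"), meta("B")])

    def test_quality_orders_representatives(self):
        # B has higher quality than A -> B seeds the cluster
        metas = [meta("A", 90.0, 2.0), meta("B", 95.0, 0.1)]
        m = ani_from({("A", "B"): 97.0}, ["A", "B"])
        assert greedy_dereplicate(m, metas)[0].representative == "B"

    def test_partition_and_threshold_invariants_random_blocks(self):
        """On random block matrices: output partitions the set, members sit
        >= threshold from their representative, representatives pairwise
        below threshold."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_blocks = int(rng.integers(2, 5))
            sizes = rng.integers(1, 4, n_blocks)
            ids, block_of = [], {}
            for b, s in enumerate(sizes):
                for k in range(s):
                    gid = f"b{b}g{k}"
                    ids.append(gid)
                    block_of[gid] = b
            df = pd.DataFrame(0.0, index=ids, columns=ids)
            for a in ids:
                for b in ids:
                    if a == b:
                        df.at[a, b] = 100.0
                    elif block_of[a] == block_of[b]:
                        v = rng.uniform(96, 99)
                        df.at[a, b] = df.at[b, a] = v
                    else:
                        v = rng.uniform(75, 85)
                        df.at[a, b] = df.at[b, a] = v
            m = ANIMatrix(df)
            metas = [meta(g, completeness=float(rng.uniform(80, 100)))
                     for g in ids]
            clusters = greedy_dereplicate(m, metas)
            all_members = [g for c in clusters for g in c.members]
            assert sorted(all_members) == sorted(ids)  # partition
            for c in clusters:
                for g in c.members:
                    assert m.identity(c.representative, g) >= 95.0
            reps = [c.representative for c in clusters]
            for a, b in itertools.combinations(reps, 2):
                assert m.identity(a, b) < 95.0
            assert len(clusters) == n_blocks  # planted block recovery

    def test_planted_species_recovery(self, small_bundle):
        ani, truth = simulate_ani_matrix(small_bundle)
        clusters = greedy_dereplicate(ani, small_bundle.metas)
        assert {frozenset(c.members) for c in clusters} == set(truth)

    def test_straddling_threshold_documented_split(self):
        """Within-'species' values straddling 95: the greedy pass keeps the
        sub-threshold member out, as traced by hand."""
        metas = [meta("A", 99.0), meta("B", 95.0), meta("C", 90.0)]
        m = ani_from({("A", "B"): 96.0, ("A", "C"): 94.5, ("B", "C"): 96.0},
                     ["A", "B", "C"])
        clusters = greedy_dereplicate(m, metas)
        # A seeds, absorbs B (96) but not C (94.5); C forms its own cluster
        assert [(c.representative, set(c.members)) for c in clusters] == [
            ("A", {"A", "B"}), ("C", {"C"})]


class TestTopComplete:
    def test_top_three_by_completeness(self):
        metas = [meta("A", 99.1), meta("B", 97.3), meta("C", 96.0),
                 meta("D", 90.2)]
        assert select_top_complete(metas, "genus_A") == ["A", "B", "C"]

    def test_tie_broken_by_contamination(self):
        metas = [meta("A", 97.0, 1.0), meta("B", 97.0, 0.1), meta("C", 80.0)]
        assert select_top_complete(metas, "genus_A", n=2) == ["B", "A"]

    def test_short_genus_returned_whole_with_warning(self):
        metas = [meta("A"), meta("B")]
        with pytest.warns(UserWarning, match="only 2"):
            assert set(select_top_complete(metas, "genus_A")) == {"A", "B"}

    def test_unknown_genus(self):
        with pytest.raises(ValueError, match="unknown genus"):
            select_top_complete([meta("A")], "genus_Z")


class TestFamilySharing:
    def test_intersection(self):
        profiles = pd.DataFrame(
            {"GH16": [1, 2, 1], "GH3": [1, 0, 1], "GH29": [0, 0, 3]},
            index=["A", "B", "C"])
        assert conserved_families(profiles, ["A", "B", "C"]) == {"GH16"}

    def test_disjoint_profiles_empty(self):
        profiles = pd.DataFrame({"GH16": [1, 0], "GH3": [0, 1]},
                                index=["A", "B"])
        assert conserved_families(profiles, ["A", "B"]) == set()

    def test_empty_id_list_rejected(self):
        with pytest.raises(ValueError):
            conserved_families(pd.DataFrame({"GH16": [1]}, index=["A"]), [])

    def test_random_profiles_match_set_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n_g, n_f = int(rng.integers(2, 6)), int(rng.integers(1, 10))
            counts = rng.integers(0, 3, (n_g, n_f))
            ids = [f"G{i}" for i in range(n_g)]
            fams = [f"F{j}" for j in range(n_f)]
            profiles = pd.DataFrame(counts, index=ids, columns=fams)
            expected = set(fams)
            for i in range(n_g):
                expected &= {fams[j] for j in range(n_f) if counts[i, j] > 0}
            assert conserved_families(profiles, ids) == expected

    def test_adding_genomes_never_grows_conserved_set(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 2, (6, 12))
        profiles = pd.DataFrame(counts, index=[f"G{i}" for i in range(6)],
                                columns=[f"F{j}" for j in range(12)])
        prev = None
        for k in range(1, 7):
            cur = conserved_families(profiles, [f"G{i}" for i in range(k)])
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_partition_classes(self):
        presence = {"g1": {"T", "X"}, "g2": {"T", "X", "Y"},
                    "g3": {"T", "Y"}, "g4": {"T", "Z"}}
        part = partition_shared_families(presence)
        assert part["universal"] == {"T"}
        assert part["unique"] == {"Z"}
        assert part["shared"] == {"X": 2, "Y": 2}

    def test_partition_covers_union(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            genera = {f"g{i}": {f"F{j}" for j in range(10)
                                if rng.random() < 0.4}
                      for i in range(int(rng.integers(2, 6)))}
            part = partition_shared_families(genera)
            union = set().union(*genera.values())
            assert part["universal"] | part["unique"] | set(part["shared"]) == union
            assert not (part["universal"] & part["unique"])


class TestIdentitySummary:
    def test_two_member_cluster(self):
        m = pd.DataFrame([[100.0, 97.0], [97.0, 100.0]],
                         index=["A", "B"], columns=["A", "B"])
        s = cluster_identity_summary(m, [SpeciesCluster("A", ("A", "B"))])
        assert s["intra"]["A"] == {"min": 97.0, "median": 97.0, "mean": 97.0}
        assert s["inter"] is None

    def test_singletons_intra_absent(self):
        m = pd.DataFrame([[100.0, 60.0], [60.0, 100.0]],
                         index=["A", "B"], columns=["A", "B"])
        s = cluster_identity_summary(m, [["A"], ["B"]])
        assert s["intra"]["0"] is None and s["intra"]["1"] is None
        assert s["inter"]["mean"] == pytest.approx(60.0)

    def test_random_matrix_matches_pair_enumeration(self):
        rng = np.random.default_rng(23)
        ids = list("ABCDEF")
        vals = rng.uniform(60, 100, (6, 6))
        sym = (vals + vals.T) / 2
        np.fill_diagonal(sym, 100.0)
        m = pd.DataFrame(sym, index=ids, columns=ids)
        clusters = [["A", "B", "C"], ["D", "E", "F"]]
        s = cluster_identity_summary(m, clusters)
        intra0 = [sym[0, 1], sym[0, 2], sym[1, 2]]
        assert s["intra"]["0"]["mean"] == pytest.approx(np.mean(intra0))
        assert s["intra"]["0"]["min"] == pytest.approx(np.min(intra0))
        inter = [sym[i, j] for i in range(3) for j in range(3, 6)]
        assert s["inter"]["mean"] == pytest.approx(np.mean(inter))
        assert s["inter"]["median"] == pytest.approx(np.median(inter))
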