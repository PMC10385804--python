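"""Marker screens: candidate rules, redundancy reduction, union accounting."""
from __future__ import annotations

import numpy as np
import pytest

from cvvscan.orfs import find_orfs
from cvvscan.records import Contig
from cvvscan.references import ncvog_refs, virophage_marker_refs
from cvvscan.screen import (
    consensus_sequence,
    global_identity,
    merge_candidate_sets,
    reduce_redundancy,
    screen_large_viruses,
    screen_virophages,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def levenshtein(a: str, b: str) -> int:
    """Independent pure-Python edit distance for the redundancy oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def marker_contig(rng, families, refs, pad_to, identity=0.7, builder=None):
    proteins = []
    for fam in families:
        _, ref = refs[fam][0]
        mutated = list(ref)
        for i in range(1, len(mutated)):
            if rng.random() > identity:
                mutated[i] = [a for a in AA if a != mutated[i]][rng.integers(19)]
        proteins.append("".join(mutated))
    return builder(rng, proteins, pad_to)


class TestVirophageRule:
    def test_two_markers_above_5kb_is_candidate(self, gene_contig_builder):
        rng = np.random.default_rng(61)
        seq = marker_contig(rng, ["MCP", "ATPase"], virophage_marker_refs(),
                            6000, builder=gene_contig_builder)
        contig = Contig("c6k", seq)
        res = screen_virophages([contig], find_orfs(contig))
        assert res[0].category == "virophage_candidate"
        assert res[0].distinct_markers == {"MCP", "ATPase"}

    def test_three_markers_below_5kb_rejected_on_length(self, gene_contig_builder):
        rng = np.random.default_rng(67)
        seq = marker_contig(rng, ["MCP", "mCP", "ATPase"], virophage_marker_refs(),
                            4800, builder=gene_contig_builder)
        # builder pads *up* to 4800; markers alone stay under it
        contig = Contig("c48", seq[:4800])
        res = screen_virophages([contig], find_orfs(contig))
        assert res[0].category == "rejected"
        assert "length" in res[0].reason

    def test_mcp_is_mandatory(self, gene_contig_builder):
        rng = np.random.default_rng(71)
        seq = marker_contig(rng, ["mCP", "ATPase", "CysProt"], virophage_marker_refs(),
                            8000, builder=gene_contig_builder)
        contig = Contig("nomcp", seq)
        res = screen_virophages([contig], find_orfs(contig))
        assert res[0].category == "rejected" and "MCP" in res[0].reason

    def test_empty_orf_set_rejects_all_with_reason(self):
        contigs = [Contig("a", "ACGT" * 2000), Contig("b", "ACGT" * 2000)]
        res = screen_virophages(contigs, [])
        assert all(r.category == "rejected" and r.reason == "no hits" for r in res)

    def test_unknown_contig_ids_raise(self):
        contig = Contig("a", "ATG" + "AAA" * 60 + "TAA")
        orfs = find_orfs(Contig("other", "ATG" + "AAA" * 60 + "TAA"))
        with pytest.raises(ValueError):
            screen_virophages([contig], orfs)

    def test_result_invariant_to_contig_order(self, gene_contig_builder):
        rng = np.random.default_rng(73)
        seqs = [marker_contig(rng, ["MCP", "CysProt"], virophage_marker_refs(),
                              7000, builder=gene_contig_builder) for _ in range(3)]
        contigs = [Contig(f"c{i}", s) for i, s in enumerate(seqs)]
        orfs = [o for c in contigs for o in find_orfs(c)]
        fwd = {r.contig_id: r for r in screen_virophages(contigs, orfs)}
        rev = {r.contig_id: r for r in screen_virophages(contigs[::-1], orfs[::-1])}
        assert fwd == rev


class TestLargeVirusRule:
    @pytest.mark.parametrize("mode", ["profile", "pairwise"])
    def test_two_families_rejected_three_accepted(self, mode, gene_contig_builder):
        rng = np.random.default_rng(79)
        refs = ncvog_refs()
        two = Contig("two", marker_contig(
            rng, ["NCVOG0038", "NCVOG0023"], refs, 9000, builder=gene_contig_builder))
        three = Contig("three", marker_contig(
            rng, ["NCVOG0038", "NCVOG0023", "NCVOG0249"], refs, 9000,
            builder=gene_contig_builder))
        contigs = [two, three]
        orfs = [o for c in contigs for o in find_orfs(c)]
        res = {r.contig_id: r for r in screen_large_viruses(contigs, orfs, mode=mode)}
        assert res["two"].category == "rejected"
        assert res["three"].category == "large_virus_candidate"

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            screen_large_viruses([], [], mode="hmm")

    def test_consensus_majority_and_ties(self):
        assert consensus_sequence(["MAA", "MAC", "MCC"]) == "MAC"
        # tie at column 2 (A vs C) resolves alphabetically
        assert consensus_sequence(["MA", "MC"]) == "MA"


class TestReduceRedundancy:
    def test_identical_copies_collapse(self):
        prots = [(f"p{i}", "MKVLWAALLVTFLAGC" * 5) for i in range(5)]
        assert len(reduce_redundancy(prots)) == 1

    def test_97_percent_pair_stays_separate(self):
        rng = np.random.default_rng(83)
        base = "".join(rng.choice(list(AA), size=100))
        mutated = list(base)
        for i in rng.choice(100, size=3, replace=False):
            mutated[i] = [a for a in AA if a != mutated[i]][0]
        reps = reduce_redundancy([("a", base), ("b", "".join(mutated))])
        assert len(reps) == 2

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            reduce_redundancy([])

    def test_representatives_pairwise_below_threshold(self):
        rng = np.random.default_rng(89)
        families = []
        for f in range(10):
            base = "".join(rng.choice(list(AA), size=int(rng.integers(50, 70))))
            families.append(base)
            for _ in range(4):  # near-duplicates at ~99% identity
                dup = list(base)
                if rng.random() < 0.8:
                    i = int(rng.integers(1, len(dup)))
                    dup[i] = [a for a in AA if a != dup[i]][0]
                families.append("".join(dup))
        prots = [(f"p{i:02d}", s) for i, s in enumerate(families)]
        reps = reduce_redundancy(prots)
        assert len(reps) <= 10 + 2  # near-dups folded into their founders
        for i, (_, a) in enumerate(reps):
            for _, b in reps[i + 1:]:
                ident = 1.0 - levenshtein(a, b) / max(len(a), len(b))
                ratio = min(len(a), len(b)) / max(len(a), len(b))
                assert ident < 0.98 or ratio < 0.8

    def test_identity_definition_matches_oracle(self):
        rng = np.random.default_rng(97)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(20, 60))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(20, 60))))
            expected = 1.0 - levenshtein(a, b) / max(len(a), len(b))
            assert global_identity(a, b) == pytest.approx(expected)


class TestMergeCandidateSets:
    def test_printed_union_arithmetic(self):
        a = {f"a{i}" for i in range(7)} | {f"x{i}" for i in range(20)}
        b = {f"b{i}" for i in range(105)} | {f"x{i}" for i in range(20)}
        report = merge_candidate_sets(a, b)
        assert report == {"a": 27, "b": 125, "intersection": 20, "union": 132}

    def test_disjoint_sets(self):
        assert merge_candidate_sets({"a", "b", "c"}, {"d", "e", "f", "g"})["union"] == 7

    def test_inclusion_exclusion_on_random_pairs(self):
        rng = np.random.default_rng(101)
        for _ in range(200):
            universe = [f"c{i}" for i in range(40)]
            a = {u for u in universe if rng.random() < 0.4}
            b = {u for u in universe if rng.random() < 0.4}
            rep = merge_candidate_sets(a, b)
            brute = sum(1 for u in universe if u in a or u in b)
            assert rep["union"] == brute == rep["a"] + rep["b"] - rep["intersection"]


class TestGroundTruthRecovery:
    def test_all_planted_virophages_recovered_no_background(self, default_run, truth_by_id):
        results = {r.contig_id: r for r in default_run["vp_results"]}
        for cid, t in truth_by_id.items():
            if t.category == "virophage":
                assert results[cid].category == "virophage_candidate"
            elif t.category == "background":
                assert results[cid].category == "rejected"

    @pytest.mark.parametrize("key", ["lv_profile", "lv_pairwise"])
    def test_all_planted_large_viruses_recovered_both_modes(self, key, default_run,
                                                            truth_by_id):
        results = {r.contig_id: r for r in default_run[key]}
        for cid, t in truth_by_id.items():
            if t.category == "large_virus":
                assert results[cid].category == "large_virus_candidate"
            elif t.category == "background":
                assert results[cid].category == "rejected"
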