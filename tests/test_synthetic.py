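"""Synthetic virome generator: determinism, planted-feature fidelity."""
from __future__ import annotations

import numpy as np
import pytest

from cvvscan.codon import CODONS, profile
from cvvscan.io import read_fasta, read_truth_tsv, write_fasta, write_truth_tsv
from cvvscan.orfs import find_orfs, orf_nt, translate
from cvvscan.records import Contig
from cvvscan.synthetic import (
    GeneratorConfig,
    apply_codon_bias,
    generate,
    plant_spacer,
)


def small_config(seed=5, **overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(
        seed=seed, n_background=10, n_virophage=3, n_virophage_complete=2,
        n_circular=1, n_linear=1, n_large_virus=1,
        large_virus_length_range=(40000, 45000),
        spacer_plants=[("vp_01", "lv_01", 20, 1)],
        codon_couples=[("vp_01", "lv_01", 0.8)],
        shared_protein_plants=[("vp_01", "lv_01")],
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


class TestConfigValidation:
    def test_inconsistent_topology_counts_rejected(self):
        cfg = small_config(n_circular=2, n_linear=2)  # 4 != n_complete (2)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_complete_count_cannot_exceed_total(self):
        cfg = small_config(n_virophage=1, n_virophage_complete=2,
                          n_circular=1, n_linear=1)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_bad_spacer_k_rejected(self):
        cfg = small_config(spacer_plants=[("vp_01", "lv_01", 17, 1)])
        with pytest.raises(ValueError):
            cfg.validate()

    def test_bias_strength_out_of_range_rejected(self):
        cfg = small_config(codon_couples=[("vp_01", "lv_01", 1.5)])
        with pytest.raises(ValueError):
            cfg.validate()

    def test_roundtrips_through_dict(self):
        cfg = small_config()
        assert GeneratorConfig.from_dict(cfg.to_dict()) == cfg


class TestGenerate:
    def test_all_zero_config_yields_empty_outputs(self):
        cfg = GeneratorConfig(seed=1, n_background=0, n_virophage=0,
                              n_virophage_complete=0, n_circular=0, n_linear=0,
                              n_large_virus=0, spacer_plants=[], codon_couples=[],
                              shared_protein_plants=[])
        contigs, truths = generate(cfg)
        assert contigs == [] and truths == []

    def test_topology_composition_matches_config(self):
        cfg = GeneratorConfig(seed=3, n_background=0, n_virophage=8,
                              n_virophage_complete=8, n_circular=7, n_linear=1,
                              n_large_virus=0, spacer_plants=[], codon_couples=[],
                              shared_protein_plants=[])
        _, truths = generate(cfg)
        topo = [t.topology for t in truths if t.category == "virophage"]
        assert topo.count("circular") == 7 and topo.count("linear") == 1

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        files = []
        for run in ("a", "b"):
            contigs, truths = generate(small_config(seed=9))
            write_fasta(contigs, tmp_path / f"{run}.fasta")
            write_truth_tsv(truths, tmp_path / f"{run}.tsv")
            files.append(((tmp_path / f"{run}.fasta").read_bytes(),
                          (tmp_path / f"{run}.tsv").read_bytes()))
        assert files[0] == files[1]

    def test_different_seeds_differ(self):
        a, _ = generate(small_config(seed=9))
        b, _ = generate(small_config(seed=10))
        assert a[0].seq != b[0].seq

    def test_truth_coordinates_slice_planted_markers(self):
        contigs, truths = generate(small_config(seed=11))
        by_id = {c.id: c for c in contigs}
        checked = 0
        for t in truths:
            for m in t.planted_markers:
                cds = by_id[t.contig_id].seq[m.start - 1:m.end]
                assert len(cds) % 3 == 0
                prot = translate(cds)
                assert len(prot) >= 50 and "*" not in prot
                checked += 1
        assert checked > 0

    def test_planted_markers_discoverable_by_orf_finder(self):
        contigs, truths = generate(small_config(seed=13))
        by_id = {c.id: c for c in contigs}
        for t in truths:
            if not t.planted_markers:
                continue
            found = {(o.start, o.end) for o in find_orfs(by_id[t.contig_id])
                     if o.strand == "+"}
            for m in t.planted_markers:
                assert (m.start, m.end) in found

    def test_complete_genomes_within_configured_length_range(self):
        cfg = small_config(seed=15)
        contigs, truths = generate(cfg)
        lo, hi = cfg.virophage_length_range
        for t in truths:
            if t.category == "virophage" and t.topology != "fragment":
                assert lo <= len(next(c for c in contigs if c.id == t.contig_id)) <= hi

    def test_sites_assigned_round_robin(self):
        cfg = small_config(seed=17)
        contigs, truths = generate(cfg)
        assert all(c.site in cfg.site_labels for c in contigs)
        assert {c.site for c in contigs} == set(
            cfg.site_labels[i % len(cfg.site_labels)] for i in range(len(contigs)))

    def test_fasta_truth_roundtrip(self, tmp_path):
        contigs, truths = generate(small_config(seed=19))
        write_fasta(contigs, tmp_path / "v.fasta")
        write_truth_tsv(truths, tmp_path / "t.tsv")
        assert read_fasta(tmp_path / "v.fasta") == contigs
        assert read_truth_tsv(tmp_path / "t.tsv") == truths


class TestPlantSpacer:
    def hamming(self, a, b):
        return sum(x != y for x, y in zip(a, b))

    def test_zero_mismatch_copy_is_verbatim(self):
        rng = np.random.default_rng(21)
        vp = Contig("v", "".join(rng.choice(list("ACGT"), size=500)))
        lv = Contig("l", "".join(rng.choice(list("ACGT"), size=500)))
        vp2, lv2, truth = plant_spacer(vp, lv, 20, 0, rng)
        word = vp2.seq[truth.position_in_virophage - 1:truth.position_in_virophage + 19]
        assert word in lv2.seq

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            plant_spacer(Contig("v", "ACGT" * 50), Contig("l", "ACGT" * 50), 21, 0)

    def test_hamming_distance_equals_recorded_mismatches(self):
        rng = np.random.default_rng(23)
        for trial in range(100):
            k = [15, 20, 25, 30, 35, 40][trial % 6]
            mm = trial % 2
            vp = Contig("v", "".join(rng.choice(list("ACGT"), size=300)))
            lv = Contig("l", "".join(rng.choice(list("ACGT"), size=300)))
            _, lv2, truth = plant_spacer(vp, lv, k, mm, rng)
            a = vp.seq[truth.position_in_virophage - 1:
                       truth.position_in_virophage - 1 + k]
            b = lv2.seq[truth.position_in_large_virus - 1:
                        truth.position_in_large_virus - 1 + k]
            assert self.hamming(a, b) == mm == truth.mismatches

    def test_generated_spacer_truth_positions_check_out(self):
        contigs, truths = generate(small_config(seed=25))
        by_id = {c.id: c for c in contigs}
        checked = 0
        for t in truths:
            if t.category != "virophage":
                continue
            for s in t.planted_spacers:
                a = by_id[t.contig_id].seq[
                    s.position_in_virophage - 1:s.position_in_virophage - 1 + s.k]
                b = by_id[s.partner_id].seq[
                    s.position_in_large_virus - 1:s.position_in_large_virus - 1 + s.k]
                assert self.hamming(a, b) == s.mismatches
                checked += 1
        assert checked > 0


class TestApplyCodonBias:
    def planted_orf_contig(self, rng, n_genes=4):
        from cvvscan.synthetic import _assemble_genome, _codon_preference, _random_protein
        pref = _codon_preference(rng)
        draft = _assemble_genome(rng, "g", 8000, [],
                                 [_random_protein(rng, 150) for _ in range(n_genes)],
                                 pref, 0.45)
        return Contig("g", draft.seq), draft.orf_spans

    def test_zero_bias_is_identity(self):
        rng = np.random.default_rng(27)
        contig, spans = self.planted_orf_contig(rng)
        target = profile("t", ["ATGAAATAA"])
        assert apply_codon_bias(contig, spans, target, 0.0, rng) == contig

    def test_proteins_preserved_under_bias(self):
        rng = np.random.default_rng(29)
        contig, spans = self.planted_orf_contig(rng)
        target = profile("t", ["".join(rng.choice(
            [c for c in CODONS if c not in ("TAA", "TAG", "TGA")], size=400)) + "TAA"])
        biased = apply_codon_bias(contig, spans, target, 0.7, rng)
        for start, end in spans:
            assert translate(biased.seq[start - 1:end]) == \
                translate(contig.seq[start - 1:end])

    def test_full_bias_converges_to_target(self):
        rng = np.random.default_rng(31)
        contig, spans = self.planted_orf_contig(rng, n_genes=12)
        # target prefers one codon per amino acid: AAA over AAG, etc.
        sense = [c for c in CODONS if c not in ("TAA", "TAG", "TGA")]
        target = profile("t", ["".join(sense) ])  # uniform over sense codons
        biased = apply_codon_bias(contig, spans, target, 1.0, rng)
        # start codons are never resampled (they fix the ORF), so tally from
        # the second codon on
        got = profile("g", [biased.seq[s + 2:e] for s, e in spans])
        # per-amino-acid conditional frequencies approach the (uniform) target
        from cvvscan.orfs import SYNONYMOUS
        for aa, codons in SYNONYMOUS.items():
            idx = [CODONS.index(c) for c in codons]
            mass = got.freq[idx].sum()
            if mass < 0.02 or len(codons) == 1:
                continue
            conditional = got.freq[idx] / mass
            assert np.allclose(conditional, 1.0 / len(codons), atol=0.12)

    def test_out_of_range_bias_rejected(self):
        rng = np.random.default_rng(33)
        contig, spans = self.planted_orf_contig(rng)
        with pytest.raises(ValueError):
            apply_codon_bias(contig, spans, profile("t", ["ATGAAATAA"]), 1.2, rng)
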