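import numpy as np
import pytest

from wtfkit.annotation import (
    CandidateHit, GeneModel, assign_loci, call_pseudogene, detect_poison_starts,
    find_family_members, flag_solo_ltr, transfer_exon_structure,
)
from wtfkit.io_formats import SeqEntry, SeqRecordSet
from .conftest import mutate_dna, random_dna


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _records(**kw):
    return SeqRecordSet([SeqEntry(k, v) for k, v in kw.items()])


class TestFindFamilyMembers:
    def test_verbatim_query_found_with_full_identity(self, rng):
        query = random_dna(rng, 300)
        genome = random_dna(rng, 1500) + query + random_dna(rng, 1500)
        hits = find_family_members(_records(chr1=genome), _records(q1=query))
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "+" and h.identity == pytest.approx(1.0)
        assert h.start <= 1501 and h.end >= 1500 + 300

    def test_reverse_complement_query_reported_on_minus_strand(self, rng):
        query = random_dna(rng, 300)
        genome = random_dna(rng, 1000) + _revcomp(query) + random_dna(rng, 1000)
        hits = find_family_members(_records(chr1=genome), _records(q1=query))
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_absent_query_yields_no_hits(self, rng):
        genome = random_dna(rng, 2000)
        query = random_dna(rng, 200)
        # fixed seed: no shared 11-mer between these two draws
        hits = find_family_members(_records(chr1=genome), _records(q1=query))
        assert hits == []

    def test_query_shorter_than_seed_rejected(self, rng):
        with pytest.raises(ValueError, match="seed length"):
            find_family_members(_records(chr1=random_dna(rng, 100)),
                                _records(q1="ACGTACGT"))

    def test_overlapping_hits_from_different_queries_merge(self, rng):
        gene = random_dna(rng, 400)
        genome = random_dna(rng, 800) + gene + random_dna(rng, 800)
        queries = _records(q1=gene, q2=mutate_dna(rng, gene, 0.05))
        hits = find_family_members(_records(chr1=genome), queries)
        assert len(hits) == 1


def _gene_model(seq, exons, gene_id="g", strain="s"):
    return GeneModel(gene_id=gene_id, strain=strain, contig="c",
                     span=(1, len(seq)), strand="+", exons=exons, seq=seq)


class TestTransferExonStructure:
    def _reference(self, rng):
        e1, i1, e2 = random_dna(rng, 90), random_dna(rng, 60), random_dna(rng, 120)
        seq = e1 + i1 + e2
        return _gene_model(seq, [(1, 90), (151, 270)], gene_id="ref1")

    def test_identical_candidate_inherits_exact_structure(self, rng):
        ref = self._reference(rng)
        genome = _records(chr1=random_dna(rng, 200) + ref.seq + random_dna(rng, 200))
        cand = CandidateHit("chr1", 201, 200 + len(ref.seq), "+", "ref1",
                            100.0, 1e-20, 1.0)
        model = transfer_exon_structure(cand, genome, [ref], strain="s2")
        assert model.exons == ref.exons
        assert model.spliced() == ref.spliced()

    def test_single_substitution_recorded_below_unit_identity(self, rng):
        ref = self._reference(rng)
        mutated = mutate_dna(rng, ref.seq, 0.01)
        genome = _records(chr1=mutated)
        cand = CandidateHit("chr1", 1, len(mutated), "+", "ref1", 90.0, 1e-18, 0.99)
        model = transfer_exon_structure(cand, genome, [ref], strain="s2")
        assert any("identity 0." in n for n in model.notes)

    def test_tie_between_references_broken_by_order_and_logged(self, rng):
        ref = self._reference(rng)
        ref_b = _gene_model(ref.seq, ref.exons, gene_id="ref2")
        genome = _records(chr1=ref.seq)
        cand = CandidateHit("chr1", 1, len(ref.seq), "+", "ref1", 100.0, 1e-20, 1.0)
        model = transfer_exon_structure(cand, genome, [ref, ref_b], strain="s2")
        assert any("tie" in n for n in model.notes)
        assert any("structure from ref1" in n for n in model.notes)

    def test_low_identity_candidate_rejected(self, rng):
        ref = self._reference(rng)
        junk = random_dna(rng, len(ref.seq))
        genome = _records(chr1=junk)
        cand = CandidateHit("chr1", 1, len(junk), "+", "ref1", 20.0, 1e-6, 0.3)
        with pytest.raises(ValueError, match="rejected"):
            transfer_exon_structure(cand, genome, [ref], strain="s2")


class TestCallPseudogene:
    def test_terminal_stop_is_intact(self):
        m = _gene_model("ATGAAATAG", [(1, 9)])
        status, dis = call_pseudogene(m)
        assert status == "intact" and dis == []

    def test_internal_stop_is_pseudogene(self):
        cds = "ATG" + "TAA" + "AAA" * 97 + "TAG"
        m = _gene_model(cds, [(1, len(cds))])
        status, dis = call_pseudogene(m)
        assert status == "pseudogene"
        assert any("premature stop" in d for d in dis)

    def test_frameshifting_length_is_pseudogene(self):
        cds = "ATG" + "A" * 298  # 301 nt
        m = _gene_model(cds, [(1, 301)])
        status, dis = call_pseudogene(m)
        assert status == "pseudogene"
        assert any("frameshift" in d for d in dis)

    def test_missing_start_is_pseudogene(self):
        m = _gene_model("TTGAAATAG", [(1, 9)])
        status, dis = call_pseudogene(m)
        assert status == "pseudogene"
        assert any("start" in d for d in dis)


class TestDetectPoisonStarts:
    def _two_exon(self, exon2: str, intron: str = "T" * 30):
        e1 = "ATGAAA"  # off2 = 6, phase 0
        seq = e1 + intron + exon2
        return _gene_model(seq, [(1, 6), (7 + len(intron), 6 + len(intron) + len(exon2))])

    def test_exon2_atg_in_frame_detected(self):
        flags = detect_poison_starts(self._two_exon("ATGCCCAAA"))
        assert flags["exon2_atg"]

    def test_intron1_terminal_atg_in_frame_detected(self):
        flags = detect_poison_starts(self._two_exon("CCCAAATTT", intron="T" * 27 + "ATG"))
        assert flags["intron1_atg"]

    def test_no_atg_in_either_window(self):
        flags = detect_poison_starts(self._two_exon("CCCAAATTT"))
        assert not flags["exon2_atg"] and not flags["intron1_atg"]

    def test_out_of_frame_atg_ignored(self):
        flags = detect_poison_starts(self._two_exon("CATGCCAAA"))
        assert not flags["exon2_atg"]

    def test_single_exon_model_flags_false_with_warning(self):
        m = _gene_model("ATGAAATAG", [(1, 9)])
        flags = detect_poison_starts(m)
        assert flags == {"exon2_atg": False, "intron1_atg": False}
        assert any("single-exon" in n for n in m.notes)


class TestAssignLoci:
    def _strain(self, rng, flank_l, flank_r, gene):
        contig = flank_l + gene + flank_r
        return contig, (len(flank_l) + 1, len(flank_l) + len(gene))

    def test_shared_flanks_group_into_one_locus(self, rng):
        fl, fr = random_dna(rng, 300), random_dna(rng, 300)
        gene = random_dna(rng, 200)
        models, genomes = [], {}
        for strain in ("s1", "s2"):
            contig, span = self._strain(rng, fl, fr, mutate_dna(rng, gene, 0.02))
            genomes[strain] = _records(**{f"{strain}_c": contig})
            models.append(GeneModel(f"{strain}.g", strain, f"{strain}_c", span,
                                    "+", [(1, 200)], gene))
        pm = assign_loci(models, genomes, flank_len=300)
        assert pm.n_loci == 1
        assert pm.locus_of["s1.g"] == pm.locus_of["s2.g"]

    def test_unrelated_flanks_stay_distinct(self, rng):
        gene = random_dna(rng, 200)
        models, genomes = [], {}
        for strain in ("s1", "s2"):
            contig, span = self._strain(rng, random_dna(rng, 300),
                                        random_dna(rng, 300), gene)
            genomes[strain] = _records(**{f"{strain}_c": contig})
            models.append(GeneModel(f"{strain}.g", strain, f"{strain}_c", span,
                                    "+", [(1, 200)], gene))
        pm = assign_loci(models, genomes, flank_len=300)
        assert pm.n_loci == 2

    def test_invariant_to_strain_input_order(self, default_sim):
        from wtfkit.annotation import gene_models_from_tables
        models = gene_models_from_tables(default_sim.genomes, default_sim.models)
        pm1 = assign_loci(models, default_sim.genomes)
        pm2 = assign_loci(list(reversed(models)), default_sim.genomes)
        assert pm1.locus_of == pm2.locus_of

    def test_per_strain_totals_match_model_counts(self, default_sim):
        from wtfkit.annotation import gene_models_from_tables
        models = gene_models_from_tables(default_sim.genomes, default_sim.models)
        pm = assign_loci(models, default_sim.genomes)
        counts = {}
        for m in models:
            counts[m.strain] = counts.get(m.strain, 0) + 1
        assert pm.per_strain_totals().to_dict() == counts


class TestFlagSoloLtr:
    def test_planted_ltr_copy_detected(self, rng):
        ltr = random_dna(rng, 120)
        gene = random_dna(rng, 200)
        contig = random_dna(rng, 400) + ltr + random_dna(rng, 50) + gene
        start = len(contig) - len(gene) + 1
        m = GeneModel("g", "s", "c", (start, len(contig)), "+", [(1, 200)], gene)
        assert flag_solo_ltr(m, _records(c=contig), _records(ltr1=ltr),
                             window=300)

    def test_no_ltr_within_window(self, rng):
        gene = random_dna(rng, 200)
        contig = random_dna(rng, 500) + gene + random_dna(rng, 500)
        m = GeneModel("g", "s", "c", (501, 700), "+", [(1, 200)], gene)
        assert not flag_solo_ltr(m, _records(c=contig),
                                 _records(ltr1=random_dna(rng, 120)), window=300)

    def test_degenerate_ltr_below_identity_floor_ignored(self, rng):
        ltr = random_dna(rng, 120)
        degenerate = mutate_dna(rng, ltr, 0.4)
        gene = random_dna(rng, 200)
        contig = random_dna(rng, 200) + degenerate + random_dna(rng, 50) + gene
        start = len(contig) - len(gene) + 1
        m = GeneModel("g", "s", "c", (start, len(contig)), "+", [(1, 200)], gene)
        assert not flag_solo_ltr(m, _records(c=contig), _records(ltr1=ltr),
                                 window=300)
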