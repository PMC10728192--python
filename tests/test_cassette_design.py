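import numpy as np
import pytest

from wormforge.cassette_design import (
    DEFAULT_ENZYMES,
    DesignError,
    DesignParams,
    design_gene,
    design_genotyping,
    design_ssodn,
    find_cut_sites,
    predict_edited_allele,
    validate_design,
)
from wormforge.genome_io import GeneModel, Genome, reverse_complement, translate

from _oracles import pam_scan_oracle, revcomp


def _single_exon_gene(genome_seq: str, start: int, end: int, strand: str = "+",
                      gene_id: str = "g1") -> tuple[GeneModel, Genome]:
    genome = Genome({"chrI": genome_seq})
    seg = genome_seq[start:end]
    cds = seg if strand == "+" else reverse_complement(seg)
    protein = translate(cds)
    protein = protein[:-1] if protein.endswith("*") else protein
    model = GeneModel(gene_id, "NA", "chrI", strand, [(start, end)], cds, protein)
    return model, genome


class TestFindCutSites:
    def test_matches_sliding_window_oracle(self, toy_study):
        genome = toy_study["genome"]
        for model in toy_study["models"][:5]:
            start, end = model.cds_span
            region = genome["chrI"][start:end]
            oracle_cuts = {
                (start + pos, strand)
                for pos, strand in pam_scan_oracle(region)
                if start < start + pos < end
            }
            got = {(s.cut_pos, s.strand) for s in find_cut_sites(model, genome)}
            # the scanner also sees sites whose protospacer extends past the
            # CDS edge into flanking DNA; restrict to the oracle's domain
            assert oracle_cuts <= got

    def test_cut_three_nt_from_pam(self):
        # 17 A's + 20-nt protospacer region ending ...CGG PAM
        seq = "T" * 30 + "ATG" + "A" * 20 + "CGG" + "A" * 34 + "T" * 30
        model, genome = _single_exon_gene(seq, 30, 90)
        sites = [s for s in find_cut_sites(model, genome) if s.strand == "+"]
        pam_starts = {s.cut_pos + 3 for s in sites}
        for s in sites:
            pam_pos = s.cut_pos + 3
            assert genome["chrI"][pam_pos + 1 : pam_pos + 3] == "GG"
        assert any(genome["chrI"][p : p + 3] == "CGG" for p in pam_starts)

    def test_reverse_strand_site_reported(self):
        # CCN on the reference means an NGG protospacer on the minus strand
        seq = "T" * 30 + "ATG" + "CCA" + "T" * 51 + "T" * 3 + "G" * 0 + "A" * 0
        seq = seq + "T" * (120 - len(seq))
        model, genome = _single_exon_gene(seq, 30, 90)
        minus = [s for s in find_cut_sites(model, genome) if s.strand == "-"]
        assert minus
        for s in minus:
            # PAM is NGG on the protospacer strand = CCN on the reference
            ref = genome["chrI"]
            pam_ref_start = s.cut_pos - 6
            assert ref[pam_ref_start : pam_ref_start + 2] == "CC"
            assert s.pam[1:] == "GG"
            assert s.protospacer == revcomp(ref[s.cut_pos - 3 : s.cut_pos + 17])

    def test_no_pam_returns_empty(self):
        seq = "T" * 30 + "ATG" + "ATA" * 19 + "TAA" + "T" * 30
        model, genome = _single_exon_gene(seq, 30, 30 + 3 + 57 + 3)
        assert find_cut_sites(model, genome) == []

    def test_sorted_by_cds_offset_and_preferred_flag(self, toy_study):
        model = toy_study["models"][0]
        sites = find_cut_sites(model, toy_study["genome"])
        offsets = [s.cds_offset for s in sites]
        assert offsets == sorted(offsets)
        half = len(model.cds_seq) / 2
        for s in sites:
            assert s.preferred == (s.cds_offset < half)


class TestDesignSsodn:
    def test_structure_and_invariants(self, toy_study):
        genome = toy_study["genome"]
        for model in toy_study["models"]:
            design, assay = toy_study["designs"][model.gene_id]
            assert len(design.left_arm) == len(design.right_arm) == 35
            assert design.ssodn_seq == (
                design.left_arm + design.insert_seq + design.right_arm
            )
            assert design.net_length_change % 3 != 0
            report = validate_design(design, assay, genome, gene=model)
            assert report["pass"], report["checks"]

    def test_enzyme_skipped_when_site_in_wildtype(self, toy_study):
        genome = toy_study["genome"]
        model = toy_study["models"][0]
        design, _ = toy_study["designs"][model.gene_id]
        # plant the first enzyme's site right next to the cut in a copy of
        # the genome; the designer must then pick a later enzyme
        name0, site0 = DEFAULT_ENZYMES[0]
        seq = genome["chrI"]
        pos = design.cut.cut_pos + 200
        hacked = Genome({"chrI": seq[:pos] + site0 + seq[pos + len(site0):]})
        design2 = design_ssodn(model, design.cut, hacked)
        assert design2.enzyme[0] != name0
        halo = hacked["chrI"][design.cut.cut_pos - 1050 : design.cut.cut_pos + 1050]
        assert design2.enzyme[1] not in halo

    def test_frameshift_arithmetic(self, toy_study):
        # del_len 7 with a 6-cutter insert (23 nt) -> net +16 == 1 (mod 3)
        design, _ = next(iter(toy_study["designs"].values()))
        start, end = design.deleted_interval
        assert end - start == 7
        assert (len(design.insert_seq) - 7) % 3 == 1

    def test_triple_frame_stops_in_coding_insert(self, toy_study):
        stops = {"TAA", "TAG", "TGA"}
        for design, _ in toy_study["designs"].values():
            ins = design.coding_insert
            for frame in range(3):
                codons = [ins[i : i + 3] for i in range(frame, len(ins) - 2, 3)]
                assert stops & set(codons), f"no stop in frame {frame}"

    def test_edited_cds_translation_truncates(self, toy_study):
        genome = toy_study["genome"]
        for model in toy_study["models"]:
            design, _ = toy_study["designs"][model.gene_id]
            start, end = model.cds_span
            ds, de = design.deleted_interval
            edited_cds = (
                genome["chrI"][start:ds] + design.insert_seq + genome["chrI"][de:end]
            )
            aa = translate(edited_cds, allow_truncation=True)
            assert "*" in aa
            assert aa.index("*") < len(model.protein)


class TestPredictAndGenotype:
    def test_predicted_allele_contains_site_once(self, toy_study):
        genome = toy_study["genome"]
        for design, _ in toy_study["designs"].values():
            allele = predict_edited_allele(design, genome)
            assert allele == design.expected_edited_locus
            assert allele.count(design.enzyme[1]) == 1

    def test_amplicon_bounds_and_fragments(self, toy_study):
        for design, assay in toy_study["designs"].values():
            assert 400 <= assay.wt_amplicon_len <= 1000
            assert assay.edited_amplicon_len == (
                assay.wt_amplicon_len + design.net_length_change
            )
            f1, f2 = assay.edited_digest_fragments
            assert f1 + f2 == assay.edited_amplicon_len
            assert min(f1, f2) >= 100
            assert abs(f2 - f1) >= 50
            assert assay.wt_digest_fragments == [assay.wt_amplicon_len]

    def test_fragment_arithmetic_from_site_position(self, toy_study):
        genome = toy_study["genome"]
        for design, assay in toy_study["designs"].values():
            lo, hi = assay.amplicon_interval
            ds, de = design.deleted_interval
            edited_amp = (
                genome["chrI"][lo:ds] + design.insert_seq + genome["chrI"][de:hi]
            )
            pos = edited_amp.find(design.enzyme[1])
            cut = pos + len(design.enzyme[1]) // 2
            assert sorted([cut, len(edited_amp) - cut]) == assay.edited_digest_fragments

    def test_primer_composition_rules(self, toy_study):
        for _, assay in toy_study["designs"].values():
            for primer in (assay.fwd_primer, assay.rev_primer):
                assert 18 <= len(primer) <= 25
                gc = (primer.count("G") + primer.count("C")) / len(primer)
                assert 0.40 <= gc <= 0.60
                for base in "ACGT":
                    assert base * 5 not in primer


class TestValidation:
    def test_forced_frameshift_failure_detected(self, toy_study):
        genome = toy_study["genome"]
        gene_id, (design, assay) = next(iter(toy_study["designs"].items()))
        import dataclasses

        # pad the insert so the net length change becomes 0 mod 3
        pad = (3 - design.net_length_change % 3) % 3
        bad = dataclasses.replace(design, insert_seq=design.insert_seq + "A" * pad)
        report = validate_design(bad, assay, genome)
        assert not report["checks"]["frameshift"]
        assert not report["pass"]

    def test_del_len_bounds(self):
        with pytest.raises(ValueError):
            DesignParams(del_len=3)
        with pytest.raises(ValueError):
            DesignParams(del_len=31)
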