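import pytest

from plastevo.codon_align import align_codon
from plastevo.io_formats import SequenceRecord
from plastevo.phylo import compile_tree, fitch_steps_matrix, leaf_state_masks
from plastevo.io_formats import parse_newick
from plastevo.pseudogene import (PseudogeneCall, build_status_matrix,
                                 calls_table, mask_pseudogenes, scan_gene,
                                 scan_records)

REF = "ATGAAATTTTAA"


class TestScanGene:
    def test_identical_query_intact(self):
        call = scan_gene(REF, REF)
        assert call.status == "intact"
        assert call.lesion_kind == "none"
        assert call.first_lesion_codon is None
        assert call.intact_fraction == 1.0

    def test_premature_stop_at_codon_two(self):
        call = scan_gene(REF, "ATGTAATTTTAA")
        assert call.status == "pseudogene"
        assert call.lesion_kind == "premature_stop"
        assert call.first_lesion_codon == 2

    def test_empty_query_absent(self):
        call = scan_gene(REF, "")
        assert call.status == "absent"
        assert call.intact_fraction == 0.0

    def test_single_base_deletion_is_frameshift_at_codon_two(self):
        # delete one 'A' inside codon 2 of a gene long enough to persist
        ref = "ATG" + "AAA" + "TTTCCCGGGATTCTTGAACATCCGGAT" * 2 + "TAA"
        q = ref[:4] + ref[5:]
        call = scan_gene(ref, q)
        assert call.status == "pseudogene"
        assert call.lesion_kind == "frameshift"
        assert call.first_lesion_codon == 2

    def test_compensated_frameshift_within_window_is_intact(self):
        ref = "ATGAAATTTCCCGGGAAATTTCCCGGGAAATTTCCCGGGTAA"
        # +1 bp in codon 3, compensating -1 bp in codon 7 (< F codons apart)
        q = ref[:6] + "A" + ref[6:19] + ref[20:]
        call = scan_gene(ref, q)
        assert call.status == "intact"

    def test_terminal_truncation_detected_with_position(self):
        ref = ("ATG" + "GATCGTACTGAGCTTAAGGCTCAGATCGAT" * 4 + "TAA")
        n_codons = len(ref) // 3
        cut = 3 * (n_codons // 2)
        call = scan_gene(ref, ref[:cut])
        assert call.status == "pseudogene"
        assert call.lesion_kind == "truncation"
        assert call.first_lesion_codon == n_codons // 2 + 1

    def test_terminal_stop_never_a_lesion(self):
        call = scan_gene(REF, "ATGAAATTTTAA")
        assert call.status == "intact"

    def test_untranslatable_reference_raises(self):
        with pytest.raises(ValueError, match="clean ORF"):
            scan_gene("ATGTAAAA", REF)


class TestScanRecords:
    def test_planted_lesions_recovered(self, small_dataset):
        truth = small_dataset.truth
        for gene, recs in small_dataset.genes.items():
            calls = {c.taxon: c for c in scan_records(recs, gene=gene)}
            for taxon, true_status in truth["status"][gene].items():
                assert calls[taxon].status == true_status, (gene, taxon)

    def test_stop_lesion_position_exact(self, small_dataset):
        les = small_dataset.truth["genes"]["atpA"]["lesions"]["t02"]
        calls = {c.taxon: c
                 for c in scan_records(small_dataset.genes["atpA"], gene="atpA")}
        assert calls["t02"].lesion_kind == "premature_stop"
        assert abs(calls["t02"].first_lesion_codon - les["codon"]) <= 1


class TestStatusMatrix:
    def _call(self, gene, taxon, status="intact", frac=1.0, kind="none",
              codon=None):
        return PseudogeneCall(gene, taxon, status, kind, codon, frac)

    def test_all_intact_single_category(self):
        calls = [self._call("g", t) for t in "abc"]
        mat = build_status_matrix(calls)
        assert set(mat.values.ravel()) == {"intact"}

    @pytest.mark.parametrize("frac,expected", [
        (0.1, "pseudo_severe"),
        (0.5, "pseudo_moderate"),
        (0.8, "pseudo_mild"),
    ])
    def test_shading_thresholds(self, frac, expected):
        call = self._call("g", "a", status="pseudogene", frac=frac,
                          kind="premature_stop", codon=2)
        assert build_status_matrix([call]).loc["g", "a"] == expected

    def test_duplicate_cell_raises(self):
        calls = [self._call("g", "a"), self._call("g", "a")]
        with pytest.raises(ValueError, match="duplicate"):
            build_status_matrix(calls)

    def test_missing_cells_are_absent(self):
        calls = [self._call("g1", "a"), self._call("g2", "b")]
        mat = build_status_matrix(calls)
        assert mat.loc["g1", "b"] == "absent"

    def test_matrix_matches_truth_on_synthetic(self, small_dataset):
        calls = []
        for gene, recs in small_dataset.genes.items():
            calls.extend(scan_records(recs, gene=gene))
        mat = build_status_matrix(calls)
        truth = small_dataset.truth["status"]
        hits = total = 0
        for gene, by_taxon in truth.items():
            for taxon, status in by_taxon.items():
                cat = mat.loc[gene, taxon]
                ok = (status == "intact" and cat == "intact") or \
                     (status == "absent" and cat == "absent") or \
                     (status == "pseudogene" and cat.startswith("pseudo"))
                hits += ok
                total += 1
        assert hits / total >= 0.95


class TestMasking:
    def _toy_alignment(self):
        recs = [SequenceRecord(t, seq) for t, seq in
                [("a", "ATGAAATTTTAA"), ("b", "ATGAAATTTTAA"),
                 ("c", "ATGAATTTTTAA"), ("d", "ATGAAATTTTAA")]]
        return align_codon(recs, gene="g")

    def _calls(self, statuses):
        return [PseudogeneCall("g", t, s,
                               "none" if s == "intact" else "premature_stop",
                               None if s == "intact" else 2,
                               1.0 if s == "intact" else 0.1)
                for t, s in statuses.items()]

    def test_no_pseudogenes_identity(self):
        aln = self._toy_alignment()
        calls = self._calls({t: "intact" for t in "abcd"})
        out = mask_pseudogenes({"g": aln}, calls)["g"]
        assert [r.residues for r in out.records] == \
            [r.residues for r in aln.records]

    def test_one_pseudogene_row_becomes_all_gap(self):
        aln = self._toy_alignment()
        calls = self._calls({"a": "intact", "b": "pseudogene",
                             "c": "intact", "d": "intact"})
        out = mask_pseudogenes({"g": aln}, calls)["g"]
        rows = out.rows()
        assert set(rows["b"]) == {"-"}
        assert sum(set(r) == {"-"} for r in rows.values()) == 1

    def test_masked_taxon_contributes_zero_parsimony(self):
        # taxon c carries the only variant base; masking it removes all steps
        aln = self._toy_alignment()
        ctree = compile_tree(parse_newick("((a:1,b:1):1,(c:1,d:1):1);"))
        before = fitch_steps_matrix(
            ctree, leaf_state_masks(aln.rows(), ctree)).sum()
        assert before > 0
        calls = self._calls({"a": "intact", "b": "intact",
                             "c": "pseudogene", "d": "intact"})
        out = mask_pseudogenes({"g": aln}, calls)["g"]
        after = fitch_steps_matrix(
            ctree, leaf_state_masks(out.rows(), ctree)).sum()
        assert after == 0

    def test_missing_call_raises(self):
        aln = self._toy_alignment()
        with pytest.raises(ValueError, match="no pseudogene call"):
            mask_pseudogenes({"g": aln}, self._calls({"a": "intact"}))


def test_calls_table_columns():
    call = PseudogeneCall("g", "t", "pseudogene", "frameshift", 3, 0.2)
    df = calls_table([call])
    assert list(df.columns) == ["gene", "taxon", "status", "lesion_kind",
                                "first_lesion_codon", "intact_fraction"]
    assert df.iloc[0]["first_lesion_codon"] == 3
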