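"""Group alignment, variant calling and codon-aware effects."""

import numpy as np
import pytest
from Bio.Seq import Seq

from cyanopan.evaluate import score_indels, score_snps
from cyanopan.genomeio import GeneFeature, GenomeBundle, Replicon
from cyanopan.orthologs import HomologyGroup
from cyanopan.variants import (
    align_group,
    call_variants,
    summarize,
)


def bundle_with_gene(strain, orf, strand="+"):
    pad = "TTTTTTTT"
    seq = pad + (orf if strand == "+"
                 else str(Seq(orf).reverse_complement())) + pad
    f = GeneFeature(f"{strain}_g", "chr", 9, 8 + len(orf), strand, "CDS")
    return GenomeBundle(strain, [Replicon("chr", seq)], [f])


def group_of(*strains):
    return HomologyGroup("OG1", {s: f"{s}_g" for s in strains}, "core")


def aligned_calls(variants_by_strain, strands=None):
    """Helper: build single-gene bundles and call variants."""
    strands = strands or {}
    bundles = [bundle_with_gene(s, orf, strands.get(s, "+"))
               for s, orf in variants_by_strain.items()]
    g = group_of(*variants_by_strain)
    aln = align_group(g, bundles, reference=list(variants_by_strain)[0])
    return call_variants(aln, reference=list(variants_by_strain)[0])


BASE = "ATGAAGCTGACGTTCAGGATCGATTGCGCTGGTCCAGCTTGGTGA"


class TestAlignGroup:
    def test_identical_members_zero_gap_columns(self):
        bundles = [bundle_with_gene(s, BASE) for s in "ab"]
        aln = align_group(group_of("a", "b"), bundles, reference="a")
        assert "-" not in aln.rows["a"] + aln.rows["b"]

    def test_planted_deletion_single_left_shifted_run(self):
        mutant = BASE[:12] + BASE[15:]  # 3-bp deletion
        bundles = [bundle_with_gene("a", BASE), bundle_with_gene("b", mutant)]
        aln = align_group(group_of("a", "b"), bundles, reference="a")
        row = aln.rows["b"]
        assert row.count("-") == 3
        i = row.index("-")
        assert row[i:i + 3] == "---"

    def test_single_member_trivial(self):
        bundles = [bundle_with_gene("a", BASE)]
        g = HomologyGroup("OG1", {"a": "a_g"}, "unique")
        aln = align_group(g, bundles, reference="a")
        assert aln.rows == {"a": BASE}
        assert call_variants(aln, reference="a") == []


class TestCallVariants:
    def test_all_identical_empty(self):
        calls = aligned_calls({s: BASE for s in "abcdef"})
        assert calls == []

    def test_minor_strain_snp(self):
        mut = BASE[:7] + "A" + BASE[8:]
        calls = aligned_calls({"a": BASE, "b": BASE, "c": BASE,
                               "d": BASE, "e": BASE, "f": mut})
        assert len(calls) == 1
        c = calls[0]
        assert c.var_type == "SNP"
        alleles = set(c.per_strain_allele.values())
        assert alleles == {BASE[7], "A"}
        assert [s for s, a in c.per_strain_allele.items() if a == "A"] == ["f"]

    def test_two_bp_gap_run_single_deletion(self):
        mut = BASE[:10] + BASE[12:]
        calls = aligned_calls({"a": BASE, "b": mut})
        assert len(calls) == 1
        assert calls[0].var_type == "deletion"
        assert calls[0].length == 2

    def test_snp_position_backcomputed_on_minus_strand(self):
        mut = BASE[:7] + "A" + BASE[8:]
        calls = aligned_calls({"a": BASE, "b": mut}, strands={"b": "-"})
        c = calls[0]
        # 1-based genomic position inside b's minus-strand feature
        f_end = 8 + len(BASE)
        assert c.per_strain_position["b"] == f_end - 7
        assert c.per_strain_allele["b"] == "T"  # complement of A

    def test_calls_sorted_by_reference_coordinate(self, panel_calls):
        by_group = {}
        for c in panel_calls:
            by_group.setdefault(c.group_id, []).append(
                c.per_strain_position.get("legacy1"))
        for positions in by_group.values():
            known = [p for p in positions if p is not None]
            assert known == sorted(known)


class TestClassifyEffect:
    def codon_orf(self, codon121):
        rng = np.random.default_rng(0)
        sense = [c for c in ("".join(t) for t in
                             __import__("itertools").product("ACGT", repeat=3))
                 if str(Seq(c).translate(table=11)) not in "*"]
        body = [sense[i] for i in rng.integers(0, len(sense), 130)]
        body[120] = codon121  # codon numbering is 1-based
        return "ATG" + "".join(body) + "TAA"

    def test_cga_to_caa_is_missense_r121q(self):
        ref = self.codon_orf("CGA")
        mut = ref[:3 + 120 * 3 + 1] + "A" + ref[3 + 120 * 3 + 2:]
        calls = aligned_calls({"a": ref, "b": mut})
        hit = [c for c in calls if c.effect == "missense"]
        assert len(hit) == 1
        assert hit[0].aa_change == "R122Q"  # codon 122 counting the start

    def test_third_position_gga_to_ggg_synonymous(self):
        ref = self.codon_orf("GGA")
        i = 3 + 120 * 3 + 2
        mut = ref[:i] + "G" + ref[i + 1:]
        calls = aligned_calls({"a": ref, "b": mut})
        assert [c.effect for c in calls] == ["synonymous"]

    def test_tgg_to_tga_is_nonsense(self):
        ref = self.codon_orf("TGG")
        i = 3 + 120 * 3 + 2
        mut = ref[:i] + "A" + ref[i + 1:]
        calls = aligned_calls({"a": ref, "b": mut})
        assert [c.effect for c in calls] == ["nonsense"]
        assert calls[0].aa_change.endswith("*")

    def test_two_bp_deletion_is_frameshift(self):
        ref = self.codon_orf("CGA")
        mut = ref[:30] + ref[32:]
        calls = aligned_calls({"a": ref, "b": mut})
        assert [c.effect for c in calls] == ["frameshift"]

    def test_three_bp_deletion_inframe(self):
        ref = self.codon_orf("CGA")
        mut = ref[:30] + ref[33:]
        calls = aligned_calls({"a": ref, "b": mut})
        assert [c.effect for c in calls] == ["inframe_indel"]

    def test_noncoding_gene_effect_for_trna(self):
        seq = "TTTTTTTT" + "ACGTACGTACGTACGTACGTACGTACGT" + "TTTTTTTT"
        mut_seq = seq[:12] + "C" + seq[13:]
        bundles = []
        for sid, s in (("a", seq), ("b", mut_seq)):
            f = GeneFeature(f"{sid}_g", "chr", 9, 36, "+", "tRNA")
            bundles.append(GenomeBundle(sid, [Replicon("chr", s)], [f]))
        aln = align_group(group_of("a", "b"), bundles, reference="a")
        calls = call_variants(aln, reference="a")
        assert [c.effect for c in calls] == ["noncoding_gene"]

    def test_agrees_with_whole_protein_retranslation_oracle(self):
        """Brute-force oracle: retranslate the fully mutated CDS and diff
        the proteins; the per-column classifier must agree."""
        rng = np.random.default_rng(42)
        sense = [c for c in ("".join(t) for t in
                             __import__("itertools").product("ACGT", repeat=3))
                 if str(Seq(c).translate(table=11)) != "*"]
        checked = 0
        for _ in range(250):
            ncod = int(rng.integers(20, 60))
            body = [sense[i] for i in rng.integers(0, len(sense), ncod)]
            ref = "ATG" + "".join(body) + "TAA"
            k = int(rng.integers(1, 4))
            mut = list(ref)
            for _ in range(k):
                i = int(rng.integers(3, len(ref) - 3))
                mut[i] = "ACGT"[(("ACGT".index(mut[i])) + int(rng.integers(1, 4))) % 4]
            mut = "".join(mut)
            prot_ref = str(Seq(ref).translate(table=11))
            prot_mut = str(Seq(mut).translate(table=11))
            calls = aligned_calls({"a": ref, "b": mut})
            want_any_change = prot_ref != prot_mut
            want_nonsense = "*" in prot_mut[:-1]
            effects = {c.effect for c in calls}
            assert ({"missense", "nonsense"} & effects != set()) \
                == want_any_change
            assert ("nonsense" in effects) == want_nonsense
            checked += 1
        assert checked == 250


class TestSummarize:
    def test_pct_matches_definition(self, panel_calls):
        s = summarize(panel_calls, "legacy1",
                      ["legacy1", "legacy2", "legacy3", "legacy4", "legacy5",
                       "env1"])
        cds = [c for c in panel_calls if c.var_type == "SNP"
               and c.effect in ("synonymous", "missense", "nonsense")]
        aa = [c for c in cds if c.effect != "synonymous"]
        assert s.pct_aa_changing == pytest.approx(100 * len(aa) / len(cds))
        assert s.total_snps == sum(1 for c in panel_calls
                                   if c.var_type == "SNP")

    def test_ten_cds_snps_two_changing_gives_20(self):
        ref = "ATG" + "CTG" * 40 + "TAA"  # Leu repeats
        # build 10 single-SNP strains: 2 missense, 8 synonymous
        genomes = {"ref": ref}
        for i in range(8):
            j = 3 + i * 3 + 2  # third position of a Leu codon: CTG->CTA
            genomes[f"syn{i}"] = ref[:j] + "A" + ref[j + 1:]
        for i in range(2):
            j = 3 + (20 + i) * 3 + 1  # second position: CTG->CAG (L->Q)
            genomes[f"mis{i}"] = ref[:j] + "A" + ref[j + 1:]
        calls = aligned_calls(genomes)
        s = summarize(calls, "ref", list(genomes))
        assert s.pct_aa_changing == pytest.approx(20.0)

    def test_empty_calls_zeroed(self):
        s = summarize([], "ref", ["ref", "b"])
        assert (s.total_snps, s.total_indels) == (0, 0)
        assert s.pct_aa_changing is None
        assert s.sharing_matrix.shape == (2, 0)

    def test_sharing_matrix_marks_nonreference_carriers(self):
        mut = BASE[:7] + "A" + BASE[8:]
        calls = aligned_calls({"a": BASE, "b": BASE, "c": mut})
        s = summarize(calls, "a", ["a", "b", "c"])
        col = s.sharing_matrix.iloc[:, 0]
        assert list(col) == [0, 0, 1]


class TestPanelTruthRecovery:
    def test_snp_precision_recall(self, panel_calls, panel_truth,
                                  panel_pangenome):
        pr, effect_agreement = score_snps(panel_calls, panel_truth,
                                          panel_pangenome)
        assert pr.precision >= 0.99 and pr.recall >= 0.99
        assert effect_agreement >= 0.99

    def test_indel_precision_recall(self, panel_calls, panel_truth,
                                    panel_pangenome):
        pr = score_indels(panel_calls, panel_truth, panel_pangenome)
        assert pr.precision >= 0.99 and pr.recall >= 0.99

    def test_pct_aa_changing_tracks_generator(self, panel_calls, panel_truth,
                                              panel_pangenome):
        """Carrier-level %%aa-changing converges on the realized
        generator fraction within binomial error."""
        from cyanopan.evaluate import _predicted_snp_carriers
        pred, eff = _predicted_snp_carriers(panel_calls)
        cds = [eff[k[:3]][0] for k in pred
               if eff[k[:3]][0] in ("synonymous", "missense", "nonsense")]
        frac = np.mean([e != "synonymous" for e in cds])
        truth_snps = [x for st in panel_truth.strains.values()
                      for x in st.snps
                      if x["effect"] in ("synonymous", "missense", "nonsense")]
        truth_frac = np.mean([x["effect"] != "synonymous"
                              for x in truth_snps])
        se = np.sqrt(truth_frac * (1 - truth_frac) / len(cds))
        assert abs(frac - truth_frac) <= 4 * se + 0.01
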