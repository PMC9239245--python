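"""Prophage, HIP1, inversion, plasmid and CRISPR detectors."""

import numpy as np
import pytest
from scipy import stats

from cyanopan.genomeio import GeneFeature, GenomeBundle, Replicon
from cyanopan.mobilome import (
    HIP1,
    compare_plasmids,
    detect_inversions,
    find_att_prophages,
    find_crispr_arrays,
    scan_hip1,
)
from cyanopan.synthgenomes import (
    AncestorConfig,
    BranchParams,
    ProphageSpec,
    derive_strain,
    generate_ancestor,
)


def subset(bundle, rid):
    return GenomeBundle(f"{bundle.strain_id}_{rid}",
                        [bundle.replicon(rid)],
                        [f for f in bundle.features if f.replicon_id == rid])


class TestHip1:
    def test_single_site_at_position_one(self):
        b = GenomeBundle("x", [Replicon("c", HIP1)], [])
        sites, dens = scan_hip1(b)
        assert list(sites["position"]) == [1]

    def test_overlapping_occurrences_counted(self):
        b = GenomeBundle("x", [Replicon("c", "GCGATCGCGATCGC")], [])
        sites, _ = scan_hip1(b)
        assert list(sites["position"]) == [1, 7]

    def test_background_count_matches_motif_probability(self):
        # closed form under independent bases at GC 0.5: p = (1/4)^8
        rng = np.random.default_rng(5)
        L = 400_000
        seq = "".join(rng.choice(list("ACGT"), L))
        b = GenomeBundle("x", [Replicon("c", seq)], [])
        sites, _ = scan_hip1(b)
        lam = (L - 7) * 0.25 ** 8
        lo, hi = stats.poisson.ppf([0.005, 0.995], lam)
        assert lo <= len(sites) <= hi

    def test_octamer_is_its_own_reverse_complement(self):
        from cyanopan.synthgenomes import revcomp
        assert revcomp(HIP1) == HIP1


@pytest.fixture(scope="module")
def prophage_host():
    return generate_ancestor(AncestorConfig(
        chromosome_length=60_000, n_genes=35, n_trna=3, plasmid_specs=(),
        n_unsupported_hypothetical=0, seed=21))


class TestProphage:
    def test_panel_calls_match_truth_exactly(self, panel_bundles, panel_truth):
        for b in panel_bundles:
            calls = find_att_prophages(b)
            truths = panel_truth.strains[b.strain_id].prophages
            assert len(calls) == len(truths)
            for c, t in zip(calls, truths):
                assert tuple(c.attL) == tuple(t["attL"])
                assert tuple(c.attR) == tuple(t["attR"])
                assert c.duplication_len == t["att_len"] == 60
                assert tuple(c.element_span) == tuple(t["element_span"])
                assert set(panel_truth.strains[b.strain_id].orthology[u]
                           for u in t["cargo"]) <= set(c.cargo_locus_tags)

    def test_no_insertion_no_call(self, prophage_host):
        assert find_att_prophages(prophage_host[0]) == []

    def test_duplication_below_min_att_ignored(self, prophage_host):
        anc, anct = prophage_host
        b, truth = derive_strain(anc, BranchParams(
            strain_id="d", snp_rate=0, indel_rate=0,
            prophage=ProphageSpec(0, element_length=6000, att_len=20),
            seed=2), anct)
        assert len(find_att_prophages(b, min_att=15)) == 1
        assert find_att_prophages(b, min_att=25) == []

    def test_no_trna_warns_and_returns_empty(self):
        b = GenomeBundle("x", [Replicon("c", "ACGT" * 100)], [])
        with pytest.warns(UserWarning, match="no tRNA"):
            assert find_att_prophages(b) == []

    def test_recall_one_no_false_calls_over_replicates(self):
        """Planted prophages are always found with exact boundaries and
        clean genomes never yield a call (12 seeded replicates)."""
        for seed in range(12):
            anc, anct = generate_ancestor(AncestorConfig(
                chromosome_length=40_000, n_genes=22, n_trna=2,
                plasmid_specs=(), n_unsupported_hypothetical=0, seed=100 + seed))
            assert find_att_prophages(anc) == []
            b, truth = derive_strain(anc, BranchParams(
                strain_id="d", snp_rate=0.002, indel_rate=2e-5,
                prophage=ProphageSpec(seed % 2, element_length=7000),
                seed=seed), anct)
            calls = find_att_prophages(b)
            assert len(calls) == 1
            t = truth.prophages[0]
            assert tuple(calls[0].attL) == tuple(t["attL"])
            assert tuple(calls[0].attR) == tuple(t["attR"])


class TestInversions:
    def test_panel_inversion_recovered_with_hip1_bounds(self, panel_by_id,
                                                        panel_truth):
        blocks = detect_inversions(panel_by_id["legacy1"],
                                   panel_by_id["legacy4"])
        t = panel_truth.strains["legacy4"].inversions[0]
        assert len(blocks) == 1
        b = blocks[0]
        assert abs(b.span_b[0] - t["start_point"]) <= 50
        assert abs(b.span_b[1] - t["end_point"]) <= 50
        assert b.boundary_hip1

    def test_identical_genomes_no_inversions(self, panel_by_id):
        assert detect_inversions(panel_by_id["legacy1"],
                                 panel_by_id["legacy1"]) == []

    def test_detection_symmetric(self, panel_by_id):
        fwd = detect_inversions(panel_by_id["legacy1"], panel_by_id["legacy5"])
        rev = detect_inversions(panel_by_id["legacy5"], panel_by_id["legacy1"])
        assert len(fwd) == len(rev) == 1
        assert abs(fwd[0].span_a[0] - rev[0].span_b[0]) <= 25
        assert abs(fwd[0].span_b[1] - rev[0].span_a[1]) <= 25

    def test_two_planted_inversions_two_blocks(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 60_000))
        mut = (seq[:10_000]
               + seq[10_000:18_000][::-1].translate(
                   str.maketrans("ACGT", "TGCA"))
               + seq[18_000:40_000]
               + seq[40_000:52_000][::-1].translate(
                   str.maketrans("ACGT", "TGCA"))
               + seq[52_000:])
        a = GenomeBundle("a", [Replicon("c", seq)], [])
        b = GenomeBundle("b", [Replicon("c", mut)], [])
        blocks = detect_inversions(a, b)
        spans = sorted(bl.span_a for bl in blocks)
        assert len(blocks) == 2
        assert abs(spans[0][0] - 10_001) <= 25 and abs(spans[0][1] - 18_000) <= 25
        assert abs(spans[1][0] - 40_001) <= 25 and abs(spans[1][1] - 52_000) <= 25


class TestPlasmids:
    def test_fusion_flanks_and_backbone(self, panel_by_id, panel_truth):
        cmp = compare_plasmids(subset(panel_by_id["legacy1"], "pL"),
                               subset(panel_by_id["env1"], "pMAL"))
        t = [p for p in panel_truth.strains["env1"].plasmids
             if p["kind"] == "fuse"][0]
        assert abs(cmp.shared_length - t["backbone_length"]) \
            <= 0.05 * t["backbone_length"]
        assert len(cmp.duplicated_flanks) == 1
        lo, hi = cmp.expanded_region
        t_lo, t_hi = t["expanded_span"]
        assert abs(lo - t_lo) <= 5 and abs(hi - t_hi) <= 5

    def test_identical_plasmids_full_cover_no_dup_flanks(self, panel_by_id):
        cmp = compare_plasmids(subset(panel_by_id["legacy1"], "pL"),
                               subset(panel_by_id["legacy2"], "pL"))
        pl = len(panel_by_id["legacy1"].replicon("pL"))
        assert cmp.shared_length >= 0.95 * pl
        assert cmp.duplicated_flanks == []

    def test_unrelated_plasmids_share_nothing(self, panel_by_id):
        cmp = compare_plasmids(subset(panel_by_id["legacy1"], "pS"),
                               subset(panel_by_id["env1"], "pMAS"))
        assert cmp.shared_length == 0


class TestCrispr:
    def test_panel_array_matches_truth(self, panel_by_id, panel_truth):
        calls = find_crispr_arrays(panel_by_id["env1"])
        t = panel_truth.strains["env1"].crispr[0]
        assert len(calls) == 1
        c = calls[0]
        assert c.repeat_seq == t["repeat"]
        assert c.n_repeats == t["n_repeats"]
        assert list(c.spacers) == list(t["spacers"])
        assert tuple(c.span) == tuple(t["span"])

    def test_clean_genome_empty(self, panel_by_id):
        assert find_crispr_arrays(panel_by_id["legacy1"]) == []

    def test_tandem_repeat_rejected_by_spacer_uniqueness(self):
        rng = np.random.default_rng(4)
        repeat = "".join(rng.choice(list("ACGT"), 32))
        spacer = "".join(rng.choice(list("ACGT"), 34))
        pad = "".join(rng.choice(list("ACGT"), 3000))
        arr = repeat + (spacer + repeat) * 4  # identical "spacers"
        b = GenomeBundle("x", [Replicon("c", pad + arr + pad)], [])
        assert find_crispr_arrays(b) == []

    def test_spacer_length_bounds_enforced(self):
        rng = np.random.default_rng(6)
        repeat = "".join(rng.choice(list("ACGT"), 32))
        pad = "".join(rng.choice(list("ACGT"), 3000))
        # spacers of 200 bp: far beyond 2.5 x repeat length
        arr = repeat
        for _ in range(4):
            arr += "".join(rng.choice(list("ACGT"), 200)) + repeat
        b = GenomeBundle("x", [Replicon("c", pad + arr + pad)], [])
        assert find_crispr_arrays(b) == []
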