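"""Generator contracts: determinism, planted-event statistics, and the
replay invariant (ancestor + edit script == derived genome)."""

import numpy as np
import pytest
from scipy import stats

from cyanopan.genomeio import bundles_equal
from cyanopan.synthgenomes import (
    AncestorConfig,
    BranchParams,
    ConfigError,
    ProphageSpec,
    derive_strain,
    generate_ancestor,
    make_study_panel,
    replay_events,
)

HIP1 = "GCGATCGC"


def small_config(**kw):
    base = dict(chromosome_length=40_000, n_genes=25, n_trna=2,
                plasmid_specs=(), n_unsupported_hypothetical=0, seed=5)
    base.update(kw)
    return AncestorConfig(**base)


class TestAncestor:
    def test_same_seed_byte_identical(self):
        b1, _ = generate_ancestor(small_config())
        b2, _ = generate_ancestor(small_config())
        assert bundles_equal(b1, b2)

    def test_no_genes_still_valid(self):
        b, _ = generate_ancestor(small_config(n_genes=0, n_trna=0))
        assert b.features == []
        assert len(b.replicons[0]) == 40_000

    def test_genes_are_intact_orfs(self):
        b, _ = generate_ancestor(small_config())
        from cyanopan.genomeio import extract_cds
        for _, nt, prot, flags in extract_cds(b):
            assert nt.startswith("ATG")
            assert flags["frame_intact"] and not flags["internal_stop"]

    def test_trna_lengths(self):
        b, _ = generate_ancestor(small_config())
        lens = [f.length for f in b.features if f.kind == "tRNA"]
        assert lens and all(70 <= L <= 90 for L in lens)

    def test_hip1_count_in_poisson_band(self):
        # rate 1.0/kb on a 100-kb chromosome: planted count within the
        # central 99% of Poisson(100)
        cfg = small_config(chromosome_length=100_000, hip1_rate=1.0, seed=9)
        _, truth = generate_ancestor(cfg)
        n = len(truth["hip1_planted"]["chr"])
        lo, hi = stats.poisson.ppf([0.005, 0.995], 100)
        assert lo <= n <= hi

    def test_infeasible_packing_raises(self):
        with pytest.raises(ConfigError, match="cannot pack"):
            generate_ancestor(small_config(chromosome_length=5_000, n_genes=40))


@pytest.fixture(scope="module")
def ancestor():
    return generate_ancestor(small_config(chromosome_length=100_000,
                                          n_genes=60, seed=13))


class TestDeriveStrain:

    def test_snp_count_in_binomial_band(self, ancestor):
        anc, anct = ancestor
        _, truth = derive_strain(anc, BranchParams(
            strain_id="d", snp_rate=0.01, indel_rate=0, seed=3), anct)
        n = len(truth.snps)
        L = sum(len(r) for r in anc.replicons)
        lo, hi = stats.binom.ppf([0.005, 0.995], L, 0.01)
        assert lo <= n <= hi

    def test_prophage_att_duplicated_exactly_twice(self, ancestor):
        anc, anct = ancestor
        b, truth = derive_strain(anc, BranchParams(
            strain_id="d", snp_rate=0.001, indel_rate=0,
            prophage=ProphageSpec(0, element_length=6000, att_len=60),
            seed=3), anct)
        ph = truth.prophages[0]
        seq = b.replicon(ph["replicon"]).seq
        att = seq[ph["attL"][0] - 1:ph["attL"][1]]
        assert len(att) == 60
        assert att == seq[ph["attR"][0] - 1:ph["attR"][1]]
        assert seq.count(att) == 2
        assert ph["element_length"] >= 6000

    def test_minus_strand_anchor_also_exact(self, ancestor):
        anc, anct = ancestor
        trnas = [f for f in anc.features if f.kind == "tRNA"]
        minus = next(i for i, f in enumerate(trnas) if f.strand == "-")
        b, truth = derive_strain(anc, BranchParams(
            strain_id="d", snp_rate=0.001, indel_rate=0,
            prophage=ProphageSpec(minus, element_length=6000), seed=3), anct)
        ph = truth.prophages[0]
        seq = b.replicon(ph["replicon"]).seq
        assert (seq[ph["attL"][0] - 1:ph["attL"][1]]
                == seq[ph["attR"][0] - 1:ph["attR"][1]])

    def test_anchor_index_out_of_range(self, ancestor):
        anc, anct = ancestor
        with pytest.raises(ConfigError, match="out of range"):
            derive_strain(anc, BranchParams(
                strain_id="d", prophage=ProphageSpec(99), seed=3), anct)

    def test_rate_bounds_validated(self):
        with pytest.raises(ConfigError):
            BranchParams(strain_id="d", snp_rate=0.5)

    def test_inversion_bounded_by_hip1(self, ancestor):
        anc, anct = ancestor
        from cyanopan.synthgenomes import InvertSpec
        b, truth = derive_strain(anc, BranchParams(
            strain_id="d", snp_rate=0.001, indel_rate=0,
            invert=InvertSpec(approx_length=15_000), seed=3), anct)
        inv = truth.inversions[0]
        seq = b.replicon(inv["replicon"]).seq
        s, e = inv["start_point"], inv["end_point"]
        assert seq[s - 1:s + 7] == HIP1
        assert seq[e - 8:e] == HIP1


class TestStudyPanel:
    def test_replay_reproduces_every_strain(self, panel):
        bundles, truth = panel
        cfg = {k: (tuple(tuple(x) for x in v) if k == "plasmid_specs" else v)
               for k, v in truth.ancestor["config"].items()}
        ancestor, _ = generate_ancestor(AncestorConfig(**cfg))
        for b in bundles:
            seqs = replay_events(ancestor, truth.strains[b.strain_id].events)
            assert set(seqs) == {r.id for r in b.replicons}
            for r in b.replicons:
                assert seqs[r.id] == r.seq

    def test_two_distinct_prophages_planted(self, panel_truth):
        elements = {tuple(st.prophages[0]["cargo"])
                    for st in panel_truth.strains.values() if st.prophages}
        assert len(elements) == 2  # one legacy element, one environmental

    def test_seed_changes_sequence_not_design(self):
        b1, t1 = make_study_panel(seed=3, scale=0.25)
        b2, t2 = make_study_panel(seed=4, scale=0.25)
        assert [x.strain_id for x in b1] == [x.strain_id for x in b2]
        assert b1[0].replicons[0].seq != b2[0].replicons[0].seq
        assert (sum(len(s.prophages) for s in t1.strains.values())
                == sum(len(s.prophages) for s in t2.strains.values()))

    def test_truth_json_and_tsv_export(self, panel_truth, tmp_path):
        panel_truth.to_json(tmp_path / "truth.json")
        panel_truth.events_tsv(tmp_path / "events.tsv")
        import json
        data = json.loads((tmp_path / "truth.json").read_text())
        assert set(data["strains"]) == set(panel_truth.strains)
        assert (tmp_path / "events.tsv").read_text().startswith("strain\t")

    def test_cds_snp_synonymous_bias_near_calibration(self, panel_truth):
        # generator draws CDS substitutions at 80% synonymous; joint
        # multi-hit codons push the realized aa-changing share a little
        # above 20%
        snps = [x for st in panel_truth.strains.values() for x in st.snps
                if x["effect"] in ("synonymous", "missense", "nonsense")]
        frac = np.mean([x["effect"] != "synonymous" for x in snps])
        assert 0.17 <= frac <= 0.27
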