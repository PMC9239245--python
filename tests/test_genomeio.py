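"""Genome bundle model, format round-trips and CDS extraction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyanopan.genomeio import (
    BundleError,
    Evidence,
    GeneFeature,
    GenomeBundle,
    Replicon,
    bundles_equal,
    extract_cds,
    load_bundle,
    write_bundle,
)


def make_bundle(seq="ACGT" * 30, features=(), strain="s1", topology="linear"):
    return GenomeBundle(strain, [Replicon("chr", seq, topology)], list(features))


class TestValidation:
    def test_minimal_valid_bundle(self):
        f = GeneFeature("g1", "chr", 1, 30, "+", "CDS")
        b = make_bundle(features=[f])
        assert len(b.features) == 1
        assert len(b.replicons[0]) == 120

    def test_feature_beyond_replicon_rejected(self):
        f = GeneFeature("g1", "chr", 1, 200, "+", "CDS")
        with pytest.raises(BundleError, match="beyond replicon"):
            make_bundle(seq="A" * 90, features=[f])

    def test_duplicate_locus_tag_rejected(self):
        fs = [GeneFeature("g1", "chr", 1, 9, "+", "CDS"),
              GeneFeature("g1", "chr", 20, 28, "+", "CDS")]
        with pytest.raises(BundleError, match="duplicate locus_tag"):
            make_bundle(features=fs)

    def test_start_after_end_rejected(self):
        with pytest.raises(BundleError):
            GeneFeature("g1", "chr", 30, 10, "+", "CDS")

    def test_alphabet_restricted(self):
        with pytest.raises(BundleError):
            Replicon("chr", "ACGU")

    def test_frame_flag_recorded_not_enforced(self):
        f = GeneFeature("g1", "chr", 1, 10, "+", "CDS")  # 10 bp CDS allowed
        assert not f.frame_intact


class TestRoundTrip:
    def test_write_load_identity(self, tmp_path):
        fs = [
            GeneFeature("g1", "chr", 4, 33, "+", "CDS", "thing",
                        Evidence(True, False), frozenset({"J", "X"})),
            GeneFeature("g2", "chr", 40, 110, "-", "tRNA", "tRNA-Leu",
                        Evidence(None, True)),
        ]
        b = make_bundle(features=fs, topology="circular")
        b2 = load_bundle(*write_bundle(b, tmp_path), strain_id="s1")
        assert bundles_equal(b, b2)

    def test_circular_topology_recovered(self, tmp_path):
        b = make_bundle(topology="circular")
        b2 = load_bundle(*write_bundle(b, tmp_path), strain_id="s1")
        assert b2.replicons[0].topology == "circular"

    def test_zero_feature_bundle(self, tmp_path):
        b = make_bundle()
        fasta, gff3, tsv = write_bundle(b, tmp_path)
        assert all(line.startswith("#") or "\tregion\t" in line
                   for line in open(gff3))
        assert bundles_equal(b, load_bundle(fasta, gff3, tsv, strain_id="s1"))

    def test_evidence_tsv_omitted_defaults_unknown(self, tmp_path):
        f = GeneFeature("g1", "chr", 1, 30, "+", "CDS",
                        evidence=Evidence(True, True))
        b = make_bundle(features=[f])
        fasta, gff3, _ = write_bundle(b, tmp_path)
        # strip evidence attributes from the GFF3 to emulate a bare file
        lines = [l.replace("evidence_transcribed=yes;", "")
                  .replace("evidence_essential=yes", "")
                 for l in open(gff3)]
        open(gff3, "w").writelines(lines)
        b2 = load_bundle(fasta, gff3, None, strain_id="s1")
        assert b2.features[0].evidence == Evidence(None, None)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_bundle_round_trip(self, tmp_path_factory, data):
        rng = data.draw(st.randoms(use_true_random=False))
        n = data.draw(st.integers(0, 6))
        seq = "".join(rng.choice("ACGTN") for _ in range(400))
        feats = []
        pos = 1
        for i in range(n):
            start = pos + rng.randrange(5, 15)
            end = start + rng.randrange(8, 40)
            if end > 400:
                break
            feats.append(GeneFeature(
                f"g{i}", "chr", start, end, rng.choice("+-"),
                rng.choice(["CDS", "tRNA", "ncRNA", "pseudogene"]),
                rng.choice(["", "hypothetical protein", "porin SomB"]),
                Evidence(rng.choice([True, False, None]),
                         rng.choice([True, False, None])),
                frozenset(rng.sample(["J", "X", "V", "N"],
                                     rng.randrange(0, 3)))))
            pos = end
        b = make_bundle(seq=seq, features=feats,
                        topology=rng.choice(["circular", "linear"]))
        out = tmp_path_factory.mktemp("rt")
        assert bundles_equal(b, load_bundle(*write_bundle(b, out),
                                            strain_id="s1"))


class TestExtractCds:
    def test_forward_translation(self):
        f = GeneFeature("g1", "chr", 1, 9, "+", "CDS")
        b = make_bundle(seq="ATGAAATAA" + "C" * 40, features=[f])
        (tag, nt, prot, flags), = extract_cds(b)
        assert (tag, nt, prot) == ("g1", "ATGAAATAA", "MK")
        assert flags == {"frame_intact": True, "internal_stop": False}

    def test_minus_strand_matches_plus(self):
        fwd = "ATGAAATAA"
        rc = "TTATTTCAT"
        b_plus = make_bundle(seq=fwd + "C" * 40,
                             features=[GeneFeature("g1", "chr", 1, 9, "+", "CDS")])
        b_minus = make_bundle(seq=rc + "C" * 40,
                              features=[GeneFeature("g1", "chr", 1, 9, "-", "CDS")])
        assert extract_cds(b_plus)[0][2] == extract_cds(b_minus)[0][2] == "MK"

    def test_frameshifted_cds_translates_full_codons(self):
        f = GeneFeature("g1", "chr", 1, 10, "+", "CDS")
        b = make_bundle(seq="ATGAAACCCG" + "C" * 40, features=[f])
        (_, _, prot, flags), = extract_cds(b)
        assert prot == "MKP"  # 3 full codons of the 10-bp CDS
        assert not flags["frame_intact"]

    def test_internal_stop_flagged_not_fatal(self):
        f = GeneFeature("g1", "chr", 1, 12, "+", "CDS")
        b = make_bundle(seq="ATGTAAAAATAA" + "C" * 40, features=[f])
        (_, _, prot, flags), = extract_cds(b)
        assert flags["internal_stop"]
        assert "*" in prot


class TestMismatchedInputs:
    def test_gff_unknown_replicon_named_in_error(self, tmp_path):
        b = make_bundle(features=[GeneFeature("g1", "chr", 1, 30, "+", "CDS")])
        fasta, gff3, tsv = write_bundle(b, tmp_path)
        text = open(gff3).read().replace("chr\t", "plasmidX\t")
        open(gff3, "w").write(text)
        with pytest.raises(BundleError, match="plasmidX"):
            load_bundle(fasta, gff3, tsv, strain_id="s1")
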