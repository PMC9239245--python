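"""Genome bundle model and FASTA/GFF3/TSV input-output.

A :class:`GenomeBundle` is the canonical in-memory representation of one
strain used throughout the package: an ordered set of replicon sequences
(chromosome plus plasmids) together with gene-level annotations and
optional per-gene evidence flags (transcription, essentiality) and
categorical labels (COG-like letters or free text).

External coordinates are 1-based inclusive everywhere (GFF3 convention);
any half-open arithmetic is internal and never visible in files or
reports.  The genetic code is fixed to the bacterial table 11: every
organism this package targets is a cyanobacterium.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")
VALID_KINDS = ("CDS", "tRNA", "ncRNA", "pseudogene")
GENETIC_CODE_TABLE = 11


class BundleError(ValueError):
    """Raised when a bundle or its on-disk representation is invalid."""


@dataclass(frozen=True)
class Evidence:
    """Per-gene evidence flags; ``None`` means unknown."""

    transcribed: bool | None = None
    essential: bool | None = None


@dataclass(frozen=True)
class GeneFeature:
    locus_tag: str
    replicon_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    kind: str  # CDS | tRNA | ncRNA | pseudogene
    product: str = ""
    evidence: Evidence = field(default_factory=Evidence)
    categories: frozenset = frozenset()

    def __post_init__(self):
        if self.start > self.end:
            raise BundleError(f"{self.locus_tag}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise BundleError(f"{self.locus_tag}: bad strand {self.strand!r}")
        if self.kind not in VALID_KINDS:
            raise BundleError(f"{self.locus_tag}: bad kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def frame_intact(self) -> bool:
        """True when a CDS length is divisible by 3 (not required, recorded)."""
        return self.length % 3 == 0


@dataclass(frozen=True)
class Replicon:
    id: str
    seq: str
    topology: str = "linear"  # circular | linear

    def __post_init__(self):
        if self.topology not in ("circular", "linear"):
            raise BundleError(f"{self.id}: bad topology {self.topology!r}")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise BundleError(f"{self.id}: non-ACGTN characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeBundle:
    strain_id: str
    replicons: list  # list[Replicon], ordered
    features: list  # list[GeneFeature]

    def __post_init__(self):
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        ids = [r.id for r in self.replicons]
        if len(ids) != len(set(ids)):
            raise BundleError(f"{self.strain_id}: duplicate replicon ids")
        lengths = {r.id: len(r) for r in self.replicons}
        seen = set()
        for f in self.features:
            if f.locus_tag in seen:
                raise BundleError(f"duplicate locus_tag {f.locus_tag}")
            seen.add(f.locus_tag)
            if f.replicon_id not in lengths:
                raise BundleError(
                    f"{f.locus_tag}: unknown replicon {f.replicon_id!r}"
                )
            if f.end > lengths[f.replicon_id]:
                raise BundleError(
                    f"{f.locus_tag}: end {f.end} beyond replicon "
                    f"{f.replicon_id} length {lengths[f.replicon_id]}"
                )

    # -- accessors --------------------------------------------------------
    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def feature(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)

    def features_on(self, replicon_id: str) -> list:
        return [f for f in self.features if f.replicon_id == replicon_id]

    def gene_seq(self, feature: GeneFeature | str) -> str:
        """Oriented (5'->3') nucleotide sequence of a feature."""
        if isinstance(feature, str):
            feature = self.feature(feature)
        raw = self.replicon(feature.replicon_id).seq[feature.start - 1 : feature.end]
        if feature.strand == "-":
            raw = str(Seq(raw).reverse_complement())
        return raw


# ---------------------------------------------------------------------------
# translation


def translate_cds(nt_seq: str) -> tuple[str, bool, bool]:
    """Translate an oriented CDS with the bacterial code.

    Returns ``(protein, frame_intact, internal_stop)``.  Sequences whose
    length is not a multiple of 3 are translated up to the last full codon
    and flagged.  A terminal stop is removed; a stop before the final codon
    is flagged (pseudogene-like), never fatal.
    """
    frame_intact = len(nt_seq) % 3 == 0
    trimmed = nt_seq[: len(nt_seq) - len(nt_seq) % 3]
    prot = str(Seq(trimmed).translate(table=GENETIC_CODE_TABLE))
    if prot.endswith("*"):
        prot = prot[:-1]
    internal_stop = "*" in prot
    return prot, frame_intact, internal_stop


def extract_cds(bundle: GenomeBundle) -> list:
    """All CDS features as ``(locus_tag, nt_seq, protein, flags)`` tuples.

    ``flags`` is a dict with ``frame_intact`` and ``internal_stop``.
    Minus-strand CDSs are reverse-complemented before translation.
    """
    out = []
    for f in bundle.features:
        if f.kind != "CDS":
            continue
        nt = bundle.gene_seq(f)
        prot, intact, istop = translate_cds(nt)
        out.append((f.locus_tag, nt, prot, {"frame_intact": intact, "internal_stop": istop}))
    return out


# ---------------------------------------------------------------------------
# serialisation helpers

_BOOL_OUT = {True: "yes", False: "no", None: "unknown"}
_BOOL_IN = {"yes": True, "true": True, "1": True,
            "no": False, "false": False, "0": False,
            "unknown": None, "": None, "na": None}


def _flag(value: str) -> bool | None:
    try:
        return _BOOL_IN[value.strip().lower()]
    except KeyError:
        raise BundleError(f"bad evidence flag {value!r}") from None


def _esc(text: str) -> str:
    return (
        text.replace("%", "%25").replace(";", "%3B")
        .replace("=", "%3D").replace(",", "%2C").replace("\t", "%09")
    )


def _unesc(text: str) -> str:
    return (
        text.replace("%09", "\t").replace("%2C", ",")
        .replace("%3D", "=").replace("%3B", ";").replace("%25", "%")
    )


def write_bundle(bundle: GenomeBundle, out_dir: str | os.PathLike) -> tuple:
    """Write FASTA + GFF3 + evidence TSV; returns the three paths.

    Round-trip guarantee: :func:`load_bundle` on the written files
    reconstructs an equal bundle.  Topology is carried on a ``region``
    feature per replicon (``Is_circular=true`` for circular ones, the
    GenBank/GFF3 convention).
    """
    os.makedirs(out_dir, exist_ok=True)
    base = os.path.join(str(out_dir), bundle.strain_id)
    fasta_path = base + ".fna"
    gff3_path = base + ".gff3"
    tsv_path = base + ".evidence.tsv"

    records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in bundle.replicons]
    SeqIO.write(records, fasta_path, "fasta")

    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in bundle.replicons:
            fh.write(f"##sequence-region {r.id} 1 {len(r)}\n")
        for r in bundle.replicons:
            circ = ";Is_circular=true" if r.topology == "circular" else ""
            fh.write(
                f"{r.id}\tcyanopan\tregion\t1\t{len(r)}\t.\t+\t.\t"
                f"ID=region-{r.id}{circ}\n"
            )
        for f in sorted(bundle.features, key=lambda x: (x.replicon_id, x.start, x.locus_tag)):
            attrs = [f"ID={_esc(f.locus_tag)}", f"locus_tag={_esc(f.locus_tag)}"]
            if f.product:
                attrs.append(f"product={_esc(f.product)}")
            attrs.append(f"evidence_transcribed={_BOOL_OUT[f.evidence.transcribed]}")
            attrs.append(f"evidence_essential={_BOOL_OUT[f.evidence.essential]}")
            if f.categories:
                attrs.append("category=" + "%2C".join(_esc(c) for c in sorted(f.categories)))
            fh.write(
                f"{f.replicon_id}\tcyanopan\t{f.kind}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{';'.join(attrs)}\n"
            )

    with open(tsv_path, "w") as fh:
        fh.write("locus_tag\ttranscribed\tessential\tcategories\n")
        for f in sorted(bundle.features, key=lambda x: (x.replicon_id, x.start, x.locus_tag)):
            fh.write(
                f"{f.locus_tag}\t{_BOOL_OUT[f.evidence.transcribed]}\t"
                f"{_BOOL_OUT[f.evidence.essential]}\t{','.join(sorted(f.categories))}\n"
            )
    return fasta_path, gff3_path, tsv_path


def load_bundle(
    fasta_path: str,
    gff3_path: str,
    evidence_tsv_path: str | None = None,
    strain_id: str | None = None,
) -> GenomeBundle:
    """Load a strain bundle from FASTA + GFF3 (+ optional evidence TSV).

    FASTA record ids must match the GFF3 seqid column; the evidence TSV is
    keyed by locus_tag.  Evidence missing anywhere defaults to unknown.
    Errors name the offending replicon or locus tag.
    """
    if strain_id is None:
        strain_id = os.path.splitext(os.path.basename(fasta_path))[0]
        if strain_id.endswith(".fna"):
            strain_id = strain_id[:-4]

    seqs: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        order.append(rec.id)
    if not order:
        raise BundleError(f"{fasta_path}: no FASTA records")

    db = gffutils.create_db(
        gff3_path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    topology = {rid: "linear" for rid in order}
    features: list[GeneFeature] = []
    seen_tags: set[str] = set()
    for feat in db.all_features(order_by=("seqid", "start", "end")):
        if feat.seqid not in seqs:
            raise BundleError(f"GFF3 references unknown replicon {feat.seqid!r}")
        if feat.featuretype == "region":
            circ = feat.attributes.get("Is_circular", ["false"])[0]
            if circ.lower() == "true":
                topology[feat.seqid] = "circular"
            continue
        if feat.featuretype not in VALID_KINDS:
            continue
        tag = _unesc(feat.attributes.get("locus_tag", feat.attributes.get("ID", ["?"]))[0])
        if tag in seen_tags:
            raise BundleError(f"duplicate locus_tag {tag} in {gff3_path}")
        seen_tags.add(tag)
        if feat.end > len(seqs[feat.seqid]):
            raise BundleError(
                f"{tag}: end {feat.end} beyond replicon {feat.seqid} "
                f"length {len(seqs[feat.seqid])}"
            )
        cats = feat.attributes.get("category", [])
        cats = frozenset(_unesc(c) for v in cats for c in v.split(","))
        features.append(
            GeneFeature(
                locus_tag=tag,
                replicon_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                kind=feat.featuretype,
                product=_unesc(feat.attributes.get("product", [""])[0]),
                evidence=Evidence(
                    _flag(feat.attributes.get("evidence_transcribed", ["unknown"])[0]),
                    _flag(feat.attributes.get("evidence_essential", ["unknown"])[0]),
                ),
                categories=cats,
            )
        )

    if evidence_tsv_path is not None:
        evidence = _read_evidence(evidence_tsv_path)
        features = [
            replace(
                f,
                evidence=evidence.get(f.locus_tag, (f.evidence, None))[0],
                categories=(
                    evidence[f.locus_tag][1]
                    if f.locus_tag in evidence and evidence[f.locus_tag][1] is not None
                    else f.categories
                ),
            )
            for f in features
        ]

    replicons = [Replicon(rid, seqs[rid], topology[rid]) for rid in order]
    return GenomeBundle(strain_id=strain_id, replicons=replicons, features=features)


def _read_evidence(path: str) -> dict:
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for need in ("locus_tag", "transcribed", "essential"):
            if need not in idx:
                raise BundleError(f"{path}: missing column {need!r}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            tag = parts[idx["locus_tag"]]
            ev = Evidence(_flag(parts[idx["transcribed"]]), _flag(parts[idx["essential"]]))
            cats = None
            if "categories" in idx and len(parts) > idx["categories"]:
                raw = parts[idx["categories"]].strip()
                cats = frozenset(c for c in raw.split(",") if c) if raw else frozenset()
            out[tag] = (ev, cats)
    return out


def bundles_equal(a: GenomeBundle, b: GenomeBundle) -> bool:
    """Field-for-field equality used by the round-trip guarantee."""
    if a.strain_id != b.strain_id or len(a.replicons) != len(b.replicons):
        return False
    if any((x.id, x.seq, x.topology) != (y.id, y.seq, y.topology)
           for x, y in zip(a.replicons, b.replicons)):
        return False
    key = lambda f: (f.replicon_id, f.start, f.locus_tag)  # noqa: E731
    return sorted(a.features, key=key) == sorted(b.features, key=key)
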