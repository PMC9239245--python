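"""Synthetic strain-panel generator with a machine-readable truth log.

Generates an ancestral cyanobacterium-like genome (chromosome plus
plasmids, ORF genes, tRNAs, planted HIP1 octamers, categorical gene
labels) and derives strain genomes from it by applying, in a fixed order:

    substitutions -> small indels -> inversion -> prophage insertion
    -> plasmid events (lose/gain/fuse) -> CRISPR array -> unique blocks
    -> annotation noise (start shifts, extra ncRNAs)

Every event is recorded in a :class:`TruthLog` as an ordered, replayable
edit script plus structured expectations (SNP alleles and coding effects,
prophage att coordinates, inversion breakpoints, plasmid-fusion flanks,
CRISPR repeats/spacers, and the ortholog-group membership of every gene),
so each detector in the pipeline can be scored against truth without
re-inspecting sequence.

Substitution model: within CDSs, mutations are drawn with a configurable
synonymous bias (default 80% synonymous), emulating the purifying
selection that shapes real strain panels, where only about one in five
observed SNPs changes an amino acid.  Under a uniform model roughly 70%
of random nucleotide changes would be nonsynonymous, which matches no
real bacterial panel.  Masked sites (planted HIP1 octamers) never mutate,
and indels are excluded from att and CRISPR repeats by event ordering, so
truth stays unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .genomeio import Evidence, GeneFeature, GenomeBundle, Replicon, translate_cds

HIP1 = "GCGATCGC"
_COMP = str.maketrans("ACGTN", "TGCAN")
_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"

DEFAULT_CATEGORIES = {
    # COG-like single letters; X = mobilome, V = defense, N = motility,
    # D = cell cycle -- rare in the backbone, enriched in mobile cargo.
    "J": 0.10, "C": 0.12, "E": 0.10, "G": 0.08, "M": 0.08, "K": 0.08,
    "L": 0.08, "P": 0.08, "T": 0.06, "S": 0.19, "X": 0.01, "V": 0.01,
    "N": 0.005, "D": 0.015,
}

MOBILE_CATEGORIES = {"X": 0.35, "V": 0.25, "N": 0.20, "D": 0.10, "S": 0.10}


class ConfigError(ValueError):
    pass


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class AncestorConfig:
    chromosome_length: int = 120_000
    n_genes: int = 105
    n_trna: int = 4
    gc_fraction: float = 0.55
    hip1_rate: float = 0.3  # planted octamers per kb, Poisson
    plasmid_specs: tuple = (("pL", 24_000, 18), ("pS", 8_000, 6))
    category_alphabet: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))
    n_unsupported_hypothetical: int = 6
    essential_fraction: float = 0.30
    gene_length_range: tuple = (300, 1500)
    min_gap: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.chromosome_length <= 0 or any(p[1] <= 0 for p in self.plasmid_specs):
            raise ConfigError("replicon lengths must be positive")
        if self.hip1_rate < 0:
            raise ConfigError("hip1_rate must be >= 0")


@dataclass
class ProphageSpec:
    anchor_trna_index: int
    element_length: int = 12_000
    att_len: int = 60
    n_cargo: int = 10
    cargo_categories: dict = field(default_factory=lambda: dict(MOBILE_CATEGORIES))
    element: dict | None = None  # prebuilt via build_prophage_element

    def __post_init__(self):
        if self.att_len < 15:
            raise ConfigError("att_len must be >= 15")
        if self.element_length < 5000:
            raise ConfigError("element_length must be >= 5000")


@dataclass
class InvertSpec:
    use_hip1_bounds: bool = True
    approx_length: int = 25_000


@dataclass
class CrisprSpec:
    replicon_id: str
    repeat_len: int = 32
    n_spacers: int = 6
    spacer_len: int = 34


@dataclass
class PlasmidEvent:
    kind: str  # lose | gain | fuse
    replicon_id: str | None = None  # lose/fuse target
    new_id: str | None = None  # gain/fuse product id
    length: int = 6000  # gain
    n_genes: int = 4  # gain
    expanded_length: int = 9000  # fuse
    expanded_genes: int = 8  # fuse
    duplicated_flank_pair: bool = True  # fuse
    gene_categories: dict = field(default_factory=lambda: dict(MOBILE_CATEGORIES))


@dataclass
class UniqueBlock:
    n_genes: int
    categories: dict = field(default_factory=lambda: dict(MOBILE_CATEGORIES))
    replicon_id: str | None = None  # default: first replicon


@dataclass
class BranchParams:
    strain_id: str
    snp_rate: float = 0.001
    indel_rate: float = 2e-5
    syn_bias: float = 0.8  # P(synonymous) for CDS substitutions
    indel_geom_p: float = 0.45  # lengths 1-12, geometric
    invert: InvertSpec | None = None
    prophage: ProphageSpec | None = None
    plasmid_events: tuple = ()
    crispr: CrisprSpec | None = None
    unique_blocks: tuple = ()
    start_shifts: tuple = ()  # (ancestor locus uid, n_codons) annotation-only
    add_ncrna: tuple = ()  # (replicon_id, length) annotation-only
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.snp_rate <= 0.1 and 0 <= self.indel_rate <= 0.1):
            raise ConfigError("rates must lie in [0, 0.1]")


# ---------------------------------------------------------------------------
# truth structures


@dataclass
class StrainTruth:
    strain_id: str
    events: list = field(default_factory=list)  # replayable edit script
    snps: list = field(default_factory=list)
    indels: list = field(default_factory=list)
    prophages: list = field(default_factory=list)
    inversions: list = field(default_factory=list)
    crispr: list = field(default_factory=list)
    plasmids: list = field(default_factory=list)
    annotation: list = field(default_factory=list)
    orthology: dict = field(default_factory=dict)  # uid -> locus_tag


@dataclass
class TruthLog:
    ancestor: dict = field(default_factory=dict)
    strains: dict = field(default_factory=dict)  # strain_id -> StrainTruth

    @property
    def orthology(self) -> dict:
        """uid -> {strain_id: locus_tag} across all strains."""
        out: dict[str, dict] = {}
        for sid, st in self.strains.items():
            for uid, tag in st.orthology.items():
                out.setdefault(uid, {})[sid] = tag
        return out

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, (StrainTruth,)):
                return o.__dict__
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump({"ancestor": self.ancestor, "strains": self.strains},
                      fh, default=default, indent=1)

    def events_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("strain\tevent\treplicon\tdetail\n")
            for sid, st in sorted(self.strains.items()):
                for ev in st.events:
                    detail = json.dumps({k: v for k, v in ev.items()
                                         if k not in ("op", "replicon")})
                    fh.write(f"{sid}\t{ev['op']}\t{ev.get('replicon','')}\t{detail}\n")


# ---------------------------------------------------------------------------
# ancestor generation


def _random_seq(rng, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=p)])


_SENSE_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                 if a + b + c not in _STOPS]


def _random_orf(rng, length: int) -> str:
    """ATG + sense codons + stop; length must be a multiple of 3 (>= 9)."""
    ncod = length // 3 - 2
    body = "".join(np.array(_SENSE_CODONS)[rng.integers(0, len(_SENSE_CODONS), ncod)])
    return "ATG" + body + _STOPS[rng.integers(0, 3)]


def _pack_intervals(rng, total_len: int, sizes: list, min_gap: int) -> list:
    """Non-overlapping 1-based (start, end) intervals in generated order."""
    needed = sum(sizes) + (len(sizes) + 1) * min_gap
    if needed > total_len:
        raise ConfigError(
            f"cannot pack {len(sizes)} intervals ({needed} bp) into {total_len} bp"
        )
    slack = total_len - needed
    extra = rng.multinomial(slack, np.ones(len(sizes) + 1) / (len(sizes) + 1))
    out = []
    pos = 1 + min_gap + int(extra[0])
    for size, e in zip(sizes, extra[1:]):
        out.append((pos, pos + size - 1))
        pos += size + min_gap + int(e)
    return out


def _sample_categories(rng, weights: dict, k: int = 1) -> frozenset:
    labels = sorted(weights)
    p = np.array([weights[l] for l in labels], dtype=float)
    p /= p.sum()
    return frozenset(np.array(labels)[rng.choice(len(labels), size=k, p=p)])


def _build_replicon(rng, rid, length, n_genes, n_trna, cfg, uid_prefix, counter):
    """Random replicon with packed ORFs (+ optional tRNAs). Returns
    (sequence, features, planted_hip1_positions)."""
    lo, hi = cfg.gene_length_range
    sizes = [int(rng.integers(lo // 3, hi // 3 + 1)) * 3 for _ in range(n_genes)]
    trna_sizes = [int(rng.integers(70, 91)) for _ in range(n_trna)]
    kinds = ["CDS"] * n_genes + ["tRNA"] * n_trna
    all_sizes = sizes + trna_sizes
    order = rng.permutation(len(all_sizes))
    sizes_shuffled = [all_sizes[i] for i in order]
    kinds_shuffled = [kinds[i] for i in order]
    intervals = _pack_intervals(rng, length, sizes_shuffled, cfg.min_gap)

    seq = list(_random_seq(rng, length, cfg.gc_fraction))
    features = []
    trna_i = 0
    for (start, end), kind in zip(intervals, kinds_shuffled):
        counter[0] += 1
        uid = f"{uid_prefix}{counter[0]:04d}"
        if kind == "CDS":
            strand = "+" if rng.random() < 0.5 else "-"
            orf = _random_orf(rng, end - start + 1)
            ins = orf if strand == "+" else revcomp(orf)
            product = "conserved protein"
            cats = _sample_categories(rng, cfg.category_alphabet)
        else:
            strand = "+" if trna_i % 2 == 0 else "-"
            ins = "".join(seq[start - 1:end])  # background sequence, annotated
            product = f"tRNA-{['Leu','Gly','Ser','Arg','Val','Thr'][trna_i % 6]}"
            cats = frozenset({"J"})
            trna_i += 1
        seq[start - 1:end] = list(ins)
        features.append(
            GeneFeature(uid, rid, start, end, strand, kind, product,
                        Evidence(True, bool(rng.random() < cfg.essential_fraction)),
                        cats)
        )

    # plant HIP1 octamers in intergenic gaps
    n_hip = int(rng.poisson(cfg.hip1_rate * length / 1000.0))
    occupied = [(f.start, f.end) for f in features]
    hip_positions = []
    tries = 0
    while len(hip_positions) < n_hip and tries < 50 * max(n_hip, 1):
        tries += 1
        pos = int(rng.integers(1, length - len(HIP1) + 2))  # 1-based start
        span = (pos, pos + len(HIP1) - 1)
        if any(not (span[1] < s or span[0] > e) for s, e in occupied):
            continue
        if any(abs(pos - h) < len(HIP1) for h in hip_positions):
            continue
        seq[pos - 1:pos + len(HIP1) - 1] = list(HIP1)
        hip_positions.append(pos)
    hip_positions.sort()
    return "".join(seq), features, hip_positions


def generate_ancestor(config: AncestorConfig) -> tuple:
    """Build the ancestral genome.  Deterministic given ``config.seed``.

    Genes are intact ORFs; tRNAs are 70-90 bp; HIP1 octamers are planted
    intergenically at the configured per-kb rate; every gene carries a
    category label and evidence flags.  A configurable handful of genes is
    annotated "hypothetical protein" with transcribed=no (fodder for the
    consensus module's drop rule).
    """
    rng = np.random.default_rng(config.seed)
    counter = [0]
    replicons, features, hip1 = [], [], {}
    seq, feats, hips = _build_replicon(
        rng, "chr", config.chromosome_length, config.n_genes, config.n_trna,
        config, "ANC_", counter)
    replicons.append(Replicon("chr", seq, "circular"))
    features.extend(feats)
    hip1["chr"] = hips
    for spec in config.plasmid_specs:
        rid, length, n_genes = spec
        seq, feats, hips = _build_replicon(
            rng, rid, length, n_genes, 0, config, "ANC_", counter)
        replicons.append(Replicon(rid, seq, "circular"))
        features.extend(feats)
        hip1[rid] = hips

    # plant unsupported hypotheticals among chromosome CDSs
    cds = [i for i, f in enumerate(features) if f.kind == "CDS"]
    n_unsup = min(config.n_unsupported_hypothetical, len(cds))
    unsup_idx = sorted(rng.choice(cds, size=n_unsup, replace=False).tolist())
    for i in unsup_idx:
        f = features[i]
        features[i] = GeneFeature(
            f.locus_tag, f.replicon_id, f.start, f.end, f.strand, f.kind,
            "hypothetical protein", Evidence(False, False), f.categories)

    bundle = GenomeBundle("ancestor", replicons, features)
    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.__dict__.items()
                   if k != "category_alphabet"},
        "hip1_planted": hip1,
        "unsupported_hypothetical": [features[i].locus_tag for i in unsup_idx],
        "genes": {f.locus_tag: {"replicon": f.replicon_id, "start": f.start,
                                "end": f.end, "strand": f.strand, "kind": f.kind}
                  for f in features},
    }
    return bundle, truth


# ---------------------------------------------------------------------------
# mutable derivation state


class _Pos:
    """A tracked 1-based genomic position, updated through every edit."""

    __slots__ = ("replicon", "pos", "alive", "flip")

    def __init__(self, replicon, pos):
        self.replicon = replicon
        self.pos = pos
        self.alive = True
        self.flip = False  # true when an inversion complemented this base


class _Feat:
    __slots__ = ("uid", "replicon", "start", "end", "strand", "kind",
                 "product", "evidence", "categories")

    def __init__(self, uid, replicon, start, end, strand, kind, product,
                 evidence, categories):
        self.uid = uid
        self.replicon = replicon
        self.start = start
        self.end = end
        self.strand = strand
        self.kind = kind
        self.product = product
        self.evidence = evidence
        self.categories = categories

    @classmethod
    def from_feature(cls, f: GeneFeature):
        return cls(f.locus_tag, f.replicon_id, f.start, f.end, f.strand,
                   f.kind, f.product, f.evidence, f.categories)


class _State:
    """Derivation state: sequences, features, tracked points, edit script."""

    def __init__(self, bundle: GenomeBundle):
        self.seqs = {r.id: r.seq for r in bundle.replicons}
        self.topology = {r.id: r.topology for r in bundle.replicons}
        self.order = [r.id for r in bundle.replicons]
        self.feats = [_Feat.from_feature(f) for f in bundle.features]
        self.points: list[_Pos] = []
        self.events: list[dict] = []

    def track(self, replicon: str, pos: int) -> _Pos:
        p = _Pos(replicon, pos)
        self.points.append(p)
        return p

    # -- edit operations (each records a replayable event) ----------------
    def substitute(self, rid: str, pos: int, alt: str) -> None:
        s = self.seqs[rid]
        self.seqs[rid] = s[:pos - 1] + alt + s[pos:]
        self.events.append({"op": "sub", "replicon": rid, "pos": pos, "alt": alt})

    def indel(self, rid: str, pos: int, del_len: int, ins_seq: str) -> None:
        """Delete ``del_len`` bases starting at ``pos`` or insert
        ``ins_seq`` before ``pos`` (exactly one of the two)."""
        s = self.seqs[rid]
        if del_len:
            self.seqs[rid] = s[:pos - 1] + s[pos - 1 + del_len:]
            shift = -del_len
        else:
            self.seqs[rid] = s[:pos - 1] + ins_seq + s[pos - 1:]
            shift = len(ins_seq)
        self.events.append({"op": "indel", "replicon": rid, "pos": pos,
                            "del": del_len, "ins": ins_seq})
        for f in self.feats:
            if f.replicon != rid:
                continue
            if del_len:
                if f.start >= pos + del_len:
                    f.start += shift
                    f.end += shift
                elif f.start <= pos and f.end >= pos + del_len - 1:
                    f.end += shift
            else:
                if f.start >= pos:
                    f.start += shift
                    f.end += shift
                elif f.start < pos <= f.end:
                    f.end += shift
        for p in self.points:
            if not p.alive or p.replicon != rid:
                continue
            if del_len:
                if pos <= p.pos < pos + del_len:
                    p.alive = False
                elif p.pos >= pos + del_len:
                    p.pos += shift
            elif p.pos >= pos:
                p.pos += shift

    def invert(self, rid: str, start: int, end: int) -> None:
        s = self.seqs[rid]
        self.seqs[rid] = s[:start - 1] + revcomp(s[start - 1:end]) + s[end:]
        self.events.append({"op": "invert", "replicon": rid,
                            "start": start, "end": end})
        for f in self.feats:
            if f.replicon == rid and f.start >= start and f.end <= end:
                f.start, f.end = start + end - f.end, start + end - f.start
                f.strand = "+" if f.strand == "-" else "-"
        for p in self.points:
            if p.alive and p.replicon == rid and start <= p.pos <= end:
                p.pos = start + end - p.pos
                p.flip = not p.flip

    def insert_segment(self, rid: str, after_pos: int, seq: str,
                       new_feats: list, label: str) -> None:
        """Insert ``seq`` after 1-based position ``after_pos`` (0 = front);
        ``new_feats`` carry coordinates relative to the segment (1-based)."""
        s = self.seqs[rid]
        self.seqs[rid] = s[:after_pos] + seq + s[after_pos:]
        self.events.append({"op": "insert", "replicon": rid,
                            "after_pos": after_pos, "seq": seq, "label": label})
        shift = len(seq)
        for f in self.feats:
            if f.replicon == rid and f.start > after_pos:
                f.start += shift
                f.end += shift
        for p in self.points:
            if p.alive and p.replicon == rid and p.pos > after_pos:
                p.pos += shift
        for f in new_feats:
            self.feats.append(_Feat(
                f.uid, rid, after_pos + f.start, after_pos + f.end,
                f.strand, f.kind, f.product, f.evidence, f.categories))

    def drop_replicon(self, rid: str) -> None:
        del self.seqs[rid]
        self.order.remove(rid)
        self.feats = [f for f in self.feats if f.replicon != rid]
        for p in self.points:
            if p.replicon == rid:
                p.alive = False
        self.events.append({"op": "drop_replicon", "replicon": rid})

    def add_replicon(self, rid: str, seq: str, feats: list,
                     topology: str = "circular") -> None:
        self.seqs[rid] = seq
        self.topology[rid] = topology
        self.order.append(rid)
        for f in feats:
            f.replicon = rid
            self.feats.append(f)
        self.events.append({"op": "add_replicon", "replicon": rid, "seq": seq})

    def rename_replicon(self, rid: str, new_id: str) -> None:
        self.seqs[new_id] = self.seqs.pop(rid)
        self.topology[new_id] = self.topology.pop(rid)
        self.order[self.order.index(rid)] = new_id
        for f in self.feats:
            if f.replicon == rid:
                f.replicon = new_id
        for p in self.points:
            if p.replicon == rid:
                p.replicon = new_id
        self.events.append({"op": "rename_replicon", "replicon": rid,
                            "new_id": new_id})

    # -- queries ----------------------------------------------------------
    def features_on(self, rid: str, kinds=None):
        fs = [f for f in self.feats if f.replicon == rid
              and (kinds is None or f.kind in kinds)]
        return sorted(fs, key=lambda f: f.start)

    def intergenic_gaps(self, rid: str, min_len: int,
                        forbidden: list = ()) -> list:
        """(start, end) 1-based gaps not covered by features or forbidden
        intervals, at least ``min_len`` long."""
        spans = sorted([(f.start, f.end) for f in self.features_on(rid)]
                       + [(s, e) for s, e in forbidden])
        gaps = []
        prev = 0
        for s, e in spans:
            if s - prev - 1 >= min_len:
                gaps.append((prev + 1, s - 1))
            prev = max(prev, e)
        L = len(self.seqs[rid])
        if L - prev >= min_len:
            gaps.append((prev + 1, L))
        return gaps


def replay_events(ancestor: GenomeBundle, events: list) -> dict:
    """Apply a truth-log edit script to the ancestor; returns
    ``{replicon_id: sequence}``.  The TruthLog invariant is that this
    reproduces every derived genome byte-for-byte."""
    seqs = {r.id: r.seq for r in ancestor.replicons}
    for ev in events:
        rid = ev["replicon"]
        if ev["op"] == "sub":
            s = seqs[rid]
            seqs[rid] = s[:ev["pos"] - 1] + ev["alt"] + s[ev["pos"]:]
        elif ev["op"] == "indel":
            s = seqs[rid]
            if ev["del"]:
                seqs[rid] = s[:ev["pos"] - 1] + s[ev["pos"] - 1 + ev["del"]:]
            else:
                seqs[rid] = s[:ev["pos"] - 1] + ev["ins"] + s[ev["pos"] - 1:]
        elif ev["op"] == "invert":
            s = seqs[rid]
            seqs[rid] = (s[:ev["start"] - 1]
                         + revcomp(s[ev["start"] - 1:ev["end"]]) + s[ev["end"]:])
        elif ev["op"] == "insert":
            s = seqs[rid]
            seqs[rid] = s[:ev["after_pos"]] + ev["seq"] + s[ev["after_pos"]:]
        elif ev["op"] == "drop_replicon":
            del seqs[rid]
        elif ev["op"] == "add_replicon":
            seqs[rid] = ev["seq"]
        elif ev["op"] == "rename_replicon":
            seqs[ev["new_id"]] = seqs.pop(rid)
    return seqs


# ---------------------------------------------------------------------------
# mutation drawing


def _codon_effect(ref_codon: str, mut_codon: str) -> tuple:
    ref_aa = str(Seq(ref_codon).translate(table=11))
    mut_aa = str(Seq(mut_codon).translate(table=11))
    if mut_aa == ref_aa:
        return "synonymous", None
    if mut_aa == "*":
        return "nonsense", None
    return "missense", (ref_aa, mut_aa)


def _gene_mutation_menu(gene_seq: str):
    """All (offset, alt, is_synonymous) single-base changes of a CDS,
    excluding the final stop codon."""
    syn, nonsyn = [], []
    ncod = len(gene_seq) // 3
    for ci in range(max(ncod - 1, 0)):
        codon = gene_seq[3 * ci:3 * ci + 3]
        for k in range(3):
            for alt in _BASES:
                if alt == codon[k]:
                    continue
                mut = codon[:k] + alt + codon[k + 1:]
                eff, _ = _codon_effect(codon, mut)
                (syn if eff == "synonymous" else nonsyn).append((3 * ci + k, alt))
    return syn, nonsyn


def _draw_cds_substitutions(rng, gene_seq: str, rate: float, syn_bias: float):
    """Sample substitutions for one CDS -> {offset: alt} in gene orientation."""
    n = rng.binomial(len(gene_seq), rate)
    if n == 0:
        return {}
    syn, nonsyn = _gene_mutation_menu(gene_seq)
    chosen: dict[int, str] = {}
    for _ in range(n):
        for _try in range(20):
            pool = syn if (rng.random() < syn_bias and syn) else nonsyn
            if not pool:
                pool = syn or nonsyn
            if not pool:
                break
            off, alt = pool[rng.integers(0, len(pool))]
            if off not in chosen:
                chosen[off] = alt
                break
    return chosen


# ---------------------------------------------------------------------------
# element builders


def build_prophage_element(rng, spec: ProphageSpec, uid_prefix: str,
                           gc: float = 0.55) -> dict:
    """Pre-build a prophage element (sequence + cargo gene features with
    segment-relative coordinates) so the same element can be shared by
    several strains."""
    cfg = AncestorConfig(category_alphabet=dict(spec.cargo_categories))
    n_cargo = min(spec.n_cargo, spec.element_length // 1000)
    sizes = [int(rng.integers(90, 250)) * 3 for _ in range(n_cargo)]
    intervals = _pack_intervals(rng, spec.element_length, sizes, 40)
    seq = list(_random_seq(rng, spec.element_length, gc))
    feats = []
    for i, (start, end) in enumerate(intervals):
        strand = "+" if rng.random() < 0.5 else "-"
        orf = _random_orf(rng, end - start + 1)
        seq[start - 1:end] = list(orf if strand == "+" else revcomp(orf))
        feats.append(_Feat(f"{uid_prefix}{i + 1:03d}", "", start, end, strand,
                           "CDS", "phage protein",
                           Evidence(bool(rng.random() < 0.5), False),
                           _sample_categories(rng, cfg.category_alphabet)))
    return {"seq": "".join(seq), "features": feats}


def _build_gene_segment(rng, length: int | None, n_genes: int, uid_prefix: str,
                        categories: dict, gc: float, product: str) -> dict:
    sizes = [int(rng.integers(120, 300)) * 3 for _ in range(n_genes)]
    if length is None:
        length = sum(sizes) + (n_genes + 1) * 60
    intervals = _pack_intervals(rng, length, sizes, 40)
    seq = list(_random_seq(rng, length, gc))
    feats = []
    for i, (start, end) in enumerate(intervals):
        strand = "+" if rng.random() < 0.5 else "-"
        orf = _random_orf(rng, end - start + 1)
        seq[start - 1:end] = list(orf if strand == "+" else revcomp(orf))
        feats.append(_Feat(f"{uid_prefix}{i + 1:03d}", "", start, end, strand,
                           "CDS", product, Evidence(True, False),
                           _sample_categories(rng, categories)))
    return {"seq": "".join(seq), "features": feats}


# ---------------------------------------------------------------------------
# strain derivation


def derive_strain(ancestor: GenomeBundle, params: BranchParams,
                  ancestor_truth: dict | None = None) -> tuple:
    """Apply a branch's events to the ancestor; returns
    ``(GenomeBundle, StrainTruth)``.

    Events are applied in the fixed order documented in the module
    docstring; the truth log records every event in derived-frame
    coordinates (tracked through all later edits).
    """
    rng = np.random.default_rng(params.seed)
    st = _State(ancestor)
    truth = StrainTruth(strain_id=params.strain_id)
    hip_mask = (ancestor_truth or {}).get("hip1_planted", {})
    hip_points = {rid: [st.track(rid, p) for p in pos]
                  for rid, pos in hip_mask.items()}

    _apply_substitutions(rng, st, truth, params, hip_mask)
    _apply_indels(rng, st, truth, params, hip_mask)
    if params.invert is not None:
        _apply_inversion(rng, st, truth, params, hip_points)
    if params.prophage is not None:
        _apply_prophage(rng, st, truth, params)
    for pe in params.plasmid_events:
        _apply_plasmid_event(rng, st, truth, params, pe)
    if params.crispr is not None:
        _apply_crispr(rng, st, truth, params)
    for i, ub in enumerate(params.unique_blocks):
        _apply_unique_block(rng, st, truth, params, ub, i)
    _apply_annotation_noise(st, truth, params)

    bundle, orthology = _finalise(st, params.strain_id)
    truth.orthology = orthology
    truth.events = st.events
    _resolve_points(truth)
    return bundle, truth


def _apply_substitutions(rng, st, truth, params, hip_mask):
    for rid in list(st.order):
        L = len(st.seqs[rid])
        cds = st.features_on(rid, kinds=("CDS",))
        covered = np.zeros(L + 1, dtype=bool)
        for f in cds:
            covered[f.start:f.end + 1] = True
        for pos in hip_mask.get(rid, []):
            covered[pos:pos + len(HIP1)] = True  # masked: never mutate

        # CDS substitutions with synonymous bias
        for f in cds:
            gseq = st.seqs[rid][f.start - 1:f.end]
            if f.strand == "-":
                gseq = revcomp(gseq)
            subs = _draw_cds_substitutions(rng, gseq, params.snp_rate,
                                           params.syn_bias)
            if not subs:
                continue
            # joint per-codon effect (all of this strain's changes applied)
            by_codon: dict[int, list] = {}
            for off, alt in subs.items():
                by_codon.setdefault(off // 3, []).append((off, alt))
            for ci, muts in sorted(by_codon.items()):
                ref_codon = gseq[3 * ci:3 * ci + 3]
                mut_codon = list(ref_codon)
                for off, alt in muts:
                    mut_codon[off % 3] = alt
                eff, change = _codon_effect(ref_codon, "".join(mut_codon))
                aa_change = None
                if eff == "missense":
                    aa_change = f"{change[0]}{ci + 1}{change[1]}"
                elif eff == "nonsense":
                    aa_change = (f"{str(Seq(ref_codon).translate(table=11))}"
                                 f"{ci + 1}*")
                for off, alt in muts:
                    gpos = f.start + off if f.strand == "+" else f.end - off
                    galt = alt if f.strand == "+" else alt.translate(_COMP)
                    ref = st.seqs[rid][gpos - 1]
                    st.substitute(rid, gpos, galt)
                    truth.snps.append({
                        "replicon": rid, "point": st.track(rid, gpos),
                        "ref": ref, "alt": galt, "gene": f.uid,
                        "gene_offset": off, "effect": eff,
                        "aa_change": aa_change,
                    })

        # non-CDS substitutions, uniform
        noncds = st.features_on(rid, kinds=("tRNA", "ncRNA", "pseudogene"))
        hits = np.nonzero((rng.random(L) < params.snp_rate) & ~covered[1:])[0] + 1
        for gpos in hits.tolist():
            ref = st.seqs[rid][gpos - 1]
            alt = _BASES[(_BASES.index(ref) + rng.integers(1, 4)) % 4] \
                if ref in _BASES else "A"
            host = next((f for f in noncds if f.start <= gpos <= f.end), None)
            st.substitute(rid, gpos, alt)
            truth.snps.append({
                "replicon": rid, "point": st.track(rid, gpos),
                "ref": ref, "alt": alt,
                "gene": host.uid if host else None,
                "gene_offset": (gpos - host.start if host and host.strand == "+"
                                else host.end - gpos if host else None),
                "effect": "noncoding_gene" if host else "intergenic",
                "aa_change": None,
            })


def _apply_indels(rng, st, truth, params, hip_mask):
    for rid in list(st.order):
        L = len(st.seqs[rid])
        n = rng.binomial(L, params.indel_rate)
        if n == 0:
            continue
        cds = st.features_on(rid, kinds=("CDS",))
        other = st.features_on(rid, kinds=("tRNA", "ncRNA", "pseudogene"))
        hips = [(p, p + len(HIP1) - 1) for p in hip_mask.get(rid, [])]
        chosen = []  # (ancestor-frame pos, del_len, ins_seq, host uid or None)
        for _ in range(n):
            for _try in range(100):
                length = int(min(rng.geometric(params.indel_geom_p), 12))
                is_del = rng.random() < 0.5
                pos = int(rng.integers(10, L - 14))
                span = (pos, pos + length - 1) if is_del else (pos - 1, pos)
                host = next((f for f in cds
                             if f.start + 3 <= span[0] and span[1] <= f.end - 3),
                            None)
                if host is None:
                    # must be fully intergenic: clear of all features, HIP1
                    if any(not (span[1] < f.start or span[0] > f.end)
                           for f in cds + other):
                        continue
                    if any(not (span[1] < s or span[0] > e) for s, e in hips):
                        continue
                if any(abs(pos - c[0]) <= 13 for c in chosen):
                    continue
                ins = "" if is_del else "".join(
                    np.array(list(_BASES))[rng.integers(0, 4, length)])
                chosen.append((pos, length if is_del else 0, ins,
                               host.uid if host else None))
                break
        offset = 0
        for pos, del_len, ins, host_uid in sorted(chosen):
            cur = pos + offset
            length = del_len or len(ins)
            var_type = "deletion" if del_len else "insertion"
            seq = st.seqs[rid][cur - 1:cur - 1 + del_len] if del_len else ins
            st.indel(rid, cur, del_len, ins)
            effect = None
            if host_uid is not None:
                effect = "frameshift" if length % 3 else "inframe_indel"
            truth.indels.append({
                "replicon": rid, "point": st.track(rid, cur - 1),
                "type": var_type, "length": length, "seq": seq,
                "gene": host_uid, "effect": effect,
            })
            offset += (len(ins) - del_len)


def _apply_inversion(rng, st, truth, params, hip_points):
    spec = params.invert
    rid = st.order[0]  # chromosome
    pts = [p for p in hip_points.get(rid, []) if p.alive]
    trnas = st.features_on(rid, kinds=("tRNA",))
    best = None
    for i, a in enumerate(pts):
        for b in pts[i + 1:]:
            start, end = a.pos, b.pos + len(HIP1) - 1
            if any(f.start < end and f.end > start for f in trnas):
                continue  # keep prophage anchor tRNAs outside the segment
            if any(f.start < start <= f.end or f.start <= end < f.end
                   for f in st.features_on(rid)):
                continue
            d = abs((end - start + 1) - spec.approx_length)
            if best is None or d < best[0]:
                best = (d, start, end)
    if best is None:
        raise ConfigError("no HIP1-bounded segment available for inversion")
    _, start, end = best
    st.invert(rid, start, end)
    truth.inversions.append({
        "replicon": rid,
        "start_point": st.track(rid, start), "end_point": st.track(rid, end),
        "length": end - start + 1, "boundary_hip1": spec.use_hip1_bounds,
    })


def _apply_prophage(rng, st, truth, params):
    spec = params.prophage
    rid = st.order[0]
    trnas = st.features_on(rid, kinds=("tRNA",))
    if not 0 <= spec.anchor_trna_index < len(trnas):
        raise ConfigError(
            f"anchor tRNA index {spec.anchor_trna_index} out of range "
            f"(genome has {len(trnas)} tRNAs)")
    anchor = trnas[spec.anchor_trna_index]
    element = spec.element or build_prophage_element(
        rng, spec, f"{params.strain_id}_PHG_")
    eseq = element["seq"]
    att = spec.att_len
    s = st.seqs[rid]
    if anchor.strand == "+":
        E = anchor.end
        tail = s[E - att:E]
        guard = s[E - att - 1]
        if eseq[-1] == guard:  # keep the duplication exactly att long
            eseq = eseq[:-1] + _BASES[(_BASES.index(guard) + 1) % 4]
        st.insert_segment(rid, E, eseq + tail, element["features"],
                          label=f"prophage@{anchor.uid}")
        attL = (E - att + 1, E)
        attR = (E + len(eseq) + 1, E + len(eseq) + att)
        span = (E + 1, attR[1])
    else:
        S = anchor.start
        tail = s[S - 1:S - 1 + att]
        guard = s[S - 1 + att]
        if eseq[0] == guard:
            eseq = _BASES[(_BASES.index(guard) + 1) % 4] + eseq[1:]
        st.insert_segment(rid, S - 1, tail + eseq, element["features"],
                          label=f"prophage@{anchor.uid}")
        attR = (S, S + att - 1)  # new copy, 3'-ward in gene orientation
        attL = (S + att + len(eseq), S + 2 * att + len(eseq) - 1)
        span = (attR[0], attL[0] - 1)
    truth.prophages.append({
        "replicon": rid, "anchor_trna": anchor.uid,
        "anchor_strand": anchor.strand, "att_len": att,
        "attL": (st.track(rid, attL[0]), st.track(rid, attL[1])),
        "attR": (st.track(rid, attR[0]), st.track(rid, attR[1])),
        "element_span": (st.track(rid, span[0]), st.track(rid, span[1])),
        "element_length": span[1] - span[0] + 1,
        "cargo": [f.uid for f in element["features"]],
    })


def _apply_plasmid_event(rng, st, truth, params, pe: PlasmidEvent):
    if pe.kind == "lose":
        st.drop_replicon(pe.replicon_id)
        truth.plasmids.append({"kind": "lose", "replicon": pe.replicon_id})
    elif pe.kind == "gain":
        seg = _build_gene_segment(
            rng, pe.length, pe.n_genes,
            f"{params.strain_id}_{pe.new_id}_", pe.gene_categories, 0.55,
            "plasmid protein")
        st.add_replicon(pe.new_id, seg["seq"], seg["features"])
        truth.plasmids.append({"kind": "gain", "replicon": pe.new_id,
                               "genes": [f.uid for f in seg["features"]]})
    elif pe.kind == "fuse":
        rid = pe.replicon_id
        backbone_len = len(st.seqs[rid])
        cds = st.features_on(rid, kinds=("CDS",))
        pair = None
        for a, b in zip(cds, cds[1:]):
            if b.start - a.end < 400:
                pair = (a, b)
                break
        if pair is None:
            pair = (cds[0], cds[1])
        a, b = pair
        pair_seq = st.seqs[rid][a.start - 1:b.end]
        dup_feats = []
        exp = _build_gene_segment(
            rng, pe.expanded_length, pe.expanded_genes,
            f"{params.strain_id}_FUS_", pe.gene_categories, 0.55,
            "plasmid maintenance protein")
        for j, f in enumerate((a, b)):
            dup_feats.append(_Feat(
                f"{params.strain_id}_FUSDUP_{j + 1}", "",
                pe.expanded_length + (f.start - a.start) + 1,
                pe.expanded_length + (f.end - a.start) + 1,
                f.strand, f.kind, f.product, f.evidence, f.categories))
        st.insert_segment(rid, b.end, exp["seq"] + pair_seq,
                          exp["features"] + dup_feats, label="plasmid_fusion")
        st.rename_replicon(rid, pe.new_id)
        truth.plasmids.append({
            "kind": "fuse", "replicon": pe.new_id, "source": rid,
            "backbone_length": backbone_len,
            "flank_pair": [a.uid, b.uid],
            "dup_pair": [f.uid for f in dup_feats],
            "expanded_span": (st.track(pe.new_id, b.end + 1),
                              st.track(pe.new_id, b.end + pe.expanded_length)),
            "expanded_genes": [f.uid for f in exp["features"]],
        })
    else:
        raise ConfigError(f"unknown plasmid event {pe.kind!r}")


def _apply_crispr(rng, st, truth, params):
    spec = params.crispr
    rid = spec.replicon_id if spec.replicon_id in st.seqs else st.order[-1]
    repeat = _random_seq(rng, spec.repeat_len, 0.5)
    spacers = []
    while len(spacers) < spec.n_spacers:
        sp = _random_seq(rng, spec.spacer_len, 0.5)
        if sp not in spacers:
            spacers.append(sp)
    array = repeat + "".join(sp + repeat for sp in spacers)
    # insertion needs an intergenic point, not a gap of array size
    gaps = st.intergenic_gaps(rid, 20)
    if not gaps:
        raise ConfigError(f"no intergenic point for CRISPR array on {rid}")
    g = gaps[rng.integers(0, len(gaps))]
    after = g[0] + (g[1] - g[0]) // 2
    st.insert_segment(rid, after, array, [], label="crispr_array")
    truth.crispr.append({
        "replicon": rid, "repeat": repeat, "spacers": spacers,
        "n_repeats": spec.n_spacers + 1,
        "span": (st.track(rid, after + 1), st.track(rid, after + len(array))),
    })


def _apply_unique_block(rng, st, truth, params, ub: UniqueBlock, idx: int):
    rid = ub.replicon_id or st.order[0]
    seg = _build_gene_segment(
        rng, None, ub.n_genes,
        f"{params.strain_id}_UB{idx}_", ub.categories, 0.55, "strain-specific protein")
    forbidden = [(p["element_span"][0].pos, p["element_span"][1].pos)
                 for p in truth.prophages]
    gaps = st.intergenic_gaps(rid, 30, forbidden=forbidden)
    if not gaps:
        raise ConfigError(f"no room for unique block on {rid}")
    g = gaps[rng.integers(0, len(gaps))]
    after = g[0] + (g[1] - g[0]) // 2
    st.insert_segment(rid, after, seg["seq"], seg["features"],
                      label=f"unique_block_{idx}")
    st.events[-1]["n_genes"] = ub.n_genes
    # block truth lives in orthology: its genes are strain-unique uids


def _apply_annotation_noise(st, truth, params):
    by_uid = {f.uid: f for f in st.feats}
    for uid, n_codons in params.start_shifts:
        f = by_uid.get(uid)
        if f is None or f.kind != "CDS":
            continue
        if f.strand == "+":
            f.start += 3 * n_codons
        else:
            f.end -= 3 * n_codons
        truth.annotation.append({"kind": "start_shift", "gene": uid,
                                 "codons": n_codons})
    for i, (rid, length) in enumerate(params.add_ncrna):
        if rid not in st.seqs:
            continue
        gaps = st.intergenic_gaps(rid, length + 20)
        if not gaps:
            continue
        g = gaps[len(gaps) // 2]
        start = g[0] + 5
        uid = f"{params.strain_id}_NCR{i + 1}"
        st.feats.append(_Feat(uid, rid, start, start + length - 1, "+",
                              "ncRNA", "putative small RNA",
                              Evidence(True, True), frozenset({"S"})))
        truth.annotation.append({"kind": "ncrna", "gene": uid,
                                 "replicon": rid, "start": start,
                                 "length": length})


def _finalise(st: _State, strain_id: str) -> tuple:
    feats = sorted(st.feats, key=lambda f: (st.order.index(f.replicon),
                                            f.start, f.uid))
    orthology = {}
    out_feats = []
    for i, f in enumerate(feats, 1):
        tag = f"{strain_id}_{i:04d}"
        orthology[f.uid] = tag
        out_feats.append(GeneFeature(tag, f.replicon, f.start, f.end,
                                     f.strand, f.kind, f.product,
                                     f.evidence, f.categories))
    replicons = [Replicon(rid, st.seqs[rid], st.topology[rid])
                 for rid in st.order]
    return GenomeBundle(strain_id, replicons, out_feats), orthology


def _resolve_points(truth: StrainTruth) -> None:
    """Replace tracked-point objects with plain coordinates (JSON-safe)."""

    def fix(obj):
        if isinstance(obj, _Pos):
            return obj.pos if obj.alive else None
        if isinstance(obj, tuple):
            return tuple(fix(x) for x in obj)
        if isinstance(obj, list):
            return [fix(x) for x in obj]
        if isinstance(obj, dict):
            return {k: fix(v) for k, v in obj.items()}
        return obj

    for rec in truth.snps:
        p = rec.pop("point")
        rec["pos"] = p.pos if p.alive else None
        rec["replicon"] = p.replicon
        if p.flip and rec["pos"] is not None:
            rec["ref"] = rec["ref"].translate(_COMP)
            rec["alt"] = rec["alt"].translate(_COMP)
    truth.snps = [r for r in truth.snps if r["pos"] is not None]
    for rec in truth.indels:
        p = rec.pop("point")
        rec["pos_before"] = p.pos if p.alive else None
        rec["replicon"] = p.replicon
    truth.indels = [r for r in truth.indels if r["pos_before"] is not None]
    truth.prophages = fix(truth.prophages)
    truth.inversions = fix(truth.inversions)
    truth.crispr = fix(truth.crispr)
    truth.plasmids = fix(truth.plasmids)


# ---------------------------------------------------------------------------
# the six-strain study panel


def make_study_panel(seed: int = 0, scale: float = 1.0) -> tuple:
    """Six-strain panel emulating the study design: five nearly identical
    long-domesticated "legacy" strains (pairwise divergence ~0.1%) and one
    divergent environmental isolate (~1.5%) carrying a different prophage,
    different plasmids (one a fusion with duplicated flanking genes, one
    gained with a CRISPR array) and unique gene blocks enriched in
    mobilome/defense/motility/cell-cycle categories.

    ``scale`` < 1 shrinks the genomes proportionally (used by fast tests).
    Returns ``(list of 6 GenomeBundles, TruthLog)``; strain 0 ("legacy1")
    is the conventional reference frame.
    """
    rng = np.random.default_rng(seed)
    cfg = AncestorConfig(
        chromosome_length=int(120_000 * scale),
        n_genes=max(int(105 * scale), 12),
        n_trna=4,
        plasmid_specs=(("pL", max(int(24_000 * scale), 6000),
                        max(int(18 * scale), 4)),
                       ("pS", max(int(8_000 * scale), 3000),
                        max(int(6 * scale), 2))),
        n_unsupported_hypothetical=4 if scale >= 0.5 else 2,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ancestor, anc_truth = generate_ancestor(cfg)

    legacy_element = build_prophage_element(
        rng, ProphageSpec(0, element_length=max(int(12_000 * scale), 5000),
                          n_cargo=max(int(10 * scale), 4)),
        "LPHG_")
    anc_cds = [f.locus_tag for f in ancestor.features
               if f.kind == "CDS" and f.replicon_id == "chr"
               and f.product != "hypothetical protein"]

    bundles, truth = [], TruthLog(ancestor=anc_truth)
    legacy_rate, env_rate = 0.0005, 0.0145
    for i in range(5):
        sid = f"legacy{i + 1}"
        p = BranchParams(
            strain_id=sid, snp_rate=legacy_rate, indel_rate=2e-5,
            prophage=ProphageSpec(
                0, element_length=len(legacy_element["seq"]),
                n_cargo=len(legacy_element["features"]),
                element=legacy_element),
            invert=(InvertSpec(approx_length=max(int(25_000 * scale), 4000))
                    if i >= 3 else None),
            start_shifts=(((anc_cds[3 + i], 4),) if i in (1, 2) else ()),
            add_ncrna=((("chr", 120),) if i == 0 else ()),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        b, t = derive_strain(ancestor, p, anc_truth)
        bundles.append(b)
        truth.strains[sid] = t

    env = BranchParams(
        strain_id="env1", snp_rate=env_rate, indel_rate=1e-4,
        prophage=ProphageSpec(1, element_length=max(int(18_000 * scale), 6000),
                              n_cargo=max(int(14 * scale), 5)),
        plasmid_events=(
            PlasmidEvent("lose", replicon_id="pS"),
            PlasmidEvent("fuse", replicon_id="pL", new_id="pMAL",
                         expanded_length=max(int(9_000 * scale), 3000),
                         expanded_genes=max(int(8 * scale), 3)),
            PlasmidEvent("gain", new_id="pMAS",
                         length=max(int(6_000 * scale), 3000),
                         n_genes=max(int(4 * scale), 2)),
        ),
        crispr=CrisprSpec("pMAS"),
        unique_blocks=(UniqueBlock(n_genes=max(int(30 * scale), 8)),),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    b, t = derive_strain(ancestor, env, anc_truth)
    bundles.append(b)
    truth.strains["env1"] = t
    return bundles, truth
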