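"""Pangenome construction from reciprocal-best-hit orthology.

Homology groups are formed from pairwise reciprocal best hits (RBH) on
*nucleotide* gene sequences, scored by global affine-gap alignment, then
closed under single linkage across all strain pairs.  Components in which
one strain contributes two genes are split conflict-free (best-scoring
edges kept, remaining genes re-seeded), so every input gene ends up in
exactly one group.  Groups present in all strains are ``core``, in one
strain ``unique``, otherwise ``accessory``.

A k-mer prefilter limits which gene pairs are aligned; with the default
settings it cannot change results for genes of ordinary length, because
any pair passing the 70%-identity RBH floor shares far more k-mers than
the candidate cutoff.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from . import _align
from .genomeio import GenomeBundle, translate_cds

GROUPABLE_KINDS = ("CDS", "tRNA", "ncRNA")


@dataclass
class HomologyGroup:
    group_id: str
    members: dict  # strain_id -> locus_tag (at most one per strain)
    classification: str = "unique"  # core | accessory | unique
    nt_identity_pct: float | None = None
    aa_identity_pct: float | None = None  # CDS groups only
    kind: str = "CDS"


@dataclass
class Pangenome:
    strain_ids: list
    groups: list = field(default_factory=list)

    @property
    def pangenome_size(self) -> int:
        return len(self.groups)

    @property
    def core_size(self) -> int:
        return sum(1 for g in self.groups if g.classification == "core")

    @property
    def unique_counts(self) -> dict:
        out = {s: 0 for s in self.strain_ids}
        for g in self.groups:
            if g.classification == "unique":
                out[next(iter(g.members))] += 1
        return out

    def group_of(self, strain_id: str, locus_tag: str) -> HomologyGroup:
        for g in self.groups:
            if g.members.get(strain_id) == locus_tag:
                return g
        raise KeyError((strain_id, locus_tag))

    def to_tsv(self, path) -> None:
        """One row per group, one locus-tag column per strain (the shape
        of a typical pangenome supplementary table)."""
        with open(path, "w") as fh:
            cols = ["group_id", *self.strain_ids, "kind", "classification",
                    "nt_identity_pct", "aa_identity_pct"]
            fh.write("\t".join(cols) + "\n")
            for g in self.groups:
                row = [g.group_id]
                row += [g.members.get(s, "") for s in self.strain_ids]
                row += [g.kind, g.classification,
                        "" if g.nt_identity_pct is None else f"{g.nt_identity_pct:.2f}",
                        "" if g.aa_identity_pct is None else f"{g.aa_identity_pct:.2f}"]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# reciprocal best hits


def _gene_table(bundle: GenomeBundle) -> list:
    return [(f.locus_tag, bundle.gene_seq(f), f.kind)
            for f in bundle.features if f.kind in GROUPABLE_KINDS]


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _candidates(genesA, genesB, k: int = 13, max_cand: int = 5) -> dict:
    """For each A gene, B genes ranked by shared-k-mer count (top few)."""
    index = defaultdict(set)
    for j, (_, seq, _) in enumerate(genesB):
        for km in _kmer_set(seq, k):
            index[km].add(j)
    out = {}
    for i, (_, seq, _) in enumerate(genesA):
        counts: dict[int, int] = defaultdict(int)
        for km in _kmer_set(seq, k):
            for j in index.get(km, ()):
                counts[j] += 1
        ranked = sorted(counts, key=lambda j: (-counts[j], j))[:max_cand]
        out[i] = ranked
    return out


def rbh_pairs(bundleA: GenomeBundle, bundleB: GenomeBundle,
              min_identity: float = 70.0, min_coverage: float = 0.5,
              aligner=None) -> list:
    """Reciprocal best hits between two strains.

    Returns ``(locus_tag_A, locus_tag_B, score, identity_pct)`` for every
    gene pair in which each gene is the other's highest-scoring hit, with
    identity >= ``min_identity`` over >= ``min_coverage`` of the shorter
    gene.  Ties break on the lexicographically smaller locus tag, making
    the output deterministic.
    """
    genesA = _gene_table(bundleA)
    genesB = _gene_table(bundleB)
    if not genesA or not genesB:
        return []
    if aligner is None:
        aligner = _align.nt_aligner()

    cand = _candidates(genesA, genesB)
    # alignment cache over candidate pairs (scores are symmetric)
    cell: dict[tuple, tuple] = {}
    for i, js in cand.items():
        for j in js:
            if genesA[i][2] != genesB[j][2]:
                continue  # never pair a CDS with a tRNA/ncRNA
            score, ga, gb = _align.align_pair(genesA[i][1], genesB[j][1], aligner)
            ident = _align.identity_pct(ga, gb)
            cov = _align.coverage_fraction(ga, gb)
            cell[(i, j)] = (score, ident, cov)

    def best(hits, tag_of):
        ok = [(s, tag_of(j), j) for j, s in hits]
        ok.sort(key=lambda t: (-t[0], t[1]))
        return ok[0][2] if ok else None

    bestA = {}
    for i in range(len(genesA)):
        hits = [(j, cell[(i, j)][0]) for j in cand.get(i, ()) if (i, j) in cell]
        bestA[i] = best(hits, lambda j: genesB[j][0])
    byB = defaultdict(list)
    for (i, j), (score, _, _) in cell.items():
        byB[j].append((i, score))
    bestB = {j: best(hits, lambda i: genesA[i][0]) for j, hits in byB.items()}

    pairs = []
    for i, j in bestA.items():
        if j is None or bestB.get(j) != i:
            continue
        score, ident, cov = cell[(i, j)]
        if ident >= min_identity and cov >= min_coverage:
            pairs.append((genesA[i][0], genesB[j][0], score, ident))
    pairs.sort()
    return pairs


# ---------------------------------------------------------------------------
# pangenome assembly


def build_pangenome(bundles: list, min_identity: float = 70.0,
                    min_coverage: float = 0.5,
                    compute_identities: bool = True) -> Pangenome:
    """Single-linkage closure over all pairwise RBH edges, with
    conflict-splitting so no strain contributes two genes to one group."""
    strain_ids = [b.strain_id for b in bundles]
    nodes = [(b.strain_id, f.locus_tag)
             for b in bundles for f in b.features if f.kind in GROUPABLE_KINDS]
    edges = []  # ((strainA, tagA), (strainB, tagB), score)
    for x in range(len(bundles)):
        for y in range(x + 1, len(bundles)):
            for ta, tb, score, _ in rbh_pairs(bundles[x], bundles[y],
                                              min_identity, min_coverage):
                edges.append(((strain_ids[x], ta), (strain_ids[y], tb), score))

    # union-find restricted to strain-conflict-free merges, best edges first
    parent = {n: n for n in nodes}
    members = {n: {n} for n in nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    for a, b, _ in sorted(edges, key=lambda e: (-e[2], e[0], e[1])):
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        strains_a = {s for s, _ in members[ra]}
        strains_b = {s for s, _ in members[rb]}
        if strains_a & strains_b:
            continue  # would give one strain two members: re-seed later
        parent[rb] = ra
        members[ra] |= members.pop(rb)

    kind_of = {(b.strain_id, f.locus_tag): f.kind
               for b in bundles for f in b.features}
    comps = sorted(members.values(),
                   key=lambda ms: min(ms))
    groups = []
    n_strains = len(strain_ids)
    for idx, ms in enumerate(comps, 1):
        mdict = {s: t for s, t in sorted(ms)}
        cls = ("unique" if len(mdict) == 1
               else "core" if len(mdict) == n_strains else "accessory")
        groups.append(HomologyGroup(
            group_id=f"OG{idx:05d}", members=mdict, classification=cls,
            kind=kind_of[next(iter(ms))]))

    pg = Pangenome(strain_ids=strain_ids, groups=groups)
    if compute_identities:
        compute_group_identities(pg, bundles)
    return pg


def compute_group_identities(pg: Pangenome, bundles: list) -> None:
    """Fill nt (and, for CDS groups, aa) identity of each multi-member
    group: identical columns over the trimmed group alignment."""
    by_id = {b.strain_id: b for b in bundles}
    nt_al = _align.nt_aligner()
    aa_al = _align.aa_aligner()
    for g in pg.groups:
        seqs = {s: by_id[s].gene_seq(t) for s, t in g.members.items()}
        if len(seqs) < 2:
            g.nt_identity_pct = 100.0
            g.aa_identity_pct = 100.0 if g.kind == "CDS" else None
            continue
        anchor = max(seqs, key=lambda s: (len(seqs[s]), s))
        msa = _align.anchored_msa(seqs, anchor, nt_al)
        g.nt_identity_pct = _align.column_identity_pct(list(msa.values()))
        if g.kind == "CDS":
            prots = {s: translate_cds(q)[0] for s, q in seqs.items()}
            if min(len(p) for p in prots.values()) == 0:
                g.aa_identity_pct = 0.0
            else:
                pmsa = _align.anchored_msa(prots, anchor, aa_al)
                g.aa_identity_pct = _align.column_identity_pct(
                    list(pmsa.values()), ambiguous_n=False)
        else:
            g.aa_identity_pct = None


def conserved_sets(pg: Pangenome) -> tuple:
    """(groups at exactly 100% nt identity, CDS groups at >= 95% aa
    identity) — the two high-conservation gene sets used for enrichment."""
    nt100 = {g.group_id for g in pg.groups
             if g.nt_identity_pct is not None and g.nt_identity_pct == 100.0}
    aa95 = {g.group_id for g in pg.groups
            if g.kind == "CDS" and g.aa_identity_pct is not None
            and g.aa_identity_pct >= 95.0}
    return nt100, aa95
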