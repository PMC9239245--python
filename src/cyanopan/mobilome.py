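"""Mobile-element detection.

* Prophages: integrase-mediated insertion into a tRNA duplicates the
  gene's 3' terminus, leaving identical attL/attR copies.  For each tRNA
  the maximal exact duplication of its 3'-terminal k bases (k scanned
  from ``max_att`` down to ``min_att``) is sought on the same strand
  within a window downstream of the tRNA; the largest k whose second
  copy delimits an element of at least ``min_span`` bp yields a call.
* HIP1: all occurrences of the octamer GCGATCGC (its own reverse
  complement, so one strand suffices; overlaps counted).
* Inversions: k-mers unique in both genomes are anchors; anchors chain
  into collinear blocks, and blocks whose orientation is flipped
  relative to flanking context are reported with boundary uncertainty
  equal to the inter-anchor gap.  ``boundary_hip1`` marks a HIP1 octamer
  inside the uncertainty interval at both ends.
* Plasmid comparison: anchor-chained shared blocks plus detection of a
  gene pair duplicated around an "expanded region" (plasmid-fusion
  signature).
* CRISPR arrays: exact-repeat detection seeded by k-mer multiplicity,
  validated by spacer length bounds and spacer uniqueness.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from . import _align
from .genomeio import GenomeBundle

HIP1 = "GCGATCGC"


@dataclass
class ProphageCall:
    replicon_id: str
    anchor_trna_locus: str
    attL: tuple  # (start, end) 1-based inclusive, leftmost copy in gene orientation
    attR: tuple
    duplication_len: int
    element_span: tuple  # first base after attL end .. last base of attR
    element_length: int
    cargo_locus_tags: tuple = ()


@dataclass
class InversionBlock:
    replicon_a: str
    replicon_b: str
    span_a: tuple  # (start, end) in A, 1-based inclusive, anchor-resolution
    span_b: tuple
    length: int
    boundary_uncertainty: tuple  # (left gap bp, right gap bp)
    boundary_hip1: bool


@dataclass
class PlasmidComparison:
    shared_blocks: list  # [(startA, endA, startB, endB, strand)]
    shared_length: int  # bp of A covered by shared blocks
    duplicated_flanks: list  # [((tagA1, tagA2), [(tagB1, tagB2), ...])]
    expanded_region: tuple | None  # (start, end) in B between flank copies


@dataclass
class CrisprArrayCall:
    replicon_id: str
    repeat_seq: str
    n_repeats: int
    spacers: tuple
    span: tuple


# ---------------------------------------------------------------------------
# prophages


def find_att_prophages(bundle: GenomeBundle, min_att: int = 15,
                       max_att: int = 200, window: int = 150_000,
                       min_span: int = 5000) -> list:
    """tRNA-anchored prophage calls, sorted by coordinate.

    The search runs 3'-ward of each tRNA on its own strand: rightward for
    plus-strand tRNAs, leftward for minus-strand ones (where the gene's
    3' terminus sits at the genomic start of the feature).
    """
    trnas = [f for f in bundle.features if f.kind == "tRNA"]
    if not trnas:
        warnings.warn(f"{bundle.strain_id}: no tRNA annotations; "
                      "prophage scan skipped")
        return []
    calls = []
    for t in trnas:
        seq = bundle.replicon(t.replicon_id).seq
        hit = (_scan_plus(seq, t, min_att, max_att, window, min_span)
               if t.strand == "+"
               else _scan_minus(seq, t, min_att, max_att, window, min_span))
        if hit is None:
            continue
        attL, attR, k, span = hit
        cargo = tuple(
            f.locus_tag for f in bundle.features
            if f.replicon_id == t.replicon_id
            and span[0] <= f.start and f.end <= span[1])
        calls.append(ProphageCall(
            t.replicon_id, t.locus_tag, attL, attR, k, span,
            span[1] - span[0] + 1, cargo))
    calls.sort(key=lambda c: (c.replicon_id, c.element_span[0]))
    return calls


def _scan_plus(seq, t, min_att, max_att, window, min_span):
    E = t.end  # 1-based; tail = seq[E-k:E] 0-based
    kmax = min(max_att, t.end - t.start + 1)
    for k in range(kmax, min_att - 1, -1):
        tail = seq[E - k:E]
        region = seq[E:E + window]
        start = 0
        while True:
            i = region.find(tail, start)
            if i < 0:
                break
            # second copy at 1-based E+i+1 .. E+i+k
            span = (E + 1, E + i + k)
            if span[1] - span[0] + 1 - k >= min_span:
                return (E - k + 1, E), (E + i + 1, E + i + k), k, span
            start = i + 1
    return None


def _scan_minus(seq, t, min_att, max_att, window, min_span):
    S = t.start  # tail region = seq[S-1:S-1+k] 0-based
    kmax = min(max_att, t.end - t.start + 1)
    for k in range(kmax, min_att - 1, -1):
        tail = seq[S - 1:S - 1 + k]
        lo = max(S - 1 - window, 0)
        region = seq[lo:S - 1]
        start = len(region)
        while True:
            i = region.rfind(tail, 0, start)
            if i < 0:
                break
            copy_start = lo + i + 1  # 1-based
            span = (copy_start, S - 1)
            if span[1] - span[0] + 1 - k >= min_span:
                # attL = copy inside the tRNA, attR = distal new copy
                return (S, S + k - 1), (copy_start, copy_start + k - 1), k, span
            start = i
    return None


# ---------------------------------------------------------------------------
# HIP1


def scan_hip1(bundle: GenomeBundle) -> tuple:
    """(site table, density table).  Sites are 1-based start positions;
    overlapping occurrences are counted (the octamer is palindromic, so a
    single-strand scan is complete)."""
    rows = []
    dens = []
    for r in bundle.replicons:
        positions = []
        i = r.seq.find(HIP1)
        while i >= 0:
            positions.append(i + 1)
            i = r.seq.find(HIP1, i + 1)
        rows.extend((r.id, p) for p in positions)
        dens.append((r.id, len(positions),
                     1000.0 * len(positions) / len(r) if len(r) else 0.0))
    sites = pd.DataFrame(rows, columns=["replicon", "position"])
    density = pd.DataFrame(dens, columns=["replicon", "n_sites", "per_kb"])
    return sites, density


# ---------------------------------------------------------------------------
# inversions


def _unique_kmers(seq: str, k: int) -> dict:
    counts: dict[str, int] = defaultdict(int)
    for i in range(len(seq) - k + 1):
        counts[seq[i:i + k]] += 1
    return {km: i for i, km in
            ((i, seq[i:i + k]) for i in range(len(seq) - k + 1))
            if counts[km] == 1}


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _anchors(seqA: str, seqB: str, k: int) -> list:
    """(posA, posB, strand) for k-mers unique in both genomes."""
    ua = _unique_kmers(seqA, k)
    ub = _unique_kmers(seqB, k)
    out = []
    for km, pa in ua.items():
        pb = ub.get(km)
        if pb is not None:
            out.append((pa, pb, 1))
        else:
            pb = ub.get(_revcomp(km))
            if pb is not None:
                out.append((pa, pb, -1))
    out.sort()
    return out


def _chain_blocks(anchors: list, k: int, max_gap: int = 5000) -> list:
    """Maximal collinear runs -> (startA, endA, startB, endB, strand,
    left_gap, right_gap)."""
    blocks = []
    i = 0
    n = len(anchors)
    while i < n:
        j = i
        while j + 1 < n:
            pa, pb, s = anchors[j]
            qa, qb, t = anchors[j + 1]
            if (t == s and qa - pa <= max_gap
                    and (qb - pb > 0 if s == 1 else pb - qb > 0)
                    and abs(abs(qb - pb) - (qa - pa)) <= max_gap):
                j += 1
            else:
                break
        pa0, pb0, s = anchors[i]
        pa1, pb1, _ = anchors[j]
        left_gap = anchors[i][0] - (anchors[i - 1][0] + k) if i > 0 else 0
        right_gap = (anchors[j + 1][0] - (pa1 + k)) if j + 1 < n else 0
        if s == 1:
            span_b = (pb0, pb1 + k - 1)
        else:
            span_b = (pb1, pb0 + k - 1)
        blocks.append((pa0, pa1 + k - 1, span_b[0], span_b[1], s,
                       max(left_gap, 0), max(right_gap, 0)))
        i = j + 1
    return blocks


def detect_inversions(bundleA: GenomeBundle, bundleB: GenomeBundle,
                      k: int = 21, min_len: int = 2000) -> list:
    """Inverted collinear blocks between matching replicons of two
    genomes (0-based anchor chaining; coordinates reported 1-based)."""
    out = []
    ids_b = {r.id for r in bundleB.replicons}
    for ra in bundleA.replicons:
        if ra.id not in ids_b:
            continue
        seqA = ra.seq
        seqB = bundleB.replicon(ra.id).seq
        anchors = _anchors(seqA, seqB, k)
        if len(anchors) < 10:
            warnings.warn(f"{ra.id}: too few unique k-mer anchors")
        blocks = _chain_blocks(anchors, k)
        for bstart, bend, sb, eb, strand, lg, rg in blocks:
            if strand != -1 or bend - bstart + 1 < min_len:
                continue
            span_a = (bstart + 1, bend + 1)
            hipL = HIP1 in seqA[max(bstart - lg - len(HIP1), 0):bstart + len(HIP1)]
            hipR = HIP1 in seqA[max(bend - len(HIP1) + 1, 0):bend + rg + len(HIP1)]
            out.append(InversionBlock(
                ra.id, ra.id, span_a, (sb + 1, eb + 1),
                bend - bstart + 1, (lg, rg), hipL and hipR))
    return out


# ---------------------------------------------------------------------------
# plasmid comparison


def compare_plasmids(plasmidA: GenomeBundle, plasmidB: GenomeBundle,
                     k: int = 21, min_identity: float = 70.0) -> PlasmidComparison:
    """Shared-content blocks between two single-replicon bundles plus the
    duplicated-flank signature of a plasmid fusion: a pair of adjacent
    genes in B occurring twice, both copies homologous to one adjacent
    pair in A; the inter-flank segment is the candidate expanded region."""
    if len(plasmidA.replicons) != 1 or len(plasmidB.replicons) != 1:
        raise ValueError("compare_plasmids expects single-replicon bundles")
    seqA = plasmidA.replicons[0].seq
    seqB = plasmidB.replicons[0].seq
    anchors = _anchors(seqA, seqB, k)
    blocks = [(a + 1, b + 1, c + 1, d + 1, s)
              for a, b, c, d, s, _, _ in _chain_blocks(anchors, k)
              if b - a + 1 >= 100]
    # shared content by fragment mapping (immune to duplicated regions,
    # which are not k-mer-unique and so never anchor)
    from .identity import _kmer_index, _place_fragment
    frag = 500
    index = _kmer_index(seqB, 15)
    shared = 0
    for start in range(0, len(seqA) - frag + 1, frag):
        placed = _place_fragment(seqA[start:start + frag], seqB, index, 15)
        if placed is not None and placed[0] >= 50.0 and placed[1] >= 0.7:
            shared += frag

    # homology map B gene -> best A gene (one-way best hit is enough:
    # duplicated B copies cannot both be reciprocal)
    aligner = _align.nt_aligner()
    genesA = sorted((f for f in plasmidA.features if f.kind == "CDS"),
                    key=lambda f: f.start)
    genesB = sorted((f for f in plasmidB.features if f.kind == "CDS"),
                    key=lambda f: f.start)
    best_hit = {}
    for fb in genesB:
        sb = plasmidB.gene_seq(fb)
        best = None
        for fa in genesA:
            if abs(fa.length - fb.length) > 0.5 * fa.length:
                continue
            score, ga, gb = _align.align_pair(plasmidA.gene_seq(fa), sb, aligner)
            ident = _align.identity_pct(ga, gb)
            if ident >= min_identity and (best is None or score > best[0]):
                best = (score, fa.locus_tag)
        if best:
            best_hit[fb.locus_tag] = best[1]

    pairsA = {(a.locus_tag, b.locus_tag) for a, b in zip(genesA, genesA[1:])}
    hits = defaultdict(list)
    for fb1, fb2 in zip(genesB, genesB[1:]):
        key = (best_hit.get(fb1.locus_tag), best_hit.get(fb2.locus_tag))
        if key in pairsA:
            hits[key].append((fb1, fb2))
    duplicated = []
    expanded = None
    for key, copies in sorted(hits.items()):
        if len(copies) >= 2:
            duplicated.append((key, [(x.locus_tag, y.locus_tag)
                                     for x, y in copies]))
            copies.sort(key=lambda p: p[0].start)
            first, last = copies[0], copies[-1]
            expanded = (first[1].end + 1, last[0].start - 1)
    return PlasmidComparison(blocks, shared, duplicated, expanded)


# ---------------------------------------------------------------------------
# CRISPR arrays


def find_crispr_arrays(bundle: GenomeBundle, min_repeats: int = 3,
                       min_repeat_len: int = 21, max_repeat_len: int = 50,
                       seed_k: int = 21) -> list:
    """Exact-repeat CRISPR array calls.

    Seeds are k-mers occurring >= ``min_repeats`` times with regular
    spacing; each seed set is extended to the maximal identical repeat,
    then validated: spacer lengths within [0.6, 2.5] x repeat length and
    mutually distinct (rejecting plain tandem repeats).
    """
    calls = []
    for r in bundle.replicons:
        seq = r.seq
        positions_by_kmer = defaultdict(list)
        for i in range(len(seq) - seed_k + 1):
            positions_by_kmer[seq[i:i + seed_k]].append(i)
        seen_spans = set()
        for km, pos in positions_by_kmer.items():
            if len(pos) < min_repeats:
                continue
            gaps = [b - a for a, b in zip(pos, pos[1:])]
            if not all(min_repeat_len <= g <= max_repeat_len * 3.5 for g in gaps):
                continue
            call = _extend_array(seq, pos, seed_k, min_repeats,
                                 min_repeat_len, max_repeat_len)
            if call is None:
                continue
            repeat, starts = call
            span = (starts[0] + 1, starts[-1] + len(repeat))
            if span in seen_spans:
                continue
            seen_spans.add(span)
            spacers = tuple(seq[starts[i] + len(repeat):starts[i + 1]]
                            for i in range(len(starts) - 1))
            rl = len(repeat)
            if not all(0.6 * rl <= len(sp) <= 2.5 * rl for sp in spacers):
                continue
            if len(set(spacers)) != len(spacers):
                continue  # identical "spacers": a tandem repeat, not CRISPR
            calls.append(CrisprArrayCall(r.id, repeat, len(starts),
                                         spacers, span))
    calls.sort(key=lambda c: (c.replicon_id, c.span[0]))
    return _dedupe_arrays(calls)


def _extend_array(seq, pos, k, min_repeats, min_len, max_len):
    """Extend seed occurrences to the maximal shared exact repeat."""
    left = 0
    while (pos[0] - left - 1 >= 0
           and len({seq[p - left - 1] for p in pos}) == 1
           and k + left < max_len):
        left += 1
    right = 0
    while (pos[-1] + k + right < len(seq)
           and len({seq[p + k + right] for p in pos}) == 1
           and k + left + right < max_len):
        right += 1
    length = k + left + right
    if not (min_len <= length <= max_len):
        return None
    starts = [p - left for p in pos]
    return seq[starts[0]:starts[0] + length], starts


def _dedupe_arrays(calls: list) -> list:
    """Drop calls nested inside another call's span (keep longest repeat)."""
    kept = []
    for c in sorted(calls, key=lambda c: (-c.n_repeats * len(c.repeat_seq),
                                          c.span[0])):
        if any(k.replicon_id == c.replicon_id
               and k.span[0] <= c.span[0] and c.span[1] <= k.span[1]
               for k in kept):
            continue
        kept.append(c)
    kept.sort(key=lambda c: (c.replicon_id, c.span[0]))
    return kept


# ---------------------------------------------------------------------------
# exports


def mobilome_to_tsv(prophages, inversions, crisprs, path) -> None:
    with open(path, "w") as fh:
        fh.write("call_type\treplicon\tstart\tend\tdetail\n")
        for p in prophages:
            fh.write(f"prophage\t{p.replicon_id}\t{p.element_span[0]}\t"
                     f"{p.element_span[1]}\tanchor={p.anchor_trna_locus};"
                     f"att_len={p.duplication_len};"
                     f"attL={p.attL[0]}-{p.attL[1]};attR={p.attR[0]}-{p.attR[1]}\n")
        for v in inversions:
            fh.write(f"inversion\t{v.replicon_a}\t{v.span_a[0]}\t{v.span_a[1]}\t"
                     f"length={v.length};boundary_hip1={v.boundary_hip1}\n")
        for c in crisprs:
            fh.write(f"crispr\t{c.replicon_id}\t{c.span[0]}\t{c.span[1]}\t"
                     f"repeat={c.repeat_seq};n_repeats={c.n_repeats}\n")


def mobilome_to_bed(prophages, inversions, crisprs, path) -> None:
    """BED6 (0-based half-open, per the BED standard)."""
    with open(path, "w") as fh:
        for p in prophages:
            fh.write(f"{p.replicon_id}\t{p.element_span[0] - 1}\t"
                     f"{p.element_span[1]}\tprophage_{p.anchor_trna_locus}\t0\t+\n")
        for v in inversions:
            fh.write(f"{v.replicon_a}\t{v.span_a[0] - 1}\t{v.span_a[1]}\t"
                     f"inversion\t0\t+\n")
        for c in crisprs:
            fh.write(f"{c.replicon_id}\t{c.span[0] - 1}\t{c.span[1]}\t"
                     f"crispr\t0\t+\n")


def spacers_to_fasta(crisprs, path) -> None:
    with open(path, "w") as fh:
        for ci, c in enumerate(crisprs, 1):
            for si, sp in enumerate(c.spacers, 1):
                fh.write(f">array{ci}_spacer{si} {c.replicon_id}:"
                         f"{c.span[0]}-{c.span[1]}\n{sp}\n")
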