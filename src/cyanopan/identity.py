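"""Fragment-based average nucleotide identity and RBH average amino
acid identity.

ANI follows the fragment (BLAST-style, "ANIb-like") definition: the
query is chopped into non-overlapping 1,020-bp fragments, each fragment
is placed on the subject by k-mer seeding and aligned with a banded
edit-distance alignment (full local dynamic programming as fallback when
no seed chain exists), and fragments are kept when they align at >= 30%
identity over >= 70% of their length — the published cutoffs of the
method.  One-way ANI is the mean identity of kept fragments; the
reported ANI is the mean of the two directions, which makes the
all-pairs matrix symmetric.

AAI is the mean protein identity over reciprocal-best-hit protein pairs
passing the same 30%/70% floors.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from . import _align
from .genomeio import GenomeBundle, extract_cds

FRAGMENT_LEN = 1020
MIN_FRAG_IDENTITY = 30.0  # %
MIN_FRAG_COVERAGE = 0.70


@dataclass
class ANIResult:
    pair: tuple
    ani_pct: float | None
    n_fragments_used: int
    n_fragments_total: int
    aligned_fraction: float
    no_homology: bool = False
    method: str = "fragment (ANIb-like), two-way mean"


@dataclass
class AAIResult:
    pair: tuple
    aai_pct: float | None
    n_pairs_used: int
    no_homology: bool = False
    method: str = "RBH proteins, BLOSUM62 global"


# ---------------------------------------------------------------------------


def _genome_seq(bundle: GenomeBundle) -> str:
    return "".join(r.seq for r in bundle.replicons)


def _kmer_index(seq: str, k: int) -> dict:
    idx = defaultdict(list)
    for i in range(len(seq) - k + 1):
        idx[seq[i:i + k]].append(i)
    return idx


def _local_trim_stats(qa: str, ta: str, frag_len: int) -> tuple | None:
    """Best local segment of a semi-global alignment (Kadane over
    +1 match / -2 otherwise columns) -> (identity_pct, coverage).

    This recovers BLAST-like local semantics from the edit-distance
    placement: a fragment straddling the boundary of strain-specific
    sequence aligns well only over its homologous part, so identity is
    measured there and the non-aligning remainder counts against
    coverage (N never matches).
    """
    best = cur = 0
    best_span = None
    start = 0
    for i, (x, y) in enumerate(zip(qa, ta)):
        score = 1 if (x == y and x != "-" and x != "N") else -2
        if cur <= 0:
            cur = 0
            start = i
        cur += score
        if cur > best:
            best = cur
            best_span = (start, i + 1)
    if best <= 0 or best_span is None:
        return None
    lo, hi = best_span
    matches = sum(1 for x, y in zip(qa[lo:hi], ta[lo:hi])
                  if x == y and x != "-" and x != "N")
    qbases = sum(1 for x in qa[lo:hi] if x != "-")
    return 100.0 * matches / (hi - lo), qbases / frag_len


def _place_fragment(frag: str, subject: str, index: dict, k: int) -> tuple | None:
    """Best placement of one fragment -> (identity_pct, coverage) or None."""
    # seed votes binned by diagonal
    votes: dict[int, int] = defaultdict(int)
    step = max(len(frag) // 40, 1)
    for i in range(0, len(frag) - k + 1, step):
        for j in index.get(frag[i:i + k], ()):
            votes[(j - i) // 200] += 1
    if votes:
        diag = max(sorted(votes), key=lambda d: votes[d]) * 200
        band = int(0.2 * len(frag))
        lo = max(diag - band, 0)
        hi = min(diag + len(frag) + band, len(subject))
        window = subject[lo:hi]
        res = edlib.align(frag, window, mode="HW", task="path")
        if res["editDistance"] < 0:
            return None
        nice = edlib.getNiceAlignment(res, frag, window)
        return _local_trim_stats(nice["query_aligned"],
                                 nice["target_aligned"], len(frag))
    # no seed chain: full-width edit-distance search over the whole
    # subject, trimmed to the best local segment (same statistics as the
    # seeded path; a fragment with no real homolog fails the coverage
    # floor because its best local segment is short)
    res = edlib.align(frag, subject, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    nice = edlib.getNiceAlignment(res, frag, subject)
    return _local_trim_stats(nice["query_aligned"],
                             nice["target_aligned"], len(frag))


def _one_way_ani(query: GenomeBundle, subject: GenomeBundle,
                 fragment_len: int, k: int = 15) -> tuple:
    sub = _genome_seq(subject)
    index = _kmer_index(sub, k)
    idents = []
    total = 0
    for rep in query.replicons:
        seq = rep.seq
        for start in range(0, len(seq) - fragment_len + 1, fragment_len):
            # the trailing partial fragment is discarded by construction
            total += 1
            placed = _place_fragment(seq[start:start + fragment_len], sub,
                                     index, k)
            if placed is None:
                continue
            ident, cov = placed
            if ident >= MIN_FRAG_IDENTITY and cov >= MIN_FRAG_COVERAGE:
                idents.append(ident)
    return idents, total


def compute_ani(bundleA: GenomeBundle, bundleB: GenomeBundle,
                fragment_len: int = FRAGMENT_LEN) -> ANIResult:
    """Two-way fragment ANI between two genomes.

    A genome against itself gives exactly 100.0.  When no fragment in
    either direction passes the identity/coverage filters the result is
    flagged ``no_homology`` and ``ani_pct`` is None.
    """
    if not bundleA.replicons or not bundleB.replicons:
        raise ValueError("both genomes must be non-empty")
    fwd, nf = _one_way_ani(bundleA, bundleB, fragment_len)
    rev, nr = _one_way_ani(bundleB, bundleA, fragment_len)
    used = len(fwd) + len(rev)
    if used == 0:
        return ANIResult((bundleA.strain_id, bundleB.strain_id), None, 0,
                         nf + nr, 0.0, no_homology=True)
    means = [np.mean(d) for d in (fwd, rev) if d]
    ani = float(np.mean(means))
    return ANIResult((bundleA.strain_id, bundleB.strain_id), ani, used,
                     nf + nr, used / (nf + nr) if nf + nr else 0.0)


# ---------------------------------------------------------------------------
# AAI


def _protein_table(bundle: GenomeBundle) -> list:
    table = [(tag, prot) for tag, _, prot, flags in extract_cds(bundle)
             if prot and not flags["internal_stop"]]
    if not table:
        raise ValueError(f"{bundle.strain_id}: no usable CDS for AAI")
    return table


def _best_hits(protsA, protsB, aligner, k: int = 5, max_cand: int = 5) -> dict:
    index = defaultdict(set)
    for j, (_, p) in enumerate(protsB):
        for i in range(len(p) - k + 1):
            index[p[i:i + k]].add(j)
    cells = {}
    best = {}
    for i, (_, p) in enumerate(protsA):
        counts: dict[int, int] = defaultdict(int)
        for x in range(len(p) - k + 1):
            for j in index.get(p[x:x + k], ()):
                counts[j] += 1
        ranked = sorted(counts, key=lambda j: (-counts[j], j))[:max_cand]
        scored = []
        for j in ranked:
            score, ga, gb = _align.align_pair(p, protsB[j][1], aligner)
            ident = _align.identity_pct(ga, gb, ambiguous_n=False)
            cov = _align.coverage_fraction(ga, gb)
            cells[(i, j)] = (score, ident, cov)
            scored.append((score, protsB[j][0], j))
        if scored:
            scored.sort(key=lambda t: (-t[0], t[1]))
            best[i] = scored[0][2]
    return best, cells


def compute_aai(bundleA: GenomeBundle, bundleB: GenomeBundle,
                min_identity: float = MIN_FRAG_IDENTITY,
                min_coverage: float = MIN_FRAG_COVERAGE) -> AAIResult:
    """Mean protein identity over reciprocal-best-hit pairs passing the
    30%/70% identity/coverage floors."""
    protsA = _protein_table(bundleA)
    protsB = _protein_table(bundleB)
    aligner = _align.aa_aligner()
    bestA, cells = _best_hits(protsA, protsB, aligner)
    bestB, _ = _best_hits(protsB, protsA, aligner)
    idents = []
    for i, j in bestA.items():
        if bestB.get(j) != i:
            continue
        _, ident, cov = cells[(i, j)]
        if ident >= min_identity and cov >= min_coverage:
            idents.append(ident)
    if not idents:
        return AAIResult((bundleA.strain_id, bundleB.strain_id), None, 0,
                         no_homology=True)
    return AAIResult((bundleA.strain_id, bundleB.strain_id),
                     float(np.mean(idents)), len(idents))


# ---------------------------------------------------------------------------


def identity_matrix(bundles: list, metric: str = "ani",
                    fragment_len: int = FRAGMENT_LEN) -> pd.DataFrame:
    """Symmetric all-pairs identity matrix (diagonal exactly 100)."""
    ids = [b.strain_id for b in bundles]
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i in range(len(bundles)):
        for j in range(i + 1, len(bundles)):
            if metric == "ani":
                r = compute_ani(bundles[i], bundles[j], fragment_len)
                v = r.ani_pct
            elif metric == "aai":
                r = compute_aai(bundles[i], bundles[j])
                v = r.aai_pct
            else:
                raise ValueError(f"unknown metric {metric!r}")
            v = float("nan") if v is None else v
            mat.iloc[i, j] = mat.iloc[j, i] = v
    return mat
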