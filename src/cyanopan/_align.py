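"""Shared pairwise-alignment helpers.

All affine-gap dynamic programming goes through Bio.Align.PairwiseAligner.
Default nucleotide scoring: match +2, mismatch -3, gap open -5, gap
extend -2 (a gap of length L costs 5 + 2L), close to common nucleotide
search defaults.  Identity is defined once, here: identical columns over
alignment length *including internal gap columns but excluding terminal
overhangs*; an N never counts as a match.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices


def nt_aligner(match: float = 2, mismatch: float = -3,
               gap_open: float = -5, gap_extend: float = -2,
               mode: str = "global") -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = match
    al.mismatch_score = mismatch
    # PairwiseAligner folds the first extension into the open score.
    al.open_gap_score = gap_open + gap_extend
    al.extend_gap_score = gap_extend
    return al


def aa_aligner(gap_open: float = -11, gap_extend: float = -1,
               mode: str = "global") -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = gap_open + gap_extend
    al.extend_gap_score = gap_extend
    return al


def align_pair(a: str, b: str, aligner: Align.PairwiseAligner) -> tuple:
    """Best alignment of two sequences -> (score, gapped_a, gapped_b).

    Deterministic: PairwiseAligner enumerates co-optimal alignments in a
    fixed order and the first is taken; gap runs are then left-shifted to
    their leftmost equivalent placement.
    """
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    ga, gb = canonicalize_indels(ga, gb)
    ga, gb = left_shift_gaps(ga, gb)
    return aln.score, ga, gb


def canonicalize_indels(a: str, b: str, max_sep: int = 6,
                        max_run: int = 12) -> tuple:
    """Collapse nearby complementary gap runs into substitutions.

    A dense cluster of substitutions can score better as a short
    insertion plus a short deletion (gap "slippage" recovers shifted
    matches); re-written as plain mismatch columns plus at most one net
    gap, the alignment reports the simpler event the sequences actually
    differ by.  Only opposite-row runs separated by <= ``max_sep``
    columns are merged.
    """
    while True:
        runs = []  # (row, start, end)
        for row_i, row in enumerate((a, b)):
            i = 0
            while i < len(row):
                if row[i] == "-":
                    j = i
                    while j < len(row) and row[j] == "-":
                        j += 1
                    runs.append((row_i, i, j))
                    i = j
                else:
                    i += 1
        runs.sort(key=lambda r: r[1])
        hit = None
        for r1, r2 in zip(runs, runs[1:]):
            if (r1[0] != r2[0] and r2[1] - r1[2] <= max_sep
                    and r1[2] - r1[1] <= max_run and r2[2] - r2[1] <= max_run):
                hit = (r1[1], r2[2])
                break
        if hit is None:
            return a, b
        lo, hi = hit
        sa = a[lo:hi].replace("-", "")
        sb = b[lo:hi].replace("-", "")
        pad = abs(len(sa) - len(sb))
        if len(sa) < len(sb):
            sa += "-" * pad
        else:
            sb += "-" * pad
        a = a[:lo] + sa + a[hi:]
        b = b[:lo] + sb + b[hi:]


def left_shift_gaps(a: str, b: str) -> tuple:
    """Move every gap run to its leftmost equivalent position.

    A deletion run in one row may slide left one column whenever the base
    just before the run equals the base under the run's last column (the
    classic indel left-normalisation used for variant reporting).
    """
    a = list(a)
    b = list(b)
    changed = True
    while changed:
        changed = False
        for row, other in ((a, b), (b, a)):
            i = 0
            n = len(row)
            while i < n:
                if row[i] != "-":
                    i += 1
                    continue
                j = i
                while j < n and row[j] == "-":
                    j += 1
                # gap run [i, j)
                while (i > 0 and row[i - 1] != "-" and other[i - 1] != "-"
                       and other[i - 1] == other[j - 1]):
                    row[i - 1], row[j - 1] = row[j - 1], row[i - 1]
                    other.insert(i - 1, other.pop(j - 1))
                    i -= 1
                    j -= 1
                    changed = True
                i = j
    return "".join(a), "".join(b)


def trim_bounds(rows: list) -> tuple:
    """Column range [lo, hi) excluding terminal-overhang columns.

    A terminal overhang is a run of leading/trailing columns in which some
    row is all-gap up to its first (or past its last) residue.
    """
    ncol = len(rows[0])
    lo, hi = 0, ncol
    for row in rows:
        first = next((i for i, c in enumerate(row) if c != "-"), ncol)
        last = next((i for i in range(ncol - 1, -1, -1) if row[i] != "-"), -1)
        lo = max(lo, first)
        hi = min(hi, last + 1)
    if lo >= hi:
        return 0, 0
    return lo, hi


def identity_pct(a: str, b: str, ambiguous_n: bool = True) -> float:
    """Pairwise identity over the trimmed alignment.

    With ``ambiguous_n`` (the nucleotide default) an N never counts as a
    match; protein callers disable it (N is asparagine there).
    """
    lo, hi = trim_bounds([a, b])
    if hi <= lo:
        return 0.0
    same = sum(
        1 for x, y in zip(a[lo:hi], b[lo:hi])
        if x == y and x != "-" and not (ambiguous_n and x == "N")
    )
    return 100.0 * same / (hi - lo)


def column_identity_pct(rows: list, ambiguous_n: bool = True) -> float:
    """Fraction of trimmed columns where all rows agree (gap-free)."""
    lo, hi = trim_bounds(rows)
    if hi <= lo:
        return 0.0
    same = 0
    for i in range(lo, hi):
        col = {row[i] for row in rows}
        if len(col) == 1 and "-" not in col and not (ambiguous_n and "N" in col):
            same += 1
    return 100.0 * same / (hi - lo)


def coverage_fraction(a: str, b: str) -> float:
    """Trimmed alignment span over the shorter sequence length."""
    lo, hi = trim_bounds([a, b])
    shorter = min(len(a.replace("-", "")), len(b.replace("-", "")))
    if shorter == 0:
        return 0.0
    return (hi - lo) / shorter


# ---------------------------------------------------------------------------
# anchor-based progressive multiple alignment


def anchored_msa(seqs: dict, anchor_key, aligner=None, refine: bool = True) -> dict:
    """Reference-anchored progressive multiple alignment.

    Every sequence is globally aligned to the anchor; the pairwise
    alignments are merged through anchor coordinates.  Insertions relative
    to the anchor occupy a shared left-aligned block per anchor position.
    With ``refine`` a second pass realigns every member against the
    column-majority consensus of the first pass, which places members'
    inserts consistently when the anchor itself carries a deletion
    (center-star refinement).  Near-identical inputs (the regime this
    package targets) make this equivalent to a full progressive
    alignment, and it is deterministic.

    Returns ``{key: gapped_sequence}`` with equal-length rows.
    """
    if aligner is None:
        aligner = nt_aligner()
    anchor = seqs[anchor_key]
    others = [k for k in seqs if k != anchor_key]
    if not others:
        return {anchor_key: anchor}

    # per-member: for each anchor position p (0..len), the insertion string
    # that precedes anchor base p, and the member base aligned to p ('-' ok)
    aligned_to = {}
    inserts = {}
    for k in others:
        _, ga, gb = align_pair(anchor, seqs[k], aligner)
        pos_bases = []
        ins = {0: ""}
        p = 0
        buf = ""
        for ca, cb in zip(ga, gb):
            if ca == "-":
                buf += cb
            else:
                ins[p] = buf
                buf = ""
                pos_bases.append(cb)
                p += 1
        ins[p] = buf
        aligned_to[k] = pos_bases
        inserts[k] = ins

    n = len(anchor)
    ins_len = [0] * (n + 1)
    for k in others:
        for p, s in inserts[k].items():
            ins_len[p] = max(ins_len[p], len(s))

    rows = {k: [] for k in seqs}
    for p in range(n + 1):
        if ins_len[p]:
            rows[anchor_key].append("-" * ins_len[p])
            for k in others:
                s = inserts[k].get(p, "")
                rows[k].append(s + "-" * (ins_len[p] - len(s)))
        if p < n:
            rows[anchor_key].append(anchor[p])
            for k in others:
                rows[k].append(aligned_to[k][p])
    out = {k: "".join(v) for k, v in rows.items()}
    out = _normalize_insert_blocks(out, anchor_key)
    if refine:
        cons = _column_consensus(out)
        if cons != seqs[anchor_key]:
            key = "\x00consensus"
            refined = anchored_msa({**seqs, key: cons}, key, aligner,
                                   refine=False)
            del refined[key]
            ncol = len(next(iter(refined.values())))
            keep = [i for i in range(ncol)
                    if any(row[i] != "-" for row in refined.values())]
            out = {k: "".join(v[i] for i in keep)
                   for k, v in refined.items()}
    return out


def _column_consensus(rows: dict) -> str:
    """Majority character per column (base beats gap on ties), gaps
    stripped — a proxy for the group's ancestral sequence."""
    ncol = len(next(iter(rows.values())))
    out = []
    for i in range(ncol):
        counts: dict[str, int] = {}
        for row in rows.values():
            c = row[i]
            counts[c] = counts.get(c, 0) + 1
        best = sorted(counts, key=lambda c: (-counts[c], c == "-", c))[0]
        if best != "-":
            out.append(best)
    return "".join(out)


def _normalize_insert_blocks(rows: dict, anchor_key, pad: int = 4) -> dict:
    """Re-anchor members around anchor-gap (insert) blocks.

    When the anchor itself carries a deletion, a member whose sequence
    also differs by a substitution nearby may place its extra base in a
    different insert column, which reads as a spurious insertion plus
    deletion.  Within a small window around each insert block, any
    member whose base count equals the anchor's is rewritten to sit
    exactly on the anchor's base columns; all-gap columns left behind
    are dropped.
    """
    anchor = rows[anchor_key]
    ncol = len(anchor)
    gap_cols = [i for i, c in enumerate(anchor) if c == "-"]
    if not gap_cols:
        return rows
    # merge gap columns into padded windows
    windows = []
    start = prev = gap_cols[0]
    for c in gap_cols[1:]:
        if c - prev <= 2 * pad:
            prev = c
        else:
            windows.append((max(start - pad, 0), min(prev + pad + 1, ncol)))
            start = prev = c
    windows.append((max(start - pad, 0), min(prev + pad + 1, ncol)))

    rows = {k: list(v) for k, v in rows.items()}
    for lo, hi in windows:
        anchor_slots = [i for i in range(lo, hi) if anchor[i] != "-"]
        for k, row in rows.items():
            if k == anchor_key:
                continue
            chars = [c for c in row[lo:hi] if c != "-"]
            if len(chars) != len(anchor_slots):
                continue
            for i in range(lo, hi):
                row[i] = "-"
            for c, i in zip(chars, anchor_slots):
                row[i] = c
    keep = [i for i in range(ncol)
            if any(rows[k][i] != "-" for k in rows)]
    return {k: "".join(v[i] for i in keep) for k, v in rows.items()}
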