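"""Score pipeline output against a simulation truth log.

Every detector in the pipeline has an expected output computable from
the :class:`~cyanopan.synthgenomes.TruthLog` alone; this module turns
(calls, truth) pairs into precision/recall numbers.  It is used by the
test suite and by the acceptance script, and is part of the public
surface: the whole point of the synthetic panel is that detector
performance is measurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass


@dataclass
class PR:
    n_pred: int
    n_true: int
    n_match: int

    @property
    def precision(self) -> float:
        return self.n_match / self.n_pred if self.n_pred else 1.0

    @property
    def recall(self) -> float:
        return self.n_match / self.n_true if self.n_true else 1.0


# ---------------------------------------------------------------------------


def _group_pairs(groups) -> set:
    out = set()
    for g in groups:
        ms = sorted(g)
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                out.add((ms[i], ms[j]))
    return out


def score_orthologs(pangenome, truth) -> PR:
    """Pair-level precision/recall of group membership vs truth
    orthology (a pair = two genes placed in the same group)."""
    pred = _group_pairs([set(g.members.items()) for g in pangenome.groups])
    true = _group_pairs([set(m.items()) for m in truth.orthology.values()])
    return PR(len(pred), len(true), len(pred & true))


# ---------------------------------------------------------------------------


def _predicted_snp_carriers(calls) -> tuple:
    """Per-strain SNP differences from the column-majority allele:
    {(strain, replicon, pos, genomic allele)} plus per-site effects."""
    pred = set()
    effects = {}
    for c in calls:
        if c.var_type != "SNP":
            continue
        maj = Counter(c.oriented_allele.values()).most_common(1)[0][0]
        for s, a in c.oriented_allele.items():
            if a == maj:
                continue
            key = (s, c.replicon[s], c.per_strain_position[s])
            pred.add(key + (c.per_strain_allele[s],))
            effects[key] = c.per_strain_effect.get(s, (None, None))
    return pred, effects


def _truth_snps(truth, grouped_tags) -> tuple:
    true = set()
    effects = {}
    for sid, st in truth.strains.items():
        for x in st.snps:
            if x["gene"] is None:
                continue
            tag = st.orthology.get(x["gene"])
            if (sid, tag) not in grouped_tags:
                continue
            true.add((sid, x["replicon"], x["pos"], x["alt"]))
            effects[(sid, x["replicon"], x["pos"])] = (x["effect"],
                                                       x["aa_change"])
    return true, effects


def score_snps(calls, truth, pangenome) -> tuple:
    """(PR for SNP carriers, effect-class agreement fraction).

    Truth is restricted to SNPs inside genes that belong to multi-member
    groups — the only SNPs a group-alignment caller can see.
    """
    grouped = {(s, t) for g in pangenome.groups if len(g.members) > 1
               for s, t in g.members.items()}
    pred, pred_eff = _predicted_snp_carriers(calls)
    true, true_eff = _truth_snps(truth, grouped)
    match = pred & true
    agree = tot = 0
    for k in match:
        key = k[:3]
        tot += 1
        if pred_eff.get(key, (None,))[0] == true_eff[key][0]:
            agree += 1
    return PR(len(pred), len(true), len(match)), (agree / tot if tot else 1.0)


def score_indels(calls, truth, pangenome, pos_tol: int = 10) -> PR:
    """Indel events matched by (strain, replicon, type, length) with a
    position tolerance (left-shift ambiguity in repeats)."""
    grouped = {(s, t) for g in pangenome.groups if len(g.members) > 1
               for s, t in g.members.items()}
    true = []
    for sid, st in truth.strains.items():
        for x in st.indels:
            if x["gene"] is None:
                continue
            if (sid, st.orthology.get(x["gene"])) not in grouped:
                continue
            true.append((sid, x["replicon"], x["type"], x["length"],
                         x["pos_before"]))
    pred = []
    for c in calls:
        if c.var_type == "SNP":
            continue
        maj = Counter(c.oriented_allele.values()).most_common(1)[0][0]
        maj_len = len(maj.replace("-", ""))
        for s, a in c.oriented_allele.items():
            alen = len(a.replace("-", ""))
            if alen == maj_len:
                continue
            etype = "deletion" if alen < maj_len else "insertion"
            pred.append((s, c.replicon[s], etype, abs(alen - maj_len),
                         c.per_strain_position[s]))
    used = set()
    match = 0
    for t in true:
        for i, p in enumerate(pred):
            if i in used:
                continue
            if (p[0], p[1], p[2], p[3]) == (t[0], t[1], t[2], t[3]) \
                    and abs(p[4] - t[4]) <= pos_tol:
                used.add(i)
                match += 1
                break
    return PR(len(pred), len(true), match)


# ---------------------------------------------------------------------------


def score_prophages(calls_by_strain: dict, truth) -> PR:
    """Exact-boundary prophage matching: attL, attR and duplication
    length must all equal truth."""
    n_pred = sum(len(v) for v in calls_by_strain.values())
    n_true = sum(len(st.prophages) for st in truth.strains.values())
    match = 0
    for sid, calls in calls_by_strain.items():
        st = truth.strains.get(sid)
        if st is None:
            continue
        for c in calls:
            for t in st.prophages:
                if (c.replicon_id == t["replicon"]
                        and tuple(c.attL) == tuple(t["attL"])
                        and tuple(c.attR) == tuple(t["attR"])
                        and c.duplication_len == t["att_len"]):
                    match += 1
                    break
    return PR(n_pred, n_true, match)


def score_inversions(blocks_by_strain: dict, truth, tol: int = 50) -> PR:
    """Inversion blocks matched against truth breakpoints within the
    anchor-resolution tolerance (strain-side coordinates)."""
    n_pred = sum(len(v) for v in blocks_by_strain.values())
    n_true = sum(len(st.inversions) for st in truth.strains.values())
    match = 0
    for sid, blocks in blocks_by_strain.items():
        st = truth.strains.get(sid)
        if st is None:
            continue
        for b in blocks:
            for t in st.inversions:
                if (abs(b.span_b[0] - t["start_point"]) <= tol
                        and abs(b.span_b[1] - t["end_point"]) <= tol):
                    match += 1
                    break
    return PR(n_pred, n_true, match)


def score_crispr(calls_by_strain: dict, truth) -> PR:
    """CRISPR arrays matched on repeat sequence, repeat count and the
    full ordered spacer list."""
    n_pred = sum(len(v) for v in calls_by_strain.values())
    n_true = sum(len(st.crispr) for st in truth.strains.values())
    match = 0
    for sid, calls in calls_by_strain.items():
        st = truth.strains.get(sid)
        if st is None:
            continue
        for c in calls:
            for t in st.crispr:
                if (c.repeat_seq == t["repeat"]
                        and c.n_repeats == t["n_repeats"]
                        and list(c.spacers) == list(t["spacers"])):
                    match += 1
                    break
    return PR(n_pred, n_true, match)
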