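"""Evidence-based consensus annotation of a pangenome.

Per homology group:

* ``start_adjust`` — when members' annotated 5' starts disagree (seen as
  5'-terminal overhangs in the group alignment), adopt the majority
  start; ties break toward the longest ORF (the conservative choice).
* ``drop_unsupported`` — groups annotated hypothetical or pseudogene
  whose every evidence-bearing member has transcribed=no are removed
  from the unified annotation.  A group with any essential member is
  never dropped.
* ``promote_ncRNA`` — ncRNA features annotated in at least one strain
  with transcriptional evidence (essentiality evidence strengthens the
  call) are promoted into the unified table.
* ``keep`` — everything else; groups with no evidence anywhere are kept
  with a note.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _align
from .genomeio import GenomeBundle


@dataclass
class AnnotationAdjustment:
    group_id: str
    action: str  # start_adjust | drop_unsupported | promote_ncRNA | keep
    detail: str
    affected_strains: tuple = ()


@dataclass
class UnifiedGene:
    group_id: str
    members: dict
    kind: str
    product: str
    categories: frozenset
    essential_any: bool
    transcribed_any: bool
    action: str


def reconcile(pangenome, bundles: list) -> tuple:
    """Unified annotation from per-strain annotations plus evidence.

    Returns ``(unified gene list, adjustment list)``; every group yields
    exactly one adjustment record.  Deterministic.
    """
    by_id = {b.strain_id: b for b in bundles}
    unified, adjustments = [], []
    for g in pangenome.groups:
        feats = {s: by_id[s].feature(t) for s, t in g.members.items()}
        evid = [f.evidence for f in feats.values()]
        transcribed = [e.transcribed for e in evid if e.transcribed is not None]
        essential_any = any(e.essential for e in evid)
        transcribed_any = any(transcribed)
        products = sorted({f.product for f in feats.values()})
        product = products[0] if products else ""
        kind = next(iter(feats.values())).kind
        cats = frozenset().union(*(f.categories for f in feats.values()))

        action, detail, affected = "keep", "", ()
        hypothetical = (kind == "pseudogene"
                        or any("hypothetical" in f.product.lower()
                               for f in feats.values()))
        if g.kind == "ncRNA" and len(g.members) < len(pangenome.strain_ids):
            if transcribed_any:
                action = "promote_ncRNA"
                strength = "transcribed+essential" if essential_any else "transcribed"
                detail = f"ncRNA promoted on {strength} evidence"
                affected = tuple(sorted(feats))
        elif hypothetical and transcribed and not any(transcribed) \
                and not essential_any:
            action = "drop_unsupported"
            detail = "hypothetical/pseudogene without transcriptional evidence"
            affected = tuple(sorted(feats))
        elif kind == "CDS" and len(feats) > 1:
            shift = _start_disagreement(g, feats, by_id)
            if shift:
                action = "start_adjust"
                detail, affected = shift
        if action == "keep" and not transcribed:
            detail = "no evidence"

        adjustments.append(AnnotationAdjustment(g.group_id, action, detail,
                                                affected))
        if action != "drop_unsupported":
            unified.append(UnifiedGene(g.group_id, dict(g.members), kind,
                                       product, cats, essential_any,
                                       transcribed_any, action))
    return unified, adjustments


def _start_disagreement(g, feats, by_id) -> tuple | None:
    """Majority-start rule via 5' overhangs in the group alignment."""
    seqs = {s: by_id[s].gene_seq(f) for s, f in feats.items()}
    anchor = max(seqs, key=lambda s: (len(seqs[s]), s))
    msa = _align.anchored_msa(seqs, anchor, _align.nt_aligner())
    # leading overhang of each member relative to the longest member
    lead = {}
    for s, row in msa.items():
        first = next((i for i, c in enumerate(row) if c != "-"), len(row))
        lead[s] = first
    values = sorted(lead.values())
    if len(set(values)) == 1:
        return None
    counts: dict[int, int] = {}
    for v in lead.values():
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    # tie toward the longest ORF = the smallest leading overhang
    majority = min(v for v, c in counts.items() if c == best)
    moved = tuple(sorted(s for s, v in lead.items() if v != majority))
    delta = {s: lead[s] - majority for s in moved}
    parts = ", ".join(f"{s}: start moved {-d:+d} nt to majority start"
                      for s, d in delta.items())
    return parts, moved


def export_pangenome_table(unified: list, adjustments: list,
                           strain_ids: list, path) -> None:
    """One row per unified pangenome gene; stable sort => re-export is
    byte-identical."""
    act = {a.group_id: a for a in adjustments}
    with open(path, "w") as fh:
        cols = ["group_id", *strain_ids, "kind", "product", "categories",
                "essential_any", "transcribed_any", "action"]
        fh.write("\t".join(cols) + "\n")
        for u in sorted(unified, key=lambda u: u.group_id):
            row = [u.group_id]
            row += [u.members.get(s, "") for s in strain_ids]
            row += [u.kind, u.product, ",".join(sorted(u.categories)),
                    str(int(u.essential_any)), str(int(u.transcribed_any)),
                    act[u.group_id].action]
            fh.write("\t".join(row) + "\n")


def export_reference_gff3(unified: list, reference: str, bundle, path) -> None:
    """Unified annotation projected onto a designated reference strain."""
    feats = {f.locus_tag: f for f in bundle.features}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in bundle.replicons:
            fh.write(f"##sequence-region {r.id} 1 {len(r)}\n")
        rows = []
        for u in unified:
            tag = u.members.get(reference)
            if tag is None or tag not in feats:
                continue
            f = feats[tag]
            rows.append((f.replicon_id, f.start, f.end, f.strand, f.kind,
                         tag, u.group_id, u.product))
        for rep, start, end, strand, kind, tag, gid, product in sorted(rows):
            fh.write(f"{rep}\tcyanopan\t{kind}\t{start}\t{end}\t.\t{strand}\t.\t"
                     f"ID={tag};locus_tag={tag};pangenome_group={gid};"
                     f"product={product}\n")
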