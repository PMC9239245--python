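"""SNP/indel calling within homology groups and codon-aware effects.

Each multi-member group is multiple-aligned (reference-anchored
progressive alignment, gaps left-shifted); polymorphic gap-free columns
become SNP calls and contiguous gap runs become single merged indel
calls.  Effects are classified against a designated reference strain's
reading frame: the full mutated codon is rebuilt from the member's
aligned bases (so two SNPs in one codon are judged jointly), indels in a
CDS are frameshift when their length is not a multiple of three, and
calls in tRNA/ncRNA/pseudogene members are ``noncoding_gene``.

Multi-allelic columns are emitted as one call with per-strain alleles;
the reported effect is the most severe across alternate alleles
(nonsense > missense > synonymous).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from . import _align
from .genomeio import GenomeBundle

_COMP = str.maketrans("ACGTN-", "TGCAN-")
_SEVERITY = {"nonsense": 3, "missense": 2, "synonymous": 1}


@dataclass
class GroupAlignment:
    group_id: str
    rows: dict  # strain_id -> gapped gene-oriented sequence
    features: dict  # strain_id -> GeneFeature
    anchor: str  # strain id of the anchor row

    @property
    def ncol(self) -> int:
        return len(next(iter(self.rows.values())))

    def consensus(self) -> tuple:
        """Majority row (gaps included) and its per-column offsets.

        The consensus gap pattern recovers the shared ancestral frame of
        the group, which member-specific indels (e.g. a frameshift in the
        reference strain) would otherwise distort.
        """
        if not hasattr(self, "_consensus"):
            strains = sorted(self.rows)
            cons = []
            for i in range(self.ncol):
                counts: dict[str, int] = {}
                for s in strains:
                    c = self.rows[s][i]
                    counts[c] = counts.get(c, 0) + 1
                cons.append(sorted(counts, key=lambda c: (-counts[c], c))[0])
            offs, o = [], 0
            for c in cons:
                if c == "-":
                    offs.append(-1)
                else:
                    offs.append(o)
                    o += 1
            self._consensus = ("".join(cons), offs)
        return self._consensus

    def position_maps(self) -> dict:
        """strain -> array of gene offsets per column (-1 on gaps)."""
        out = {}
        for s, row in self.rows.items():
            offs, o = [], 0
            for c in row:
                if c == "-":
                    offs.append(-1)
                else:
                    offs.append(o)
                    o += 1
            out[s] = offs
        return out


@dataclass
class VariantCall:
    group_id: str
    column: int  # 0-based alignment column (start of run for indels)
    var_type: str  # SNP | insertion | deletion
    per_strain_allele: dict  # strain -> base(s) in genomic strand, '-' for gap
    per_strain_position: dict  # strain -> 1-based replicon coordinate
    oriented_allele: dict = field(default_factory=dict)  # gene-orientation bases
    replicon: dict = field(default_factory=dict)  # strain -> replicon id
    length: int = 1
    effect: str | None = None
    aa_change: str | None = None
    per_strain_effect: dict = field(default_factory=dict)
    flags: tuple = ()


@dataclass
class VariantSummary:
    total_snps: int
    total_indels: int
    pct_aa_changing: float | None  # over CDS-located SNPs; None if none
    sharing_matrix: pd.DataFrame  # strains x variants, 1 = non-reference allele


# ---------------------------------------------------------------------------


def align_group(group, bundles: list, reference: str | None = None) -> GroupAlignment:
    """Multiple alignment of one homology group's gene sequences.

    The anchor is the reference strain's member when present, else the
    longest member; every other member is globally aligned to it and the
    pairwise alignments are merged through anchor coordinates with
    left-shifted gaps.  Deterministic.
    """
    by_id = {b.strain_id: b for b in bundles}
    feats = {s: by_id[s].feature(t) for s, t in group.members.items()}
    seqs = {s: by_id[s].gene_seq(f) for s, f in feats.items()}
    if reference is not None and reference in seqs:
        anchor = reference
    else:
        anchor = max(seqs, key=lambda s: (len(seqs[s]), s))
    rows = _align.anchored_msa(seqs, anchor, _align.nt_aligner())
    return GroupAlignment(group.group_id, rows, feats, anchor)


def _genomic_allele(base: str, strand: str) -> str:
    return base if strand == "+" else base.translate(_COMP)[::-1]


def _genomic_pos(feature, offset: int) -> int:
    return feature.start + offset if feature.strand == "+" else feature.end - offset


def call_variants(alignment: GroupAlignment, reference: str | None = None) -> list:
    """Variant calls from one group alignment.

    One call per polymorphic gap-free column; contiguous columns
    containing any gap are merged into a single indel call per run.
    Per-strain replicon coordinates are back-computed from the alignment;
    calls come out sorted by reference-strain coordinate.  Alleles are
    reported on the genomic strand of each member.
    """
    rows = alignment.rows
    strains = sorted(rows)
    if len(strains) < 2:
        return []
    if reference is None or reference not in rows:
        reference = alignment.anchor
    ncol = alignment.ncol
    offs = alignment.position_maps()
    feats = alignment.features
    lo, hi = _align.trim_bounds([rows[s] for s in strains])

    calls = []
    i = lo
    while i < hi:
        col = {s: rows[s][i] for s in strains}
        if "-" in col.values():
            j = i
            while j < hi and any(rows[s][j] == "-" for s in strains):
                j += 1
            calls.append(_make_indel(alignment, strains, i, j, offs, reference))
            i = j
        else:
            if len(set(col.values())) > 1:
                calls.append(_make_snp(alignment, strains, i, offs, reference))
            i += 1
    calls = [c for c in calls if c is not None]
    calls.sort(key=lambda c: c.per_strain_position.get(reference, c.column))
    return calls


def _positions_at(alignment, strains, col, offs):
    """Per-strain (replicon, 1-based position) of the base at/nearest
    before a column (indel anchor semantics)."""
    out_pos, out_rep = {}, {}
    for s in strains:
        f = alignment.features[s]
        o = offs[s][col]
        if o < 0:  # gap: anchor at last preceding base
            k = col
            while k >= 0 and offs[s][k] < 0:
                k -= 1
            o = offs[s][k] if k >= 0 else 0
        out_pos[s] = _genomic_pos(f, o)
        out_rep[s] = f.replicon_id
    return out_pos, out_rep


def _make_snp(alignment, strains, col, offs, reference):
    rows = alignment.rows
    oriented = {s: rows[s][col] for s in strains}
    alleles = {s: _genomic_allele(oriented[s], alignment.features[s].strand)
               for s in strains}
    pos, rep = _positions_at(alignment, strains, col, offs)
    call = VariantCall(alignment.group_id, col, "SNP", alleles, pos,
                       oriented, rep)
    classify_effect(call, alignment, reference)
    return call


def _make_indel(alignment, strains, start, end, offs, reference):
    rows = alignment.rows
    alleles, oriented = {}, {}
    for s in strains:
        seg = rows[s][start:end].replace("-", "")
        oriented[s] = seg or "-"
        alleles[s] = (_genomic_allele(seg, alignment.features[s].strand)
                      or "-")
    pos, rep = _positions_at(alignment, strains, start, offs)
    lens = {len(a.replace("-", "")) for a in alleles.values()}
    if len(lens) < 2:
        return None  # a gap column shared by all members: no event
    longest = max(lens)
    shortest = min(lens)
    ref_len = len(alleles[reference].replace("-", "")) \
        if reference in alleles else longest
    var_type = "deletion" if ref_len == longest else "insertion"
    call = VariantCall(alignment.group_id, start, var_type, alleles, pos,
                       oriented, rep, length=longest - shortest)
    classify_effect(call, alignment, reference)
    return call


# ---------------------------------------------------------------------------
# effect classification


def classify_effect(call: VariantCall, alignment: GroupAlignment,
                    reference: str) -> None:
    """Annotate a call in place against the reference strain's frame."""
    f = alignment.features.get(reference)
    if f is None:
        call.effect = "intergenic"
        return
    if f.kind != "CDS":
        call.effect = "noncoding_gene"
        call.per_strain_effect = {s: ("noncoding_gene", None)
                                  for s in alignment.rows if s != reference}
        return
    if call.var_type != "SNP":
        call.effect = "frameshift" if call.length % 3 else "inframe_indel"
        call.per_strain_effect = {s: (call.effect, None)
                                  for s in alignment.rows if s != reference}
        return

    rows = alignment.rows
    offs = alignment.position_maps()
    ref_row = rows[reference]
    o = offs[reference][call.column]
    if o < 0:  # reference gapped here (shouldn't happen for SNP columns)
        call.effect = "intergenic"
        call.flags = call.flags + ("boundary",)
        return
    ci = o // 3
    codon_offsets = (3 * ci, 3 * ci + 1, 3 * ci + 2)
    # columns holding the reference codon
    inv = {off: col for col, off in enumerate(offs[reference]) if off >= 0}
    try:
        cols = [inv[x] for x in codon_offsets]
    except KeyError:
        call.effect = "synonymous"
        call.flags = call.flags + ("boundary",)
        return
    ref_codon = "".join(ref_row[c] for c in cols)
    ref_aa = str(Seq(ref_codon).translate(table=11))

    codons = {s: "".join(rows[s][c] for c in cols) for s in rows}

    def judge(from_codon: str, to_codon: str) -> tuple:
        faa = str(Seq(from_codon).translate(table=11))
        taa = str(Seq(to_codon).translate(table=11))
        if taa == faa:
            return "synonymous", None
        if taa == "*":
            return "nonsense", f"{faa}{ci + 1}*"
        return "missense", f"{faa}{ci + 1}{taa}"

    # call-level effect: most severe change relative to the reference frame
    best = ("synonymous", None)
    for s, mut in codons.items():
        if s == reference or "-" in mut or mut == ref_codon:
            continue
        eff, change = judge(ref_codon, mut)
        if _SEVERITY[eff] > _SEVERITY[best[0]]:
            best = (eff, change)
    call.effect, call.aa_change = best

    # per-strain effect: each strain's codon against the panel-consensus
    # codon in the consensus frame (the proxy for the ancestral state)
    cons_row, cons_offs = alignment.consensus()
    oc = cons_offs[call.column]
    if oc < 0:
        return
    cj = oc // 3
    cons_inv = {off: col for col, off in enumerate(cons_offs) if off >= 0}
    try:
        ccols = [cons_inv[x] for x in (3 * cj, 3 * cj + 1, 3 * cj + 2)]
    except KeyError:
        return
    cons_codon = "".join(cons_row[c] for c in ccols)
    if "-" in cons_codon:
        return
    caa = str(Seq(cons_codon).translate(table=11))
    for s in rows:
        mut = "".join(rows[s][c] for c in ccols)
        if "-" in mut or mut == cons_codon:
            continue
        aa = str(Seq(mut).translate(table=11))
        if aa == caa:
            call.per_strain_effect[s] = ("synonymous", None)
        elif aa == "*":
            call.per_strain_effect[s] = ("nonsense", f"{caa}{cj + 1}*")
        else:
            call.per_strain_effect[s] = ("missense", f"{caa}{cj + 1}{aa}")


# ---------------------------------------------------------------------------
# pipeline over a pangenome


def call_pangenome_variants(pg, bundles: list,
                            reference: str | None = None) -> list:
    """Align every multi-member group and call variants; the designated
    reference strain (default: first bundle) fixes the effect frame."""
    if reference is None:
        reference = bundles[0].strain_id
    calls = []
    for g in pg.groups:
        if len(g.members) < 2:
            continue
        aln = align_group(g, bundles, reference)
        calls.extend(call_variants(aln, reference))
    return calls


def summarize(calls: list, reference: str, strain_ids: list,
              cds_group_ids: set | None = None) -> VariantSummary:
    """Totals, %% of CDS SNPs that change the protein, and the
    strain-by-variant sharing matrix (1 = carries a non-reference allele)."""
    snps = [c for c in calls if c.var_type == "SNP"]
    indels = [c for c in calls if c.var_type != "SNP"]
    cds_snps = [c for c in snps
                if c.effect in ("synonymous", "missense", "nonsense")
                and (cds_group_ids is None or c.group_id in cds_group_ids)]
    aa = sum(1 for c in cds_snps if c.effect in ("missense", "nonsense"))
    pct = 100.0 * aa / len(cds_snps) if cds_snps else None

    ids = [f"{c.group_id}:{c.column}" for c in calls]
    data = []
    for s in strain_ids:
        row = []
        for c in calls:
            # compare in gene orientation: immune to strand flips from
            # inversions that place orthologs on opposite genomic strands
            refa = c.oriented_allele.get(reference)
            a = c.oriented_allele.get(s)
            row.append(int(a is not None and refa is not None and a != refa))
        data.append(row)
    mat = pd.DataFrame(data, index=strain_ids, columns=ids)
    return VariantSummary(len(snps), len(indels), pct, mat)


def calls_to_tsv(calls: list, strain_ids: list, path) -> None:
    with open(path, "w") as fh:
        cols = ["group_id", "column", "type", "length", "effect", "aa_change"]
        cols += [f"{s}_allele" for s in strain_ids]
        cols += [f"{s}_pos" for s in strain_ids]
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            row = [c.group_id, str(c.column), c.var_type, str(c.length),
                   c.effect or "", c.aa_change or ""]
            row += [c.per_strain_allele.get(s, "") for s in strain_ids]
            row += [str(c.per_strain_position.get(s, "")) for s in strain_ids]
            fh.write("\t".join(row) + "\n")


def calls_to_vcf(calls: list, strain: str, reference: str, bundle,
                 path) -> None:
    """Minimal single-sample VCF v4.2 of one strain against the reference
    frame (CHROM/POS in the *strain's* coordinates, indels symbolic)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=cyanopan\n##reference={reference}\n")
        for r in bundle.replicons:
            fh.write(f"##contig=<ID={r.id},length={len(r)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = []
        for c in calls:
            a = c.per_strain_allele.get(strain)
            refa = c.per_strain_allele.get(reference)
            if a is None or refa is None or a == refa:
                continue
            chrom = c.replicon.get(strain, "")
            pos = c.per_strain_position.get(strain)
            if c.var_type == "SNP":
                ref_out, alt_out = refa, a
            else:
                ref_out = refa if refa != "-" else "<DEL>"
                alt_out = a if a != "-" else "<DEL>"
            info = f"TYPE={c.var_type};GROUP={c.group_id};EFFECT={c.effect}"
            rows.append((chrom, pos, ref_out, alt_out, info))
        for chrom, pos, ref_out, alt_out, info in sorted(rows):
            fh.write(f"{chrom}\t{pos}\t.\t{ref_out}\t{alt_out}\t.\tPASS\t{info}\n")
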