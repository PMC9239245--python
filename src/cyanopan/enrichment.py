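"""Gene-set enrichment over categorical metadata.

For a gene set g and category c in a genome of N genes:

    fc  = Nc / N          frequency of the category
    Egc = Ng x fc         expected overlap under independence
    F   = Ngc / Egc       fold enrichment

Significance is a two-sided Fisher exact test on the 2x2 table
(in-set & in-category, in-set & out, out & in-category, out & out),
with Benjamini-Hochberg FDR adjustment across the categories tested for
one gene set; q <= 0.05 is significant.  Genes carrying several
category labels contribute to each category's table independently
(N stays the total gene count).

The Fisher p-value is computed with exact integer hypergeometric
weights (sum of the probabilities of all tables with the same margins
whose probability does not exceed the observed table's), so it is
stable to large margins and matches exhaustive enumeration bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np


@dataclass
class EnrichmentResult:
    gene_set_id: str
    category: str
    N: int
    Ng: int
    Nc: int
    Ngc: int
    fc: float
    Egc: float
    F: float
    p: float
    q: float
    significant: bool
    direction: str  # enriched | depleted


# ---------------------------------------------------------------------------
# statistics


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Standard definition: the sum of hypergeometric probabilities of all
    tables with the same margins whose probability is <= that of the
    observed table.  Computed with exact integer weights
    ``C(r1, x) * C(r2, c1 - x)`` and converted to float once at the end.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(num, comb(n, c1)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        q[i] = running
    return q


# ---------------------------------------------------------------------------
# gene-set enrichment


def run_gsea(gene_set, metadata: dict, gene_set_id: str = "set") -> list:
    """Enrichment of one gene set against every category in ``metadata``.

    ``metadata`` maps every genome gene to a (possibly empty) set of
    category labels; ``gene_set`` must be a subset of its keys.  Returns
    one :class:`EnrichmentResult` per category with Nc > 0, sorted by q
    then category.  Empty gene set -> empty list.
    """
    gene_set = set(gene_set)
    unknown = gene_set - set(metadata)
    if unknown:
        raise ValueError(f"gene set contains genes absent from metadata: "
                         f"{sorted(unknown)[:3]}...")
    if not gene_set:
        return []
    N = len(metadata)
    Ng = len(gene_set)
    categories = sorted({c for cats in metadata.values() for c in cats})
    rows = []
    for cat in categories:
        members = {g for g, cats in metadata.items() if cat in cats}
        Nc = len(members)
        if Nc == 0:
            continue  # Egc would be 0: category skipped
        Ngc = len(gene_set & members)
        fc = Nc / N
        Egc = Ng * fc
        F = Ngc / Egc
        p = fisher_two_sided(Ngc, Ng - Ngc, Nc - Ngc, N - Ng - Nc + Ngc)
        rows.append((cat, Nc, Ngc, fc, Egc, F, p))
    qs = bh_fdr([r[6] for r in rows])
    out = []
    for (cat, Nc, Ngc, fc, Egc, F, p), q in zip(rows, qs):
        out.append(EnrichmentResult(
            gene_set_id, cat, N, Ng, Nc, Ngc, fc, Egc, F, p, float(q),
            bool(q <= 0.05), "enriched" if Ngc > Egc else "depleted"))
    out.sort(key=lambda r: (r.q, r.category))
    return out


def results_to_tsv(results: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_set\tcategory\tN\tNg\tNc\tNgc\tfc\tEgc\tF\tp\tq\t"
                 "significant\tdirection\n")
        for r in results:
            fh.write(f"{r.gene_set_id}\t{r.category}\t{r.N}\t{r.Ng}\t{r.Nc}\t"
                     f"{r.Ngc}\t{r.fc:.6g}\t{r.Egc:.6g}\t{r.F:.6g}\t"
                     f"{r.p:.6g}\t{r.q:.6g}\t{int(r.significant)}\t"
                     f"{r.direction}\n")


def metadata_from_bundles(bundles: list) -> dict:
    """locus-tag -> category set across a strain panel (tags are
    panel-unique because they are strain-prefixed)."""
    out = {}
    for b in bundles:
        for f in b.features:
            out[f.locus_tag] = set(f.categories)
    return out
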