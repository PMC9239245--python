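# Methods

## Scope and model of the data

cyanopan compares a panel of bacterial strains that diverged recently
from a common ancestor — the regime of a laboratory strain collection,
where genomes are colinear except for a small number of large events
and nucleotide divergence is fractions of a percent to a few percent.
Every analysis assumes this regime: orthologs are near-identical,
alignments are anchored rather than exhaustive, and structural events
are detected by exact-sequence signatures rather than probabilistic
models. The package is not designed for cross-genus comparisons.

Coordinates are 1-based inclusive at every external boundary (GFF3
convention); internal arithmetic is 0-based half-open and never visible
in outputs. The genetic code is fixed to bacterial table 11. N bases
are permitted but never count as matches in any nucleotide identity.

## The synthetic study panel

`synthgenomes.make_study_panel` emulates the design of a six-strain
cyanobacterial panel: five nearly identical "legacy" strains and one
divergent "environmental" isolate. Defaults (full scale):

| parameter | value | rationale |
|---|---|---|
| chromosome | 120 kb, 105 genes, 4 tRNAs | large enough for every event class, small enough for minutes-scale runs |
| plasmids | pL 24 kb / 18 genes, pS 8 kb / 6 genes | a large and a small plasmid, as in freshwater *Synechococcus* strains |
| GC fraction | 0.55 | cyanobacterial chromosome-like |
| HIP1 planting | 0.3 octamers/kb, intergenic | hyperabundant palindrome; intergenic so ORFs stay intact |
| legacy branch SNP rate | 5×10⁻⁴ /site | gives pairwise legacy ANI ≈ 99.9% |
| environmental SNP rate | 1.45×10⁻² /site | gives ANI to legacy strains ≈ 98.5% |
| indel rates | 2×10⁻⁵ (legacy), 10⁻⁴ (env), lengths 1–12 geometric | a few hundred indels per 40,000 SNPs, as observed in such panels |
| prophages | legacy: one shared 12-kb element in tRNA 0; env: an 18-kb element in tRNA 1; att 60 bp | integrase-style insertion duplicating the tRNA 3′ terminus exactly |
| inversion | ≈ 25 kb, HIP1-bounded, in two legacy strains | mirrors an inversion shared by two related lab strains |
| plasmid events (env) | lose pS; fuse pL → pMAL (9-kb expanded region, duplicated flanking gene pair); gain pMAS with CRISPR (32-bp repeat, 6 unique 34-bp spacers) | the fusion/CRISPR signatures the mobilome detectors target |
| unique blocks (env) | 30 genes, mobilome/defense/motility/cell-cycle-weighted labels | drives the planted enrichment signal |

**Substitution model.** Within CDSs, mutations are drawn per gene
(count ~ Binomial(L, rate)) from precomputed menus of synonymous and
nonsynonymous single-base changes, choosing a synonymous change with
probability 0.8. This emulates purifying selection: in real strain
panels only about one in five observed SNPs changes an amino acid,
whereas under a uniform model ~70% would. Two consequences are
deliberate: the amino-acid-changing share of SNPs comes out near 20%
(slightly above, because two mutations landing in one codon are judged
jointly), and AAI exceeds ANI on simulated pairs, as in real data.
The final stop codon is excluded from the menus. Intergenic and
RNA-gene sites mutate uniformly. Planted HIP1 octamers are masked from
both substitutions and indels so inversion bounds stay exact; indels
are placed fully inside a CDS interior or fully intergenic (re-drawn
otherwise) so no feature boundary is ever straddled.

**Truth log.** Every event is recorded twice: as an ordered, replayable
edit script (`TruthLog.strains[s].events`; re-applying it to the
ancestor must reproduce the derived genome byte-for-byte — a tested
invariant) and as structured expectations (SNP positions/alleles/
effects tracked through all later coordinate-shifting events, prophage
att coordinates, inversion breakpoints, fusion flanks, CRISPR
repeats/spacers, and the ortholog group of every gene). Detector
scoring (`cyanopan.evaluate`) needs only the truth log, never the
sequences.

**What the simulation does not model** — and hence what passing tests
do not show about real data: assembly and sequencing error, repeat
families and IS elements (beyond the planted duplications), horizontal
transfer of diverged homologs, rearrangements other than one inversion,
biased gene conversion, and real codon usage. Detector performance on
real genomes will be bounded by those factors, not by the logic tested
here.

## Pangenome

RBH runs on nucleotide gene sequences (CDS, tRNA, ncRNA; pseudogenes
are carried in bundles but not grouped), scored by global affine-gap
alignment (match +2, mismatch −3, gap open −5, extend −2 — near common
nucleotide-search defaults; a gap of length L costs 5 + 2L). A 13-mer
prefilter selects up to five candidate partners per gene; at the 70%
identity / 50% coverage RBH floors this cannot change results for genes
of ordinary length. Identity is defined once: identical columns over
the alignment including internal gap columns, excluding terminal
overhangs. Groups are single-linkage closures over all pairwise RBH
edges; edges are merged best-score-first and a merge that would give
one strain two members is skipped, so conflicted genes re-seed their
own groups. Ties break lexicographically, making the construction
deterministic.

## Group alignment and variants

Group alignments are reference-anchored: each member is globally
aligned to an anchor (the reference strain's member when present) and
merged through anchor coordinates; gap runs are left-shifted to their
leftmost equivalent placement; nearby complementary gap runs (an
artifact of substitution clusters scoring as gap "slippage") are
collapsed back into substitutions. A second pass realigns all members
against the column-majority consensus of the first pass, which places
inserts consistently when the anchor itself carries a deletion
(center-star refinement). For the near-identical groups this pipeline
targets, the result is equivalent to a full progressive alignment and
is deterministic.

SNPs are called per polymorphic gap-free column; contiguous columns
containing any gap merge into one indel call (indels are counted as
merged events, not per column). Effects are codon-aware with the full
mutated codon judged at once (two SNPs in one codon are classified
jointly). Two frames are reported: the call-level effect uses the
designated reference strain's frame — the frame in which "SNPs relative
to the reference" are conventionally tabulated, so a reference-strain
frameshift legitimately changes downstream effect calls — while
per-strain effects use the panel-consensus frame, a proxy for the
ancestral state, and are the quantities scored against simulation
truth. The `pct_aa_changing` summary is the share of CDS-located SNP
calls whose effect is missense or nonsense.

## ANI and AAI

ANI follows the fragment-based (BLAST-style) definition: 1,020-bp
non-overlapping query fragments (the trailing partial fragment is
discarded), each placed on the subject by 15-mer seed voting over
diagonal bins and aligned with a banded edit-distance alignment
(edlib); fragments without any seed fall back to a full-width
edit-distance search over the whole subject. Either placement is
trimmed to its best local segment (linear-time maximum-scoring window, +1 match / −2 otherwise)
so that a fragment straddling strain-specific sequence is scored only
over its homologous part — the behaviour of the local aligner the
method was defined with. Fragments are kept at ≥ 30% identity over
≥ 70% of their length (the method's published cutoffs; configurable),
one-way ANI is the mean identity of kept fragments, and the reported
value is the two-direction mean, making the all-pairs matrix symmetric
with a diagonal of exactly 100. When no fragment passes in either
direction the pair is flagged `no_homology` rather than given a number.

AAI is the mean identity of reciprocal-best-hit protein pairs (BLOSUM62
global alignment, gap open −12/extend −1) passing the same 30%/70%
floors. Proteins with internal stops are excluded.

## Mobilome detectors

*Prophages.* For each tRNA, the maximal exact duplication of its
3′-terminal k bases is sought on the same strand within 150 kb
downstream of the gene's 3′ end (k scanned from 200, capped at the tRNA
length, down to 15); the largest k whose second copy delimits an
element ≥ 5 kb yields a call. Minus-strand tRNAs are scanned leftward
— their 3′ terminus sits at the genomic start of the feature. The
element span runs from the first base after attL to the last base of
attR; reported lengths are exact, and comparisons against literature
kb-scale figures should round to the nearest kb since whether printed
element sizes include the att copies varies by convention. The 150-kb
window covers the largest elements reported in cyanobacterial strain
panels (~90 kb) with margin.

*HIP1.* The octamer GCGATCGC is its own reverse complement, so one
strand scan is complete; overlapping occurrences count. The octamer
itself is the standard literature definition of the motif — an
assumption recorded here because publications often name HIP1 without
printing the sequence.

*Inversions.* 21-mers occurring exactly once in each genome become
anchors (orientation from forward vs reverse-complement matches);
anchors chain into maximal collinear blocks (gap tolerance 5 kb), and
reverse-orientation blocks ≥ 2 kb between forward context are reported.
Boundary uncertainty is the inter-anchor gap; `boundary_hip1` is true
when a HIP1 octamer lies inside the uncertainty interval at both ends.
Because the planted boundary octamers are palindromic, they are never
unique anchors, so detected breakpoints sit within a few bases of
truth — the "anchor resolution" used in the tests (±50 bp).

*Plasmid fusion.* Shared content is measured by mapping 500-bp
fragments of plasmid A onto plasmid B (≥ 50% identity over ≥ 70%
coverage), which is robust to duplicated regions that k-mer-unique
anchoring cannot cover; anchor-chained blocks are still reported for
structure. The fusion signature is a pair of adjacent genes in B whose
two copies are both homologous (one-way best hit, ≥ 70% identity) to a
single adjacent pair in A; the inter-flank segment is reported as the
candidate expanded region.

*CRISPR arrays.* Candidate repeats are seeded by 21-mers occurring
≥ 3 times with plausible spacing, extended to the maximal shared exact
repeat (21–50 bp), and validated: spacer lengths within [0.6, 2.5] ×
repeat length and spacers mutually distinct — the uniqueness rule is
what rejects plain tandem repeats. Nested calls collapse to the
longest-repeat call. Spacers are exported as FASTA for external search;
the search itself is out of scope.

## Enrichment statistics

The two-sided Fisher exact p is the sum of hypergeometric probabilities
of all tables with the observed margins whose probability does not
exceed the observed table's. It is computed with exact integer weights
`C(r1,x)·C(r2,c1−x)` (Python big integers) and converted to float once,
so it is stable for margins in the thousands and matches exhaustive
rational enumeration bit-for-bit; the test suite cross-checks it
against an independent implementation. BH-FDR is the standard step-up
with q-values capped at 1 and order preserved. The FDR family is the
set of categories tested for one gene set (per-set adjustment), not all
gene sets pooled — the convention matching per-figure analyses; genes
with several category labels enter each category's table independently
while N stays the total gene count; categories with `Nc = 0` are
skipped so `F` is never NaN.

The type-I-error check draws random gene sets (N = 3000, Ng = 120) and
tests four disjoint 150-gene categories over 1,000 replicates. These
sizes were fixed analytically before any simulation: the attained size
of the discrete two-sided test under the hypergeometric null is exactly
computable, and 150-gene categories give 0.0495 — close enough to the
nominal 0.05 for the empirical rate to sit inside the binomial 99%
band.

## Consensus annotation

Per group: (i) members whose annotated 5′ starts disagree (observed as
5′-terminal alignment overhangs) are adjusted to the majority start,
ties broken toward the longest ORF (conservative: keeps sequence);
(ii) groups annotated hypothetical or pseudogene in which every
evidence-bearing member has `transcribed = no` are dropped — unless any
member is flagged essential, which always vetoes a drop; (iii) ncRNA
features annotated in a subset of strains with transcriptional evidence
are promoted into the unified table (essentiality strengthens the
call). Transcription and essentiality are consumed as booleans supplied
with the annotation; the thresholds that produced them are upstream of
this package and are not re-derived.

## Problem sizes and determinism

The default test suite and the acceptance script run the full-scale
panel (≈ 160-kb derived genomes, six strains); unit tests use reduced
panels (`scale` 0.15–0.35) and 40–60-kb single-replicon hosts, and the
prophage recall property runs 12 seeded replicates at 40 kb — sizes
chosen so the whole suite completes in minutes while every event class
stays represented. All randomness flows from `numpy.random.default_rng`
seeded explicitly; same seed, same bytes, end to end (a tested CLI
contract).

## Known limitations

* RBH orthology has no paralog model: a duplicated gene's second copy
  re-seeds a unique group rather than forming a family.
* The reference-anchored aligner assumes near-identity; groups at the
  70% identity floor get coarser gap placement than a full progressive
  aligner would give.
* Fragment ANI is meaningful only above roughly 80% identity, as for
  the method it follows.
* Prophage detection requires the att duplication to be exact; a
  degenerate att (as in anciently domesticated prophages) is invisible.
* The CRISPR detector targets exact repeats; one terminal-repeat
  mismatch is tolerated in validation but diverged arrays are missed.
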