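# Methods

## Problem setting

A TCR is an αβ heterodimer; each chain's variable (V) domain carries three
antigen-contacting CDR loops on a conserved framework scaffold (FR1–FR4).
When T cells are transduced with a strongly expressed synthetic TCR, their
endogenous receptors split into two phenotypes: *dominant* (still surface
co-expressed) and *weak* (out-competed). Sequencing sorted dominant and weak
repertoires from several donors gives clonotype tables per (donor,
phenotype); positional statistics on the IMGT-aligned V domains then reveal
framework residues associated with dominant expression, and those residues
define substitution plans that raise the surface expression of arbitrary
TCRs. `tcrforge` implements this pipeline with a synthetic data generator in
place of the sequencing data, so that every stage is testable against
planted ground truth.

## IMGT numbering and the framework mask

Numbering is template-based: clonotypes arrive with a V-gene call, so the
germline supplies positions 1–104 through its gapped sequence and the
junctional CDR3 is spliced into 105–117 by the center-out rule
(ceil(L/2) residues fill 105 upward, floor(L/2) fill 117 downward; lengths
over 13 would need IMGT insertion codes and are rejected — CDR3 is excluded
from framework statistics regardless). Region bounds are fixed (FR1 1–26,
CDR1 27–38, FR2 39–55, CDR2 56–65, FR3 66–104, CDR3 105–117, FR4 118–128),
anchors are C23, W41, C104; a missing anchor is flagged, not fatal.

The framework mask per chain is the union of occupied FR1–FR3 positions
across the germline set. FR4 is excluded because it is J-encoded and the
per-domain framework residue count of interest is 77. The full FR1–FR3 span
is 82 positions; the packaged reference convention places five gaps per
chain (α: 10, 73, 81–83; β: 73, 81–84), calibrated so each chain's mask is
exactly 77 positions. All public coordinates are 1-based IMGT positions;
0-based indices never cross a module boundary.

### The synthetic germline reference

Real germline V sequences cannot be bundled, so the packaged reference
(`germline_reference_synthetic.fasta`, 18 genes) is **synthetic**:
fabricated sequences that carry (i) the anchors, (ii) the shared gap
convention above, and (iii) the documented residue identities of each
covered gene at their IMGT positions — e.g. P96 in TRAV13-2 vs L96 in
TRAV38-2, S9/N10 in TRBV7-3 vs R9/Y10 in TRBV7-8, F39/D55 (weak) vs L39/R55
(dominant) in the α chain, R43 vs Q43 in the β chain. Everything positional
(numbering, masks, designs, candidate identities) is therefore exact, while
the residues *between* documented positions are plausible filler. Users with
access to the IMGT reference directory can drop in a real gapped FASTA; all
functions accept any germline set.

The reference dominant TCR is carried as TRAV38-2/TRBV7-8 throughout (its
gene call appears inconsistently in upstream records; TRAV38-2 is the name
the conversion fixtures use).

## Synthetic libraries and planted effects

`generate_library` emulates the sorted-library design: per donor and
phenotype, clonotypes are drawn as (V gene, J gene, CDR3) triples with
configurable per-phenotype V-usage weights, CDR3 length range 8–13 and
uniform residue usage. Distinctness is global on (chain, V gene, J gene,
CDR3), enforced by CDR3 resampling on collision, so pooling donors and
phenotypes never collapses clonotypes. The default "Sanger emulation"
configuration is three donors contributing 442 distinct clonotypes per
phenotype in total (148/147/147 per donor — the even split is a
documented choice; per-donor counts were not specified for the pooled
884-clonotype library being emulated), half α and half β chains, with
usage skew toward the genes observed enriched per arm and moderate planted
effects (odds ratios 3–4) at documented candidate positions.

A planted effect (chain, position, A, r) fixes the frequency of amino acid
A at that position to f in the weak arm (default baseline 0.25) and to the
frequency whose odds equal r times the weak odds in the dominant arm. The
draw is deliberately **independent of the V gene**: a clonotype carries A
with the phenotype-specific probability, otherwise a fallback residue (its
germline identity, or a fixed alternate when the germline already is A).
This makes the marginal log-odds between phenotypes exactly log r in
expectation, so effect-size recovery can be asserted tightly. Deviations
from germline are recorded per clonotype in a `fw_variants` override column
(`POS:AA;...`), which the tally applies when counting — residue-level
variation rides on real gene calls rather than on invented genes, and an
override can never "un-gap" a position the germline lacks. Donor-specific
multipliers on r are available for sensitivity work; by default the effect
is common across donors, matching the CMH assumption.

What the generator does *not* model: nucleotide-level V(D)J recombination,
UMI/read counts and sequencing error, CDR3 length/composition biases, and
linkage between framework residues within a gene beyond what shared
germlines induce. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated sampling model, not robustness to
real-world artifacts such as clonal expansion or annotation error.

## Enrichment statistics

Counting is clonotype-weighted (each distinct clonotype counts once;
abundance weighting is a flag) because the libraries being emulated are
collections of distinct rearrangements. For each chain, donor, masked
position and amino acid A, the 2×2 table of A vs ~A across phenotypes is
formed; gapped positions contribute nothing, so per-position totals vary.

* **Fisher exact (two-sided)**: the p-value sums hypergeometric point
  probabilities not exceeding the observed table's (classical
  point-probability ordering). Probabilities are compared with 1e-12
  relative tolerance to avoid platform-dependent strict-inequality
  artifacts at ties. Tables with a zero margin are degenerate: p = 1,
  flagged. The pmf is computed from log-gamma binomials; the test suite
  checks every table with row margins ≤ 30 against exact integer
  enumeration and random tables against an independent library
  implementation.
* **CMH score test**: statistic (Σa_k − ΣE_k)²/ΣV_k with hypergeometric
  mean/variance per stratum, no continuity correction — the correction is
  immaterial at the library sizes of interest and omitting it keeps the
  single-stratum case exactly equal to the Mantel–Haenszel score
  chi-square. Degenerate strata drop out; if all are degenerate, (0, 1).
* **Bonferroni**: family = all (position, amino acid) pairs with nonzero
  pooled count, counted per chain (a genuinely open choice; this one is
  conservative and the family size is reported in every result row so a
  different family can be applied downstream). Pairs with pooled count < 5 are reported but flagged
  untested (exact tests on vanishing counts only inflate the family); the
  threshold is configurable.
* **Modes**: `sanger` pools donors into one table and applies Fisher only,
  uncorrected; `ngs` runs per-donor Fisher, CMH across donors, and
  Bonferroni on the CMH p-values.
* **V-usage**: per-donor clonotype-weighted gene frequencies per phenotype,
  compared by a two-sided unpaired Student t-test (equal variances;
  Welch available by flag).

Direction is defined by the pooled odds ratio (Haldane–Anscombe +0.5
applied only when a cell is zero).

## Candidate selection and design

Selection intersects dominant-enriched, tested, significant results with a
static structural-category annotation (the categories come from 3D
modeling, which is out of scope here; the annotation is packaged,
user-replaceable data). The weak-arm identity reported for a selected
residue is the sibling amino acid at that position with the largest
weak-arm count, preferring weak-enriched siblings. Ties order by smaller
p, then larger |log OR|, then lower position. The curated 14-residue
candidate table (9 α + 5 β positions spanning all four categories) ships as
package data; twelve of its identities are documented individually, the
remaining two β-chain entries are curated stand-ins marked as such.

Substitution plans validate every edit against the current residue and
apply atomically (no partial application), mirroring site-directed
mutagenesis bookkeeping; edits are restricted to FR1–FR3, so CDR loops are
invariant by construction. Biochemical-equivalence expansion replaces each
edit's target with members of its class from a packaged Taylor-style table
(hydrophobic, basic, aromatic, acidic, polar, small; a residue's primary
class is the first listed containing it), with a configurable cap on the
Cartesian product.

## Assay arithmetic

`specific_killing` implements 100 − (relevant/irrelevant with T cells) /
(relevant/irrelevant without) × 100; negative values are reported as-is.
The peptide scan substitutes alanine at every position, and serine wherever
the native residue is already alanine; the serine substitution tracks the
native alanine rather than any fixed position, which reproduces all three
reference variant panels (one reference panel contains an entry
inconsistent with any single-substitution rule at its position; it is
treated as a typo and excluded from exact-match tests). `net_response` floors the
background-subtracted value at zero by default (legend convention), with
the raw difference available. `fold_change` divides by a positive
reference.

## Numerical and scale choices

Test problem sizes are chosen to make the statistical assertions sharp at
desk scale: effect-size fidelity uses 5 000 clonotypes per arm (empirical
OR within ±20% of a planted OR 5); family-wise error control uses 100 null
libraries of 500 clonotypes per arm across 3 donors (≤ 8 libraries with any
Bonferroni discovery allows binomial slack on the 5% target); planted-effect
recovery uses OR 5 at one annotated position with 5 000 per arm over 100
seeds (≥ 95 must rank it first). The Fisher oracle sweep is exhaustive for
row margins ≤ 30; CMH is checked against a stratified permutation null
(margins fixed per stratum, 10⁵–10⁶ draws) within Monte-Carlo error plus
the observed point mass of the discrete statistic.

All randomness flows through a single seeded NumPy generator per library;
identical (config, seed) reproduce byte-identical serialized output, and
pipeline manifests record SHA-256 checksums of every artifact.

## Known limitations

* The germline reference is synthetic; absolute residue identities at
  undocumented positions are filler (positional machinery is unaffected).
* No HMM/profile numbering of unannotated sequences; clonotypes must carry
  V-gene calls. CDR3 insertions (length > 13) are rejected, not numbered.
* Correlated tests are not modeled: residues private to one gene move
  together with usage fluctuations, so a single null event can produce a
  block of tied discoveries (Bonferroni still controls the family-wise
  rate, as the null-calibration suite verifies).
* No FDR alternative to Bonferroni, no logistic modeling of position
  effects, and no structural or stability prediction.
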