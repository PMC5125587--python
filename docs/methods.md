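# Methods

This note records the statistical definitions the package implements, the
conventions chosen where the literature offers more than one, and what the
synthetic-data generator does and does not emulate.

## Sequence handling

All computation is done in the RNA alphabet; DNA input is canonicalized
(T→U) on construction. A CDS is analysis-eligible when its length is a
multiple of 3 and it contains no internal stop codon; a trailing stop codon
is trimmed (GenBank CDS extracts vary in whether they include it, so the
trim makes inputs comparable). `truncate` and `allow_internal_stop` relax
the two rules for imperfect extracts. Codons containing N are excluded from
every count rather than imputed. Only the standard genetic code is
supported: the degeneracy structure — 9 two-fold families, Ile three-fold,
5 four-fold, Leu/Ser/Arg six-fold, 59 synonymous codons — is built from
Biopython's NCBI table 1 and asserted at import-test time.

## Composition conventions

`GC3` is G+C at the third position of **all** codons; `GC3s` restricts to
synonymous codons (Met, Trp, stop excluded). The per-base `X3s` values
follow the CodonW convention: the numerator counts synonymous codons ending
in base X, the denominator counts only synonymous codons whose family can
place X at the wobble position (Phe can never end in A, so Phe codons do
not enter the A3s denominator). This is why A3s+U3s+C3s+G3s ≠ 100% and
why GC3s ≠ GC3 in per-strain tables. `GC12` is exactly (GC1+GC2)/2.
Percentages are carried at full precision and rounded only at report time.

Dinucleotide frequencies are taken over the L−1 overlapping windows of the
linear sequence (no circular wraparound — the common convention for CDSs;
codon boundaries are included). ρ<sub>xy</sub> = f<sub>xy</sub>/(f<sub>x</sub>f<sub>y</sub>),
with >1.23 / <0.78 as the over/under-representation thresholds. Windows
containing N are skipped.

## ENc

Per family with total count n ≥ 2, codon homozygosity is
F̂ = (nΣp̂² − 1)/(n − 1). Class means average F̂ over the families of each
degeneracy class with F̂ > 0; if the three-fold class (Ile alone) has no
usable F̂ it is replaced by (F̄₂+F̄₄)/2; any other empty class is an error.
ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61. Eligibility rules,
substitution and cap follow Wright (1990) as implemented in CodonW. The
implementation is tested against an independent symbol-by-symbol oracle
that regroups codons via Biopython translation.

## CAI

Reference relative adaptiveness w<sub>ij</sub> = RSCU<sub>ij</sub>(ref) /
RSCU<sub>i,max</sub>(ref), with zero reference counts replaced by a 0.5
pseudo-count before the reference RSCU is formed (Sharp & Li convention).
The geometric mean runs over the 59 synonymous codons of the query,
weighted by their counts; Met and Trp are excluded by default because their
w ≡ 1 only dilutes the index (the CodonW dialect; `include_single_codon`
selects the EMBOSS-style dialect). A reference may be a 64-codon count
table (e.g. a Kazusa file) or an RSCU vector directly — both yield the
same w.

## Host similarity

RSCU bins: under at ≤ 0.6, over at ≥ 1.6, average between. Values exactly
equal to a threshold fall in the extreme bin; this matters because
published RSCU tables are printed at 3 decimals (the packaged virus vector
contains a codon at exactly 0.600), and the boundary-in-extreme-bin rule is
what reproduces the published virus-vs-human agreement count of 47/59.
Full-precision pipelines may flip individual boundary codons.

D(A,B) = (1 − R)/2 with R the cosine of the two 59-codon RSCU vectors.
The halved form is used (rather than 1 − R/2) because D is defined on
[0, 1] and R on [−1, 1]; only (1 − R)/2 maps one onto the other. D can be
computed once on the pooled vector or per strain and averaged; both modes
exist because published means are often per-strain averages (on the
packaged tables the two differ by less than 0.001).

## tAI

Absolute adaptiveness of codon i is W<sub>i</sub> = Σ (1 − s) · tGCN over
the anticodons that can read it: the Watson–Crick anticodon (s = 0) and one
wobble reader per third base with the dos Reis et al. (2004) default
penalties s(U:G) = 0.41, s(C:I) = 0.28, s(A:I) = 0.9999, s(G:U) = 0.68
(inosine is the A-encoded wobble base; penalties are configurable).
w = W/max W; codons with w = 0 receive the geometric mean of the non-zero
w; tAI is the geometric mean of w over the sense codons of the sequence.
tRNA pools are user-supplied anticodon→gene-copy-number files; no genome
snapshot is bundled.

## Multivariate analyses

Correspondence analysis operates on the strains × 59 RSCU matrix (the
"COA on RSCU" of CodonW), not raw counts; columns of families absent from
any strain are dropped first. With P = X/ΣX and row/column masses r, c,
the SVD of D<sub>r</sub><sup>−1/2</sup>(P − rcᵀ)D<sub>c</sub><sup>−1/2</sup>
yields principal coordinates and per-axis inertia fractions
σ<sub>k</sub>²/Σσ². Axis signs are arbitrary; each axis is flipped so the
first row is non-negative, and downstream correlations with axes should be
read as |ρ|. A rank-0 matrix (identical row profiles) gives a zero-inertia
result with a warning, not a failure. The implementation is validated
against brute-force chi-square distance and inertia computations.

PR2 coordinates use only the eight four-codon quartets (Ala, Gly, Pro,
Thr, Val, and the CUN/UCN/CGN blocks of Leu/Ser/Arg); the AGR/AGY codons
of the six-fold families are outside the quartets and excluded.

Spearman correlations are tie-corrected with the two-sided t-approximation
p-value (n − 2 df), appropriate at the n ≈ 46 regime of strain panels; an
exact permutation p is available for n ≤ 8. The neutrality analysis
reports Spearman ρ of GC12 vs GC3 plus the OLS slope of GC12 on GC3 for
plotting.

## Synthetic-data generator

The generator draws residues i.i.d. from an amino-acid composition
(default: the Swiss-Prot average composition) and codons per residue from
a per-family distribution. Defaults emulate the study panel: 46 strains ×
3423 codons (a flavivirus polyprotein) with θ = 0.515, matching the
observed GC3s regime of the packaged table (51.53%). In `gc3_biased` mode
the G/C-ending codons of every family share probability θ and the
A/U-ending codons 1 − θ, which makes the expected pooled GC3s equal θ
exactly, independent of amino-acid composition; empirically the generator
is unbiased with sampling SD ≈ 0.005 at 10⁴ codons, so parameter-recovery
tests use ≥5×10⁴ codons to make the ±0.01 check a >4σ band. The mixing
weight λ interpolates toward a point mass on each family's preferred codon
(default: the packaged virus RSCU winners); λ = 1 gives ENc = 20.
A separate `mutation_driven_pool` draws codons as i.i.d. bases under a
per-strain GC level, reproducing the neutrality limit in which GC12 tracks
GC3 across strains.

What the generator does **not** emulate: phylogenetic correlation between
strains (real strain panels are a tree, not an i.i.d. sample — published
correlations across strains are therefore not targets for synthetic data),
dinucleotide-level selection (CpG/UpA depletion), position-dependent
amino-acid composition, and recombination. Tests passing on synthetic
pools validate the statistics' arithmetic and invariances, not any claim
about real viral evolution.

## Packaged tables

Two CSVs ship with the package and are sha256-checksummed on load: the
per-strain index table of the 46 ZIKV polyprotein CDSs (CAI, ENc, GC3s,
GC, X3s, GRAVY, AROMO, GC12, GC3) and the 59-codon RSCU vectors of the
pooled ZIKV set and its three hosts. They are transcriptions of printed
tables, not downloads, and are the basis of the offline acceptance checks;
quantities that require the underlying GenBank sequences themselves
(per-strain dinucleotide means, the full correlation matrices, CA axis
inertias of the real panel, the tAI range) are produced by the pipeline
when those sequences are supplied but have no packaged reference values.

## Numerical and reporting choices

Report-time rounding follows the conventions of published tables: CAI
3 dp, ENc 2 dp, percentages 2 dp, D(A,B) 4 dp, GRAVY/AROMO 3 dp; full
precision is kept internally and pipeline outputs are deterministic per
seed. RSCU of a pooled strain set is the RSCU of summed counts, not the
mean of per-strain RSCU vectors (the two differ when strain lengths
differ); the pooled/per-strain distinction is explicit in the API.
Preferred-codon ties are broken lexicographically and flagged. Empty
denominators (Met/Trp-only input, missing families) yield NaN plus a flag
or warning rather than silent zeros.

## Known limitations

- Only the standard genetic code; no alternative tables.
- The ENc class-mean treatment of sparse families (n < 2 skipped) makes
  ENc unstable below a few hundred codons; that is a property of the
  statistic, not the implementation.
- The exact-permutation Spearman p is factorial-time and capped at n ≤ 8.
- The CLI reads whole FASTA files into memory; fine for viral CDS panels,
  not intended for genome-scale input.
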