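# Methods

This note documents the models, conventions and design choices behind
`kdrpop`, in the spirit of the methods documentation of established
population-genetics packages.

## Coordinates, formats and missing data

All genomic coordinates are 1-based inclusive (VCF convention) at every
interface; any half-open arithmetic is internal. Multiallelic VCF records are
kept as single variant rows with up to three alternate alleles and are never
split into biallelic rows — the triallelic V402L site, where g>t and g>c
both encode valine→leucine, is a central object and splitting it would
destroy the allele-specific analyses. Missing genotypes are allele index −1
and are excluded pairwise per computation: per variant for allele
frequencies, per locus pair for LD, per haplotype pair per site for π. Input
tables are tab-separated with mandatory headers; outputs are tab-separated
text, JSON, Newick (dendrograms) and DOT (networks). Floating-point table
cells are printed with 6 significant digits so that output checksums are
stable across reruns.

## Diversity statistics

Statistics operate on haplotype matrices (diploids contribute two rows;
every estimator here depends only on per-site allele counts, so phase never
changes the values).

* **Segregating sites.** A site segregates when ≥ 2 distinct non-missing
  alleles are observed in the sample subset; the multiallelic fraction is
  the share of segregating sites with > 2 observed alleles.
* **π (θπ).** Mean pairwise difference over all n(n−1)/2 haplotype pairs,
  divided by the region length L. Multiallelic sites contribute through the
  full heterozygosity term (every cross-allele pair is a difference). A pair
  missing at a site contributes no difference there and the denominator is
  *not* renormalized (the site is dropped for that pair, L stays fixed) — a
  deliberate, simple convention that is exact in the missingness-free
  synthetic setting and slightly conservative otherwise.
* **θw.** S/(a1·L) with a1 = Σ_{i<n} 1/i.
* **Tajima's D.** (Π − S/a1)/√(e1·S + e2·S(S−1)) with Π the *total* mean
  pairwise difference and the 1989 normalizing constants
  (a1, a2, b1, b2, c1, c2, e1, e2) computed at n = the number of haplotype
  rows (the region-wide modal sample size). D is reported as NaN
  ("undefined"), never 0, when S = 0 — a zero would fabricate a neutral
  signal.

The 4-haplotype worked instance {000, 001, 011, 111} (Π = 10/6,
θπ = 10/18 per site at L = 3, θw = 3/(a1·3), D = 0.16766) was verified
constant-by-constant against an independent enumeration before being frozen
into the tests.

## Effect annotation and allele frequencies

Annotation is per alt allele against a single supplied transcript model
(coding exons + reference sequence): positions outside coding exons are
"intronic"; otherwise the affected codon is translated with the standard
genetic code and the label is "synonymous" or `<refAA><index><altAA>`.
Reverse-strand transcripts use reverse-complemented alleles. The codon index
is counted within the supplied transcript's CDS; community numbering (the
kdr literature has carried both modern and legacy indices for the same
sites) is a display concern, handled by alias maps in configuration rather
than hard-coded.

Allele frequency = alt alleles among non-missing calls / non-missing
alleles, per population. The reporting filter keeps a (variant, alt) row
when its frequency reaches `min_freq` (default 0.05) in *at least one*
population — the permissive reading of a max-over-populations rule. The
cumulative V402L row (freq(g>t) + freq(g>c)) is emitted per population as
the quantity directly comparable with the 1527T frequency. The Ace1
organophosphate-resistance site (G280S) reuses this machinery with its own
panel; there is no separate code path.

## Diplotype classification

Haplotypes at the kdr panel are labelled by table lookup per locus
(995: L/F/S; 402: V/L1/L2; 1527: I/T) and concatenated in fixed locus
order. Phased input maps directly to an unordered label pair; the pair is
one of the five named groups or OD (other diplotypes — the catch-all for
everything else, including all S-carrying combinations and any call with a
missing panel locus). Unphased input is matched against the per-locus
allele multisets each named group implies. The triple heterozygote is
genuinely phase-ambiguous (FL1T/LVI vs FVI/LL1T); it is assigned by the
**coupling rule** — place 995F, 402L and 1527T on the same haplotype, i.e.
FL1T/LVI — and flagged `ambiguous=True` so downstream consumers retain the
phase uncertainty. Unphased and phased classification agree whenever the
flag is false (a tested invariant). Statistical phasing is out of scope;
phased input is the primary path.

Clustering uses Hamming distance on per-site unordered genotypes with UPGMA
(average) linkage via scipy; determinism comes from scipy's fixed scan
order. PCA uses per-alt dosage columns (so the triallelic 402 signal
survives), Patterson scaling (center by mean, divide by √(p(1−p)),
p = mean dosage/2), mean imputation of missing entries, and a sign
convention that makes each component's largest-magnitude loading positive.
The clustered-heatmap ordering applies UPGMA on Euclidean distances to rows
and columns independently.

## Two-locus EM linkage disequilibrium

Each locus is collapsed to the 0/1/2 dosage of one focal mutant allele,
pooling all other alleles — at the 402 site the two mutants are therefore
analyzed against 1527T one at a time. From the 3×3 genotype-count table the
four haplotype frequencies are estimated by EM under Hardy–Weinberg (the
classic Hill-lineage estimator): only the double-heterozygote cell is
phase-ambiguous; the E-step splits it between coupling and repulsion with
weight f_AB·f_ab/(f_AB·f_ab + f_Ab·f_aB), the M-step divides expected
haplotype counts by 2n. Initialization is at linkage equilibrium
(f_XY = p_X·p_Y); convergence when max |Δf| < 1e-10 (default) or 1000
iterations. The allele-frequency margins are invariant under the update, so
fitted frequencies reproduce the data margins exactly at every iteration,
and the observed-data log-likelihood is non-decreasing (both tested).

Degenerate cases: a monomorphic margin makes r² undefined — rendered NA in
tables by default, with a configuration switch to print 0 for fidelity with
the common table convention; an all-double-heterozygote sample leaves the
likelihood flat between coupling and repulsion, the equilibrium start is
stationary, and the result is reported deterministically as D = 0 with a
`saddle` flag. A phased count-based estimator is provided separately and is
used only as the independent oracle in tests — never as the implementation.

## Median-joining networks

Unique haplotypes are collapsed with multiplicities and annotation tallies.
The network construction: (1) a minimum spanning network (Kruskal by
distance level; all links within ε of the minimal connection cost between
components; ε defaults to 0, the parsimonious network); (2) for node
triplets with at least two pairwise links, add the coordinate-wise majority
median (Steiner) vector; (3) iterate to a fixed point; (4) remove obsolete
medians (multiplicity 0, degree ≤ 2, not on any shortest path between
sampled nodes). Multi-state columns count any state change as distance 1;
all ties break lexicographically, so output is deterministic. On every
instance with ≤ 4 sampled haplotypes over ≤ 6 binary sites in the test
battery, the network's connection cost (MST weight over the final node set)
equals the brute-force minimal Steiner cost over candidate hypercube
vertices.

## CNV classification

Modal copy numbers are inputs; discovery from read depth is upstream.
State is amp/del/normal strictly by comparison with the sex- and
chromosome-aware baseline; CN = 0 is a complete deletion. An amplification
at baseline+1 counts the same as baseline+10 for frequencies (the binary
amp/del convention); the magnitude is retained in the scatter export. The
per-population frequency denominator is samples-with-a-call for the gene —
a configurable choice, since all-samples is equally defensible when
no-calls are rare.

## Synthetic cohorts: what they emulate, and what they do not

The generator's defaults define the study conditions: eight collection
sites across the Sudanian / Sudano-Sahelian / Sahelian zones; An. gambiae
s.s. essentially fixed for FVI (0.995); An. coluzzii segregating for
LVI/FVI/LL1T/FL1T with the g>c classes rare (≤ 0.03 LL2T, ≤ 0.02 FL2T) and
absent from two sites; An. arabiensis mixing FVI and SVI; ~60/30/40
mosquitoes per site and species; ~6000 neutral background sites cohort-wide;
CNV rates at nine detoxification/Ace1 genes spanning the reported range
(amp up to 0.85–0.90, complete GSTD5-style deletions at 1.0). With these
class frequencies the implied pooled An. coluzzii r²(402L(g>t), 1527T) is
≈ 0.82 and r²(402L(g>c), 1527T) ≈ 0.05 by construction of the classes.
Haplotype pairing is Hardy–Weinberg with no inbreeding parameter — the EM
estimator's own assumption. Each haplotype class carries two class-private
marker mutations at fixed positions so networks are non-degenerate; the
number is configurable and is a modelling convenience, not an empirical
claim.

What the generator does **not** emulate: linkage between background sites
(they are independent, so linked-selection signatures are absent), within-
class haplotype diversity beyond the private markers, genotyping error and
missingness, inbreeding, and geographic gradients beyond the configured
per-site frequencies. Passing tests therefore demonstrate correctness of
the estimators under their stated assumptions — not robustness to
real-data artefacts. Gene coordinates in the default annotation are
illustrative placeholders (synthetic), not genome-build coordinates.

## Problem sizes and numerics

Test and acceptance runs use the default cohort (~680 samples, ~6000 sites;
the full pipeline completes in well under five minutes on one CPU), 200
neutral replicates of n = 20, S = 200 for the Tajima's D calibration
(under the fixed-S neutral SFS, E[Π] = S/a1 exactly, so the mean D is ~0),
and 20 replicates of 1000 diploids for the EM-vs-phased comparison. EM
tolerance 1e-10; frequency-sum and margin invariants at 1e-9–1e-12;
degenerate inputs (S = 0, monomorphic margins, all-double-heterozygotes,
single haplotypes, empty CN tables) return flagged values rather than
raising wherever a flagged value is well-defined.

## Known limitations

* Per-site-n Tajima constants under missingness are not implemented (the
  modal-n convention is used); with heavy missingness D is biased.
* The unphased diplotype path resolves only the named-group ambiguity; a
  full phase-probability model is out of scope.
* The EM estimator gives point estimates only — no bias correction or
  confidence intervals for r².
* Median-joining is exponential in the worst case; it is intended for the
  collapsed haplotype sets of a gene region (tens of unique vectors), not
  genome-scale input.
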