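# Methods

This note documents the models implemented in `mhclineage`, the defaults
and their rationale, the numerical choices, and what the synthetic-data
tests do and do not establish about real allele sets.

## Sequence model and coordinates

All analyses operate on equal-length, in-frame nucleotide alignments over
`{A,C,G,T,N,-}` whose records carry IMGT-style names
(`HLA-DRB1*03:01`: species prefix, locus, colon-separated numeric fields;
the first field is the allelic lineage).  Internally coordinates are
0-based half-open; every report is 1-based.  Codons containing `-` or `N`
are treated as incomplete: pairwise analyses delete them for the affected
pair only (pairwise deletion), which keeps the maximum number of usable
codons per pair in allele sets where a few sequences are locally gapped.

Region masks are sets of 1-based mature-protein codon positions plus a
signal-peptide codon offset (DRB1 complete CDS carry a 29-codon leader, so
the shipped peptide-binding-region mask is applied with `offset=29` on full
CDS and `offset=0` on mature-coordinate alignments).  The shipped mask
holds 27 codons — the 24 classical DR β1 peptide-contact residues plus
positions 57, 67 and 90 — and is an editable data file, not a constant:
the exact contact-residue set varies between structural studies, and every
analysis accepts any mask.  On a 257-codon alignment the default mask
leaves a 230-codon (690-nt) non-PBR region.

## Recombinant screening

For each unordered pair of alleles, nucleotide differences are counted in
sliding windows (default 30 codons, stepped by 5).  Under the null of
uniformly scattered differences, the window count `m` out of `n` total
differences is Binomial(n, l/L) with `l` the usable window length and `L`
the usable alignment length for the pair; the exact upper tail
`P(X >= m)` is computed by direct summation (scipy's binomial survival
function), with no normal approximation.  Windows are corrected per pair
with a Šidák correction over the number of windows tested
(α′ = 1 − (1 − α)^(1/W), default α = 0.01).

An allele is removed when it is flagged against two or more distinct
partners: a splice recombinant clusters its differences against *both*
parental lineages, while removing both members of every flagged pair would
discard the parents along with the hybrid.

Two properties of this test matter in practice:

- **Scale matching.**  The window length sets the tract scale the test can
  see.  A 30-codon window has good power against exon-sized conversion
  tracts but little against a half-gene splice, whose signal lives at the
  half-alignment scale; screening for long splices should use windows
  comparable to the suspected tract (the detection tests use 50-codon
  windows against midpoint splices of 100-codon alignments).
- **Conservatism.**  With differences at discrete positions the achievable
  size of the exact test is below α, and Šidák over positively correlated
  overlapping windows is further conservative, so the realized family-wise
  false-positive rate is at or below the nominal level.  The type-I test
  therefore compares the observed flag rate to the exact achievable size
  (hypergeometric enumeration over difference placements), not to α
  itself.  Note also that in sequences under strong diversifying selection
  the PBR itself regionally concentrates differences; screening is best
  interpreted on the non-PBR region or with the PBR contribution in mind.

## Codon-level distances (modified Nei–Gojobori)

Potential site counting: each codon position contributes one site, split
into a synonymous fraction equal to the κ-weighted share of the three
possible single-nucleotide changes that are synonymous (transitions weight
κ, transversions 1).  κ = 1 recovers the classic NG86 equal-weight counts;
κ is an input (default 1.0) with a moment estimator available
(κ = 2·transitions/transversions over observed pairwise differences) —
maximum-likelihood estimation of κ is out of scope, matching the usual
workflow in which κ comes from a separate model fit.  Changes creating a
stop codon count as nonsynonymous potential.

Observed differences: single-difference codon pairs are classified
directly; 2- and 3-difference pairs are averaged over all orderings of the
single steps, excluding pathways that pass through a stop codon.  If every
pathway is blocked (possible only for rare stop-adjacent pairs), each
differing position is classified independently in the first codon's
context.  By construction `sd + nd` equals the codon pair's Hamming
distance.  The per-pair denominators are the averages of the two
sequences' S (and N) totals over the codons both have complete, per NG86.

Proportions are corrected with Jukes–Cantor, `d = −(3/4) ln(1 − 4p/3)`.
Saturation (`p ≥ 3/4`) is reported per pair (NaN entry plus a record), not
silently clipped — in practice this only occurs in degenerate toy inputs,
since within-locus allelic divergence is far from saturation.

The "modified" variant implemented here is the transition/transversion
bias-weighted site counting; the test suite pins it to an independent
enumeration oracle over all 61×61 sense-codon pairs.

## Divergence dating

`T = dS/(2μ)` with μ = 10⁻⁹ synonymous substitutions per site per year,
the standard neutral rate used for primate MHC loci.  Group mean pairwise
dS dates the average allelic divergence; the group maximum (dSmax) dates
the TMRCA.  The re-count estimator divides the maximum tree-path
synonymous count KSmax by the mean number of synonymous sites LS and
applies the same clock.  Machine outputs carry raw years; the human report
rounds half-up to integer million years (so 20.5 → 21 MYA and
28.5 → 29 MYA), which is the rounding consistent with the conventional
presentation of such tables.  Dating is computed from the unrounded dS the
pipeline supplies.

## Site compatibility

A variable column's effect is judged within each sequence's own codon
context: *synonymous* when every observed state leaves the amino acid
unchanged in every context, *nonsynonymous* when it changes it in every
context, *mixed* otherwise.  Mixed columns are excluded from the
synonymous tally — the conservative choice where a column's effect is
background-dependent.  Frequency categories: singleton (exactly two
states, minor count 1), informative (at least two states each carried at
least twice).  The four-gamete test is applied to all unordered pairs of
informative sites; it is defined for biallelic sites, so columns with more
than two states are excluded and reported separately, and sequences gapped
at either column are dropped for that pair.  Incompatible pairs (all four
gametes present) indicate recombination/gene conversion or repeated
mutation; the package reports the raw incompatible-pair list and leaves
formal recombination-rate inference out of scope.

## Parsimony mapping and the KS re-count

Synonymous substitutions are placed on a supplied tree (newick; unrooted
input is rooted on a named outgroup) by Fitch parsimony: bottom-up state
sets with a polytomy-safe sequential intersection, then the classic
top-down refinement (a node takes its parent's state when that state is in
its preliminary set, otherwise the lexicographically smallest member — a
change on that branch).  Per-site change counts equal the Fitch minimum,
verified against an exhaustive-labeling oracle; branch *attribution* among
equally parsimonious reconstructions is not unique (the tie rule here is
deterministic, and the two branches joining at the root are mutually
unidentifiable from leaf data), but per-site totals — and therefore path
sums on homoplasy-free data — are invariant, and path sums between leaves
on opposite sides of the root are invariant to the root-edge ambiguity.

KS between two alleles is the sum of mapped changes along their tree path.
Because parallel and back mutations on different branches both contribute,
KS is never less than the raw pairwise difference count; this is exactly
why the re-count corrects TMRCA estimates that multiple hits would
otherwise bias.  By default only columns classified synonymous are mapped.

## Ancestral lineage probabilities

`g_nk(t)` follows the classical ancestral-process solution

    g_nk(t) = Σ_{j=k..n} e^{−j(j−1)t/2} (2j−1)(−1)^{j−k} a_kj b_nj,
    a_kj = k(k+1)…(k+j−2) / (k!(j−k)!),
    b_nj = [n(n−1)…(n−j+1)] / [n(n+1)…(n+j−1)],

with t in coalescent units of N generations.  The alternating sum loses
all precision in double arithmetic for moderate n at small t, so the
coefficients are computed exactly as rationals and the sum is evaluated in
160-digit decimal arithmetic; normalization Σ_k g_nk(t) = 1 holds to
1e−9 for all n ≤ 64, and n > 64 raises rather than returning noise.  A
vectorized Monte-Carlo coalescent (exponential waiting times with rates
j(j−1)/2) serves as the independent oracle in tests.

Mapping coalescent time onto calendar years for a balanced polymorphism
requires the effective size of the allelic subpopulation, which is
generally unknown for an allelic group embedded in a larger locus; queries
therefore carry an explicit `scale` (time units per N generations) and the
package asserts no Ne.  The distribution and tail `P(K ≥ k)` make
questions like "could seven ancestral lineages persist among 31 sampled
alleles since time t" expressible once the user supplies the scaling.

## Synthetic data generator

The generator emulates a DRB1-like allele set: default 257 codons with the
27-codon PBR mask (non-PBR width 690 nt), 30 alleles on a random Yule tree
scaled to a root-to-tip synonymous depth of `branch_scale` (default 0.03,
within the range of within-group allelic divergence at such loci), κ = 2
transition bias, ω = 0.5 purifying background and ω = 5 diversifying PBR
(an order-of-magnitude elevation over background, as observed at
peptide-contact codons under balancing selection).  Branch lengths are in
expected synonymous substitutions per synonymous site: proposals arrive at
the neutral rate, synonymous changes are always accepted, nonsynonymous
changes are thinned by ω (ω ≤ 1) or proposed at ω-fold rate (ω > 1), and
stop-creating changes are rejected.  This acceptance-thinning scheme is a
deliberately simple stand-in for a full codon substitution model: it makes
the synonymous process exactly the neutral clock the analyses assume
(verified by parameter recovery to within Monte-Carlo error) while giving
the PBR/non-PBR dN/dS contrast the right direction and order.

An `infinite_sites` switch forbids repeated hits on a column, producing
homoplasy-free data on which Fitch mapping must recover the recorded
per-branch counts exactly.  Splice recombinants are constructed post hoc
(`s1[:breakpoint] + s2[breakpoint:]`) and appended with a registry entry.
A single seeded NumPy generator drives the whole run; identical seeds give
byte-identical output.

What the generator does **not** emulate: coalescent-with-selection tree
shapes (tree topology is an input), rate variation among synonymous sites,
codon-usage bias, indels and alignment error, allele-frequency information,
and database artifacts (partial CDS, annotation errors).  Passing tests on
synthetic data therefore establish the correctness of the *computations*
under the stated model, not the robustness of the *inferences* to
real-data complications such as unmodeled gene conversion.

## Problem sizes and determinism

The test and acceptance workloads are sized for quick, repeatable runs:
the codon oracle covers the full 61×61 table; the Fitch oracle uses 1,000
random ≤6-leaf instances against 4^internal exhaustive labelings; the
coalescent Monte-Carlo uses 10⁵ replicates (3-SE agreement per k); screen
calibration uses 1,000 null pairs against the exact hypergeometric size;
dS recovery averages eight two-leaf simulations of 10,000 codons (relative
SE ≈ 2%).  All randomness flows from explicit seeds; reruns are
bit-reproducible, and the pipeline report embeds a content hash to make
drift visible.

## Known limitations

- The screen's per-allele removal rule (flagged against ≥ 2 partners) is a
  pragmatic default; a recombinant between one sampled and one unsampled
  parent can escape it.
- Fitch branch attribution under ambiguity follows one deterministic
  minimal reconstruction; analyses should rely on per-site totals and path
  sums, which are reconstruction-invariant on clean data.
- Dating inherits the assumptions of the strict neutral clock: rate
  constancy across lineages and time, and no selection on synonymous
  sites; no confidence intervals are attached.
- The mixed-site rule for segregating columns is conservative and can
  undercount synonymous segregating sites relative to analyses that assign
  such columns by majority context.
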