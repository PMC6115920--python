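# Methods

This note documents the models and procedures implemented in nlrscan, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
demonstrate.

## Identification and domain grammar

A protein enters the survey when it carries at least one NB-ARC (NBS)
domain hit; proteins without one are excluded with an explicit reason (the
TIR-without-NBS "TX" class is deliberately out of scope). Domain evidence
comes from a tab-separated table keyed by Pfam-style accessions (PF01582
TIR, PF00931 NBS, PF05659 RPW8, PF01344 Kelch) or from the built-in
scanners; all hit coordinates are 1-based inclusive, mirroring the input
formats, and no score filtering is applied to table rows — filtering is
left to upstream tools or configuration.

The architecture of a protein is the ordered string of its
C/T/R/N-lettered domains (hits sorted by start; overlapping same-kind hits
merged by interval union before lettering). LRR evidence is the greedy
left-to-right count of non-overlapping `LxxLxxLxx` nine-mers. The subgroup
code appends `L` when at least one signature is present; when explicit LRR
hit spans are available, the `L` is instead interleaved at its observed
position, which is what distinguishes a tandem TNL-TNL duplication
(`TNLTNL`) from other four-unit strings. Codes outside the 18-entry
taxonomy are reported as `unclassified_architecture` rather than forced
into a bin.

Group assignment uses a dominance rule, T > R > C, chosen because it is
the unique simple rule consistent with the mixed codes in the taxonomy
(CTNL and CTN belong with TNLs; RCNL with RNLs). Strand is carried but
ignored: none of the classification or clustering criteria depend on it.

Kinase-2 signatures are the four residues starting at the first `DD` dyad
inside a Kinase-2 motif hit; `DDVW` and `DDVD` subtype NL-group genes into
the CC-lineage (N_CC) and TIR-lineage (N_TIR) respectively, any other
signature leaves the subtype unassigned. The RNBS-B signature is the match
of `T[TS]RD?` inside an RNBS-B hit (TSR vs TTRD). The RX-like coiled-coil
flag is accepted as input metadata only; computing it would require a
similarity search against a reference Rx protein, which is outside this
package.

## Motif discovery (ZOOPS EM)

De novo motif discovery fits one position probability matrix at a time
under the ZOOPS model: a sequence contains zero or one occurrence, with
prior probability `gamma` of containing one, uniform over start positions.
The E-step computes the exact posterior over start positions plus the
absent state; the M-step re-estimates the matrix with Dirichlet
pseudocounts (0.1 per cell) and updates `gamma`. The traced objective is
the relative log likelihood plus the pseudocount prior term, which MAP-EM
makes non-decreasing; tests assert this monotonicity. Fixing `gamma` at 1
degenerates ZOOPS to OOPS exactly.

Two practical devices matter:

* **Phase refinement.** Plain EM cannot slide an established alignment
  sideways, so seeds that partially overlap a motif stall a column or two
  off. After convergence the matrix is shifted by ±1 column (vacated
  columns refilled with background), EM is re-run briefly, and the shift is
  kept only when the objective improves. This is the standard column-shift
  remedy for EM motif finders.
* **Width selection.** Likelihoods at different widths are not comparable,
  so the winning width in [minw, maxw] (defaults 6, 25) maximises the
  relative log likelihood minus a description-length penalty of 0.5 nats
  per column per sequence. The penalty must exceed the overfitting gain of
  a pure-background column (about (19/2)/n nats per sequence for n
  sequences) and be far below the gain of a conserved column (2–3 nats per
  sequence); 0.5 sits comfortably between.

Each motif uses 10 random subsequence-seeded restarts; the best occurrence
per sequence is masked before the next motif is fitted. A 100,000-residue
cap on the input guards the quadratic work. Scanning uses curated regex
patterns by default (P-loop `G[GAV].{2}G[KR][TS]T`, Kinase-2
`[LIVMF]{2}DD[VIML][WDR]`, RNBS-B `[GN]S[RK][ILVMF]{3}T[TS]RD?`, GLPL
`G[LIVM]PL[AG]`, MHDL `[MQ]HD[LV]`); these are package-curated defaults,
config-overridable, and fitted matrices can be scanned instead (log-odds
threshold 0, greedy non-overlap within each motif, ties to the leftmost).

## Coiled-coil and NLS signals

The coiled-coil scorer is intentionally transparent rather than a
re-implementation of a trained coiled-coil HMM: every 21-residue window is
scored under its best of 7 heptad register phases, +1 for hydrophobic
residues (L/I/V/M/F) at the core *a*/*d* positions and for polar/charged
residues (E/K/R/Q/D/N) at *e*/*g*, −1 otherwise, averaged over the 12
scored positions and mapped through a logistic (slope 12, midpoint 0.25).
The logistic constants are set so that an ideal heptad repeat scores above
0.9 and a polyproline stretch below 0.1 (both are unit tests). A CC call is
the longest run of residues at or above the 0.4 threshold, and it counts as
architectural `C` evidence only when it starts before the first NBS hit —
coiled-coils of these receptors are N-terminal.

NLS detection uses a two-state background/signal HMM over amino acids with
exact log-space decoding. The default static parameterisation — initial
(0.95, 0.05), background→signal 0.005, signal→background 0.10, signal
emissions 0.38 for K and R with the rest uniform, uniform background — is
a declared stand-in for trained basic-stretch NLS models and is
config-overridable via YAML. Viterbi mode reports maximal signal-state
runs on the best path; posterior mode reports maximal runs with
forward–backward posterior ≥ 0.5. Unknown residues (X) are emitted with
probability one by both states, i.e. they carry no information. Tests
check Viterbi against exhaustive path enumeration (all 2^n paths, n ≤ 12)
and forward/backward agreement to 1e-9.

## Cluster calling

Two consecutive NLR genes on a chromosome are linked iff the intergenic
gap (end-to-start, negatives clamped to zero) is **strictly** below 200 kb
and the number of annotated non-NLR genes strictly between them is **at
most** 8; maximal linked runs of two or more genes are clusters. Both
criteria are combined with AND, "distance" is the intergenic gap (a
start-to-start anchor is available by flag since the literature does not
pin the anchor down), and the strict/inclusive readings of the two bounds
are probed at 199,999/200,000 bp and 8/9 genes by boundary tests. The
caller is validated against a brute-force pair-linkage oracle on hundreds
of random toy genomes. Per-chromosome averages divide by the 17 placed
chromosomes; genes on unplaced scaffolds still cluster but are excluded
from per-chromosome rows.

## Ka/Ks (Nei–Gojobori with Jukes–Cantor correction)

Synonymous site counts per codon come from enumerating all nine
single-nucleotide mutants against the standard genetic code: a synonymous
mutant contributes 1/3 of a site at its position, mutations to stop codons
count as nonsynonymous, and n + s = 3 identically. Sites are averaged over
the two sequences. Codon pairs differing at 2–3 positions average their
difference counts over all minimal mutational pathways, excluding pathways
through stop codons unless every pathway passes through one. Proportions
pN = Nd/N and pS = Sd/S are corrected with K = −(3/4)·ln(1 − (4/3)p),
undefined at p ≥ 3/4 (flagged, never silently clamped). The ratio is
undefined when Ks = 0. Codons containing non-ACGT characters or stops in
either sequence are excluded pairwise.

Clade-level ω is the arithmetic mean of defined pairwise ratios, with the
count of excluded pairs reported; which pair set a survey averages over is
genuinely underdetermined in the literature, so the package makes the
all-within-clade-pairs choice explicit and treats reported clade averages
as inputs, not targets. The implementation is verified to 1e-9 against an
independent literal re-implementation and to 1e-4 against the hand-derived
single-codon case (TTT vs TTA: N = 2.5, S = 0.5, Ka ≈ 0.5716, Ks = 0).

## Expression

Size factors are the median-of-ratios estimator: factor_j = median over
all-positive genes of value_ij / geometric-mean_i. The estimator is
scale-invariant — multiplying the whole matrix by c leaves factors
unchanged and scales normalised values by c — which is the behaviour of
the standard estimator (a closed-form test pins the two-tissue
proportionality case to (1/√2, √2)).

K-means is implemented directly so the seeding semantics are exact: rows
are sorted by gene id, k distinct genes are drawn uniformly as initial
centroids, Lloyd iterations run to convergence or the 1000-iteration cap,
and empty clusters are re-seeded to the farthest points. The result is a
function of data and seed only, never of row order. The "1000 iterations"
convention is read as the per-run iteration cap, not a restart count; a
single seeded run is the default with restarts (`n_init`) available, and
the analysis driver uses 10 restarts because single-run Lloyd's can land
in a split/merge local optimum. With k = 3 the clusters are labelled by
descending mean centroid magnitude: moderate-to-minimal, minimal-to-basal,
basal-to-none.

## Synthetic data: what it emulates and what it does not

The generator builds proteins as concatenations of unit blocks dictated by
the planted subgroup code: an ideal heptad coiled-coil block, TIR and RPW8
placeholder blocks (their evidence carried by domain-table rows), an
NB-ARC block embedding the curated motifs with planted Kinase-2 and RNBS-B
signatures, and LRR blocks with an exact number of `LxxLxxLxx` units.
Linkers draw from an alphabet excluding L, D, W (no spurious LRR or
Kinase-2 signals), I/V/M/F (no spurious coiled-coil cores) and K/R (no
spurious NLS stretches), which makes planted truth exact rather than
probabilistic. The default blueprint plants 352 genes in the survey-scale
subgroup proportions, 75 clusters holding 200 genes (25 clusters / 73
genes on chromosome 13, none on chromosomes 5 and 12), group exon-count
means 2.7/6.1/6.2/2.9 (shifted-Poisson), a handful of genes on an
unplaced scaffold, and a 52,243-protein proteome denominator. Planted
clusters satisfy both criteria with margin (gaps 20–150 kb, ≤ 3
intervening genes); everything else is separated by ≥ 250 kb.

Codon-pair clades share a random sense-codon ancestor; the derived copy
receives Poisson numbers of synonymous and nonsynonymous single-nucleotide
codon changes whose expectations match the Jukes–Cantor-implied
proportions of the target Ks (default 0.2) and ω·Ks. No codon is hit
twice and no stops are created, so realised difference counts are exact.
Expression matrices plant three level classes (means 20 / 0.3 / 6, sizes
13 / 43 / 15, log-normal noise σ = 0.2); the class means were chosen to be
separable under *Euclidean* K-means, because multiplicative noise on a
high-mean class otherwise makes Lloyd's prefer splitting it over
separating the two low classes.

Because blocks are clean and linkers are adversarially letter-free, a
perfect recovery on synthetic data demonstrates the correctness of the
rules, not robustness to real-world noise: degraded domains, partial
repeats, compositionally biased linkers and fragmented gene models are all
absent. Conversely, any failure on this data is a genuine defect.

## Numerical choices and degenerate inputs

All HMM and EM arithmetic is in log space. EM convergence is a relative
objective change below 1e-6; K-means stops on unchanged assignments.
Overlap resolution everywhere is greedy by descending score with ties to
the leftmost start, making outputs deterministic. Empty inputs return
empty outputs with warnings where the condition is legal (empty FASTA,
no-cluster genomes) and errors where it is not (no comparable codons, no
all-positive gene for size factors, zero proteome size). All randomness
flows from explicit integer seeds; the pipeline derives per-stage seeds
from one root seed by hashing.

## Known limitations

* The coiled-coil scorer is a propensity heuristic; it separates clean
  positives from clean negatives but has not been calibrated against real
  coiled-coil annotations.
* The NLS model's parameters are declared defaults, not trained values.
* Exon statistics assume one primary transcript per gene (the mRNA with
  the most exons, ties by file order) and that gene and protein
  identifiers coincide.
* Ka/Ks uses the standard genetic code only and the unweighted
  Nei–Gojobori pathway average; no transition/transversion weighting or
  maximum-likelihood codon model is provided.
* Clade membership for Ka/Ks averaging is an input; the package does not
  reconstruct phylogenies.
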