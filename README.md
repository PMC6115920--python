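# nlrscan

Desk-scale reimplementation of a genome-wide **NBS-LRR (NLR) resistance-gene
survey** for plant genomes: identification of NBS-encoding proteins from
domain evidence, classification into the CNL / TNL / RNL / NL groups and
their letter-code subgroups, physical gene-cluster calling, Nei–Gojobori
Ka/Ks, conserved-motif discovery and signal decoding, and tissue-expression
clustering. A synthetic-genome generator with planted ground truth stands in
for a real multi-gigabase genome, so every stage runs — and is validated end
to end — in seconds on a laptop.

It is aimed at people who study plant disease-resistance gene families and
want a small, fully tested, reproducible version of the standard survey
workflow, with every rule stated explicitly and checkable against planted
truth.

## What it computes

**Domain-architecture classification.** Each protein with an NB-ARC (NBS,
Pfam PF00931) domain receives an ordered letter string over
{C, T, R, N} from its domain hits (coiled-coil, TIR PF01582, RPW8 PF05659,
NBS), plus a trailing `L` when LxxLxxLxx leucine-rich-repeat signatures are
present. Group membership follows domain dominance T > R > C — any TIR makes
a TNL (so CTNL/CTN sit in the TNL group), any RPW8 without TIR an RNL
(covering RCNL), any coiled-coil alone a CNL, and bare architectures are NLs.
Subgroups are the 18 letter codes (CNL, CN, CNNL, CNN, RNL, RN, RCNL, TNL,
TN, TNNL, TTNL, TNLTNL, CTNL, CTN, N, NL, NN, NNL). NL-group genes are
subtyped by their Kinase-2 signature: `DDVW` marks the CC lineage (N_CC),
`DDVD` the TIR lineage (N_TIR).

**Cluster calling.** Two consecutive NLR genes on a chromosome are linked iff
the intergenic gap is < 200 kb **and** at most 8 annotated non-NLR genes lie
between them; maximal linked runs of ≥ 2 genes are clusters.

**Ka/Ks.** Nei–Gojobori (1986) with equal pathway weighting and Jukes–Cantor
correction: per-codon synonymous site counts from all nine single-nucleotide
mutants, differences averaged over minimal mutational pathways (stop-codon
pathways excluded), and

K = −(3/4)·ln(1 − (4/3)·p)

applied to pN and pS separately. ω = Ka/Ks < 1 indicates purifying
selection.

**Signals and motifs.** A two-state (background/signal) HMM with exact
log-space Viterbi and forward–backward posterior decoding detects
K/R-rich nuclear-localization signals (0.5 posterior cutoff); a
heptad-register propensity profile scores coiled-coils (0.4 threshold,
N-terminal to the NBS domain); ZOOPS expectation–maximization discovers
NB-ARC motifs (P-loop, Kinase-2, RNBS-B, GLPL, MHDL) de novo, with curated
regex patterns as the scanning default.

**Expression.** Median-of-ratios size factors (the DESeq estimator) followed
by seeded K-means (k = 3, Euclidean, ≤ 1000 iterations) labels genes as
moderate-to-minimal, minimal-to-basal, or basal-to-none expression.

## Worked example

The numbered drivers under `analysis/` run the whole survey on the default
synthetic genome (352 NLR genes in realistic subgroup proportions, 75
planted clusters on 17 chromosomes, a 52,243-protein proteome denominator):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_identify_classify.py --seed 1
python analysis/03_clusters.py --seed 1
python analysis/04_kaks.py --seed 1
python analysis/05_expression.py --seed 1
python analysis/06_report.py --seed 1
```

which prints, step by step:

```
planted 352 NLR genes: {'CNL': 100, 'RNL': 13, 'TNL': 77, 'NL': 162}
planted 75 clusters holding 200 genes
...
subgroup recovery: 352/352; Kinase-2 signature recovery: 352/352
75 clusters holding 200 of 352 NLR genes (56.8% clustered)
2.7 genes/cluster, 4.4 clusters/chromosome
chromosome 13: 25 clusters, 73 genes
CNL: target omega 0.68, recovered 0.650 (50 pairs, 0 excluded)
TNL: target omega 0.89, recovered 0.877 (50 pairs, 0 excluded)
RNL: target omega 0.31, recovered 0.335 (50 pairs, 0 excluded)
clustered 71 genes into expression levels: {'basal-to-none': 43,
  'minimal-to-basal': 15, 'moderate-to-minimal': 13}
total NBS-encoding genes: 352 (0.67% of the proteome)
CNL:TNL ratio: 1.3:1
```

Every number above is computed, not asserted: the classifier recovers all
352 planted subgroup codes from sequence and domain evidence alone, the
cluster caller finds exactly the planted clusters, and the Ka/Ks estimator
recovers the simulated selection intensities within sampling noise.

The same stages are available as a CLI (`nlrscan synth / identify /
classify / cluster / kaks / express / report / run`) driven by a YAML
config; intermediate tables are plain TSV throughout.

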