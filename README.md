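# crstool

A toolkit for discovering and characterising conserved RNA secondary
structures in multiple alignments:

* **pscore** — a three-model phylogenetic ranking statistic for
  structure-annotated alignments. Every consensus base pair is scored (in
  bits) under a 16-state reversible pair model against two single-nucleotide
  alternatives — a conserved unstructured model and a faster neutral /
  misaligned model — with column likelihoods computed by Felsenstein pruning
  on a tree with branch lengths. Pair contributions are weighted by
  equilibrium base-pair probabilities from a partition-function recursion,
  and the final score is the minimum of the two total log-odds, so a
  structure must beat *both* alternatives.
* **null model and FDR** — dinucleotide-preserving shuffles (Eulerian-walk
  construction), joint column shuffles and GC-matched phylogenetic
  re-simulation provide null alignment ensembles; false-discovery rates are
  estimated per GC bin and score threshold as the clipped null/real call
  ratio, so score thresholds can be calibrated at a target FDR.
* **downstream statistics** — midpoint-overlap enrichment Z-tests stratified
  by GC content and sequence identity with BH correction, one-sided Fisher
  tests for cross-species conserved sites, the purifying-selection ratio rule
  (both ratios < 0.95), empirical-p expression calls with CPM/RLE
  normalization, CaptureSeq read-island calling (150-nt unified reads),
  exosome-sensitivity stability classes, and structure-probing pairing calls
  (log2 fold change with pseudo-count 5, paired at lfc > 1) with concordance
  against a consensus structure.
* **synthetic fixtures** — seeded generators for alignments evolved on a tree
  with compensatory substitutions at paired columns, negative-binomial count
  matrices and probing count profiles, so the whole pipeline is testable
  offline.

## CLI

All functionality is exposed under a single `crstool` entry point:

```bash
crstool stats  --aln block.sto                       # GC / SI / size summary
crstool filter-blocks *.sto --classes classes.tsv \
        --anchor human --min-len 60 --min-nonprimates 3
crstool bpp    --fasta seqs.fa                       # base-pair probabilities
crstool score  --aln block.sto --tree tree.nwk [--params models.yaml]
               [--threshold T] [--both-strands]
crstool null   --aln block.sto --tree tree.nwk --mode shuffle|evolve \
               --replicates 10 --seed 7 --out-dir nulls/
crstool fdr    --real real.tsv --null null.tsv --bins 0,0.2,0.4,0.65,0.8,1.0
crstool enrich --crs crs.bed --features f.bed --windows windows.tsv
crstool fet    --table 30,10,10,30
crstool dist   --seqs ACGU... ACGC...
crstool fit-gtr --aln block.sto --tree tree.nwk
crstool express --counts counts.tsv --background bg.tsv
crstool islands --reads reads.bed --repeats rep.bed --probes probes.bed
crstool stability --exo 8 --ctr 2
crstool probing --native n.tsv --denatured d.tsv [--structure s.sto]
crstool synth  aln|counts|probing --seed 3 --out dir/
```

Model parameters for `crstool score` are a YAML mapping with keys `pi`
(stationary frequencies per base), `exch` (six GTR exchangeabilities),
`rho` (neutral rate multiplier > 1) and `stacking_bias` (per canonical pair).
The default is a Jukes–Cantor backbone with canonical-pair stationary bias
(8 for Watson–Crick pairs, 3 for GU/UG) and rho = 4.

## Scores and thresholds

pscores are reported in bits and are *not* on the same scale as any
previously published cutoff; calibrate thresholds against a null ensemble at
a target FDR (`FDRTable.threshold_at_fdr`), which is what `crstool fdr`
supports.

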