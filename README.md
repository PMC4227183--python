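# crackseq

Differential expression and annotation for **two-library RNA-Seq designs
without replicates**, as used in de novo transcriptome studies that compare
one pooled library per condition — the motivating case being litchi
pericarp from cracking vs non-cracking fruit, screened for candidate
fruit-cracking genes.

## Who this is for

Analysts with (a) a de novo unigene assembly (FASTA), (b) one read-count
table covering two libraries, and optionally (c) BLASTx-style annotation
hit tables against NR / Swiss-Prot / KEGG / COG / GO. The package computes
expression levels, calls differentially expressed genes (DEGs), merges
annotations by database priority, and classifies DEGs into candidate
mechanism pathways by gene-family keywords. A synthetic-data module
generates complete datasets with known ground truth so the whole pipeline
is testable without external data.

## The statistic

With library totals N1, N2 (clean reads mapped to all unigenes) and
per-gene counts x (library 1) and i (library 2), the significance of a
count difference is based on

```
p(i | x) = (N2/N1)^i * (x+i)! / (x! i!) / (1 + N2/N1)^(x+i+1)
```

the probability of observing i reads in library 2 given x in library 1
under Poisson sampling — equivalently the negative-binomial mass with size
x+1 and success probability N1/(N1+N2). The two-sided p-value is
`min(1, 2*min(P(I<=i|x), P(I>=i|x)))`, adjusted across all genes by
Benjamini–Hochberg step-up FDR. Expression is normalized as RPKM
(`1e9*count/(N*length)`); fold change is the RPKM ratio with 0.001
substituted for exact zeros. A gene is a DEG when FDR <= 0.001 and
|log2 ratio| >= 1 (both inclusive, both configurable).

## Worked example

Simulate a two-library experiment (2,000 genes, 1M reads per library, 5%
of genes truly differential at four-fold, every differential gene given an
annotation carrying a candidate-family keyword), then run each stage:

```
$ crackseq simulate --genes 2000 --depth1 1000000 --depth2 1000000 \
    --de-fraction 0.05 --fc 4 --seed 42 --candidate-fraction 1.0 --out-prefix sim
wrote sim.counts.tsv .lengths.tsv .truth.tsv .fasta .hits.tsv (n1=1000000, n2=1000000)

$ crackseq deg --counts sim.counts.tsv --lengths sim.lengths.tsv --out deg_results.tsv
99 DEGs (50 up, 49 down) of 2000 unigenes

$ crackseq annotate --hits sim.hits.tsv --out merged.tsv
2000 unigenes annotated

$ crackseq candidates --deg deg_results.tsv --merged merged.tsv --rules rules.tsv --out candidates.tsv
99 candidate DEGs
  water transport       25
  GA metabolism 14
  ABA metabolism        24
  Ca transport  16
  cell wall metabolism  20
```

Of the 100 truly differential genes, 99 are called at the default
thresholds (the one miss is a low-abundance gene) and every called DEG is
recovered into the pathway whose keyword its annotation carries. The
per-gene statistic is also available directly:

```
$ crackseq pvalue --x 0 --i 60 --n1 1000000 --n2 1000000
point_prob      4.33680868994e-19
lower_tail      1
upper_tail      4.33680868994e-19
two_sided_p     8.67361737988e-19
```

`deg_results.tsv` holds one row per unigene:

```
unigene_id      rpkm_sample1    rpkm_sample2    log2fc  p_value fdr     is_deg  direction
Unigene_00001   719.901 615.455 -0.226144       0.0201333       0.143297        false   none
Unigene_00002   118.725 128.498 0.114122        0.623198        0.830108        false   none
```

The same workflow is available programmatically (`crackseq.simulate_counts`,
`crackseq.call_degs`, `crackseq.merge_annotations`,
`crackseq.classify_candidates`) and as one `crackseq run --config run.yaml`
invocation that writes all tables plus a reproducibility manifest.

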