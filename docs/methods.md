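# Methods

## Model and procedure

The pipeline targets the classic two-library digital-gene-expression
design: one pooled sequencing library per condition, no biological
replicates. Under Poisson sampling of reads, the count i of a gene in
library 2 given its count x in library 1 and library totals N1, N2 follows

    p(i|x) = r^i (x+i)! / (x! i!) / (1+r)^(x+i+1),   r = N2/N1,

the posterior predictive of a Poisson rate under a flat prior —
identically the negative binomial with size x+1 and success probability
N1/(N1+N2). This is exact for Poisson noise and makes no allowance for
biological variability between replicate libraries; with only one library
per condition that variance is not estimable, which is the central caveat
of the design. Significance statements therefore concern sampling noise
only.

Pipeline order: assembly summary → expression/DEG calling → annotation
merge → candidate classification. Each stage is a pure function over
tables and is exposed both as a library call and a CLI subcommand.

## Statistical choices

* **Sidedness.** The two-sided p-value is min(1, 2·min(lower, upper)),
  where both tails include the observed point mass. For a discrete
  statistic this construction is conservative (the attainable p-value
  nearest a level α generally falls below it), so empirical null rejection
  fractions sit at or slightly below nominal. It is also not exactly
  invariant under exchanging the two libraries, because the statistic
  conditions on the library-1 count; the asymmetry vanishes at moderate
  counts and never changes which tail is extreme. One-sided tails remain
  available via `ac_tail_probs`.
* **Multiplicity.** Benjamini–Hochberg step-up FDR over all tested
  unigenes jointly (delegated to statsmodels, validated in-suite against a
  from-definition implementation). Rows with x = i = 0 are assigned
  p-value 1 and kept, which cannot lower any other gene's adjusted value
  and keeps row alignment trivial.
* **Zero-substitution.** Fold change uses 0.001 in place of a zero RPKM,
  per-value, before the ratio. The substitute is configurable because its
  effect scales with sequencing depth: at greater depths a zero RPKM is
  stronger evidence and a smaller substitute may be preferred.
* **Thresholds.** Defaults FDR ≤ 0.001 and |log2fc| ≥ 1, both inclusive.
  A DEG with log2fc exactly 0 (possible only when the fold-change
  threshold is 0) is reported without a direction.

## Numerics

The point probability is evaluated in log space via log-gamma; counts up
to at least 1e6 neither overflow nor underflow. Tail sums pick the cheaper
side: the lower tail is summed directly when the observed count is below
the distribution bulk, otherwise the upper tail is accumulated in 16k-term
blocks until a geometric remainder bound (successive-term ratio
r(x+i+1)/((i+1)(1+r)) < 1 past the mode) falls below 1e-15 of the running
total; the other tail is obtained by complement plus the point term.
Results are clipped to [0,1]. The test suite checks the implementation
against exact rational arithmetic (fractions + binomial coefficients) on
all x, i ≤ 40 across depth ratios, against scipy's independent
negative-binomial pmf, and for mass normalization at x ≤ 50 within 1e-9.

Percentages in summary tables round half-up to two decimals, and mean
lengths half-up to integers, matching how such tables are conventionally
printed; Python's banker's rounding is deliberately avoided (Decimal
quantization throughout).

## Synthetic data

`simulate_counts` draws per-gene relative abundances log-normal(μ=0, σ=1),
marks a configurable fraction of genes differential by multiplying their
library-2 abundance by the fold change (alternating up/down across the
chosen genes so both directions occur), renormalizes abundances to the two
configured depths, and draws Poisson counts. Defaults mirror the
motivating experiment: depths 25,867,380 and 29,444,512 reads, 46,641
genes, unigene lengths uniform on [200, 1700] bp (mean ≈ 950), 5%
differential at four-fold. Tests and the acceptance script use 1e5–1e6
read depths and 2,000–20,000 genes, which preserve the per-gene count
regime (tens to hundreds of reads) at a fraction of the cost.

What the generator does **not** emulate: overdispersion between biological
replicates (intentional — the statistic is exact only under Poisson),
mapping ambiguity and multi-mapped reads, length-dependent count bias
within a library, assembly artifacts, and correlated annotation errors.
Passing simulation tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness of the design
to biological variance.

`simulate_annotations` gives a chosen fraction of truly differential genes
an NR description embedding a candidate-family keyword (each default rule
carries an `example` token guaranteed to match its own pattern); all other
genes receive generic descriptions verified not to match any default rule.
E-values are log-uniform in [1e-50, 1e-6], below the 1e-5 filter.

## Annotation and classification

Hits are filtered at E-value < 1e-5 (strict inequality), then one
description per unigene is adopted: highest-priority database with any hit
(NR > Swiss-Prot > KEGG > COG > GO by default), best E-value within it,
with description and database name as deterministic final tie-breaks so
the merge is independent of input order. Category summaries support two
denominators — distinct classified unigenes (the COG/KEGG reporting
convention; percentages can exceed 100 in sum because one unigene may
carry several categories) or total assignments (GO-figure convention,
sums to 100 up to rounding) — because published reports mix the two bases.

Candidate classification matches case-insensitive regular expressions
against the adopted description only (one function per unigene), in rule
order, first match wins, so each DEG is assigned at most once. The shipped
default rules encode the gene families of the five fruit-cracking
pathways: water transport (PIP, NIP, SIP, AQP), GA metabolism (KS, GA2ox,
GID1), ABA metabolism (CYP707A, glucosyltransferase, β-glucosidase, PP2C,
ABI1, ABI5), Ca transport (TPC, CAX, Ca²⁺-ATPase, CDPK, CBL) and cell
wall metabolism (PG, EG, PE, EXP, β-galactosidase, XET). Specific family
acronym rules precede broad keyword rules within a pathway (e.g. PIP
before the generic aquaporin rule) so the finer label is preferred.

## Degenerate inputs and validation

Counts must be integral (integral-valued floats are narrowed, fractional
values rejected — the formula takes factorials of counts); duplicate
unigene ids, counts exceeding library totals, missing lengths and unknown
databases are hard errors naming the offender. Genes absent from the
count table are treated as absent, not zero. The full-pipeline driver
removes partial outputs on any stage failure and writes a manifest
(config, input SHA-256 checksums, version) sufficient to re-execute a run
identically.

## Known limitations

* No replicate-aware dispersion modeling; results from this design should
  be treated as a screen, to be validated (e.g. by qRT-PCR) rather than as
  confirmatory inference.
* Keyword classification inherits the annotation's vocabulary; families
  described with unusual synonyms need user-supplied rules.
* Combining two per-sample assemblies into a joint unigene set (a
  clustering step) is out of scope; the pipeline takes one unigene set as
  given.
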