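# Methods

This note records the models and procedures `coexbench` implements, the
parameter and numerical conventions it fixes, and the design choices
made where more than one reasonable convention exists.

## Pipeline

Every workflow processes a non-negative gene-by-sample count matrix in a
fixed stage order:

1. **within-sample normalization** (none | CPM | TPM | RPKM),
2. **between-sample normalization** (none | QNT | TMM | UQ | CTF | CUF),
3. **asinh transformation** (always),
4. **Pearson (or Spearman) correlation** between all gene pairs,
5. **network transformation** (none | CLR | WTO).

Within-sample normalization rescales counts away from the raw scale, so
the count-factor methods cannot follow it: with a non-trivial
within-sample step, the between-sample step must be `none` or `qnt`.
The matrices carry a unit-provenance chain and the factor estimators
reject already-normalized input, so incompatible compositions fail
loudly. The valid space is (1·6 + 3·2) pairs × 3 transforms = **36
workflows**.

### Count preprocessing

Base-pair-per-gene quantifications are converted to read counts by
dividing by the sample's average read length, and by a further factor of
two for paired-end samples (two mates of one fragment contribute base
pairs). Fractional counts are kept as reals — downstream normalizations
are scale-based and rounding would discard information.

Quality filters, in order: optional restriction to long-RNA biotypes
(protein-coding, lncRNA, antisense; genes absent from the biotype table
are conservatively dropped); removal of samples with zero counts in at
least half the genes (inclusive bound); removal of datasets left with
fewer than five samples (a `strict_sample_qc` flag instead discards any
dataset that lost a sample); and a corpus-wide expression floor — a gene
is kept everywhere if, in at least one dataset, it reaches ≥ 1 CPM in at
least 20% of samples (both bounds inclusive). All filters are
idempotent and order-stable within a stage.

### Normalization conventions

* **CPM** count / library size × 1e6. **TPM** divides by gene length in
  kb first, then scales each column of rates to 1e6 (every sample gets
  the same total); **RPKM** corrects library size first, then length, so
  column sums are not fixed.
* **QNT** (quantile normalization): each value is replaced by the mean
  across samples of the values at its rank; tied values within a sample
  receive the mean of the rank-means they jointly occupy. Sorted
  columns are identical afterwards and the map is idempotent.
* **TMM**: the reference sample is the one whose 75th percentile of
  count/library-size is closest to that statistic's cross-sample mean.
  For each sample against the reference, genes with positive counts in
  both contribute a log2 fold-change M and average log2 intensity A.
  The top and bottom 30% by M *and* 5% by A are discarded using rank
  thresholds (floor(n·f)+1 … n−floor(n·f), average ranks, boundary ties
  kept), and the factor is 2 to the weighted mean of surviving M values
  with inverse-delta-method-variance weights
  1 / [(N_k−y_k)/(N_k y_k) + (N_r−y_r)/(N_r y_r)]. A test cross-checks
  the factors against edgeR's `calcNormFactors` (agreement ~1e-10).
* **UQ**: after removing genes with zero counts in *all* samples, the
  factor is the sample's 75th-percentile count divided by its library
  size. Percentiles use linear interpolation between order statistics
  (the common statistical default) — percentile dialects change UQ
  factors, so this choice is fixed and oracle-tested.
* Factors are **geometric-mean centered** (product exactly 1) and then
  applied either as effective library sizes (TMM/UQ: CPM with
  N_k·factor_k) or as a direct divisor of counts (CTF/CUF). The two
  applications differ exactly by the per-sample multiplier 1e6/N_k,
  which is *not* a no-op for correlation: it changes values before the
  non-linear asinh, so TMM and CTF networks genuinely differ.
* **asinh** is applied in every workflow, including plain counts. It
  compresses like a log but is defined at zero, so no pseudocount is
  needed.

### Network construction and transformation

Networks are dense symmetric matrices over the gene set with zero
diagonal. Gene pairs involving a zero-variance gene get weight 0 (the
correlation is undefined; zero keeps the network total and evaluable,
and a warning reports the count). Spearman uses average ranks for ties.

* **CLR**: per gene i, the mean μ_i and standard deviation σ_i of its
  n−1 edge weights (population denominator over those n−1 values);
  z_i(j) = max(0, (w_ij − μ_i)/σ_i); output √(z_i(j)² + z_j(i)²). Genes
  with σ_i = 0 contribute z ≡ 0. Output is ≥ 0.
* **WTO** (sign variant by default): with signed adjacency a and
  connectivity k_i = Σ|a_iu|,
  ω_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − |a_ij|).
  With signed input the output lies in [−1, 1] and *can be negative*;
  descriptions of WTO as bounded by zero and one hold only for the
  absolute-value variant, which is also provided. We do not clamp.

Both transformations are verified against independent loop-based
implementations to 1e-10 on random fixtures.

### Gold standards

Positives are unordered gene pairs co-annotated to at least one
"specific" GO Biological Process term, using experimental (EXP, IDA,
IPI, IMP, IGI, TAS) or curated (IC) evidence; IEP (inferred from
expression) is always excluded to avoid circularity, and NOT-qualified
annotations are dropped. Candidate negatives are the remaining pairs
among positive-bearing genes; a candidate stays unlabeled when its genes
sit in two different specific terms whose gene sets overlap
significantly (hypergeometric upper tail, raw p < 0.05 — no
multiple-testing correction, by design), or when the pair is
co-annotated to a curated "general" term. The hypergeometric universe
is the number of distinct annotated genes. The specific/general term
lists are user-supplied curation; the package ships none.

Annotations are used exactly as given — no propagation up the GO graph
is performed. Callers who want propagated co-annotation can propagate
before building the annotation set; term→gene-set semantics make this
composition transparent.

Tissue-aware standards keep a positive iff both genes are expressed in
the tissue, and a negative iff both genes are in the tissue or one is in
the tissue and the other is expressed in some other considered tissue
(the asymmetric rule reflects that a pair with one gene absent from the
tissue is a safe non-interaction there only if the other gene is known
to be expressed somewhere). Standards with fewer than 50 positives are
rejected (returned as `None`), not an error.

### Evaluation

Only gold-standard pairs are scored; unlabeled network edges are
ignored. Pairs are sorted by weight descending, with one confusion row
per distinct weight (ties enter together — deterministic and
order-independent). auPRC integrates precision over recall by the
trapezoidal rule, anchoring the curve at recall 0 with the precision of
the highest-threshold row (no artificial (0, 1) point). auROC
integrates TPR over FPR anchored at (0, 0). Precision at recall r is a
step function: the first row whose recall reaches r. The headline
statistic log2(auPRC/prior) equals 0 for a random ranking and
−log2(prior) for a perfect one, making scores comparable across
standards with different priors.

### Comparison statistics

For each ordered workflow pair, the win proportion is the fraction of
shared datasets where the first workflow scores higher (ties count
half). Significance uses a one-sided paired Wilcoxon signed-rank test:
zero differences are discarded (all-zero gives p = 1); up to 25 non-zero
differences the exact null is computed by enumerating all 2^n sign
assignments (as a dynamic program over tie-averaged ranks, so tied
differences are handled exactly); beyond that, the normal approximation
with continuity correction. Benjamini-Hochberg correction is applied
across all ordered pairs of one evaluation setting (one corpus × one
gold-standard kind), significant at FDR ≤ 0.01 by default.

Method impact is the proportion of (workflow-with-method vs.
workflow-without-method) comparisons that are significant wins, with
fairness exclusions: between-sample methods are judged only on workflows
without within-sample normalization, and within-sample methods (and
"none") only on workflows without count-factor between-sample methods,
because those combinations are structurally impossible.

Experimental-factor utilities: sample similarity is the median Spearman
correlation over all sample pairs using the top half of genes by count
variance (ties in the variance ranking broken by gene ID for
determinism); read-count diversity is the n−1 standard deviation of
per-sample count sums; equal-size binning sorts by value with ID
tie-break and gives the remainder to the lowest bins. The resampling
design draws, from every source dataset with ≥ 70 samples, 10
without-replacement subsets at each of the sizes
5, 6, 7, 9, 11, 13, 16, 25, 40; each (source, size, replicate) cell has
its own generator substream derived from the master seed, so the design
is reproducible under parallel or partial execution.

## Synthetic data

The generator emulates what the benchmark assumes about real data:
overdispersed counts, library-size variation, and functionally coherent
modules. Per sample j and module m, a latent activity a_mj ~ N(0,1);
a member gene's mean is μ_gj = depth · s_j · b_g · exp(β a_mj − β²/2)
(the −β²/2 keeps expected depth stable), with log-normal library factors
s_j (mean 1) and log-normal relative baselines b_g; counts are negative
binomial with variance μ + φμ². Defaults — 300 genes, 6 modules of 10,
50 samples, mean depth 3e5 (~1000× mean gene coverage), library sigma
0.35, β = 1, φ = 0.2 — describe a small but realistic bulk experiment;
φ = 0.2 is a typical bulk-tissue dispersion scale and is a fixture
choice, not an estimate from any dataset. Modules are disjoint, so the
planted gold standard (within-module pairs positive, cross-module pairs
negative, background unlabeled) is unambiguous, with prior
Σ_m C(s,2) / (Σ_m C(s,2) + cross-module pairs).

What the generator does **not** emulate: batch effects, GC and
gene-length bias in counts, isoform structure, correlated module
activities, and the mean-correlation relationship of real expression
compendia. Passing tests therefore demonstrate correctness and internal
calibration of the machinery, not that any workflow ranking measured
here transfers to real corpora.

## Numerical choices and edge cases

* Percentiles: linear interpolation (NumPy default), everywhere.
* Ranks: average ties, everywhere (rank-based trimming, Spearman,
  quantile normalization, signed-rank test).
* TMM with no co-expressed genes or fully trimmed sets falls back to
  factor 1 with a warning; a zero 75th-percentile library is a hard
  error for UQ.
* Zero-variance genes: correlation 0 (warned), CLR z ≡ 0 for
  constant-edge genes (warned).
* Evaluation sweeps drop (and count) standard pairs whose genes are
  absent from the network.
* Calibration checks of "random ranking scores at the prior" are run at
  problem sizes in the estimator's asymptotic regime: the trapezoidal
  auPRC of a random ranking has a positive finite-size bias of order
  1/(number of positives), so the property is tested on a complete
  480-gene random network (~115k labeled pairs), where the bias is well
  inside the Monte-Carlo tolerance. Smaller fixtures are used only for
  exact, non-asymptotic identities.
* All simulation-based tests and the acceptance script use fixed or
  CLI-provided seeds; outputs are bit-reproducible for a given seed.

## Known limitations

* Variance-stabilizing transforms fitted per dataset (VST/rlog-style)
  are out of scope; asinh is the only data transformation.
* CLR here operates on correlation networks; the mutual-information CLR
  of the original regulatory-network literature is not implemented.
* Gold-standard curation (choosing specific/general terms, tissue
  expression calls) is an input, not a capability of the package.
* Dense network storage targets ≤ ~25k genes; larger gene universes
  would need a chunked or sparse backend.
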