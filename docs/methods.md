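# Methods

## The diallel model and its estimators

A half diallel crosses p inbred parents in all p(p−1)/2 unordered pairs
(no reciprocals). Cell means follow the fixed-effects (Model I)
decomposition x_ij = μ + g_i + g_j + s_ij, with parent selfs
x_ii = μ + 2g_i + s_ii when they are phenotyped. Two estimators are
provided:

* **Method 2** (parents + one set of F1s; the default, because the
  design this package targets phenotypes parents alongside their
  hybrids): μ̂ = 2G/(p(p+1)); ĝ_i = (T_i + x_ii − 2G/p)/(p+2);
  ŝ_ij = x_ij − (T_i + x_ii + T_j + x_jj)/(p+2) + 2G/((p+1)(p+2)),
  where T_i is the symmetric row sum (self counted once) and G the total
  over distinct cells.
* **Method 4** (crosses only): μ̂ = 2x··/(p(p−1));
  ĝ_i = (p·x_i· − 2x··)/(p(p−2)); ŝ_ij = x_ij − μ̂ − ĝ_i − ĝ_j.

Both satisfy Σĝ = 0 exactly. The identifying restrictions differ: Method
4 imposes Σ_{j≠i} s_ij = 0 per parent; Method 2 imposes
Σ_j s_ij + s_ii = 0 per parent (the self enters its own restriction
twice). The test suite verifies each closed form against a brute-force
least-squares solve restricted to the null space of the constraint
matrix, on random tables with p from 3 to 8, to 1e-8.

Cell means aggregate replicate plots two-stage and unweighted — mean
over replicates within an environment, then mean over environments — and
no genotype-by-environment term is modeled, matching a design that
reports a single GCA score per parent and trait. Reciprocal records are
pooled into one unordered cell.

Parent–F1 phenotype correlation takes its pairing explicitly, because
the natural pairing is genuinely ambiguous: the default pools
z-standardized traits across a parent's crosses, pairing each hybrid
value with the **co-parent's** self phenotype (a parent's own phenotype
is constant across its crosses and would contribute no variance
per-trait); per-trait pairing and self-side pairing remain available.
With 4 crosses × 3 traits the pooled scheme yields n = 12 pairs, the
sample size at which correlations near 0.97–0.99 produce p-values in the
1e-7 to 1e-10 range.

## Count model and differential test

RPKM = 10⁹·C/(N·L) with L the gene-body length (end − start in 0-based
half-open coordinates). The same gene-body normalization is used for RNA
and for ChIP marks with gene-body-wide distributions (H3K36me3,
H3K27me3); exon-union lengths are deliberately not used because the
intended RNA input is nuclear hnRNA, which covers introns.

The two-library test conditions on the count x in one library:
p(y|x) = (N₂/N₁)^y (x+y)!/(x! y! (1+N₂/N₁)^(x+y+1)), which is the
negative-binomial pmf NB(x+1, N₁/(N₁+N₂)). Tail probabilities are
evaluated through the regularized incomplete beta function (exact,
O(1) per gene); the suite checks them against direct log-space summation
of the pmf. Two-sided p doubles the smaller tail, capped at 1 — a
documented convention, since the original formulation is one-sided. Note
that the test is *not* swap-symmetric: conditioning on x differs from
conditioning on y by a discreteness term (p(0,1) = 1.0 vs
p(1,0) = 0.5 at equal libraries), vanishing as counts grow; the exact
identity is N₂·p(y|x;N₁,N₂) = N₁·p(x|y;N₂,N₁).

A gene is differential when fold change > threshold (strictly; default
2) **and** BH q < threshold (default 0.05 for expression, 0.001 for
chromatin). Fold changes are ratios of count/library-size, no
pseudocount: one zero count gives infinite fold change (the gene passes
the fold criterion and the exact test decides), and genes at zero in
both samples are excluded from testing. The BH family is all genes
tested for that sample pair. A flag switches the significance criterion
to raw p for sensitivity analyses. No replication is assumed — each
library is a single pooled sample — so dispersion cannot be estimated
from the data; the test is exact under Poisson sampling and
anti-conservative under strong overdispersion, which is why the fold
gate matters in practice.

## Trio classification and bias summaries

With differential calls of F1 against each parent, a tested gene is:
non_deg (neither significant); equal to the *non*-significant parent
(exactly one significant); over_parents (both significant, F1 RPKM
strictly outside the parental range); or between_parents (both
significant, inside the range — boundary-equal values count as inside).
`closer_parent` uses |log₂| ratio distance with ε = half the smallest
nonzero RPKM substituted only when a zero is involved, because real
expression tables contain exact zeros.

Denominators are always reported alongside fractions: per-parent
similarity is over genes expressed in the hybrid (RPKM > 0 by default;
expressed-but-untested genes count as similar), the DEG fraction over
tested genes, category fractions over differential trio genes, and the
two-way parental bias over equal-to-one-parent genes.

Sample clustering uses 1 − Pearson correlation of log₂(RPKM+1) profiles
with average linkage; samples are sorted lexicographically first so leaf
order is deterministic, and the tree serializes to Newick.

## Synthetic data: what it emulates and what it does not

The generators encode the study design so recovery is a meaningful test:

* **Diallel**: p = 5 parents, three traits, 3 environments × 3
  replicate plots; SCA effects drawn once per cross (sd 1.0 trait
  units), plot error per record (sd 2.0, and 0.25×range(g) in the
  recovery runs — "moderate noise" relative to GCA spread). True g
  vectors span ±6 cm-scale units. No field-plot variance is published
  for the motivating design, so these are free, realistic choices.
* **Trio counts**: negative binomial with var = m + d·m² (Poisson at
  d = 0); default dispersion d = 0.01, appropriate for libraries pooled
  from replicate plots (technical-scale overdispersion) rather than
  biological replicates. Expected RPKM is log-normal (median 10,
  σ = 1); gene lengths uniform on 500–5000 bp; default library size
  10⁷. Differential genes separate the parents by 8-fold, direction
  random per gene — a necessary realism: were one parent uniformly
  higher, the parental log profiles would be perfectly correlated and
  clustering could never distinguish them.
* **Category placement** is chosen for identifiability under the strict
  2-fold rule: equal-to-parent genes sit exactly on a parent;
  out-of-range genes sit at 4× beyond the nearer extreme (2× would put
  the expected fold exactly on the decision boundary and randomize the
  call); intermediate genes sit at the **geometric** mid-parent, which
  is >2-fold from both parents whenever the parental fold exceeds 4 —
  an arithmetic mid-parent can never exceed 2-fold from the higher
  parent (2R/(R+1) < 2 for any ratio R) and would make the category
  undetectable by construction.
* **ChIP**: a modified fraction (default 0.3) of genes carries
  log-normal gene-body signal (median 5 RPKM, σ = 0.5), parents 4-fold
  apart; a bias fraction of modified genes has the F1 at the designated
  parent's level, the rest at the other parent's; Poisson background
  (mean 0.2 reads) everywhere. The default modified-gene rule (RPKM > 0
  and ≥ 10 reads) excludes background genes at typical depths.

What passing recovery tests shows: the estimators and classifiers invert
the generators' model at realistic depths. What it does not show:
robustness to biological replication structure, batch effects,
GC/length biases, isoform switching, mappability artifacts, or
overdispersion beyond d ≈ 0.01 — none of which the generators emulate.
In particular, with single pooled libraries the exact test's calibration
on real data rests on the Poisson assumption plus the fold gate.

## Numerical choices and degenerate inputs

Zero-sum constraints are enforced to 1e-9 (estimates are recentred to
remove accumulated rounding, a no-op analytically). Tail probabilities
are exact via betainc; p-values are in (0, 1] by construction. BH is the
standard step-up (via statsmodels), order-preserving, validated against
a hand-rolled oracle. Degenerate inputs fail loudly: incomplete diallels
name the missing cell, zero-variance samples the offending sample,
constant vectors an undefined correlation; zero denominators in
summaries yield NaN fields rather than errors. Gene models use 0-based
half-open coordinates internally; GFF3 is converted at the boundary.

## Problem sizes

Default verification runs use 2000-gene trios at 10⁷ reads (3 seeds),
200 Monte-Carlo diallel replicates per trait, 5000-gene nulls, 10
clustering seeds, and 100 random tables per estimator-oracle check —
sizes at which every recovered quantity is stable to well within its
acceptance margin and the whole suite runs in well under a minute.

## Known limitations

Griffing Model II (variance components), reciprocal effects (Methods
1/3), GxE modeling, replicated-design count tests with dispersion
estimation (DESeq-style), heterosis indices, allele-specific expression,
and peak calling are out of scope. The per-gene chromatin comparison
reuses the expression count test; published analyses of this kind state
only an FDR rule, so the choice of statistic is a documented assumption.
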