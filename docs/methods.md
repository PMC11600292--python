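# Methods

## The kinetic dilution model

Each RNA species is modelled as synthesized at a constant per-cell rate
`k_syn` (molecules/h) and removed by first-order decay `k_deg` (1/h) plus
dilution through cell division at exponential growth rate `mu` (1/h):

    dC/dt = k_syn − (k_deg + mu(t)) · C,   C* = k_syn / (k_deg + mu).

`simulate_timecourse` solves this exactly for piecewise-constant `mu(t)`
(each segment is a relaxation toward its own steady state), which is how the
serum-starvation/recovery mode is generated: growth arrest raises the
circ-to-linear ratio because the slowly-decaying circle relaxes to a much
higher steady state than its host. The closed form is verified against
fourth-order Runge-Kutta integration at 0.01 h steps to < 1e-6 relative error.

Default kinetic ranges (drawn once per feature from the design seed):

| parameter | default | rationale |
| --- | --- | --- |
| `k_deg_lin` | U(0.10, 0.35)/h | linear mRNA half-lives of ~2–7 h |
| `k_deg_circ` | U(0.002, 0.01)/h | circRNA half-lives of days; must be << typical `mu` for dilution to dominate |
| back-splice fraction `k_syn_circ / k_syn_lin` | lognormal, median 0.02, sigma 0.8 | back-splicing is a minor fate of host transcription; yields ~1–6% of circles out-expressing their host, a whole-marrow fraction below the purified one |
| gene baseline abundance | lognormal(3, 0.8) | right-skewed bulk expression |

## The cohort generator

A latent severity `s ~ N(0, 1)` per MM patient couples everything that the
analysis later tries to read back out:

- plasma-cell growth `mu_pc = 0.015 · exp(0.5·s)` (≈ 46 h doubling at s = 0);
- non-plasma marrow growth `mu_other = 0.02 · exp(−0.6·s)` — aggressive
  disease suppresses normal haematopoiesis;
- plasma-cell fraction `p = 0.10 + 0.80 · logistic(logit(0.40) + 0.8·s)`,
  hard-bounded to the diagnostic 10–90% range; healthy controls draw
  `p ~ U(0.005, 0.02)` and proliferate at `mu_other = 0.05`/h (healthy marrow
  is a strongly proliferative tissue);
- hazard `h = 0.02 · exp(0.8·s)` events/month, administratively censored at
  120 months (median survival ≈ 35 months at s = 0, matching a
  newly-diagnosed-MM scale).

All couplings are log- or logit-linear: monotone, few parameters, and signed
so that composition produces the study's central contrast — in whole marrow
the measured proliferative index is dominated by the (suppressed) non-plasma
compartment, so the index *falls* and circRNA burden *rises* with severity,
while in purified plasma cells both move the other way.

A whole-marrow expression profile is the `(p, 1−p)` mixture of the two
compartment profiles. Proliferation-signature genes scale linearly with the
compartment's `mu`; immunoglobulin genes take a fixed 25% of the plasma-cell
transcriptome (the bias the exclusion-aware TPM removes); the 50-gene
plasma-cell signature is silenced (×0.02) in the non-plasma compartment.

Counts are negative binomial with `var = mean + phi·mean²` (`phi = 0.15`;
0.1–0.2 is the usual bulk RNA-seq range), library sizes lognormal around
3·10⁵ junction-window-weighted reads — small enough to keep simulations fast,
large enough that the consensus read floor and size factors behave as they
would at depth. Caller A detects each circle with probability 0.95 and
reports its junction reads; caller B is deliberately weaker (0.70 detection,
0.6 read capture) and carries no host-linear counts, so the consensus rule is
non-trivial; the three databases jointly cover a fixed random 85% of true
circles. One RNG stream per sample is derived from the master seed by
counter, so output is byte-identical regardless of generation order.

What the generator does **not** emulate: isoform structure within a circle,
GC/length biases, batch effects, translocation-specific expression programs,
non-exponential hazards, informative censoring, or inter-gene correlation
beyond the shared severity axis. Passing tests therefore show that the
pipeline recovers effects of the planted kind and calibrates correctly under
its noise model — not that real cohorts will show effects of this size.

## Analysis conventions

- **Consensus rule**: a circRNA is kept iff caller A's junction reads sum to
  ≥ 2 *across all samples* and the identity is corroborated by caller B or a
  database (exact coordinate match; 1-based inclusive internally, BED input
  converted explicitly). A per-sample read floor is available but off by
  default.
- **TPM**: `rate = count/(length/1000)`; excluded features receive values but
  never enter the denominator; included features sum to 1e6 exactly.
  log2 with pseudocount 1.
- **Size factors**: Anders–Huber median-of-ratios on the stacked
  circular+linear matrix, rescaled to geometric mean 1; a positive-counts
  pseudo-reference variant is available for sparse matrices.
- **circ-to-linear ratio**: bounded `c/(c+l)` (undefined at 0/0) so the
  "circle exceeds host" criterion (ratio > 0.5, strict) and the time-course
  statistic are the same quantity; `c/l` with pseudocount 0.5 is an option.
- **Indexes**: arithmetic mean of log2(TPM) over signature genes (mean, not
  sum, so scores are comparable across signatures of different size); ≥ 90%
  of genes must be present; missing genes are logged. The shipped gene lists
  carry the canonical cardinalities (12/11/50) with proliferation-associated
  members; they are data files, editable without touching code.
- **Turnover**: `(TPM_BCL2 + 1)/(TPM_MKI67 + 1)`; higher = lower turnover.
- **DE stage**: rank-based (Mann-Whitney on size-factor-normalized counts,
  BH-adjusted) with fold changes from group means + 0.5 pseudocount. This is
  a deliberate simplification of negative-binomial Wald testing: robust and
  assumption-light at the cost of power at small n. Positive log2FC = higher
  in the MM/first group.
- **Mann-Whitney branching**: exact enumeration when n ≤ 20 without ties,
  otherwise normal approximation with tie and continuity corrections; a
  constant pooled sample returns p = 1 by symmetry.
- **Survival**: product-limit estimator with Greenwood variance; log-rank via
  hypergeometric moments (k-group version uses the full covariance matrix
  with k−1 df); Cox by Newton-Raphson with step halving on a standardized
  covariate, Breslow ties by default (ties are sparse at month resolution),
  Efron as an option; |beta| > 30 on the standardized scale is reported as a
  monotone-likelihood error.
- **Optimal cutpoints**: candidates are midpoints between consecutive
  distinct expression values with both groups ≥ ceil(minprop·n), minprop 0.2;
  the candidate maximizing |standardized log-rank Z| wins, ties to the
  smallest cutpoint. Screen p-values are reported unadjusted — mirroring the
  screening convention this pipeline reproduces — with a BH column alongside,
  because maximal selection inflates the null rejection rate (the test suite
  demonstrates ~20% at nominal 5%).
- **Direction of effect**: "favourable high" iff the high-expression group
  has the larger Kaplan-Meier median, falling back to the larger final
  survival when medians are undefined.
- **Clustering**: agglomerative, Euclidean distance, complete linkage
  (deterministic; linkage is configurable), cut at k = 3; features are
  z-scored per row (circRNAs on normalized counts, genes on log2 TPM,
  separately). Cluster phenotype labels are assigned from each cluster's mean
  index score and mean circRNA burden, since "high-proliferation/low-circRNA"
  is otherwise an inspection call.
- **Purity**: purified cohorts are filtered at ≥ 85% estimated purity
  (boundary inclusive) before any analysis.

## Numerical and degenerate-input choices

Zero TPM denominators, constant covariates, constant expression vectors,
single-stratum label sets, empty consensus sets, non-positive survival times
and k > n clustering all raise errors naming the offending sample/feature
rather than propagating NaNs. The log-rank scan returns statistic 0 / p 1
when the variance term vanishes (e.g. all events at one time, balanced).

## Problem sizes

Simulated cohorts default to 260 linear genes and 150 circRNAs. These sizes
were chosen so that a full paired-replicate validation (20 cohorts of n = 60
per arm) and the study-scale driver runs complete in minutes on a single
core, while keeping > 70 signature genes, multi-isoform hosts, and a
consensus set large enough for top-100 screening.

## Known limitations

- The sign-flip is demonstrated on the generator's compositional model;
  real whole-marrow cohorts mix many more than two compartments.
- The DE stage is not a shrinkage estimator; at 2–3 samples per group it has
  little power (by design it never reports a fold change without a rank test
  behind it).
- The asymptotic log-rank p deviates from the exact permutation null by up to
  ~0.1 at n = 8 (anti-conservative); below ~20 subjects per comparison,
  permutation or exact tests should be preferred to the chi-square
  approximation.
- Database matching is exact on coordinates; real databases disagree by a few
  bases at some loci and would need a tolerance window.
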