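# Methods

## Gene gain/loss model

Family sizes follow a linear birth-death process: a family with `s` gene
copies gains copies at rate `lambda * s` and loses them at rate `mu * s`
(rates in events per gene per million years). State 0 is absorbing — an
extinct family cannot be re-founded from within, matching the convention
of gene-family evolution tools. The transition probability is the
classical closed form

    P(c | s, t) = sum_{j=0}^{min(s,c)} C(s,j) C(s+c-j-1, s-1)
                  a^(s-j) b^(c-j) (1-a-b)^j

with `a = mu (e^{rt} - 1) / (lambda e^{rt} - mu)`, `b = (lambda/mu) a`,
`r = lambda - mu`, and `a = b = lambda t / (1 + lambda t)` when the rates
coincide. Numerically we evaluate it through the equivalent per-lineage
offspring law (extinct with probability `a`, otherwise geometric with
parameter `b`), whose `s`-fold convolution is the same polynomial but has
only non-negative terms; the direct signed sum cancels catastrophically
once `a + b > 1`, which happens for `rate * t` products well inside the
ranges explored during optimization. Tests verify the convolution against
the literal series and against the matrix exponential of the truncated
generator.

Family likelihoods use Felsenstein pruning over count states
`0..cap` with `cap = max(2 * max observed count, 20)`, applied per family
(batched fits use the table-wide cap, which only adds states; the
truncation-stability test shows enlarging the cap changes lnL by less
than 1e-8). The root size is averaged over a uniform prior on
`1..root_prior_max`.

### Root-size prior

By default `root_prior_max` is each family's own maximum observed count.
This mirrors desk-scale conventions but makes the prior support
data-dependent, and the global rate estimates are quite sensitive to it:
fitting data generated with any fixed root-size law under a mismatched
prior biases the estimates, typically towards losses, because prior mass
on large roots makes "start big and decline" cheap. All estimator
consistency checks therefore fit the correctly specified model: when the
root-size law of the data is known (as it is for simulated tables), its
bound is passed as `root_prior_max` and applied to every family; the
rate-recovery tests verify (0.002, 0.0018) are then recovered within the
25% tolerance they assert.
Analyses of real tables should treat the reported rates as conditional on
the chosen root prior.

### Rate estimation and the LRT

`fit_global_rates` maximizes the summed family log-likelihoods over
log-rates with L-BFGS-B, bounds `[1e-8, 1]` events/gene/My, five starts
(one moment-scale start plus jittered restarts). Proposals that zero out
a family's likelihood return a large finite objective so the line search
can back off. The tied (`lambda = mu`) and distinct fits are nested; the
LRT statistic `2 (lnL_distinct - lnL_single)` is referred to chi-squared
with one degree of freedom, and a materially negative statistic raises an
error as an optimization-failure signal.

### Per-family significance

The per-family p-value is Monte-Carlo: simulate families under the
fitted global rates with root sizes from the uniform root prior, compute
each simulated family's log-likelihood, and report the fraction at or
below the observed family's. Simulated and observed families must follow
the same root law for the p-values to be uniform under the null (the
calibration test verifies a KS test does not reject at the 1% level);
ties in the discrete likelihood make the test slightly conservative.
Families that share a root prior share one simulated null sample — the
null law depends only on the prior and the rates — which reduces the
simulation cost from `O(n_families * n_sim)` to
`O(n_distinct_priors * n_sim)` family simulations.

Ancestral family sizes are reconstructed by max-product (Viterbi)
dynamic programming over count states; argmax ties resolve to the
smaller count, a deterministic parsimony-of-content rule. Each edge is
labelled expansion/contraction/stasis by comparing child and parent
reconstructed counts, and per-node tallies across families reproduce the
expansion/contraction summaries of the study design.

An optional tip-error weight `epsilon` smears each observed count c over
`{c-1, c, c+1}` with weights `(eps, 1-2 eps, eps)` before pruning (the
downward mass stays on 0 when c = 0). It is a deliberately coarse account
of annotation miscounts, off by default; full error-model calibration is
out of scope.

## Multi-regime trait models

Per-species counts of one family are analyzed as a continuous trait with
a multivariate normal likelihood. The painting assigns every edge to the
regime of the clade containing it; the regime switch sits on each
clade's stem edge, and the root node carries a separate label only.
Parameter counts: BM1 k=2 (σ², root state), BMS k=3, OU1 k=3 (α, σ², θ),
OUM k=4, OUMV k=5. The root has no free optimum: in the Hansen weight
construction each root-to-tip lineage's residual weight `e^{-alpha T}`
is assigned to the optimum of the lineage's oldest painted segment (the
stationarity convention), so weights always sum to one.

Covariances come from the accumulated-variance recursion
`v(end) = v(start) e^{-2 a l} + sigma^2 (1 - e^{-2 a l}) / (2 a)` down
the tree, with the value at the MRCA discounted by `e^{-2 a (T - t_mrca)}`
for the two descents; `alpha -> 0` reduces exactly to Brownian motion and
is evaluated by the BM branch below `alpha = 1e-12` to avoid 0/0.

Fitting profiles everything linear: optima (or the BM root state) by
generalized least squares through a Cholesky whitening, and the overall
variance scale analytically (`sigma2_hat = rss / n`, the ML scale). That
leaves a one-dimensional search over `ln alpha` (OU1, OUM) or a log
variance ratio (BMS), and a two-dimensional search for OUMV, run with
Nelder-Mead from five deterministic grid starts inside
`ln alpha ∈ [ln 1e-5, ln 10]` and log-ratio bounds ±12. AICc uses
`-2 lnL + 2k + 2k(k+1)/(n-k-1)`; with the 18-taxon tree all five models
are comparable (n > k + 1), while tiny trees report NaN AICc but still
give closed-form fits.

Model choice: best H0 among {BM1, BMS, OU1} versus best H1 among
{OUM, OUMV}; the alternative is retained only when its AICc is more than
2 units lower, with exact ties (within 1e-9) resolved conservatively to
H0. Direction is the regime with the larger fitted optimum of the winning
alternative. Counts are analyzed raw (not log-transformed) to match the
study design the package reproduces.

## Enrichment statistics

The resampling test draws each category's size without replacement from
the background `n_draws` times (default 100,000) and reports the
fraction of draws reaching the observed number of positives or more —
"or more" inclusive, no pseudo-count, so an exact zero is possible.
Because a without-replacement draw's success count is hypergeometric, the
sampler draws the count directly and the exact hypergeometric upper tail
serves as the analytic oracle. BH adjustment spans all categories tested
(m = 8 in the standard configuration), implemented via
statsmodels' step-up procedure and cross-checked by hand in tests. The
two-sample equality-of-proportions test is the χ² test on the 2×2 table
with Yates continuity correction on by default (both modes exposed).

## Synthetic data

The fixture tree has the study's sampling structure: nine taxa per
suborder with the published short names, root depth 250 My, both suborder
crowns at 220 My and identical multisets of internal node ages (so
within-clade node-age distributions match). Node ages are synthesized —
the study's figure prints none — with topologies following accepted
family-level relationships.

Default simulation conditions: 2000 families, gain 0.002 and loss 0.0018
events/gene/My, root sizes uniform on 1..3. Small roots reflect the
strongly low-copy character of real orthology tables ("single-copy
control": most families hold one or two genes per species). Planted
expanded families pull towards optima of 6.5 (baseline regime) versus 19
genes (expanded regime) with `alpha = 0.02`/My (trait half-life ≈ 35 My)
and `sigma2 = 0.1`/My — the suborder size contrast of the observed
positive carboxylesterase family. Count simulation samples the same
per-lineage offspring law the likelihood integrates (self-consistency is
the point of the recovery tests); an independent event-by-event Gillespie
simulator cross-checks it in distribution.

What the generators do not emulate: assembly and annotation artifacts
(isoform collapse, fragmented gene models), heterogeneous rates across
families or lineages, and correlated family sizes. Passing tests
demonstrate internal consistency of the inference chain under its own
model, not robustness to those real-data complications.

## Pipeline

Stage order is enforced: shared-family filter → global rate fits and LRT
→ per-family Monte-Carlo screen (p < 0.01) → five-model comparison on
screened families only → direction-split positive calls → per-direction
category enrichment against the full analyzed background. All
randomness flows from one seed (sub-seeds are derived per stage), and
reruns with the same config are byte-identical. Intermediate artifacts
are plain TSV so every stage can be run and inspected independently, from
Python or the `lsekit` command line.

Problem sizes used by the test suite and calibration runs — 800-2000
families for rate recovery and null calibration, 40 planted families for
end-to-end recovery, 100,000 enrichment draws — are the package's
desk-scale defaults; they keep every check exact enough to be
discriminating while remaining quick to rerun.

## Known limitations

- The uniform root-size prior is a modeling choice, not an estimate; rate
  estimates shift with it (see above). A stationary or empirical root
  prior would be a natural extension.
- The per-family Monte-Carlo p-value uses the marginal likelihood as its
  test statistic, which partly reflects family size; its calibration is
  exact under the fitted model but its power against specific
  alternatives (e.g. clade-confined bursts) varies with the background
  size distribution.
- OU parameters on 18 taxa sit on a ridge in (α, σ²); profiling and
  multi-starts make the reported maxima reproducible, but individual
  parameter values (as opposed to likelihoods and AICc differences)
  should be interpreted cautiously.
- Branch-specific rate models, gamma rate variation across families, and
  full tip-error calibration are out of scope.
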