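# Methods

## Model and null hypothesis

All combiners operate per feature (gene, variant) on p-values
`p_1, ..., p_n` from n independent studies, assumed Uniform(0, 1) under
the joint null that *no* study carries an effect. The alternative is
that *one or more* studies are associated — deliberately weaker than
the usual "all studies share an effect" framing, which is what makes
the methods sensitive to incomplete association.

**Fisher** `T = -2 Σ log p_i ~ χ²(2n)`. **Stouffer**
`Z = Σ Φ⁻¹(1-p_i)/√n`. **Weighted Z** uses `w_i = √s_i` (s_i the
per-study sample size) with normalisation `√(Σ w_i²)` — the standard
sample-size weighting; the exact weights are configurable.
**Lancaster** transforms p_i through the upper-tail χ²(s_i) quantile
and refers the sum to χ²(Σ s_i). **wFisher** replaces the integer
χ² degrees of freedom by gamma shapes `k_i = n·s_i/S`, scale 2, so the
weights are sample-size proportional but the total degrees of freedom
stay at 2n; the sum is referred to χ²(2n).

### Tail convention

Every transform maps p to the *upper-tail* quantile of its reference
distribution (the value whose survival probability is p) and the
combined p-value is the upper-tail probability of the sum. This is the
unique convention under which wFisher with equal sample sizes is
identical to Fisher (and Lancaster with DF=2 to Fisher, weighted Z with
equal sizes to Stouffer) — properties the package enforces to 1e-12
relative in its tests. The alternative lower-tail reading sometimes
seen in print does not reduce to Fisher for n > 1 and is not used.

### ordmeta

With `p_(r)` the r-th smallest p-value and `F_(r)` the Beta(r, n-r+1)
CDF, the statistic is `X = min_r F_(r)(p_(r))` and the combined p-value
its exact null probability

    P(X ≤ α) = P(∃ r: p_(r) ≤ c_r),   c_r = F_(r)⁻¹(α).

Ties at the arg-min go to the smallest rank (deterministic, and the
sparsest-association explanation). The ranks `1..r*` (r* the arg-min)
are reported as the predicted associated studies.

### Directional integration

Two-tailed p-values with effect signs are halved and synchronised
(`u_i = p_i/2` along the integration direction, `1 - p_i/2` against
it); the combiner runs on `u` and on `1 - u`, and the smaller result is
doubled (capped at 1). Tables that already print synchronized
one-tailed values skip the halving (`one_tailed=True`).

## Numerical evaluation of the joint order-statistic probability

Two independent routes compute `P(∃ r: p_(r) ≤ c_r)`:

1. **First-crossing recursion** (Steck-type):
   `h_r = c_r^r − Σ_{j<r} C(r,j) h_j (c_r − c_j)^{r−j}`,
   `P = Σ_r C(n,r) h_r (1−c_r)^{n−r}`, run in mpmath arbitrary
   precision (starting at max(50, 30+2n) digits and doubling until two
   precisions agree to 1e-13 relative). O(n²), exact for arbitrarily
   small combined p-values; this is the default scalar path whenever
   the combined p is below 1e-6 or the boundary is extreme.
2. **Positive-term counting recursion**: conditioning on the counts of
   uniforms falling in successive boundary intervals gives a recursion
   with only non-negative terms, so double precision keeps near-machine
   relative accuracy for the survival probability S; `1 − S` is used
   when it exceeds 1e-6 (absolute error ~1e-14, hence ≤ 1e-8 relative
   there). This is the bulk path for simulations (factorial overflow
   limits it to n ≤ 140).

The two routes are cross-checked against each other, against exact
rational evaluation of the nested integral (sympy, n ≤ 4), and against
10⁷-draw Monte Carlo (n ≤ 30) in the test suite.

Supporting pieces: beta marginals are computed through the binomial
tail identity `F_(r)(x) = P(Bin(n,x) ≥ r)` with log-sum-exp, keeping
≤1e-10 relative error down to x = 1e-300 where the regularized
incomplete beta underflows; boundary inversion `F_(r)(c) = α` uses
safeguarded Newton on log c seeded with the small-x asymptote
`c ≈ (α r B(r, n−r+1))^{1/r}`.

Extreme tails elsewhere: p-values are clamped into
`[1e-320, 1 − 1e-16]` (with a warning) before quantile transforms;
final survival probabilities go through log-space/mpmath fallbacks so a
combined p-value is reported as 0 only below double-precision
subnormals, with a high-precision decimal carried in
`extras["p_str"]`. Note that naive double-precision evaluation of
`1 − P(X > α)` rounds to 0 for some published extreme loci; this
package returns the exact small value instead, so the two bundled loci
with printed combined p of 0 deliberately disagree with their printed
value.

Simulation-path shortcut: the vectorised ordmeta (`exact_small=False`)
clamps sub-1e-6 combined p-values into the `[X, nX]` sandwich instead
of escalating to arbitrary precision — harmless where results only
feed rejection counts at cutoffs of 0.01/0.05.

## Simulation designs

### t-test generator

Associated p-values: one-sample one-tailed t-tests of N(mean, 1)
samples; per associated study (per replicate) the mean is drawn
uniformly from [0.03, 0.1] and the integer sample size uniformly from
[30, 2000]. (A per-replicate shared (size, mean) pair is available via
`shared_effect_pairs`; the default is independent per-study draws.)
Unassociated p-values are uniform on one of [0, 1], [0.1, 1],
[0.3, 1]. Type-I experiments combine 2/10/30/100 Uniform(0,1) values —
exactly the distribution of the zero-effect one-tailed t-test — at
cutoff 0.05 (default 100,000 replicates); power experiments trace the
rejection rate at cutoff 0.01 (default 1,000 replicates) as 0–30 null
p-values are appended to 2/4/8 associated ones, reusing each
replicate's associated draws along the trace so curves are comparable
point to point. Weighted methods receive the drawn sizes (equal sizes
in the type-I runs).

### RNA-seq generator

Per study, a genes × samples count matrix `NB(mean, dispersion)` for
1000 genes (default), 20 studies, two groups of 20 samples. Gene base
means are log-normal (log-mean 4.0, log-sd 1.3 → median ~55 counts,
heavy right tail), scaled per study by Uniform(0.7, 1.3); dispersions
follow the decreasing trend `(0.05 + 2/μ) · Gamma(5, 1/5)`, emulating
the mean-dispersion relationship edgeR estimates on real tumor/normal
compendia without requiring any download. In the associated studies a
fixed fraction (10/30/60%) of genes is differentially expressed with
fold change `1.3 + Exponential(0.5)`, direction random per gene and
consistent across associated studies. Differential expression per
study is tested by Welch's t on log2(CPM + 0.5) — a deliberately plain
stand-in for the voom/moderated-t pipeline that preserves its contract
(per-gene two-tailed p + sign) without empirical-Bayes machinery.
Combined per-gene p-values (directional wrapper, sample sizes as
weights, or fixed/random-effects pooling of the log2-CPM effects) are
scored by AUC, TPR, and realized FDR at q < 0.05 (realized FDR only
when ≥ 5 genes are significant).

What the generators do *not* emulate: between-study correlation,
library-composition artefacts, count normalisation beyond CPM, and
gene-gene correlation. Passing benchmarks therefore demonstrate the
statistical behaviour of the combiners under idealised independence,
not end-to-end performance on real expression compendia.

## Benchmark scales

The bundled acceptance-style tests run the type-I experiment at
100,000 replicates (20,000 for ordmeta, whose per-replicate evaluation
is the most expensive; its comparison tolerance widens accordingly),
the power orderings at 500 replicates, the RNA-seq ordering at 200
genes × 3 replicates, and the prediction experiment at 300 replicates —
sizes chosen so the full suite completes in minutes while keeping
Monte-Carlo standard errors well inside the asserted margins. The
library defaults (`TTestSimConfig`, `RnaSeqSimConfig`) remain at the
full study scales.

## Known limitations

* All combiners assume independent studies; no dependence corrections
  (Brown/Kost-style) are provided.
* The associated-study prediction experiment's sensitivity at 100
  inputs sits essentially on its asserted 0.4 bound under the default
  design: roughly half of the replicates reach 0.4, so the median is
  seed-sensitive there.
* Fixed/random-effects support is the minimal inverse-variance /
  DerSimonian–Laird pair used as a benchmark baseline, not a general
  effect-size meta-analysis toolkit.
* roP requires the rank r a priori; choosing it adaptively (with the
  attendant multiplicity) is precisely what the minimum-marginal method
  replaces, so no adaptive roP is offered.
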