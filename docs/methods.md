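# Methods

## Statistical model

Each study contributes genotype counts (n_MM, n_MW, n_WW) for cases and
controls at one biallelic polymorphism, with M denoting the variant allele.
A genetic-model contrast collapses these into a 2×2 exposure table
(a, b | c, d); the five contrasts (allelic, homozygote, heterozygote,
dominant, recessive) are defined in the README. The per-study effect is the
log odds ratio θ̂_i = log(a·d / (b·c)) with Woolf variance
v_i = 1/a + 1/b + 1/c + 1/d. When any cell is zero, 0.5 is added to all
four cells (Haldane–Anscombe) and the estimate is flagged; the correction
is never applied preemptively. A table with an empty arm is not estimable
and raises an error naming the study — studies are never silently dropped.

Pooling assumes the usual two-level normal model
θ̂_i ~ N(θ_i, v_i), θ_i ~ N(θ, τ²). Fixed effects set τ² = 0 and weight by
1/v_i. Cochran's Q = Σ w_i (θ̂_i − θ̂_fixed)² is referred to χ²(k−1) to give
P_h; I² = max(0, (Q − (k−1))/Q); τ² is the DerSimonian–Laird moment
estimator max(0, (Q − (k−1))/c) with c = Σw − Σw²/Σw. The working rule —
random effects when P_h < 0.05, fixed otherwise — mirrors how this
literature reports stratified grids; the threshold is exposed
(`het_threshold`). With k = 1 heterogeneity statistics are undefined (NaN
in output) and fixed effects are used. The pooled log-OR is tested with
Z = θ̂/se(θ̂), two-sided normal p-value; all 95% CIs use the normal
quantile 1.959964 with no small-k t adjustment.

Hardy–Weinberg equilibrium in controls is tested by a Pearson chi-square of
the three observed genotype classes against p̂², 2p̂(1−p̂), (1−p̂)² with p̂
estimated from the same data, hence 1 df. No continuity correction; the
exact (enumeration) test is out of scope. Monomorphic control arms return
χ² = 0, p = 1 with a flag. HWE screening is off by default because
published pooled grids in this area typically retain HWE-violating studies;
`hwe_threshold` provides the sensitivity analysis.

Publication bias: Begg's test correlates (Kendall τ-b) the standardized
deviates (θ̂_i − θ̂)/√(v_i − v̂) with the variances v_i, using the normal
approximation z = τ/√(2(2k+5)/(9k(k−1))). The radicand v_i − v̂ is always
positive in exact arithmetic (v̂ = 1/Σw < min v_i) but can underflow when
one study dominates the pooled weight; it is floored at 1e−12 and the
result flagged. Egger's test is the classic unweighted regression of
θ̂_i/se_i on 1/se_i; the intercept is tested with t on k − 2 df. When the
points lie on an exact line the residual variance is numerically zero and
the t ratio is noise; the implementation then reports p = 1 for a zero
intercept (and p = 0 otherwise) instead of dividing rounding errors. Both
tests require k ≥ 3, Egger additionally at least two distinct standard
errors.

The Mantel–Haenszel fixed-effects pooled OR (with the
Robins–Breslow–Greenland variance, via statsmodels' stratified-table
implementation) is provided purely as an independent cross-check of the
inverse-variance route; the two agree to well under 1% relative on balanced
collections with hundreds of subjects per arm, and tests enforce that.

Contingency grids (clinicopathological covariates vs a low/high expression
split) use the Pearson chi-square with expected counts from the product of
margins. On 2×2 tables the Yates continuity correction subtracts 0.5 from
each |o − e| before squaring, floored at zero so a tiny deviation cannot
contribute a spurious positive term; this floor is why the statistic is
computed in-package rather than delegated to scipy's `chi2_contingency`,
whose correction shifts observed toward expected and can overshoot.
Applying Yates to 2×2 blocks and plain Pearson to larger ones is forced by
arithmetic: the published age/gender/M statistics match the corrected
values exactly and the multi-level blocks match the plain ones.

## Synthetic studies

The generator emulates a literature of case-control studies. Per study it
draws a control variant-allele frequency q ~ U(0.20, 0.45) and arm sizes
n ~ U{100..600} (defaults), forms control genotype probabilities from HWE
at q — optionally distorted by an inbreeding-style coefficient f, with
p_MM = q² + fq(1−q), p_MW = 2q(1−q)(1−f), p_WW = (1−q)² + fq(1−q) — and
obtains case probabilities by exponential tilting: multiply the MW and MM
classes by exp(β_het + δ) and exp(β_hom + δ) and renormalize, where
β = log of the genotype-level odds ratio and δ ~ N(0, τ²) is a shared
study-level shift. Counts are multinomial. Tilting makes the genotype-level
ORs exact population quantities, and when or_het = or_hom = ψ the
dominant-model OR of every study is exactly ψ·e^δ — so dominant-model
recovery has a closed-form truth, which is why `recovery_experiment`
requires or_het = or_hom. Recessive/allelic truths have no such closed form
under tilting and are deliberately not asserted against formulas.

Default parameters (k = 30, or_het = 1.2, or_hom = 1.5, τ = 0.1) describe
a moderately heterogeneous literature of common promoter variants with
modest per-genotype effects; sizes and frequencies bracket what typical
included-study tables show (tens to a few hundred subjects per arm). The
suppression mode drops a study with probability `drop_probability`
(default scenario 0.8) when its dominant-model p-value exceeds
`p_threshold` (0.1), emulating non-significant small studies never being
published; because small studies are the ones likely to be non-significant
when a real effect exists, suppression induces the funnel asymmetry the
bias tests target.

Seeding: every study uses `default_rng([seed, i])`, so enlarging k extends
a collection without reshuffling earlier studies, and suppression decisions
ride the same per-study stream. Replicate seeds in experiments are derived
by a fixed affine map modulo 2³¹.

What the generator does not emulate: linkage disequilibrium and haplotypes,
covariate-dependent effects, genotyping error, and the bookkeeping quirks
of real study tables. Calibration results on synthetic data therefore
validate the estimators' arithmetic and distributional behaviour, not the
epidemiological quality of any particular literature.

## Calibration experiments and problem sizes

`scripts/acceptance.py` (and the acceptance test suite) recompute, from
scratch at each run:

- the seven covariate chi-squares from the packaged ~400-patient count
  grids;
- dominant-model recovery at true OR 1.2, τ = 0, k = 30, n ≈ 500/arm:
  mean pooled OR over 500 replicates (compared against the truth at 2
  Monte-Carlo standard errors) and mean τ̂²;
- 95% CI coverage of the selected model over 2000 such replicates
  (expected band 93–97%);
- HWE test size: 1000 equilibrium control samples of n = 2000;
- Begg/Egger size on 1000 null funnels (k = 20, OR = 1, τ = 0) and power
  on 1000 suppressed literatures (OR = 1.2, drop p > 0.1 at 0.8);
- worst MH vs inverse-variance relative OR difference over 20 balanced
  collections (k = 20, n 200–800 per arm).

These sizes keep the whole script under a minute on one core while leaving
Monte-Carlo error well inside each acceptance band.

## Numerical and design choices

- Rounded report output: OR/CI/Z/p to 3 decimals, τ² to 4; p-values below
  5·10⁻⁴ print as "0.000" in TSV, while JSON output keeps full precision.
- The allelic model doubles totals (each subject carries two alleles);
  within-subject allele correlation is ignored, as is conventional for
  these grids.
- Which physical allele is "M" is input metadata, not inferred from
  frequencies — for −251 the convention is M = A, W = T; the site labelled
  both "+781" and "−781" in the literature is accepted under either
  spelling and canonicalized to "+781".
- Records with an all-zero arm are rejected at validation so that reported
  k always equals the number of studies actually pooled.
- Real stratified grids of this kind are not numerically reproducible
  without the primary studies' genotype counts, which published
  meta-analyses rarely deposit; the package's validation therefore rests on
  the in-package contingency grids (exact) plus the simulation-based
  calibration above.

## Known limitations

No Peto OR, Hartung–Knapp adjustment, meta-regression, trim-and-fill, or
leave-one-out influence analysis; no exact HWE test; no plot rendering
(forest data are exported as text). Begg's test is mildly conservative for
funnels with very wide variance spread — at the spread the default
generator produces, its size is nominal.
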