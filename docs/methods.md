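# Methods

This note documents the models behind `litvar`, the choices made where the
design was genuinely open, and what the synthetic data do and do not show.

## The observed trait and its estimator

The selection criterion is the intra-doe phenotypic variance of litter
size. For a doe with $n$ parities and pre-corrected litter sizes $x_i$,

$$V_e = \frac{1}{n+1}\sum_{i=1}^n (x_i-\bar x)^2 .$$

The divisor $n+1$ gives the quadratic estimator with minimum risk (smallest
expected mean square error) — preferable to the unbiased $n-1$ divisor when
$n$ is as small as 2–9. Its sampling variance under normality is
$\frac{2(n-1)}{(n+1)^2}\sigma^4$; the analysis models therefore weight the
record of a doe with $n$ parities by $c(n)=\frac{2(n-1)}{(n+1)^2}$ times a
common residual scale. Pre-correction removes year–season and
parity–lactation (first parity / later lactating / later non-lactating)
effects estimated once by OLS on the pooled records; because $V_e$ is
translation-invariant, no centering is applied, and line–generation terms
are deliberately excluded from the pre-correction model so that genuine
line differences are not absorbed into nuisance effects.

## Trait-level generative model and its calibration

In `trait_level` mode the observed record of doe $j$ with $n_j$ parities is

$$y_j = \max(0,\; \mu + v_j + \epsilon_j)\; W_j,\qquad
W_j \sim \chi^2_{n_j-1}/(n_j-1),$$

with additive value $v_j$ (variance $\sigma_v^2$, transmitted through the
pedigree with Mendelian-sampling variance $\tfrac12\sigma_v^2(1-\bar F)$)
and a doe-level environmental deviate $\epsilon_j$. $W_j$ has mean one and
variance $2/(n_j-1)$ — exactly the squared coefficient of variation of the
variance estimator — so the record is unbiased for the doe's level while
carrying realistic, strongly right-skewed estimator noise.

Calibration matches three targets: base mean $\mu = 3.73$ kits², base SD
$3.36$ kits², and regression heritability $h^2 = 0.08$ (twice the
parent–offspring regression slope of the observed records). Moment
matching gives $\sigma_v^2 = h^2\,\mathrm{SD}^2 = 0.90$,
$\sigma_T^2 = (\mathrm{SD}^2 - \mu^2\kappa)/(1+\kappa)$ with
$\kappa = E[2/(n-1)]$ over the parity distribution, and
$\sigma_\epsilon^2 = \sigma_T^2 - \sigma_v^2$. This budget is tight: most
of the observed dispersion (CV ≈ 0.90) is estimator noise, and the
calibration is only feasible when the parity distribution puts limited mass
on $n = 2,3$ ($\kappa \lesssim 0.70$). The default distribution on 2..9,
$(0.04, 0.11, 0.44, 0.26, 0.07, 0.04, 0.02, 0.02)$, has mean 4.51 and mode
4, with 70% of does at four or five parities — consistent with a breeding
program whose candidates typically had four or five parities — and yields
$\kappa = 0.665$, $\sigma_\epsilon^2 = 0.32$.

Litter-size records are simulated alongside (mean 8.71, SD 3.01 kits,
$h^2 = 0.10$, repeatability 0.20, integer-rounded at zero), sharing a
bivariate additive structure with $v$ (genetic correlation $r_g$, default
0), so the repeatability and bivariate models can be exercised on the same
experiments.

In `mechanistic` mode the residual variance of litter size is under
log-linear additive control, $e \sim N(0, \exp(\eta_0 + v))$ — the standard
genetically-structured-variance form, which guarantees positivity — and the
criterion is computed from the records through the estimation pipeline.
$\sigma_{v,\log}^2 = h^2\,\mathrm{SD}^2/\mu^2$ by the delta method, and
$\eta_0$ absorbs the $(n-1)/(n+1)$ deflation of the estimator.

## Breeding scheme and selection-time records

Each line runs ~125 does and 25 sires per discrete generation. Dams with at
least four parities are ranked on their own record — no pedigree
evaluation — and the best 20% (or a differential-matched set, below) breed
the replacement does; each sire is mated to five dams and replaced by a son
of his best mate, a within-family rule that limits inbreeding accumulation.
The base round ranks both lines' candidates on the common base pool.

All selection decisions use the record *as it stood at selection time*: the
variance of the doe's first $\min(n, 4)$ parities (sharing the early
chi-square components with her full record). This matters: ranking on
complete-career records would overstate selection accuracy and inflate
response by roughly 20% at these parameter values.

In `differential_matched` mode the per-round weighted dam differential is
pinned to prescribed targets — the package defaults are the realized
differentials of the rabbit experiment it models (base 3.0/1.5, then High
1.5–2.9 and Low 0.2–1.0 kits² over rounds 1–9). Matching starts from
truncation, adjusts the selected count, and fine-tunes by swapping boundary
dams, to a tolerance of 5% with an absolute floor of 0.05 kits² — half the
targets' printed precision (truncation lifts are discrete, so a purely
relative tolerance is unattainable for near-zero targets on finite pools).
Boundary-restricted swapping is deliberate: swapping arbitrary extreme
dams into the set would leave the differential unchanged
but alter the set's genetic composition, because the record→breeding-value
regression is strongly nonlinear under multiplicative noise. Daughters are
allocated as evenly as possible across selected dams, so contribution
weighting and equal weighting of the differential nearly coincide (both are
logged). `selected_fraction = 1` is interpreted as "no selection anywhere":
dams unranked, sons drawn at random, base pool split randomly.

## Response models

**Phenotypic response** is the per-generation High−Low difference from the
heteroscedastic line–generation model $\mathbf y=\mathbf{Xb}+\varepsilon$,
$\mathrm{Var}(\varepsilon_i)=c(n_i)\sigma_\varepsilon^2$, Gibbs-sampled
with conjugate blocks (cell means are orthogonal; $\sigma_\varepsilon^2$ is
scaled inverse-$\chi^2$ with the flat-prior degrees of freedom $N-2$).
Defaults: 60,000 iterations, 10,000 burn-in, thinning 10. Summaries:
posterior mean, SD, equal-tail 95% interval, and the guaranteed value
$k$ with $P(\text{difference} > k) = 0.80$ (the 20th posterior percentile).

**Genetic response** comes from an animal model with generation fixed and
breeding values $\mathbf u \sim N(\mathbf 0, \mathbf A\sigma_u^2)$;
$\mathbf A^{-1}$ is built by Henderson's rules with the inbreeding
adjustment (Mendelian-sampling variances $d_i$), and inbreeding
coefficients come from the tabular method ($O(n^2)$, appropriate for
pedigrees of a few thousand). The heteroscedastic weights are applied by
default (toggleable). Heritability on this trait is reported as
$\sigma_u^2/(\sigma_u^2 + \bar c\,\sigma_\varepsilon^2)$, the ratio at the
average record precision, making weighted and unweighted fits comparable.
The litter-size repeatability model adds parity–lactation and year–season
fixed effects and a permanent environmental effect per doe; the bivariate
model samples breeding values as correlated pairs with
$\mathrm{Var} = \mathbf G \otimes \mathbf A$, drawing $\mathbf G$ from its
inverse-Wishart conditional (flat prior; degrees of freedom $q-3$), with
residuals independent across traits because the two traits live at
different levels (one derived record per doe vs repeated records). The
phenotypic correlation is derived from the posterior components at the
doe-mean level.

Paper-scale chains (10⁶ iterations) exist as the `GENETIC_CHAIN` default;
tests and the acceptance pipeline use shorter chains, which are adequate
because each sampler includes a **joint scaling move**: a Metropolis step
proposing $u' = cu$ together with the matching variance rescaling
(acceptance = residual-likelihood ratio × $c^2$, or $c^3$ for one column of
$\mathbf G$). Without it, single-site Gibbs performs a slow random walk in
$(u, \sigma_u^2)$ at $h^2 \approx 0.08$ — the reason such analyses
traditionally run for a million iterations.

**Diagnostics**: Geweke $Z$ on the first 10% vs last 50% with
spectral-density-at-zero variances (Bartlett window over 4% of lags),
batch-means Monte Carlo standard errors ($\lfloor\sqrt{n}\rfloor$ batches),
and shortest-interval HPD. Chains with $|Z| > 3$ are flagged.

## What the synthetic data show — and what they do not

Passing tests show that the estimators, the selection machinery and the
samplers are correct (against brute force, hand algebra, dense inverses and
conjugate closed forms), that the generator hits its calibration targets,
and that the full calibrated pipeline reproduces the magnitude of the
experiment's response when the realized selection differentials are
matched. Across 80 replicates the generation-10 genetic divergence is
1.99 ± 0.05 kits², inside the reported interval for the real experiment's
response though some 20% above its point estimate; plausible reasons
include idealizations of the within-family male replacement (the real
scheme had "exceptions"), the normality of the latent doe-level variance,
and the parity-distribution shape, all fixed here a priori.

The generator does not emulate: overlapping generations or repeat use of
parents; mortality, culling or fertility differences (every doe completes
2–9 parities and every selected dam contributes); non-normal latent
variation; environmental trends in the variance itself; or any
mean–variance coupling beyond the additive genetic correlation. Parameter
recovery (unbiasedness of $h^2$ and $r_g$) is assessed on unselected
replicates of the same design: under selection, the animal model's
normal-likelihood assumptions are violated by the multiplicative estimator
noise and the posterior overstates $\sigma_u^2$ by roughly 40% — a
model-misspecification effect worth remembering when interpreting
variance-component estimates from selected populations.

## Numerical conventions

Tie-breaks are stable sorts on (criterion, doe id). Residual variances are
floored at $10^{-8}$. Non-PD inverse-Wishart draws are jittered through a
determinant floor. Chi-square degrees of freedom are clamped at ≥ 1.
Problem sizes in the test suite: full experiment scale (2 lines × 125 does
× 10 generations, ≈ 12,400 litters, ≈ 3,300 animals) for the calibrated
response, recovery and null-control suites — with 8–20 replicates and
8,000–12,000-iteration chains — and reduced designs (25 does × 4–5
generations) for structural unit tests. One global seed drives every
source of randomness; per-replicate seeds are spawned deterministically
from it.
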