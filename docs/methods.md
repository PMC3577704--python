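# Methods

## Stage 1: hierarchical beta-binomial stranding model

Drifter release positions are binned into square lat/lon quadrats. The model
is

    m_j ~ Binomial(N_j, p_j),   p_j ~ Beta(α, β),   j = 1..J,

with independent Uniform(0, 100) priors on α and β by default (a
Gamma(0.001, 0.001) alternative is selectable with `prior="gamma"`; the
prior used is recorded in the run metadata). The model assumes quadrats are
exchangeable given (α, β) — no spatial correlation between neighbouring
quadrats and no covariates (wind, currents, distance from shore) — and that
detection of a stranded drifter on a monitored beach is certain and equal
across sites.

**Sampling.** The conditional posterior of each p_j is conjugate,
p_j | α, β, data ~ Beta(α + m_j, β + N_j − m_j), so the p_j are marginalised
analytically and MCMC runs only on θ = (log α, log β):

    P(m | N, α, β) ∝ Π_j B(α + m_j, β + N_j − m_j) / B(α, β).

The sampler is a random-walk Metropolis with all chains advanced in lockstep
(vectorised proposals). During tuning the scalar step size adapts toward a
30% acceptance rate every 100 steps, and halfway through tuning the proposal
covariance of each chain is replaced by the empirical covariance of its
tuning history scaled by 2.38²/2 (the standard adaptive-Metropolis factor;
log α and log β are strongly correlated, so this matters for mixing). Tuning
draws are discarded; retained draws are thinned. Defaults mirror the field
protocol — 5 chains, 20,000 tuning steps, 100,000 sampling steps, thin 5 —
but tests and examples use reduced settings (typically 3–4 chains, 1,500–
5,000 tuning and 4,500–20,000 sampling steps), which the 2-D marginalised
posterior mixes well enough to support; the oracle-equivalence tests bound
the Monte-Carlo error directly. Convergence is flagged with the Gelman–Rubin
statistic (threshold 1.1) and effective sample sizes from arviz; the seed is
mandatory and identical config + seed reproduces draws exactly.

**Site summary.** The site stranding probability p̃ is the mode of the
hyper-distribution, (α − 1)/(α + β − 2) for α, β > 1. The mode transform is
applied per posterior draw; the point estimate is the posterior median of
those per-draw modes and the 95% interval their 2.5%/97.5% quantiles. This
propagates hyper-parameter uncertainty into p̃, which is how the published
intervals behave. The plug-in alternative (mode at the posterior means of α
and β) is exposed as `p_tilde_plugin()`. Per-draw boundary modes (α ≤ 1 maps
to 0, β ≤ 1 maps to 1) are retained and their fraction reported; draws with
both parameters ≤ 1 have no defined mode, are dropped from the p̃ summary,
and are likewise reported. Per-quadrat uncertainty is summarised by the
coefficient of variation sd(p_j)/mean(p_j), the quantity drawn as circles on
the stranding-probability maps.

**Gridding.** Cells are half-open [lo, hi) on both axes so the plane is
partitioned; a float-round-off guard snaps coordinates that compute to
within 1e-9 of a cell seam up to the seam, keeping the convention exact in
floating point. The default grid anchor is the integer-degree corner
south-west of the data's bounding box; counts are invariant to shifting the
anchor by whole cells (tested). Cell-size selection scans candidate sizes
(0.01°–0.05°) and returns the smallest for which every non-empty quadrat
holds at least `min_per_quadrat` releases, with the full occupancy trace
logged; if none qualifies the largest candidate is returned flagged.
Recoveries with illegible drifter codes have no known source quadrat: they
are excluded from every m_j but kept in the trial-level retrieved total used
for recovery-rate summaries. Grouping by retrieval box is available
(m_j = recoveries found in the box, N_j = releases from the box) but m ≤ N
is not guaranteed there, and the hierarchical model accepts deployment-mode
tables only.

## Stage 2: mortality models

With c observed carcasses of one species in a 15-day window (centred on the
midpoint of the deployment dates, inclusive on both ends), the
binomial–Poisson model is

    c ~ Binomial(C_total, p̃),  C_total ~ Poisson(μ),
    μ ~ Gamma(shape = c²/v, rate = c/v)    (mean c, variance v; default v = 100),

the gamma parameters obtained by moment matching from the stated mean and
variance. Conditional on (μ, p̃), c and u = C_total − c are independent
Poisson(μp̃) and Poisson(μ(1 − p̃)); hence μ | c, p̃ ~ Gamma(shape + c,
rate + p̃) and u | μ, p̃ ~ Poisson(μ(1 − p̃)). The sampler draws (p̃, μ, u)
in that order per iteration — exact, independent Monte Carlo draws from the
joint posterior rather than a Markov chain. The dual-route check against
exhaustive summation over C_total (using the closed-form gamma-Poisson
marginal, `log_pmf_fixed_p`) is part of the test suite.

The negative-binomial alternative draws u ~ NegativeBinomial(c, p̃) — u
failures (un-stranded carcasses) before the c-th success at probability p̃ —
per p̃ draw; C_total = c + u. Its posterior spread exceeds the
binomial–Poisson model's on low-p̃ inputs (tested), because the gamma prior
on μ shrinks the binomial–Poisson posterior.

p̃ uncertainty enters by drawing one p̃ per iteration from the stage-1
hyper-mode draws (resampled with replacement if lengths differ), or from a
Beta(α, β) reconstructed from a published mode and 95% interval when only a
summary line is available (`fit_beta_from_summary`, a least-squares match of
the mode and both interval endpoints in (log α, log β) space, multi-start,
with the residual reported and a warning above 0.02). Draws of p̃ = 0 are
clipped to 1e-9 so both samplers remain proper.

Point estimates of C_total are posterior means rounded half-away-from-zero
to integers (reports count animals); every posterior draw satisfies
C_total ≥ c by construction. c = 0 is refused: the gamma prior with mean 0
is degenerate and the negative-binomial has no success to condition on —
merge species or widen the window instead.

**Prior sensitivity.** `prior_sensitivity` reruns the binomial–Poisson model
across gamma-prior variances (the study values are 100 and 50) and reports
the maximum relative difference in posterior means. The effect is small when
p̃ is moderate or large (c = 11, p̃ mode 0.36: ≈7%; c = 1, p̃ mode 0.79:
≈0.1%) but necessarily large when p̃ is small: at c = 13, p̃ mode 0.05 the
count carries little information about μ (the likelihood for μ has scale
c/p̃), and exact integration puts the variance-50 vs variance-100 difference
at ≈42%. This is a property of the model, not of the sampler; users
estimating mortality at low-stranding-probability sites should treat the
prior variance as an assumption to be reported, not a nuisance setting.

## Synthetic data

The generator draws from exactly the generative model above: deployment
points on boustrophedon transect lines (spacing 0.3–1 km, default 0.5 km)
inside each quadrat, p_j ~ Beta(α*, β*), m_j ~ Binomial(N_j, p_j), recovery
lags geometric over days 1–10 (most stranded drifters are found within a few
days), per-species deaths Poisson(μ* × species mix) thinned
Binomial(·, p̃*). Default magnitudes follow the study conditions: per-trial
deployments of order 10²–10³, hyper modes spanning 0.05–0.8 across the
nine-trial bundle (total 4752 drifters), per-window observed counts of order
1–13, species mix 62/31/6/1% (loggerhead/green/olive ridley/hawksbill),
gear-mark probability 2%, seasonal peak in July. CCL is cosmetic (truncated
normal, 70 ± 12 cm) — no published size statistics constrain it. Because
the generator and the models share one data-generating process, passing
recovery/coverage tests demonstrates correctness of the inference, not
robustness to real-data violations (drift physics, carcass decay, imperfect
detection, spatially correlated p_j) — none of which are modelled.

## Numerical and design notes

- Mode of Beta(α, β): interior formula for α, β > 1; 0 when α ≤ 1 < β; 1
  when β ≤ 1 < α; undefined (NaN, flagged) when both ≤ 1.
- Uniform(0, 100) prior bounds are also the quadrature box of the
  grid-integration oracle used in tests, making the two routes directly
  comparable.
- Metropolis initialisation is a method-of-moments estimate from the
  observed m_j/N_j, jittered per chain; with one quadrat the hyper-pair is
  weakly identified and the prior upper bound matters — the single-quadrat
  oracle test covers this regime.
- Monte-Carlo standard errors use sd/√ESS for MCMC draws and sd/√n for the
  exact mortality samplers; stochastic tests assert within 3 such errors.
- Test problem sizes (30 quadrats × 100 drifters for coverage runs, 100
  replicates; reduced chain settings) were chosen as the smallest designs at
  which the checked frequentist properties are expected to hold with the
  stated margins.
- Published drifter-trial summaries are bundled as a dataset; two published
  inconsistencies are preserved as printed and noted here: the gear-mark
  fraction prints as 1.8% while 10/594 computes to 1.7%, and the October
  2011 expected-deaths value appears as 10, 11 or 12 in different parts of
  the source (the summary-table value, 10, is bundled).

## Limitations

- No spatial correlation between quadrat stranding probabilities and no
  environmental covariates; estimates are site × trial specific and not
  transferable across sites or seasons.
- Drifters are assumed to mimic carcass drift and to be detected perfectly
  on monitored beaches; violations bias p̃ and hence C_total.
- 15-day-window estimates are not extrapolated to annual mortality.
- With a single quadrat or very low counts the hyper-parameters are weakly
  identified and results depend visibly on the vague-prior choice; the
  boundary-mode fraction and convergence flags should be inspected.
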