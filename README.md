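# driftstrand

Bayesian estimation of at-sea mortality of marine megafauna from beach
strandings and marked-drifter experiments.

## The problem

Carcasses of sea turtles (and other marine megafauna) killed at sea — most
often as bycatch in small-scale coastal fisheries — are only counted when
they wash ashore on a monitored beach. The probability that a floating
carcass strands is usually small and varies strongly between sites and
between months at the same site, so raw stranding counts cannot be compared
or converted into mortality without measuring that probability. A practical
way to measure it is a mark-recovery drifter experiment: release hundreds of
individually branded surface drifters (e.g. oranges, which float like a
buoyant carcass) along transects in the fishing area, then patrol the
beaches and record which ones strand.

`driftstrand` implements the resulting two-stage inference:

**Stage 1 — stranding probability.** Release positions are grouped into
quadrats j = 1, …, J (lat/lon cells of 0.01°–0.05° per side). With N_j
drifters released in quadrat j and m_j of them recovered ashore,

    m_j ~ Binomial(N_j, p_j),        p_j ~ Beta(α, β),

with vague priors on (α, β). The site-level stranding probability p̃ is
summarised by the mode of the Beta hyper-distribution, with a 95% posterior
interval obtained by propagating the MCMC draws of (α, β) through the mode
transform. The quadrat probabilities p_j are conjugate given (α, β), so the
sampler (an adaptive random-walk Metropolis on (log α, log β), five chains,
tuned, thinned, Gelman–Rubin checked) works on the marginalised
two-parameter posterior and reconstitutes the p_j exactly.

**Stage 2 — total mortality.** Given c carcasses of one species observed
during a 15-day window centred on the drifter deployment dates, the total
number of deaths C_total (including carcasses that never stranded) follows

    c ~ Binomial(C_total, p̃),   C_total ~ Poisson(μ),
    μ ~ Gamma(mean = c, variance = 100)            (binomial–Poisson model)

or, alternatively, u = C_total − c modelled directly as
NegativeBinomial(c, p̃) failures before the c-th success
(negative-binomial model). One p̃ value per iteration is drawn from the
stage-1 posterior, so stranding-probability uncertainty propagates into the
mortality interval. The binomial–Poisson posterior factorises exactly
(μ | c, p̃ is conjugate gamma and u | μ, p̃ is Poisson), so both models are
sampled by exact Monte Carlo.

The package also ships the quadrat gridding utilities, descriptive summaries
(recovery rates, species composition, site shares, seasonality, gear-mark
fraction, per-km stranding rates), a seeded synthetic-data generator that
draws from exactly the generative model above, the published Baja California
Sur trial summaries as a built-in dataset, and a CLI.

## Worked example

```python
import driftstrand as ds

# a synthetic trial shaped like a high-stranding site: 506 drifters,
# quadrat probabilities from Beta(20.75, 6.25) (hyper mode 0.79)
cfg = ds.SyntheticSiteConfig(site_id="GNO", seed=42, true_alpha=20.75,
                             true_beta=6.25, n_quadrats=11,
                             deployments_total=506)
deployments, recoveries, truth = ds.generate_trial(cfg)
counts = ds.tabulate_counts(deployments, recoveries, cfg.grid)

res = ds.StrandingModel(counts).fit(
    ds.McmcConfig(seed=1, n_chains=4, n_tune=5000, n_sample=20000, thin=2))
print(f"p~ = {res.p_tilde_point:.2f}, 95% PI "
      f"[{res.p_tilde_interval[0]:.2f}, {res.p_tilde_interval[1]:.2f}]")

mort = ds.MortalityModel(c=6, stranding=res).fit(n_draws=100_000, seed=2)
print(f"total deaths over 15 days: {mort.point_estimate}, 95% PI "
      f"[{mort.interval[0]:.0f}, {mort.interval[1]:.0f}]")
```

prints

```
p~ = 0.82, 95% PI [0.76, 0.88]
total deaths over 15 days: 7, 95% PI [6, 11]
```

The fitted site stranding probability (0.82) recovers the generator's true
hyper-mode of 0.79 within its interval, and the 6 observed carcasses imply
roughly 7 total deaths — at a site where most carcasses strand, the observed
count is close to the truth. At a site with p̃ ≈ 0.05 the same 6 carcasses
would imply dozens of deaths.

The same workflow from the shell:

```
driftstrand simulate --seed 5 --out-dir runs/bundle
driftstrand fit-stranding --deployments runs/bundle/trial_08_GNO/deployments.csv \
    --recoveries runs/bundle/trial_08_GNO/recoveries.csv \
    --cell-size 0.04 --seed 1 --out-dir runs/gno
driftstrand estimate-mortality --carcasses runs/bundle/trial_08_GNO/carcasses.csv \
    --draws runs/gno/draws.csv --site GNO \
    --deploy-start 2010-07-26 --deploy-end 2010-07-30 \
    --model binomial_poisson --model negative_binomial \
    --seed 2 --out runs/gno/mortality.csv
```

`driftstrand reproduce-published --seed 1 --out table.csv` rebuilds every
published expected-deaths cell from the printed stranding-probability
summaries, and `driftstrand prior-sensitivity` compares gamma-prior
variances (e.g. 50 vs 100).

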