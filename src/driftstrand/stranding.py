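"""Hierarchical beta-binomial model for shoreline stranding probabilities.

The stranding of a passively drifting object released in quadrat j is a
Bernoulli trial with quadrat-specific probability p_j, so the number of
marked drifters recovered ashore out of N_j released is

    m_j ~ Binomial(N_j, p_j),      p_j ~ Beta(alpha, beta),

with vague priors on the hyper-parameters (alpha, beta).  The site-level
stranding probability is summarised by the mode of the Beta
hyper-distribution, propagated through the posterior draws of (alpha, beta)
so that its 95% posterior interval reflects hyper-parameter uncertainty.

Because the p_j are conjugate given (alpha, beta) — their full conditional is
Beta(alpha + m_j, beta + N_j - m_j) — the sampler marginalises them
analytically and runs Markov chain Monte Carlo on (log alpha, log beta) only,
using an adaptive random-walk Metropolis kernel with per-chain covariance
adaptation during the tuning phase.  Quadrat-level draws are reconstituted
exactly from the retained hyper-parameter draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "BetaHyper",
    "McmcConfig",
    "StrandingModel",
    "StrandingResults",
    "beta_mode",
    "beta_mode_draws",
    "fit_beta_from_summary",
]

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class BetaHyper:
    """Beta(alpha, beta) hyper-distribution of quadrat stranding probabilities."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"Beta parameters must be positive, got {self}")

    @property
    def mode(self) -> float:
        return beta_mode(self.alpha, self.beta)

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2
        return tuple(stats.beta.ppf([lo, 1 - lo], self.alpha, self.beta))


def beta_mode(alpha, beta):
    """Mode of a Beta(alpha, beta) density.

    Interior mode (alpha-1)/(alpha+beta-2) when both parameters exceed 1;
    0 when alpha <= 1 < beta, 1 when beta <= 1 < alpha; NaN when both are
    <= 1 (the density is bimodal at the boundary or uniform, so no single
    mode exists).  Accepts scalars; see :func:`beta_mode_draws` for arrays.
    """
    if isinstance(alpha, BetaHyper):  # beta_mode(hyper)
        alpha, beta = alpha.alpha, alpha.beta
    if not (alpha > 0 and beta > 0):
        raise ValueError("Beta parameters must be positive")
    if alpha > 1 and beta > 1:
        return (alpha - 1) / (alpha + beta - 2)
    if alpha <= 1 < beta:
        return 0.0
    if beta <= 1 < alpha:
        return 1.0
    return float("nan")


def beta_mode_draws(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Vectorised beta_mode with the boundary convention alpha=beta<=1 -> NaN."""
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    out = np.full(np.broadcast_shapes(a.shape, b.shape), np.nan)
    interior = (a > 1) & (b > 1)
    out[interior] = ((a - 1) / (a + b - 2))[interior]
    out[(a <= 1) & (b > 1)] = 0.0
    out[(b <= 1) & (a > 1)] = 1.0
    return out


@dataclass(frozen=True)
class McmcConfig:
    """Markov chain Monte Carlo settings.

    Defaults follow the field protocol for this model: five independent
    chains, 20,000 tuning steps, 100,000 sampling steps thinned every five.
    Tests and exploratory fits scale these down.  ``seed`` is mandatory:
    identical seed and config produce identical draws.
    """

    seed: int
    n_chains: int = 5
    n_tune: int = 20_000
    n_sample: int = 100_000
    thin: int = 5

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_tune < 0 or self.n_sample < self.thin:
            raise ValueError("invalid step counts")


def _log_prior(a: np.ndarray, b: np.ndarray, prior: str) -> np.ndarray:
    if prior == "uniform":
        lp = np.where((a < 100.0) & (b < 100.0), 0.0, -np.inf)
    elif prior == "gamma":
        # Gamma(shape 0.001, rate 0.001) on each hyper-parameter
        lp = 0.001 * (np.log(a) + np.log(b)) - 0.001 * (a + b)
    else:  # pragma: no cover - guarded at construction
        raise ValueError(prior)
    return lp


def _log_posterior_theta(
    theta: np.ndarray, N: np.ndarray, m: np.ndarray, prior: str
) -> np.ndarray:
    """Log posterior of theta = (log alpha, log beta), chains stacked on axis 0.

    The quadrat probabilities are marginalised analytically:
    P(m_j | N_j, a, b) ∝ B(a + m_j, b + N_j - m_j) / B(a, b).
    The log |Jacobian| of the log transform (log a + log b) is included.
    """
    a = np.exp(theta[..., 0])
    b = np.exp(theta[..., 1])
    lp = _log_prior(a, b, prior) + theta[..., 0] + theta[..., 1]
    aa = a[..., None]
    bb = b[..., None]
    loglik = np.sum(
        special.betaln(aa + m, bb + (N - m)) - special.betaln(aa, bb), axis=-1
    )
    return lp + loglik


def _moment_init(N: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    """Method-of-moments starting point for (alpha, beta)."""
    phat = (m + 0.5) / (N + 1.0)
    mu = float(np.mean(phat))
    var = float(np.var(phat)) if len(phat) > 1 else mu * (1 - mu) / 10
    var = min(max(var, 1e-4), mu * (1 - mu) * 0.9)
    kappa = mu * (1 - mu) / var - 1
    kappa = min(max(kappa, 0.5), 200.0)
    return float(np.clip(mu * kappa, 0.05, 90.0)), float(
        np.clip((1 - mu) * kappa, 0.05, 90.0)
    )


class StrandingModel:
    """Hierarchical beta-binomial model of quadrat stranding counts.

    Parameters
    ----------
    counts
        DataFrame with integer columns ``N`` (drifters deployed per quadrat)
        and ``m`` (of those, found stranded), e.g. the output of
        :func:`driftstrand.gridding.tabulate_counts`.  Any extra columns
        (row/col/centres) are carried through to the results.
    prior
        ``"uniform"``: independent Uniform(0, 100) on alpha and beta
        (default); ``"gamma"``: Gamma(0.001, 0.001) on each.

    Examples
    --------
    >>> counts = pd.DataFrame({"N": [120, 95, 140], "m": [10, 4, 15]})
    >>> res = StrandingModel(counts).fit(McmcConfig(seed=7, n_chains=4,
    ...     n_tune=2000, n_sample=8000, thin=2))
    >>> 0 < res.p_tilde_point < 1
    True
    """

    def __init__(self, counts: pd.DataFrame, prior: str = "uniform"):
        if prior not in ("uniform", "gamma"):
            raise ValueError(f"unknown prior {prior!r}")
        counts = counts.reset_index(drop=True)
        N = counts["N"].to_numpy(dtype=float)
        m = counts["m"].to_numpy(dtype=float)
        if len(N) < 1:
            raise ValueError("need at least one quadrat")
        if np.any(N < 1):
            raise ValueError("every quadrat must have N >= 1 deployments")
        if np.any((m < 0) | (m > N)):
            raise ValueError("stranded counts must satisfy 0 <= m <= N")
        self.counts = counts
        self.N = N
        self.m = m
        self.prior = prior

    @classmethod
    def from_counts(cls, N, m, prior: str = "uniform") -> "StrandingModel":
        return cls(pd.DataFrame({"N": np.asarray(N), "m": np.asarray(m)}), prior=prior)

    def log_posterior(self, alpha: float, beta: float) -> float:
        """Unnormalised log posterior density at (alpha, beta), natural scale."""
        theta = np.log([[alpha, beta]])
        # subtract the Jacobian added by the theta parameterisation
        return float(
            _log_posterior_theta(theta, self.N, self.m, self.prior)[0]
            - np.log(alpha)
            - np.log(beta)
        )

    def fit(self, mcmc: McmcConfig | None = None, **kwargs) -> "StrandingResults":
        """Run the sampler and summarise the posterior.

        ``kwargs`` are forwarded to :class:`McmcConfig` when ``mcmc`` is not
        given (``seed`` is then required).
        """
        if mcmc is None:
            mcmc = McmcConfig(**kwargs)
        theta_chains, accept_rate = self._sample_hyper(mcmc)

        nchains, ndraws, _ = theta_chains.shape
        alpha_c = np.exp(theta_chains[..., 0])
        beta_c = np.exp(theta_chains[..., 1])
        idata = az.from_dict(posterior={"alpha": alpha_c, "beta": beta_c})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        diagnostics = pd.DataFrame(
            {
                "rhat": [float(rhat["alpha"]), float(rhat["beta"])],
                "ess": [float(ess["alpha"]), float(ess["beta"])],
            },
            index=["alpha", "beta"],
        )

        alpha = alpha_c.reshape(-1)
        beta = beta_c.reshape(-1)
        rng = np.random.default_rng(np.random.SeedSequence(mcmc.seed).spawn(1)[0])
        # conjugate reconstruction of the quadrat-level probabilities
        p_draws = rng.beta(alpha[:, None] + self.m, beta[:, None] + (self.N - self.m))

        return StrandingResults(
            model=self,
            mcmc=mcmc,
            alpha_draws=alpha,
            beta_draws=beta,
            chain_shape=(nchains, ndraws),
            p_draws=p_draws,
            diagnostics=diagnostics,
            accept_rate=accept_rate,
        )

    # ----------------------------------------------------------- sampler --
    def _sample_hyper(self, mcmc: McmcConfig) -> tuple[np.ndarray, float]:
        """Adaptive random-walk Metropolis on theta = (log alpha, log beta).

        All chains advance in lockstep through vectorised proposals.  During
        tuning the scalar step size adapts toward a 30% acceptance rate and,
        halfway through, the proposal covariance is re-estimated per chain
        from the tuning history (the classic adaptive-Metropolis scaling
        2.38^2/d).  Tuning draws are discarded; retained draws are thinned.
        """
        rng = np.random.default_rng(mcmc.seed)
        C = mcmc.n_chains
        a0, b0 = _moment_init(self.N, self.m)
        theta = np.log([a0, b0]) + 0.25 * rng.standard_normal((C, 2))
        logp = _log_posterior_theta(theta, self.N, self.m, self.prior)

        scale = np.full(C, 0.3)
        chol = np.broadcast_to(np.eye(2), (C, 2, 2)).copy()
        accepted = np.zeros(C)
        window = np.zeros(C)
        half = mcmc.n_tune // 2
        history = np.empty((half, C, 2)) if half > 0 else None

        n_keep = mcmc.n_sample // mcmc.thin
        out = np.empty((C, n_keep, 2))
        kept = 0

        total = mcmc.n_tune + mcmc.n_sample
        for step in range(total):
            z = rng.standard_normal((C, 2))
            prop = theta + scale[:, None] * np.einsum("cij,cj->ci", chol, z)
            logp_prop = _log_posterior_theta(prop, self.N, self.m, self.prior)
            with np.errstate(invalid="ignore"):
                # -inf proposals against -inf states give NaN; NaN compares False
                accept = np.log(rng.random(C)) < (logp_prop - logp)
            theta[accept] = prop[accept]
            logp[accept] = logp_prop[accept]

            if step < mcmc.n_tune:
                accepted += accept
                window += 1
                if history is not None and step < half:
                    history[step] = theta
                if (step + 1) % 100 == 0:
                    rate = accepted / window
                    scale *= np.exp(1.5 * (rate - 0.3))
                    scale = np.clip(scale, 1e-3, 10.0)
                    accepted[:] = 0
                    window[:] = 0
                if history is not None and step + 1 == half:
                    for c in range(C):
                        cov = np.cov(history[:, c, :].T)
                        cov += 1e-6 * np.eye(2)
                        try:
                            chol[c] = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            pass
                    scale[:] = 2.38 / np.sqrt(2.0)
            else:
                s = step - mcmc.n_tune
                accepted += accept
                window += 1
                if (s + 1) % mcmc.thin == 0 and kept < n_keep:
                    out[:, kept, :] = theta
                    kept += 1

        accept_rate = float(np.mean(accepted / np.maximum(window, 1)))
        return out[:, :kept, :], accept_rate


@dataclass
class StrandingResults:
    """Posterior of the hierarchical stranding model.

    The site-level stranding probability point estimate ``p_tilde_point`` is
    the posterior median of the per-draw hyper-distribution mode
    ``beta_mode(alpha, beta)`` and ``p_tilde_interval`` its central 95%
    quantiles; draws where both hyper-parameters fall at or below 1 have no
    defined mode and are dropped from this summary (their fraction is
    reported as ``undefined_mode_fraction``).  Draws with a boundary mode
    (exactly 0 or 1) are retained; ``boundary_mode_fraction`` reports how
    common they are.
    """

    model: StrandingModel
    mcmc: McmcConfig
    alpha_draws: np.ndarray
    beta_draws: np.ndarray
    chain_shape: tuple[int, int]
    p_draws: np.ndarray = field(repr=False)
    diagnostics: pd.DataFrame
    accept_rate: float

    def __post_init__(self) -> None:
        self.mode_draws = beta_mode_draws(self.alpha_draws, self.beta_draws)
        finite = self.mode_draws[np.isfinite(self.mode_draws)]
        self.undefined_mode_fraction = 1.0 - finite.size / self.mode_draws.size
        self.boundary_mode_fraction = (
            float(np.mean((finite == 0.0) | (finite == 1.0))) if finite.size else 1.0
        )
        if finite.size:
            self.p_tilde_point = float(np.median(finite))
            self.p_tilde_interval = (
                float(np.quantile(finite, 0.025)),
                float(np.quantile(finite, 0.975)),
            )
        else:
            self.p_tilde_point = float("nan")
            self.p_tilde_interval = (float("nan"), float("nan"))

    # ------------------------------------------------------------ summaries
    @property
    def J(self) -> int:
        return len(self.model.N)

    @property
    def n_draws(self) -> int:
        return self.alpha_draws.size

    @property
    def converged(self) -> bool:
        return bool((self.diagnostics["rhat"] < RHAT_THRESHOLD).all())

    @property
    def boundary_counts(self) -> bool:
        """True when the data are degenerate (all m_j = 0 or all m_j = N_j)."""
        m, N = self.model.m, self.model.N
        return bool(np.all(m == 0) or np.all(m == N))

    def p_tilde_plugin(self) -> float:
        """Alternative point estimate: mode at the posterior means of (alpha, beta)."""
        return beta_mode(float(np.mean(self.alpha_draws)), float(np.mean(self.beta_draws)))

    def quadrat_cv(self, j: int) -> float:
        """Posterior coefficient of variation (sd/mean) of p_j.

        A CV of 1.0 corresponds to a quadrat whose stranding probability is
        essentially unresolved (drawn on maps as a circle filling the cell).
        NaN when the posterior mean is zero.
        """
        d = self.p_draws[:, j]
        mean = float(np.mean(d))
        if mean == 0:
            return float("nan")
        return float(np.std(d) / mean)

    def quadrat_summary(self) -> pd.DataFrame:
        """Per-quadrat posterior mean, 95% interval and CV of p_j."""
        mean = self.p_draws.mean(axis=0)
        sd = self.p_draws.std(axis=0)
        lo, hi = np.quantile(self.p_draws, [0.025, 0.975], axis=0)
        out = self.model.counts.copy()
        out["p_mean"] = mean
        out["p_lo"] = lo
        out["p_hi"] = hi
        with np.errstate(invalid="ignore", divide="ignore"):
            out["cv"] = np.where(mean > 0, sd / mean, np.nan)
        return out

    def summary(self) -> pd.DataFrame:
        """Posterior summary table for the hyper-parameters and the site p̃."""
        rows = []
        for name, draws in [
            ("alpha", self.alpha_draws),
            ("beta", self.beta_draws),
            ("p_tilde", self.mode_draws[np.isfinite(self.mode_draws)]),
        ]:
            q = np.quantile(draws, [0.025, 0.5, 0.975]) if draws.size else [np.nan] * 3
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(draws)) if draws.size else np.nan,
                    "sd": float(np.std(draws)) if draws.size else np.nan,
                    "q2.5": q[0],
                    "median": q[1],
                    "q97.5": q[2],
                    "rhat": self.diagnostics["rhat"].get(name, np.nan),
                    "ess": self.diagnostics["ess"].get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def draws_frame(self) -> pd.DataFrame:
        """All retained draws in plain columnar form (alpha, beta, p_tilde, p_j)."""
        data = {
            "alpha": self.alpha_draws,
            "beta": self.beta_draws,
            "p_tilde": self.mode_draws,
        }
        for j in range(self.J):
            data[f"p_{j}"] = self.p_draws[:, j]
        return pd.DataFrame(data)

    def mc_standard_error(self, param: str = "alpha") -> float:
        """Monte-Carlo standard error of the posterior mean via effective sample size."""
        draws = {"alpha": self.alpha_draws, "beta": self.beta_draws}[param]
        ess = float(self.diagnostics["ess"][param])
        return float(np.std(draws) / np.sqrt(max(ess, 1.0)))


def fit_beta_from_summary(
    mode: float, lo: float, hi: float, tol: float = 0.02
) -> tuple[BetaHyper, float]:
    """Recover Beta(alpha, beta) from a printed mode and 95% interval.

    Minimises the squared mismatch between {mode, 2.5% quantile, 97.5%
    quantile} of a Beta(alpha, beta) and the three targets — the inverse of
    how published stranding probabilities are reported, needed to rebuild a
    hyper-distribution from a summary line.  Returns the fitted hyper and the
    largest absolute residual; a residual above ``tol`` triggers a warning.
    """
    if not (0 < lo < mode < hi < 1):
        raise ValueError("need 0 < lo < mode < hi < 1 (interior mode)")

    def residuals(x):
        a, b = np.exp(x)
        if a > 1 and b > 1:
            md = (a - 1) / (a + b - 2)
        else:
            md = 0.0 if a <= 1 else 1.0
        q_lo, q_hi = stats.beta.ppf([0.025, 0.975], a, b)
        return [md - mode, q_lo - lo, q_hi - hi]

    best = None
    for a0, b0 in [(2.0, 2.0), (5.0, 5.0), (mode * 30 + 1, (1 - mode) * 30 + 1)]:
        sol = optimize.least_squares(residuals, x0=np.log([a0, b0]), method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    a, b = np.exp(best.x)
    resid = float(np.max(np.abs(best.fun)))
    if resid > tol:
        warnings.warn(
            f"beta summary fit residual {resid:.3g} exceeds tolerance {tol}",
            stacklevel=2,
        )
    return BetaHyper(float(a), float(b)), resid
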