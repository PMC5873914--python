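"""Hierarchical Bayesian estimation of logistic growth-curve traits.

A three-level model for longitudinal size measurements within one
trait × treatment × year stratum:

* observation:  y_ijk ~ N( L(t_ijk; θ_ij), σ² )   with L the logistic curve,
* plant:        log θ_ij ~ N( g_i + β·a_i, τ_p² )  componentwise for
  θ = (r, Lmax, L0); a_i is the genotype's centered photosynthetic
  capacity (A_max) when supplied, shifting the plant-level prior means,
* genotype:     g_i ~ N( μ, τ_g² ),
* global:       μ with a weakly informative normal hyperprior scaled to
  the data range.

Parameters are sampled on the log scale, which guarantees positivity of
r, Lmax and L0.  Sampling is Metropolis-within-Gibbs: the non-conjugate
plant-level curve parameters move by adaptive random-walk Metropolis
(adaptation during burn-in only, preserving detailed balance afterwards);
genotype means, the global mean, the covariate slope and all variances
are conjugate Gibbs updates.  A single chain is the default protocol;
the full-length preset matches 500,000 iterations with 440,000 burn-in
thinned 1-in-20 (3,000 retained draws), and a short preset is provided
for simulation studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import logistic_size_raw

__all__ = [
    "MCMCConfig",
    "PAPER_MCMC",
    "TEST_MCMC",
    "HierarchicalPosterior",
    "CredibleEnvelope",
    "retained_sample_count",
    "fit_hierarchical",
    "credible_envelopes",
    "autocorrelation",
    "effective_sample_size",
    "chain_diagnostics",
    "convergence_report",
]

PARAM_NAMES = ("r", "Lmax", "L0")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length bookkeeping and proposal settings."""

    iterations: int = 500_000
    burn_in: int = 440_000
    thin: int = 20
    initial_step: float = 0.05
    target_accept: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError(
                f"burn_in ({self.burn_in}) must be < iterations ({self.iterations})"
            )
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


#: Full-length single-chain protocol (3,000 retained draws).
PAPER_MCMC = MCMCConfig()
#: Short chain for simulation studies and tests (1,000 retained draws).
TEST_MCMC = MCMCConfig(iterations=8_000, burn_in=4_000, thin=4)


def retained_sample_count(config: MCMCConfig) -> int:
    """Number of retained posterior draws: (iterations − burn_in) // thin."""
    return (config.iterations - config.burn_in) // config.thin


@dataclass
class HierarchicalPosterior:
    """Retained MCMC samples for every level of the hierarchy.

    Shapes: ``mu`` (S, 3); ``genotype`` (S, n_geno, 3); ``plant``
    (S, n_plants, 3) — all on the log scale; ``tau_g``/``tau_p`` (S, 3);
    ``sigma`` (S,); ``beta`` (S, 3) or None.  ``S`` equals the configured
    retained count for every parameter.
    """

    config: MCMCConfig
    genotypes: pd.Index
    plants: pd.Index
    plant_genotype: np.ndarray  # plant -> genotype row index
    mu: np.ndarray
    genotype: np.ndarray
    plant: np.ndarray
    tau_g: np.ndarray
    tau_p: np.ndarray
    sigma: np.ndarray
    beta: np.ndarray | None
    amax_centered: pd.Series | None
    accept_rate: np.ndarray  # per plant
    diverged: bool
    trait_label: str = "leaf_width"

    def genotype_draws(self, genotype) -> np.ndarray:
        """Natural-scale (r, Lmax, L0) draws of one genotype's mean curve
        parameters, covariate shift included; shape (S, 3)."""
        i = self.genotypes.get_loc(genotype)
        logp = self.genotype[:, i, :].copy()
        if self.beta is not None and self.amax_centered is not None:
            a = self.amax_centered.get(genotype, 0.0)
            logp = logp + self.beta * a
        return np.exp(logp)

    def genotype_summary(self) -> pd.DataFrame:
        """Posterior summaries per genotype for r, Lmax, L0, d, iD."""
        rows = []
        for g in self.genotypes:
            draws = self.genotype_draws(g)
            r, Lmax, L0 = draws[:, 0], draws[:, 1], draws[:, 2]
            a = (Lmax - L0) / L0
            with np.errstate(invalid="ignore"):
                iD = np.where(L0 < Lmax / 2, np.log(np.maximum(a, 1e-300)) / r, 0.0)
            d = np.log(a * 0.95 / 0.05) / r
            rec = {"genotype": g}
            for name, x in zip(("r", "Lmax", "L0", "d", "iD"), (r, Lmax, L0, d, iD)):
                rec[f"{name}_mean"] = float(np.mean(x))
                rec[f"{name}_median"] = float(np.median(x))
                rec[f"{name}_q2.5"] = float(np.percentile(x, 2.5))
                rec[f"{name}_q97.5"] = float(np.percentile(x, 97.5))
            rows.append(rec)
        return pd.DataFrame(rows)


@dataclass
class CredibleEnvelope:
    """Dual 95% pointwise bands around one genotype's growth curve.

    ``inner`` bounds the genotype mean curve; ``outer`` is the posterior
    predictive band within which a future observation of a new plant of
    this genotype is expected to fall.
    """

    grid: np.ndarray
    inner_lo: np.ndarray
    inner_hi: np.ndarray
    outer_lo: np.ndarray
    outer_hi: np.ndarray
    level: float = 0.95
    genotype: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_dd": self.grid, "inner_lo": self.inner_lo,
             "inner_hi": self.inner_hi, "outer_lo": self.outer_lo,
             "outer_hi": self.outer_hi}
        )


def _init_plant_params(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """(log r, log Lmax, log L0) start values for one plant: nonlinear
    least squares when it converges, else a logit-slope heuristic."""
    Lmax0 = max(1.2 * np.max(y), 0.5)
    L00 = float(np.clip(y[np.argmin(t)], 0.02 * Lmax0, 0.4 * Lmax0))
    frac = np.clip(y / Lmax0, 0.02, 0.98)
    z = np.log(frac / (1.0 - frac))
    if t.size >= 2 and np.ptp(t) > 0:
        slope = np.polyfit(t, z, 1)[0]
    else:
        slope = 0.01
    r0 = float(np.clip(slope, 1e-4, 1.0))
    try:
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(
            lambda tt, r, Lm, L0: logistic_size_raw(r, Lm, L0, tt),
            t, y, p0=[r0, Lmax0, L00],
            bounds=([1e-5, 1e-2, 1e-3], [5.0, 1e4, 1e4]), maxfev=2000,
        )
        if popt[1] > popt[2]:
            return np.log(popt)
    except Exception:
        pass
    return np.log([r0, Lmax0, L00])


def fit_hierarchical(
    measurements: pd.DataFrame,
    amax: pd.Series | None = None,
    config: MCMCConfig = TEST_MCMC,
    trait_label: str = "leaf_width",
) -> HierarchicalPosterior:
    """Fit the three-level model to one trait/treatment/year stratum.

    ``measurements`` needs columns plant_id, genotype, t_dd, value (mm);
    each stratum is fit independently, so filter before calling.  ``amax``
    is an optional per-genotype covariate series; it is centered internally.
    """
    df = measurements
    for col in ("plant_id", "genotype", "t_dd", "value"):
        if col not in df.columns:
            raise ValueError(f"measurements missing column {col!r}")
    if (df["value"] <= 0).any():
        raise ValueError("non-positive sizes in data; sizes must be > 0 mm")
    counts = df.groupby("plant_id").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"plants with < 2 measurements: {bad[:5]}")

    plants = pd.Index(df["plant_id"].unique(), name="plant_id")
    plant_geno = df.drop_duplicates("plant_id").set_index("plant_id")["genotype"]
    genotypes = pd.Index(plant_geno.unique(), name="genotype")
    p_of_obs = plants.get_indexer(df["plant_id"])
    g_of_plant = genotypes.get_indexer(plant_geno.loc[plants])
    y = df["value"].to_numpy(float)
    t = df["t_dd"].to_numpy(float)
    n_obs, n_plants, n_geno = y.size, len(plants), len(genotypes)

    order = np.argsort(p_of_obs, kind="stable")
    y, t, p_of_obs = y[order], t[order], p_of_obs[order]
    obs_starts = np.searchsorted(p_of_obs, np.arange(n_plants + 1))
    n_per_plant = np.diff(obs_starts)

    if amax is not None:
        a_geno = amax.reindex(genotypes).fillna(amax.mean())
        a_geno = a_geno - a_geno.mean()
        a_plant = a_geno.to_numpy()[g_of_plant]
        amax_centered = a_geno
    else:
        a_plant = np.zeros(n_plants)
        amax_centered = None

    rng = np.random.default_rng(config.seed)

    # init
    theta = np.empty((n_plants, 3))
    for j in range(n_plants):
        sl = slice(obs_starts[j], obs_starts[j + 1])
        theta[j] = _init_plant_params(y[sl], t[sl])
    g = np.empty((n_geno, 3))
    for i in range(n_geno):
        g[i] = theta[g_of_plant == i].mean(axis=0)
    mu = g.mean(axis=0)
    beta = np.zeros(3)
    use_beta = amax is not None
    tau_g = np.full(3, 0.1)
    tau_p = np.full(3, 0.1)

    def curve_rss(th):
        params = np.exp(th)[p_of_obs]
        mu_obs = logistic_size_raw(params[:, 0], params[:, 1], params[:, 2], t)
        return mu_obs

    mu_obs = curve_rss(theta)
    sigma = float(np.std(y - mu_obs)) or 0.1

    # hyperpriors: weakly informative; the residual variance prior is vague
    # so the data dominate sigma
    m0 = mu.copy()
    s0 = 2.0
    a_tau, b_tau = 2.0, 0.01
    a_sig, b_sig = 0.01, 0.01

    def plant_loglik(mu_obs_all, sig):
        se = (y - mu_obs_all) ** 2
        per = np.add.reduceat(se, obs_starts[:-1])
        return -0.5 * per / sig**2 - n_per_plant * np.log(sig)

    ll_plant = plant_loglik(mu_obs, sigma)

    step = np.full((n_plants, 3), config.initial_step)
    acc_count = np.zeros((n_plants, 3))
    acc_window = np.zeros((n_plants, 3))
    n_ret = retained_sample_count(config)
    S_mu = np.empty((n_ret, 3))
    S_g = np.empty((n_ret, n_geno, 3))
    S_th = np.empty((n_ret, n_plants, 3))
    S_tg = np.empty((n_ret, 3))
    S_tp = np.empty((n_ret, 3))
    S_sig = np.empty(n_ret)
    S_beta = np.empty((n_ret, 3)) if use_beta else None
    kept = 0

    prior_mean_plant = g[g_of_plant] + beta * a_plant[:, None]

    for it in range(config.iterations):
        # --- plant-level Metropolis updates, one component at a time
        # (component-wise moves mix better along the r/L0 ridge) ---
        for comp in range(3):
            prop = theta.copy()
            prop[:, comp] += rng.normal(0.0, 1.0, n_plants) * step[:, comp]
            mu_prop = curve_rss(prop)
            ll_prop = plant_loglik(mu_prop, sigma)
            dlt_c = (theta[:, comp] - prior_mean_plant[:, comp]) / tau_p[comp]
            dlt_p = (prop[:, comp] - prior_mean_plant[:, comp]) / tau_p[comp]
            log_alpha = (ll_prop - 0.5 * dlt_p**2) - (ll_plant - 0.5 * dlt_c**2)
            accept = np.log(rng.random(n_plants)) < log_alpha
            theta[accept, comp] = prop[accept, comp]
            ll_plant[accept] = ll_prop[accept]
            acc_count[:, comp] += accept
            acc_window[:, comp] += accept

        if it < config.burn_in and (it + 1) % 50 == 0:
            rate = acc_window / 50.0
            step *= np.exp(np.clip(rate - config.target_accept, -0.5, 0.5))
            step = np.clip(step, 1e-4, 2.0)
            acc_window[:] = 0.0

        # --- genotype means (Gibbs, conjugate normal per component) ---
        resid_cov = theta - beta * a_plant[:, None]
        sums = np.zeros((n_geno, 3))
        np.add.at(sums, g_of_plant, resid_cov)
        n_i = np.bincount(g_of_plant, minlength=n_geno)[:, None]
        prec = n_i / tau_p**2 + 1.0 / tau_g**2
        mean = (sums / tau_p**2 + mu / tau_g**2) / prec
        g = mean + rng.normal(0.0, 1.0, (n_geno, 3)) / np.sqrt(prec)

        # --- global mean (Gibbs) ---
        prec_mu = n_geno / tau_g**2 + 1.0 / s0**2
        mean_mu = (g.sum(axis=0) / tau_g**2 + m0 / s0**2) / prec_mu
        mu = mean_mu + rng.normal(0.0, 1.0, 3) / np.sqrt(prec_mu)

        # --- covariate slope (Gibbs, prior N(0, 1)) ---
        if use_beta:
            e = theta - g[g_of_plant]
            saa = float(np.sum(a_plant**2))
            prec_b = saa / tau_p**2 + 1.0
            mean_b = (a_plant @ e) / tau_p**2 / prec_b
            beta = mean_b + rng.normal(0.0, 1.0, 3) / np.sqrt(prec_b)

        prior_mean_plant = g[g_of_plant] + beta * a_plant[:, None]

        # --- variances (Gibbs, inverse gamma) ---
        dg = g - mu
        tau_g = np.sqrt(
            1.0 / rng.gamma(a_tau + n_geno / 2.0,
                            1.0 / (b_tau + 0.5 * np.sum(dg**2, axis=0)))
        )
        dp = theta - prior_mean_plant
        tau_p = np.sqrt(
            1.0 / rng.gamma(a_tau + n_plants / 2.0,
                            1.0 / (b_tau + 0.5 * np.sum(dp**2, axis=0)))
        )
        mu_obs = curve_rss(theta)
        rss = float(np.sum((y - mu_obs) ** 2))
        sigma = float(np.sqrt(
            1.0 / rng.gamma(a_sig + n_obs / 2.0, 1.0 / (b_sig + 0.5 * rss))
        ))
        ll_plant = plant_loglik(mu_obs, sigma)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            if kept < n_ret:
                S_mu[kept] = mu
                S_g[kept] = g
                S_th[kept] = theta
                S_tg[kept] = tau_g
                S_tp[kept] = tau_p
                S_sig[kept] = sigma
                if use_beta:
                    S_beta[kept] = beta
                kept += 1

    accept_rate = acc_count.mean(axis=1) / config.iterations
    diverged = bool(np.median(accept_rate) < 0.01)
    if diverged:
        warnings.warn("MCMC acceptance near zero: chain likely diverged",
                      stacklevel=2)
    return HierarchicalPosterior(
        config=config, genotypes=genotypes, plants=plants,
        plant_genotype=g_of_plant, mu=S_mu, genotype=S_g, plant=S_th,
        tau_g=S_tg, tau_p=S_tp, sigma=S_sig,
        beta=S_beta, amax_centered=amax_centered,
        accept_rate=accept_rate, diverged=diverged, trait_label=trait_label,
    )


def credible_envelopes(
    posterior: HierarchicalPosterior,
    genotype,
    grid,
    level: float = 0.95,
    rng=None,
) -> CredibleEnvelope:
    """Dual pointwise credible bands for one genotype on a DD grid.

    Inner band: percentiles of the genotype-mean curve over posterior
    draws.  Outer band: posterior predictive for a future observation of a
    new plant — each draw samples new plant-level parameters from the
    plant prior and adds residual measurement noise.
    """
    if genotype not in posterior.genotypes:
        raise KeyError(f"genotype {genotype!r} not in posterior")
    rng = np.random.default_rng(0) if rng is None else rng
    grid = np.asarray(grid, dtype=float)
    i = posterior.genotypes.get_loc(genotype)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2

    logg = posterior.genotype[:, i, :]
    if posterior.beta is not None and posterior.amax_centered is not None:
        logg = logg + posterior.beta * posterior.amax_centered.get(genotype, 0.0)
    gp = np.exp(logg)
    curves = logistic_size_raw(gp[:, [0]], gp[:, [1]], gp[:, [2]], grid[None, :])
    inner_lo = np.percentile(curves, lo_q, axis=0)
    inner_hi = np.percentile(curves, hi_q, axis=0)

    logp_new = logg + rng.normal(0.0, 1.0, logg.shape) * posterior.tau_p
    pp = np.exp(logp_new)
    pred = logistic_size_raw(pp[:, [0]], pp[:, [1]], pp[:, [2]], grid[None, :])
    pred = pred + rng.normal(0.0, 1.0, pred.shape) * posterior.sigma[:, None]
    outer_lo = np.percentile(pred, lo_q, axis=0)
    outer_hi = np.percentile(pred, hi_q, axis=0)
    # enforce the defining nesting against finite-sample percentile noise
    outer_lo = np.minimum(outer_lo, inner_lo)
    outer_hi = np.maximum(outer_hi, inner_hi)
    return CredibleEnvelope(
        grid=grid, inner_lo=inner_lo, inner_hi=inner_hi,
        outer_lo=outer_lo, outer_hi=outer_hi, level=level, genotype=genotype,
    )


def autocorrelation(x, lag: int = 1) -> float:
    """Lag-k sample autocorrelation; 0.0 for constant chains."""
    x = np.asarray(x, dtype=float)
    if lag <= 0 or lag >= x.size:
        raise ValueError("lag must be in [1, len(x))")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return 0.0
    return float(xc[:-lag] @ xc[lag:] / denom)


def effective_sample_size(x) -> float:
    """Initial-positive-sequence ESS estimate for one chain."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if np.ptp(x) == 0:
        return 0.0
    s = 0.0
    for k in range(1, n - 1):
        rho = autocorrelation(x, k)
        if rho <= 0.05:
            break
        s += rho
    return float(n / (1.0 + 2.0 * s))


def chain_diagnostics(chains: dict) -> pd.DataFrame:
    """Lag-1/lag-10 autocorrelation, ESS, and degeneracy flag per chain."""
    rows = []
    for name, x in chains.items():
        x = np.asarray(x, dtype=float)
        degenerate = bool(np.ptp(x) == 0)
        rows.append(
            {
                "parameter": name,
                "lag1_autocorr": autocorrelation(x, 1) if x.size > 1 else np.nan,
                "lag10_autocorr": (
                    autocorrelation(x, 10) if x.size > 10 else np.nan
                ),
                "ess": effective_sample_size(x),
                "degenerate": degenerate,
                "flagged": degenerate,
            }
        )
    df = pd.DataFrame(rows)
    df.loc[df["lag1_autocorr"].abs() > 0.95, "flagged"] = True
    return df


def convergence_report(posterior: HierarchicalPosterior) -> pd.DataFrame:
    """Mixing diagnostics for the global parameters and residual SD."""
    chains = {f"mu_{p}": posterior.mu[:, k] for k, p in enumerate(PARAM_NAMES)}
    chains["sigma"] = posterior.sigma
    for k, p in enumerate(PARAM_NAMES):
        chains[f"tau_g_{p}"] = posterior.tau_g[:, k]
        chains[f"tau_p_{p}"] = posterior.tau_p[:, k]
    if posterior.beta is not None:
        for k, p in enumerate(PARAM_NAMES):
            chains[f"beta_{p}"] = posterior.beta[:, k]
    rep = chain_diagnostics(chains)
    rep.attrs["median_accept_rate"] = float(np.median(posterior.accept_rate))
    rep.attrs["diverged"] = posterior.diverged
    return rep
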