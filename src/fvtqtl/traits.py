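"""Genotype-mean estimation and variance partitioning for FVT parameters.

Three pieces sit between curve fitting and QTL mapping:

* a single-pass 3-SD outlier rule applied to each trait vector,
* shrinkage genotype means (BLUPs) from a random-intercept model with
  genotype and block effects fit by REML,
* likelihood-ratio chi-square tests comparing variance-component models
  with and without a given random effect, covering crossed and nested
  intercept terms (genotype, block within treatment × year, treatment,
  year, and their interactions).

The REML engine handles any set of crossed/nested random intercepts with
independent components: V = σ²_e·I + Σ_k σ²_k Z_k Z_kᵀ.  In the balanced
one-way case the genotype BLUP reduces to the textbook shrinkage
λ·(genotype mean − grand mean) with λ = σ²_g/(σ²_g + σ²_e/m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "filter_outliers",
    "shrunken_mean",
    "VarianceComponentResult",
    "fit_variance_components",
    "estimate_genotype_means",
    "RandomEffectTest",
    "test_random_effect",
    "random_effects_table",
    "significance_code",
]


def filter_outliers(values, threshold: float = 3.0):
    """Single-pass outlier rule: drop values > ``threshold`` SDs from the mean.

    Mean and SD come from the full input (one pass, not iterated).  Returns
    ``(retained, removed_indices)``.  With zero SD nothing is removed.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy(), np.array([], dtype=int)
    z = np.abs(x - mu) / sd
    removed = np.flatnonzero(z > threshold)
    keep = np.setdiff1d(np.arange(x.size), removed)
    return x[keep], removed


def shrunken_mean(raw_mean, grand_mean, sigma2_g, sigma2_e, m):
    """Balanced-case shrinkage estimate of a genotype mean.

    grand + λ·(raw − grand) with λ = σ²_g / (σ²_g + σ²_e/m), where m is the
    replicate count.
    """
    lam = sigma2_g / (sigma2_g + sigma2_e / m)
    return grand_mean + lam * (raw_mean - grand_mean)


def _term_labels(data: pd.DataFrame, term) -> pd.Series:
    """Factor labels for a term: a column name or a tuple of columns
    (interaction / nesting is their label combination)."""
    if isinstance(term, str):
        return data[term].astype(str)
    parts = [data[c].astype(str) for c in term]
    out = parts[0]
    for p in parts[1:]:
        out = out + ":" + p
    return out


def _term_name(term) -> str:
    return term if isinstance(term, str) else ":".join(term)


@dataclass
class VarianceComponentResult:
    """REML fit of a multi-term random-intercept model."""

    terms: list
    variances: dict          # term name -> variance estimate (+ "residual")
    loglik: float            # REML log-likelihood (constants dropped)
    intercept: float
    n: int
    _blups: dict
    _levels: dict

    def blups(self, term) -> pd.Series:
        """Predicted random effects (shrinkage deviations) for one term."""
        name = _term_name(term)
        return pd.Series(self._blups[name], index=self._levels[name], name=name)


def _reml_loglik(y, Z_list, log_params, gram_list=None):
    n = y.size
    sig2 = np.exp(log_params)
    V = np.eye(n) * sig2[-1]
    grams = gram_list if gram_list is not None else [Z @ Z.T for Z in Z_list]
    for G, s2 in zip(grams, sig2[:-1]):
        V += s2 * G
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -1e12
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = np.linalg.solve(V, y)
    ones = np.ones(n)
    Vi_1 = np.linalg.solve(V, ones)
    xvx = float(ones @ Vi_1)
    beta = float(ones @ Vi_y) / xvx
    r = y - beta
    Vi_r = Vi_y - beta * Vi_1
    quad = float(r @ Vi_r)
    return -0.5 * (logdetV + np.log(xvx) + quad)


def fit_variance_components(
    data: pd.DataFrame, response: str, terms: list
) -> VarianceComponentResult:
    """REML for y = μ + Σ_k u_k[level_k(obs)] + ε with independent
    Gaussian components.

    ``terms`` is a list of column names or tuples of column names (a tuple
    denotes the interaction/nesting factor built from the label
    combination).
    """
    y = data[response].to_numpy(float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    Z_list, names, levels = [], [], {}
    for term in terms:
        lab = _term_labels(data, term)
        lv = pd.Index(lab.unique())
        if len(lv) < 2:
            raise ValueError(f"term {term!r} has < 2 levels")
        Z = (lab.to_numpy()[:, None] == lv.to_numpy()[None, :]).astype(float)
        Z_list.append(Z)
        names.append(_term_name(term))
        levels[_term_name(term)] = lv

    vy = max(float(np.var(y, ddof=1)), 1e-8)
    k = len(Z_list) + 1
    x0 = np.log(np.full(k, vy / k))
    gram_list = [Z @ Z.T for Z in Z_list]

    def neg(lp):
        return -_reml_loglik(y, Z_list, np.clip(lp, -30.0, 30.0), gram_list)

    best = None
    for start in (x0, x0 - 2.0):
        res = optimize.minimize(neg, start, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-6,
                                         "fatol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    lp = np.clip(best.x, -30.0, 30.0)
    sig2 = np.exp(lp)
    ll = -best.fun

    # BLUPs and intercept at the optimum
    V = np.eye(n) * sig2[-1]
    for Z, s2 in zip(Z_list, sig2[:-1]):
        V += s2 * (Z @ Z.T)
    ones = np.ones(n)
    Vi_1 = np.linalg.solve(V, ones)
    Vi_y = np.linalg.solve(V, y)
    beta = float(ones @ Vi_y) / float(ones @ Vi_1)
    Vi_r = Vi_y - beta * Vi_1
    blups = {
        name: s2 * (Z.T @ Vi_r)
        for name, Z, s2 in zip(names, Z_list, sig2[:-1])
    }
    variances = {name: float(s2) for name, s2 in zip(names, sig2[:-1])}
    variances["residual"] = float(sig2[-1])
    return VarianceComponentResult(
        terms=list(terms), variances=variances, loglik=float(ll),
        intercept=float(beta), n=n, _blups=blups, _levels=levels,
    )


def estimate_genotype_means(
    data: pd.DataFrame,
    response: str = "value",
    genotype: str = "genotype",
    block: str = "block",
):
    """Shrinkage genotype means controlling for block.

    Fits genotype + block random intercepts by REML; the reported genotype
    mean is the grand mean plus the genotype BLUP.  Returns
    ``(means, variance_components)`` where ``means`` has columns genotype,
    shrunken_mean, raw_mean, n_reps.
    """
    if data[genotype].nunique() < 2:
        raise ValueError("need >= 2 genotypes")
    if data[block].nunique() < 2:
        raise ValueError("need >= 2 blocks")
    fit = fit_variance_components(data, response, [genotype, block])
    bl = fit.blups(genotype)
    raw = data.groupby(genotype)[response].mean()
    cnt = data.groupby(genotype)[response].size()
    means = pd.DataFrame(
        {
            "genotype": bl.index,
            "shrunken_mean": fit.intercept + bl.to_numpy(),
            "raw_mean": raw.reindex(bl.index).to_numpy(),
            "n_reps": cnt.reindex(bl.index).to_numpy(),
        }
    )
    return means, fit.variances


@dataclass(frozen=True)
class RandomEffectTest:
    effect: str
    chisq: float
    df: int
    pvalue: float


def test_random_effect(
    data: pd.DataFrame, response: str, full_terms: list, dropped
) -> RandomEffectTest:
    """Likelihood-ratio chi-square for one random effect.

    chi² = 2·(logLik_full − logLik_without), df = 1 per dropped variance
    component, upper-tail p.  The null value sits on the boundary of the
    parameter space, which makes this test conservative; the convention
    here reports the nominal 1-df p-value.
    """
    names = [_term_name(t) for t in full_terms]
    if _term_name(dropped) not in names:
        raise ValueError(f"dropped effect {dropped!r} not in full model")
    reduced = [t for t in full_terms if _term_name(t) != _term_name(dropped)]
    full = fit_variance_components(data, response, full_terms)
    if reduced:
        red = fit_variance_components(data, response, reduced)
        ll_red = red.loglik
    else:
        # intercept + residual only
        y = data[response].to_numpy(float)
        # REML optimum of the intercept-only model is the ddof=1 variance
        s2 = float(np.var(y, ddof=1))
        ll_red = _reml_loglik(y, [], np.array([np.log(max(s2, 1e-12))]))
    chisq = max(0.0, 2.0 * (full.loglik - ll_red))
    df = 1
    p = float(stats.chi2.sf(chisq, df)) if chisq > 0 else 1.0
    return RandomEffectTest(effect=_term_name(dropped), chisq=chisq, df=df,
                            pvalue=p)


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return "NS"


def random_effects_table(
    data: pd.DataFrame, response: str, terms: list
) -> pd.DataFrame:
    """Chi-square test report for every random term in a full model.

    One row per term: effect, chisq, df, p, significance code — the layout
    used for variance-partition tables over genotype, block, treatment,
    year and their interactions.
    """
    rows = []
    for term in terms:
        t = test_random_effect(data, response, terms, term)
        rows.append(
            {"effect": t.effect, "chisq": t.chisq, "df": t.df,
             "pvalue": t.pvalue, "signif": significance_code(t.pvalue)}
        )
    return pd.DataFrame(rows)
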