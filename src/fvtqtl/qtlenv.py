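"""QTL-by-environment interaction tests.

For each detected QTL, the trait is regressed on the marker genotype,
the environmental factors (density treatment, growing season), and their
interactions in a fixed-effect crossed model.  Terms are judged by
Type III F statistics — the increase in residual sum of squares when the
term's columns are removed from the otherwise full design — which is only
meaningful under sum-to-zero contrasts, so those are enforced rather than
optional:

    F_T = ((RSS_without_T − RSS_full)/Δdf_T) / (RSS_full/df_resid)

Markers are tested one at a time.  Terms rendered inestimable by empty
cells are flagged and skipped rather than silently absorbed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InteractionTest",
    "sum_to_zero_columns",
    "type3_anova",
    "marker_env_anova",
]


@dataclass(frozen=True)
class InteractionTest:
    trait: str
    marker: str
    term: str
    F: float
    df_num: int
    df_den: int
    pvalue: float
    estimable: bool = True

    @property
    def significant(self) -> bool:
        return self.estimable and self.pvalue < 0.05


def sum_to_zero_columns(labels: pd.Series) -> np.ndarray:
    """Sum-to-zero (deviation) coding: L−1 columns for L levels.

    Level order is sorted; the last level carries −1 in every column.
    """
    lv = sorted(pd.unique(labels.astype(str)))
    if len(lv) < 2:
        raise ValueError(f"factor needs >= 2 levels, got {lv}")
    lab = labels.astype(str).to_numpy()
    cols = np.zeros((lab.size, len(lv) - 1))
    for j, level in enumerate(lv[:-1]):
        cols[:, j] = np.where(lab == level, 1.0, np.where(lab == lv[-1], -1.0, 0.0))
    return cols


def _interaction_columns(blocks: list) -> np.ndarray:
    """All pairwise products across the factor blocks (full interaction)."""
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ni,nj->nij", out, b).reshape(out.shape[0], -1)
    return out


def _rss(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), int(rank)


def type3_anova(
    data: pd.DataFrame, response: str, factors: list, max_order: int | None = None
) -> pd.DataFrame:
    """Type III ANOVA table for a crossed fixed-effect factor model.

    ``factors`` are column names; all main effects and interactions up to
    ``max_order`` (default: full factorial) are included.  Returns one row
    per term with F, dfs, p, and an estimability flag.
    """
    y = data[response].to_numpy(float)
    n = y.size
    coded = {f: sum_to_zero_columns(data[f]) for f in factors}
    max_order = len(factors) if max_order is None else max_order
    terms = []
    for k in range(1, max_order + 1):
        for combo in itertools.combinations(factors, k):
            terms.append(combo)
    blocks = {t: _interaction_columns([coded[f] for f in t]) for t in terms}

    X_full = np.column_stack([np.ones(n)] + [blocks[t] for t in terms])
    rss_full, rank_full = _rss(X_full, y)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    rows = []
    for t in terms:
        others = [blocks[u] for u in terms if u != t]
        X_red = np.column_stack([np.ones(n)] + others) if others else np.ones((n, 1))
        rss_red, rank_red = _rss(X_red, y)
        df_num = rank_full - rank_red
        name = ":".join(t)
        if df_num <= 0:
            rows.append({"term": name, "F": np.nan, "df_num": 0,
                         "df_den": df_resid, "pvalue": np.nan,
                         "estimable": False})
            continue
        F = ((rss_red - rss_full) / df_num) / (rss_full / df_resid)
        rows.append({"term": name, "F": float(F), "df_num": df_num,
                     "df_den": df_resid,
                     "pvalue": float(stats.f.sf(F, df_num, df_resid)),
                     "estimable": True})
    return pd.DataFrame(rows)


def marker_env_anova(
    data: pd.DataFrame,
    response: str = "value",
    marker: str = "marker_geno",
    treatment: str = "treatment",
    year: str = "year",
    trait: str = "trait",
    marker_name: str = "",
    test_three_way: bool = True,
) -> list:
    """QTL-by-environment tests for one marker.

    ``data`` holds one row per observation with the marker genotype code
    and the environment labels.  Fits the full crossed model of marker ×
    treatment × year (three-way included only when both environmental
    factors vary and ``test_three_way``), and returns the Type III tests
    for treatment×QTL, year×QTL, and year×QTL×treatment.
    """
    factors = [marker]
    has_treat = data[treatment].nunique() > 1
    has_year = data[year].nunique() > 1
    if has_treat:
        factors.append(treatment)
    if has_year:
        factors.append(year)
    if len(factors) < 2:
        raise ValueError("need at least one environmental factor with >= 2 levels")
    max_order = len(factors) if (test_three_way or len(factors) < 3) else 2
    tab = type3_anova(data, response, factors, max_order=max_order)
    trait_name = str(data[trait].iloc[0]) if trait in data.columns else ""
    wanted = []
    if has_treat:
        wanted.append(({marker, treatment}, f"{treatment}:{marker}"))
    if has_year:
        wanted.append(({marker, year}, f"{year}:{marker}"))
    if has_treat and has_year and test_three_way:
        wanted.append(({marker, treatment, year},
                       f"{year}:{marker}:{treatment}"))
    out = []
    for parts, label in wanted:
        match = tab[tab["term"].map(lambda s: set(s.split(":")) == parts)]
        if match.empty:
            continue
        r = match.iloc[0]
        out.append(InteractionTest(
            trait=trait_name, marker=marker_name or marker, term=label,
            F=float(r["F"]) if r["estimable"] else float("nan"),
            df_num=int(r["df_num"]), df_den=int(r["df_den"]),
            pvalue=float(r["pvalue"]) if r["estimable"] else float("nan"),
            estimable=bool(r["estimable"]),
        ))
    return out


def interaction_report(tests: list) -> pd.DataFrame:
    """Table-shaped report: trait, marker, term, F(df), p, signif code."""
    from .traits import significance_code

    rows = []
    for t in tests:
        rows.append({
            "trait": t.trait, "marker": t.marker, "term": t.term,
            "F": t.F, "df_num": t.df_num, "df_den": t.df_den,
            "pvalue": t.pvalue,
            "signif": significance_code(t.pvalue) if t.estimable else "n.e.",
        })
    return pd.DataFrame(rows)
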