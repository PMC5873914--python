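"""QTL interval mapping for recombinant inbred line (RIL) populations.

Implements the regression-based mapping workflow for a fully homozygous
biparental RIL panel:

* hidden-Markov genotype probabilities on a cM grid (two homozygote
  states, Haldane map function, genotyping-error emission model),
* Haley–Knott regression of genotype means on expected allele dosage,
* genome-wide permutation LOD thresholds,
* an iterative multi-QTL search with position refinement,
* per-locus effect, direction, percent variance explained (PVE), and
  1.5-LOD support intervals.

LOD at a position is (n/2)·log10(RSS0/RSS1) comparing the dosage
regression to the null fit; PVE = 100·(1 − 10^(−2·LOD/n)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "RILGenotypes",
    "GenotypeProbabilities",
    "ScanResult",
    "QTLModel",
    "haldane",
    "genotype_probabilities",
    "scan_hk",
    "permutation_threshold",
    "stepwise_qtl_search",
    "pve_from_lod",
    "lod_from_pve",
    "lod_support_interval",
]

GENO_CODES = ("AA", "BB")  # AA = first parent (IMB211), BB = second (R500)


def haldane(d_cm):
    """Recombination fraction for map distance ``d_cm`` (Haldane, no
    interference), on the scale of the supplied map: r = (1 − e^(−2d/100))/2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def pve_from_lod(lod: float, n: int) -> float:
    """Percent variance explained from a LOD score and genotype count n.

    PVE = 100 × (1 − 10^(−2·LOD/n)).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if lod < 0:
        raise ValueError(f"LOD must be >= 0, got {lod}")
    return 100.0 * (1.0 - 10.0 ** (-2.0 * lod / n))


def lod_from_pve(pve: float, n: int) -> float:
    """Inverse of :func:`pve_from_lod`: LOD = −(n/2)·log10(1 − PVE/100)."""
    return -(n / 2.0) * np.log10(1.0 - pve / 100.0)


@dataclass
class GeneticMap:
    """Marker positions in cM, strictly increasing within each chromosome."""

    table: pd.DataFrame  # columns: marker, chrom, pos_cm

    def __post_init__(self) -> None:
        req = {"marker", "chrom", "pos_cm"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"map table needs columns {req}")
        if self.table["marker"].duplicated().any():
            raise ValueError("duplicate marker names in map")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            pos = sub["pos_cm"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def markers(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    @classmethod
    def from_csv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class RILGenotypes:
    """Line × marker genotype codes in {AA, BB, NaN}; no heterozygotes.

    Heterozygote codes, if encountered on input, are treated as missing
    (the population is expected >99% homozygous).
    """

    calls: pd.DataFrame  # index: line, columns: marker
    parents: tuple = ("IMB211", "R500")

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy(dtype=object)
        het = np.isin(vals, ("AB", "BA", "H"))
        if het.any():
            vals = vals.copy()
            vals[het] = np.nan
            self.calls = pd.DataFrame(vals, index=self.calls.index,
                                      columns=self.calls.columns)
        bad = ~(pd.isna(vals) | np.isin(vals, GENO_CODES))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {set(vals[bad].ravel())}")

    @property
    def lines(self) -> pd.Index:
        return self.calls.index

    def dosage(self, gmap: GeneticMap) -> np.ndarray:
        """Observed allele dosage (0 = AA, 1 = BB, NaN = missing), columns
        ordered as in the map."""
        missing = [m for m in gmap.table["marker"] if m not in self.calls.columns]
        if missing:
            raise ValueError(f"genotypes lack markers present in map: {missing[:5]}")
        sub = self.calls[list(gmap.table["marker"])]
        return (sub == "BB").to_numpy(float) + np.where(sub.isna(), np.nan, 0.0)

    @classmethod
    def from_csv(cls, path, **kw) -> "RILGenotypes":
        return cls(pd.read_csv(path, index_col=0), **kw)

    def to_csv(self, path) -> None:
        self.calls.to_csv(path)


@dataclass
class GenotypeProbabilities:
    """Posterior genotype probabilities on an evaluation grid.

    ``positions`` maps chromosome -> cM array (markers plus step grid);
    ``probs`` maps chromosome -> array (n_lines, n_pos, 2) with state order
    (AA, BB).  ``index`` is a flat (chrom, pos_cm, nearest_marker) table
    aligned with :meth:`dosage_matrix` columns.
    """

    lines: pd.Index
    positions: dict
    probs: dict
    index: pd.DataFrame
    step: float
    error_rate: float

    def dosage_matrix(self) -> np.ndarray:
        """Expected BB dosage, shape (n_lines, total positions)."""
        return np.concatenate([self.probs[c][:, :, 1] for c in self.positions], axis=1)


def _chrom_grid(marker_pos: np.ndarray, step: float) -> np.ndarray:
    if step <= 0:
        return marker_pos.copy()
    grid = np.arange(marker_pos[0], marker_pos[-1] + step / 2.0, step)
    return np.unique(np.concatenate([grid, marker_pos]))


def genotype_probabilities(
    gmap: GeneticMap,
    genos: RILGenotypes,
    step: float = 1.0,
    error_rate: float = 0.001,
) -> GenotypeProbabilities:
    """Two-state forward–backward genotype probabilities along each chromosome.

    Transitions between adjacent evaluation positions use the Haldane
    recombination fraction on the supplied (RIL-scale) map; emissions allow
    a symmetric genotyping-error probability ``error_rate``.  Probabilities
    at every position sum to 1 across the two homozygote states.
    """
    obs_dosage = genos.dosage(gmap)  # (n_lines, n_markers) in map order
    n_lines = obs_dosage.shape[0]
    positions: dict = {}
    probs: dict = {}
    idx_rows = []
    for chrom in gmap.chromosomes:
        sub = gmap.markers(chrom)
        mpos = sub["pos_cm"].to_numpy(dtype=float)
        mnames = sub["marker"].to_list()
        # columns of obs_dosage for this chromosome, in map order
        mcols = np.flatnonzero((gmap.table["chrom"] == chrom).to_numpy())
        grid = _chrom_grid(mpos, step)
        n_pos = grid.size
        # emission table: (n_lines, n_pos, 2)
        emit = np.ones((n_lines, n_pos, 2))
        pos_to_idx = {p: i for i, p in enumerate(grid)}
        for j, p in enumerate(mpos):
            gi = pos_to_idx[p]
            d = obs_dosage[:, mcols[j]]
            obs_aa = d == 0.0
            obs_bb = d == 1.0
            emit[obs_aa, gi, 0] = 1.0 - error_rate
            emit[obs_aa, gi, 1] = error_rate
            emit[obs_bb, gi, 0] = error_rate
            emit[obs_bb, gi, 1] = 1.0 - error_rate
        # forward-backward, scaled, vectorized over lines
        r = haldane(np.diff(grid))
        alpha = np.empty((n_lines, n_pos, 2))
        scale = np.empty((n_lines, n_pos))
        a = 0.5 * emit[:, 0, :]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / scale[:, [0]]
        for k in range(1, n_pos):
            rk = r[k - 1]
            prev = alpha[:, k - 1, :]
            pred = np.empty_like(prev)
            pred[:, 0] = prev[:, 0] * (1 - rk) + prev[:, 1] * rk
            pred[:, 1] = prev[:, 0] * rk + prev[:, 1] * (1 - rk)
            a = pred * emit[:, k, :]
            scale[:, k] = a.sum(axis=1)
            alpha[:, k, :] = a / scale[:, [k]]
        beta = np.empty_like(alpha)
        beta[:, -1, :] = 1.0
        for k in range(n_pos - 2, -1, -1):
            rk = r[k]
            nxt = beta[:, k + 1, :] * emit[:, k + 1, :]
            b = np.empty_like(nxt)
            b[:, 0] = nxt[:, 0] * (1 - rk) + nxt[:, 1] * rk
            b[:, 1] = nxt[:, 0] * rk + nxt[:, 1] * (1 - rk)
            beta[:, k, :] = b / b.sum(axis=1, keepdims=True)
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        positions[chrom] = grid
        probs[chrom] = post
        nearest = [mnames[int(np.argmin(np.abs(mpos - p)))] for p in grid]
        for p, nm in zip(grid, nearest):
            idx_rows.append((chrom, p, nm))
    index = pd.DataFrame(idx_rows, columns=["chrom", "pos_cm", "nearest_marker"])
    return GenotypeProbabilities(
        lines=genos.lines, positions=positions, probs=probs, index=index,
        step=step, error_rate=error_rate,
    )


@dataclass
class ScanResult:
    """Genome scan: LOD per evaluation position."""

    table: pd.DataFrame  # columns: chrom, pos_cm, nearest_marker, lod
    n: int

    def peak(self) -> pd.Series:
        """Highest-LOD row; ties broken by chromosome order then position."""
        t = self.table
        best = t["lod"].max()
        return t[np.isclose(t["lod"], best)].iloc[0]

    def max_lod(self) -> float:
        return float(self.table["lod"].max())


class ScanError(ValueError):
    pass


def _prepare_scan(probs, phenotypes, covariates):
    y = np.asarray(phenotypes, dtype=float)
    D = probs.dosage_matrix()
    keep = ~np.isnan(y)
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != y.size:
            C = C.T
        keep &= ~np.isnan(C).any(axis=1)
    else:
        C = None
    y, D = y[keep], D[keep]
    if C is not None:
        C = C[keep]
    if y.size < 3:
        raise ScanError(f"need >= 3 informative lines, got {y.size}")
    X0 = np.ones((y.size, 1))
    if C is not None:
        X0 = np.column_stack([X0, C])
    # residualize y and dosages on the null design
    Q, _ = np.linalg.qr(X0)
    y_r = y - Q @ (Q.T @ y)
    D_r = D - Q @ (Q.T @ D)
    rss0 = float(y_r @ y_r)
    return y_r, D_r, rss0, y.size


def _lod_profile(y_r, D_r, rss0, n):
    denom = np.einsum("ij,ij->j", D_r, D_r)
    num = D_r.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = rss0 - np.where(denom > 1e-12, num**2 / np.maximum(denom, 1e-300), 0.0)
        rss1 = np.maximum(rss1, 1e-300)
        lod = (n / 2.0) * np.log10(rss0 / rss1)
    return np.maximum(lod, 0.0)


def scan_hk(
    probs: GenotypeProbabilities,
    phenotypes,
    covariates=None,
) -> ScanResult:
    """Haley–Knott single-QTL genome scan.

    Regresses the phenotype (one value per line, NaN = unobserved) on the
    expected BB dosage at each evaluation position; optional covariate
    columns (e.g. dosages at already-modeled QTL) are residualized out of
    both sides, giving the conditional scan used by the stepwise search.
    """
    y_r, D_r, rss0, n = _prepare_scan(probs, phenotypes, covariates)
    lod = _lod_profile(y_r, D_r, rss0, n)
    table = probs.index.copy()
    table["lod"] = lod
    return ScanResult(table=table, n=n)


def permutation_threshold(
    probs: GenotypeProbabilities,
    phenotypes,
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int | np.random.Generator = 0,
    return_maxima: bool = False,
):
    """Genome-wide LOD threshold by phenotype permutation.

    Shuffles the phenotype-to-line assignment ``n_perm`` times, records the
    genome-wide maximum LOD of each permuted scan, and returns the requested
    quantile of those maxima.  Seeded and reproducible.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable threshold")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(phenotypes, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    D = probs.dosage_matrix()[keep]
    n = y.size
    if n < 3:
        raise ScanError(f"need >= 3 informative lines, got {n}")
    # center once; each permutation is a column of Y
    Y = np.empty((n, n_perm))
    for j in range(n_perm):
        Y[:, j] = y[rng.permutation(n)]
    Y -= Y.mean(axis=0, keepdims=True)
    D_c = D - D.mean(axis=0, keepdims=True)
    dnorm = np.sqrt(np.einsum("ij,ij->j", D_c, D_c))
    ynorm = np.sqrt(np.einsum("ij,ij->j", Y, Y))
    ok = dnorm > 1e-10
    R = (D_c[:, ok].T @ Y) / np.outer(dnorm[ok], ynorm)
    r2max = np.max(R**2, axis=0)
    maxlod = -(n / 2.0) * np.log10(1.0 - r2max)
    thr = float(np.quantile(maxlod, quantile))
    if return_maxima:
        return thr, maxlod
    return thr


def lod_support_interval(
    positions: np.ndarray, lods: np.ndarray, peak_index: int, drop: float = 1.5
) -> tuple:
    """Support interval: the contiguous run around the peak with
    LOD ≥ peak − drop, expanded to the flanking evaluated positions when the
    run boundary sits strictly above the drop line."""
    positions = np.asarray(positions, dtype=float)
    lods = np.asarray(lods, dtype=float)
    cut = lods[peak_index] - drop
    lo = peak_index
    while lo > 0 and lods[lo - 1] >= cut - 1e-12:
        lo -= 1
    hi = peak_index
    while hi < lods.size - 1 and lods[hi + 1] >= cut - 1e-12:
        hi += 1
    if lods[lo] > cut + 1e-12 and lo > 0:
        lo -= 1
    if lods[hi] > cut + 1e-12 and hi < lods.size - 1:
        hi += 1
    return float(positions[lo]), float(positions[hi])


@dataclass
class QTLModel:
    """A fitted multi-QTL model.

    ``loci`` columns: chrom, pos_cm, nearest_marker, lod (drop-one),
    effect (additive, half the BB−AA difference), direction (+1 when the
    first-parent allele increases the trait), pve (%), ci_lo, ci_hi.
    """

    loci: pd.DataFrame
    model_lod: float
    threshold: float
    n: int
    intercept: float = float("nan")

    def __len__(self) -> int:
        return len(self.loci)

    def predict(self, dosages: np.ndarray) -> np.ndarray:
        """Fitted trait values for lines given BB dosages at the model loci
        (columns ordered as ``loci`` rows)."""
        if len(self.loci) == 0:
            return np.full(np.atleast_2d(dosages).shape[0], self.intercept)
        b = self.loci["_coef"].to_numpy()
        return self.intercept + np.atleast_2d(dosages) @ b


def _column_for(probs: GenotypeProbabilities, chrom, pos) -> np.ndarray:
    grid = probs.positions[chrom]
    k = int(np.argmin(np.abs(grid - pos)))
    return probs.probs[chrom][:, k, 1]


def stepwise_qtl_search(
    probs: GenotypeProbabilities,
    phenotypes,
    threshold: float,
    max_qtl: int = 12,
    refine_rounds: int = 2,
) -> QTLModel:
    """Iterative additive multi-QTL search.

    Repeatedly scans conditional on the current model's dosage covariates,
    adds the highest new peak exceeding ``threshold``, refines each locus
    position by rescanning its chromosome holding the others fixed, and
    stops when no new peak passes.  The final multi-locus regression
    reports each locus's drop-one LOD, additive effect, direction with
    respect to the first parent's allele, PVE, and 1.5-LOD interval.
    """
    y = np.asarray(phenotypes, dtype=float)
    keep = ~np.isnan(y)
    yk = y[keep]
    n = int(keep.sum())
    loci: list[tuple] = []  # (chrom, pos)

    def dosage_cols(exclude=None):
        cols = []
        for i, (c, p) in enumerate(loci):
            if exclude is not None and i == exclude:
                continue
            cols.append(_column_for(probs, c, p))
        return np.column_stack(cols) if cols else None

    while len(loci) < max_qtl:
        cov = dosage_cols()
        scan = scan_hk(probs, y, covariates=cov)
        # ignore peaks within 1 cM of an existing locus on the same chromosome
        t = scan.table
        mask = np.ones(len(t), dtype=bool)
        for c, p in loci:
            mask &= ~((t["chrom"] == c) & (np.abs(t["pos_cm"] - p) < 1.0 + 1e-9))
        t_ok = t[mask]
        if t_ok.empty:
            break
        best = t_ok["lod"].max()
        pk = t_ok[np.isclose(t_ok["lod"], best)].iloc[0]
        if pk["lod"] <= threshold:
            break
        loci.append((pk["chrom"], float(pk["pos_cm"])))
        # refine positions holding others fixed
        for _ in range(refine_rounds):
            moved = False
            for i in range(len(loci)):
                c_i, p_i = loci[i]
                cov_i = dosage_cols(exclude=i)
                sc = scan_hk(probs, y, covariates=cov_i)
                sub = sc.table[sc.table["chrom"] == c_i]
                b = sub["lod"].max()
                row = sub[np.isclose(sub["lod"], b)].iloc[0]
                if abs(float(row["pos_cm"]) - p_i) > 1e-9:
                    loci[i] = (c_i, float(row["pos_cm"]))
                    moved = True
            if not moved:
                break

    if not loci:
        return QTLModel(
            loci=pd.DataFrame(
                columns=["chrom", "pos_cm", "nearest_marker", "lod", "effect",
                         "direction", "pve", "ci_lo", "ci_hi", "_coef"]
            ),
            model_lod=0.0, threshold=threshold, n=n,
            intercept=float(np.mean(yk)),
        )

    # final multi-locus fit
    D_full = np.column_stack([_column_for(probs, c, p) for c, p in loci])
    D = D_full[keep]
    X = np.column_stack([np.ones(n), D])
    beta, *_ = np.linalg.lstsq(X, yk, rcond=None)
    resid = yk - X @ beta
    rss_full = float(resid @ resid)
    rss_null = float(np.sum((yk - yk.mean()) ** 2))
    model_lod = (n / 2.0) * np.log10(max(rss_null, 1e-300) / max(rss_full, 1e-300))

    rows = []
    for i, (c, p) in enumerate(loci):
        Xi = np.delete(X, i + 1, axis=1)
        bi, *_ = np.linalg.lstsq(Xi, yk, rcond=None)
        ri = yk - Xi @ bi
        rss_i = float(ri @ ri)
        lod_i = (n / 2.0) * np.log10(max(rss_i, 1e-300) / max(rss_full, 1e-300))
        coef = float(beta[i + 1])  # BB minus AA difference
        effect = abs(coef) / 2.0
        direction = 1 if coef < 0 else -1  # +1: first-parent (AA) allele increases trait
        # support interval from a conditional scan on this chromosome
        cov_i = np.delete(D_full, i, axis=1) if D_full.shape[1] > 1 else None
        sc = scan_hk(probs, y, covariates=cov_i)
        sub = sc.table[sc.table["chrom"] == c].reset_index(drop=True)
        kpk = int(np.argmin(np.abs(sub["pos_cm"].to_numpy() - p)))
        ci_lo, ci_hi = lod_support_interval(
            sub["pos_cm"].to_numpy(), sub["lod"].to_numpy(), kpk, drop=1.5
        )
        grid = probs.positions[c]
        mrow = probs.index[(probs.index["chrom"] == c)].reset_index(drop=True)
        nearest = mrow.iloc[int(np.argmin(np.abs(grid - p)))]["nearest_marker"]
        rows.append(
            dict(chrom=c, pos_cm=p, nearest_marker=nearest, lod=lod_i,
                 effect=effect, direction=direction,
                 pve=pve_from_lod(lod_i, n), ci_lo=ci_lo, ci_hi=ci_hi, _coef=coef)
        )
    table = pd.DataFrame(rows).sort_values(["chrom", "pos_cm"]).reset_index(drop=True)
    return QTLModel(loci=table, model_lod=float(model_lod), threshold=threshold,
                    n=n, intercept=float(beta[0]))


def collapse_colocalized(models: dict) -> pd.DataFrame:
    """Deduplicate QTL reported for the same trait across environments.

    Loci from different environment fits whose 1.5-LOD intervals overlap on
    the same chromosome and whose effects share a direction collapse to one
    reported QTL (the highest-LOD representative).
    """
    rows = []
    for env, model in models.items():
        for _, r in model.loci.iterrows():
            rows.append(dict(env=env, **r.to_dict()))
    if not rows:
        return pd.DataFrame(columns=["env", "chrom", "pos_cm", "lod"])
    df = pd.DataFrame(rows).sort_values("lod", ascending=False).reset_index(drop=True)
    kept = []
    for _, r in df.iterrows():
        dup = False
        for kr in kept:
            if (
                r["chrom"] == kr["chrom"]
                and r["direction"] == kr["direction"]
                and r["ci_lo"] <= kr["ci_hi"]
                and kr["ci_lo"] <= r["ci_hi"]
            ):
                dup = True
                break
        if not dup:
            kept.append(r)
    return pd.DataFrame(kept).sort_values(["chrom", "pos_cm"]).reset_index(drop=True)
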