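"""Synthetic RIL experiments with known genetic architecture.

Everything downstream of the field — genotypes on a linkage map,
QTL-driven logistic growth parameters, genotype-by-year deviations,
blocked multi-environment designs, longitudinal measurements on a
degree-day axis, daily temperatures, and reflectance spectra — can be
generated here with stored ground truth, so the whole pipeline is testable
end to end.

The default configuration mirrors the study design the pipeline targets:
119 recombinant inbred lines plus two parents, ten chromosomes, two
density treatments crossed with multiple growing seasons and randomized
blocks, and 5–16 sequential size measurements per plant.

Genotypes are simulated as a two-state Markov walk along each chromosome
using the Haldane map function, with map distances interpreted on the
RIL scale (expansion already applied), so every line is fully homozygous.
Genotype-level parameter values are additive in the QTL genotypes
(mean + Σ direction×effect), with optional non-QTL genotypic variance and
i.i.d. genotype×year deviations; plant-level parameters add block effects
and plant noise on the log scale, matching the lognormal hierarchy of the
Bayesian growth model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import logistic_size_raw
from .qtl import GeneticMap, RILGenotypes, haldane

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_map_and_genotypes",
    "simulate_phenotypes",
    "simulate_temperatures",
    "simulate_spectra",
    "simulate_experiment",
]

PARAM_NAMES = ("r", "Lmax", "L0")


@dataclass(frozen=True)
class SimConfig:
    """Study-design and architecture knobs for the simulator.

    QTL effect sizes are allele-class differences on the natural parameter
    scale: a QTL with effect e on Lmax separates the two homozygote classes
    by e mm, i.e. each allele contributes ±e/2 around the mean.
    ``block_sd`` and ``plant_sd`` act on the log-parameter scale;
    ``residual_sd`` is measurement noise in mm.
    """

    n_ril: int = 119
    n_chrom: int = 10
    markers_per_chrom: int = 21
    chrom_length_cm: float = 100.0
    missing_rate: float = 0.0
    # growth-curve population means (leaf width, mm / per-DD scale)
    mean_r: float = 0.02
    mean_Lmax: float = 60.0
    mean_L0: float = 2.0
    # genetic architecture
    n_qtl_per_trait: int = 3
    qtl_effects_r: tuple = (0.003, 0.0025, 0.002)
    qtl_effects_Lmax: tuple = (4.0, 3.0, 2.5)
    geno_sd_r: float = 0.001
    geno_sd_Lmax: float = 2.0
    gxe_sd_r: float = 0.0008
    gxe_sd_Lmax: float = 1.0
    # design
    treatments: tuple = ("UN", "CR")
    years: tuple = (2011, 2012)
    n_blocks: int = 6
    # plant / measurement level
    block_sd: float = 0.03
    plant_sd: float = 0.05
    residual_sd: float = 1.0
    min_points: int = 5
    max_points: int = 16
    max_dd: float = 600.0
    # A_max covariate (umol m^-2 s^-1): genotypic means, slope on log params
    amax_mean: float = 20.0
    amax_sd: float = 3.0
    amax_beta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ril < 2:
            raise ValueError("n_ril must be >= 2")
        if self.markers_per_chrom < 1 or self.n_chrom < 1:
            raise ValueError("need at least one marker on at least one chromosome")
        if not (5 <= self.min_points <= self.max_points <= 16):
            raise ValueError("measurement schedule lengths must lie within [5, 16]")
        for name in ("geno_sd_r", "geno_sd_Lmax", "gxe_sd_r", "gxe_sd_Lmax",
                     "block_sd", "plant_sd", "residual_sd", "amax_sd",
                     "missing_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Ground truth backing one simulated experiment."""

    config: SimConfig
    qtl: pd.DataFrame          # trait_param, chrom, pos_cm, marker, effect
    genotype_params: pd.DataFrame  # genotype, year, r, Lmax, L0 (natural scale)
    amax: pd.Series            # per-genotype covariate truth
    variance_components: dict


def simulate_map_and_genotypes(config: SimConfig, rng=None):
    """Evenly spaced markers and homozygous RIL genotypes.

    Each line is an independent two-state Markov walk along each
    chromosome; the probability of switching parent between adjacent
    markers is the Haldane recombination fraction of their distance on
    the (RIL-scale) map.  Parent lines IMB211 (all AA) and R500 (all BB)
    are appended after the RILs.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    for c in range(1, config.n_chrom + 1):
        if config.markers_per_chrom == 1:
            pos = np.array([0.0])
        else:
            pos = np.linspace(0.0, config.chrom_length_cm, config.markers_per_chrom)
        for j, p in enumerate(pos, start=1):
            rows.append((f"A{c:02d}m{j:03d}", f"A{c:02d}", float(p)))
    gmap = GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm"]))

    lines = [f"RIL{i + 1:03d}" for i in range(config.n_ril)]
    calls = {}
    for chrom in gmap.chromosomes:
        pos = gmap.markers(chrom)["pos_cm"].to_numpy()
        names = gmap.markers(chrom)["marker"].to_list()
        n_m = pos.size
        state = np.empty((config.n_ril, n_m), dtype=int)
        state[:, 0] = rng.random(config.n_ril) < 0.5
        r = haldane(np.diff(pos))
        for k in range(1, n_m):
            flip = rng.random(config.n_ril) < r[k - 1]
            state[:, k] = np.where(flip, 1 - state[:, k - 1], state[:, k - 1])
        for j, name in enumerate(names):
            calls[name] = np.where(state[:, j] == 1, "BB", "AA")
    df = pd.DataFrame(calls, index=pd.Index(lines, name="line"))
    # parents: fixed for opposite alleles everywhere
    parents = pd.DataFrame(
        {m: ["AA", "BB"] for m in df.columns},
        index=pd.Index(["IMB211", "R500"], name="line"),
    )
    df = pd.concat([df, parents])
    if config.missing_rate > 0:
        mask = rng.random(df.shape) < config.missing_rate
        vals = df.to_numpy(dtype=object)
        vals[mask] = np.nan
        df = pd.DataFrame(vals, index=df.index, columns=df.columns)
    return gmap, RILGenotypes(df)


def _draw_qtl(config: SimConfig, gmap: GeneticMap, rng) -> pd.DataFrame:
    """Place QTL at marker positions, spread across chromosomes."""
    rows = []
    chroms = gmap.chromosomes
    for param, effects in (("r", config.qtl_effects_r[: config.n_qtl_per_trait]),
                           ("Lmax", config.qtl_effects_Lmax[: config.n_qtl_per_trait])):
        picked = rng.choice(len(chroms), size=len(effects),
                            replace=len(effects) > len(chroms))
        for eff, ci in zip(effects, picked):
            sub = gmap.markers(chroms[ci])
            k = int(rng.integers(0, len(sub)))
            rows.append((param, chroms[ci], float(sub["pos_cm"].iloc[k]),
                         sub["marker"].iloc[k], float(eff)))
    return pd.DataFrame(rows, columns=["trait_param", "chrom", "pos_cm",
                                       "marker", "effect"])


def simulate_phenotypes(gmap: GeneticMap, genos: RILGenotypes, config: SimConfig,
                        rng=None):
    """Long-format longitudinal measurements plus the generating truth.

    Returns ``(measurements, truth)``.  Measurement columns: plant_id,
    genotype, treatment, year, block, t_dd, value, trait.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    qtl = _draw_qtl(config, gmap, rng)
    ril_mask = ~genos.lines.isin(genos.parents)
    lines = genos.lines
    n_lines = len(lines)

    # effect = allele-class difference; each allele shifts by +-effect/2
    def qtl_shift(param):
        shift = np.zeros(n_lines)
        for _, q in qtl[qtl["trait_param"] == param].iterrows():
            col = genos.calls[q["marker"]]
            sgn = np.where(col == "BB", 1.0, np.where(col == "AA", -1.0, 0.0))
            shift += 0.5 * q["effect"] * sgn
        return shift

    geno_dev_r = rng.normal(0.0, config.geno_sd_r, n_lines)
    geno_dev_L = rng.normal(0.0, config.geno_sd_Lmax, n_lines)
    amax = pd.Series(rng.normal(config.amax_mean, config.amax_sd, n_lines),
                     index=lines, name="amax")
    amax_c = amax - amax.mean()

    gp_rows = []
    base_r = config.mean_r + qtl_shift("r") + geno_dev_r
    base_L = config.mean_Lmax + qtl_shift("Lmax") + geno_dev_L
    for year in config.years:
        gxe_r = rng.normal(0.0, config.gxe_sd_r, n_lines)
        gxe_L = rng.normal(0.0, config.gxe_sd_Lmax, n_lines)
        r_y = np.maximum(base_r + gxe_r, 1e-4)
        L_y = np.maximum(base_L + gxe_L, config.mean_L0 * 2 + 1.0)
        for i, g in enumerate(lines):
            gp_rows.append((g, year, r_y[i], L_y[i], config.mean_L0))
    genotype_params = pd.DataFrame(
        gp_rows, columns=["genotype", "year", "r", "Lmax", "L0"]
    )
    gp_idx = genotype_params.set_index(["genotype", "year"])

    meas_rows = []
    plant_counter = 0
    for treat in config.treatments:
        for year in config.years:
            block_eff = rng.normal(0.0, config.block_sd,
                                   (config.n_blocks, len(PARAM_NAMES)))
            for b in range(1, config.n_blocks + 1):
                for g in lines:
                    plant_counter += 1
                    pid = f"P{plant_counter:05d}"
                    tp = gp_idx.loc[(g, year)]
                    logp = np.log([tp["r"], tp["Lmax"], tp["L0"]])
                    logp = (logp + block_eff[b - 1]
                            + config.amax_beta * amax_c[g]
                            + rng.normal(0.0, config.plant_sd, 3))
                    r_p, L_p, L0_p = np.exp(logp)
                    L_p = max(L_p, L0_p * 1.5)
                    n_pts = int(rng.integers(config.min_points,
                                             config.max_points + 1))
                    # 2-3x weekly field visits converted to DD: jittered grid
                    base_t = np.linspace(config.max_dd * 0.05, config.max_dd,
                                         n_pts)
                    jit = rng.uniform(-0.4, 0.4, n_pts) * (
                        base_t[1] - base_t[0] if n_pts > 1 else 10.0)
                    t = np.sort(np.clip(base_t + jit, 1.0, config.max_dd))
                    mu = logistic_size_raw(r_p, L_p, L0_p, t)
                    yobs = mu + rng.normal(0.0, config.residual_sd, n_pts)
                    yobs = np.maximum(yobs, 0.05)
                    for tk, vk in zip(t, yobs):
                        meas_rows.append((pid, g, treat, year, b,
                                          float(tk), float(vk)))
    measurements = pd.DataFrame(
        meas_rows,
        columns=["plant_id", "genotype", "treatment", "year", "block",
                 "t_dd", "value"],
    )
    measurements["trait"] = "leaf_width"
    truth = SimTruth(
        config=config,
        qtl=qtl,
        genotype_params=genotype_params,
        amax=amax,
        variance_components=dict(
            geno_var_r=config.geno_sd_r**2 + float(np.sum(
                np.asarray(config.qtl_effects_r[: config.n_qtl_per_trait]) ** 2)) / 4.0,
            geno_var_Lmax=config.geno_sd_Lmax**2 + float(np.sum(
                np.asarray(config.qtl_effects_Lmax[: config.n_qtl_per_trait]) ** 2)) / 4.0,
            gxe_var_r=config.gxe_sd_r**2,
            gxe_var_Lmax=config.gxe_sd_Lmax**2,
            residual_var=config.residual_sd**2,
        ),
    )
    return measurements, truth


def simulate_temperatures(config: SimConfig, n_days: int = 120,
                          start: str = "2012-05-15", rng=None) -> pd.DataFrame:
    """Daily tmin/tmax for one season: seasonal sinusoid plus weather noise."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    day = np.arange(n_days)
    mean_t = 14.0 + 8.0 * np.sin(np.pi * day / n_days)
    spread = rng.uniform(4.0, 9.0, n_days)
    noise = rng.normal(0.0, 2.0, n_days)
    tmin = mean_t + noise - spread
    tmax = mean_t + noise + spread
    return pd.DataFrame(
        {"date": pd.date_range(start, periods=n_days, freq="D"),
         "tmin_c": tmin, "tmax_c": tmax}
    )


def simulate_spectra(
    config: SimConfig,
    n_plants: int = 20,
    n_sweeps: int = 10,
    noise_sd: float = 0.01,
    baseline: float | None = None,
    genotype_feature_sd: float = 0.02,
    rng=None,
) -> pd.DataFrame:
    """Per-plant reflectance spectra on the 1-nm 350–2500 nm grid.

    Each plant's spectrum is a smooth vegetation-like baseline plus
    genotype-linked band features, measured in ``n_sweeps`` replicate
    sweeps on the instrument's native grid (1.4 nm in the VIS/NIR,
    2 nm in the SWIR), averaged, then interpolated to one point per
    nanometer (2151 points).  ``baseline`` replaces the vegetation shape
    with a flat value when given.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    native = np.concatenate([np.arange(350.0, 1000.0, 1.4),
                             np.arange(1000.0, 2500.0 + 1e-9, 2.0)])
    grid = np.arange(350.0, 2501.0)
    if baseline is None:
        # green peak, red edge, NIR plateau, water absorption dips
        base = (
            0.05
            + 0.05 * np.exp(-((native - 550) ** 2) / (2 * 40.0**2))
            + 0.40 / (1.0 + np.exp(-(native - 710) / 15.0))
            - 0.15 * np.exp(-((native - 1450) ** 2) / (2 * 60.0**2))
            - 0.20 * np.exp(-((native - 1940) ** 2) / (2 * 70.0**2))
        )
    else:
        base = np.full(native.size, float(baseline))
    cols = {}
    for i in range(n_plants):
        feat = rng.normal(0.0, genotype_feature_sd)
        plant = base * (1.0 + feat * np.exp(-((native - 700) ** 2) / (2 * 60.0**2)))
        sweeps = plant[None, :] + rng.normal(0.0, noise_sd, (n_sweeps, native.size))
        mean_sweep = sweeps.mean(axis=0)
        cols[f"plant{i + 1:03d}"] = np.interp(grid, native, mean_sweep)
    out = pd.DataFrame(cols)
    out.insert(0, "wavelength_nm", grid)
    return out


def simulate_experiment(config: SimConfig):
    """Map + genotypes + phenotypes + truth in one seeded call."""
    gmap, genos = simulate_map_and_genotypes(config)
    measurements, truth = simulate_phenotypes(gmap, genos, config)
    return gmap, genos, measurements, truth
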