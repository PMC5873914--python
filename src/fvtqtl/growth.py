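"""Logistic leaf growth on a thermal-time (degree-day) axis.

The deterministic core of the pipeline: a logistic growth law
``dL/dt = r L (1 - L/Lmax)`` with ``L(0) = L0``, where *t* is accumulated
degree days (DD) since germination.  The closed-form solution is

    L(t) = Lmax / (1 + ((Lmax - L0)/L0) * exp(-r t))

Function-valued trait (FVT) parameters derived from the curve:

* ``iD`` — inflection time, where growth switches from accelerating to
  decelerating (``L(iD) = Lmax/2``),
* ``d``  — duration from germination to a stated fraction (by convention
  95%) of final size.

Thermal time accumulates as the daily mean of tmin/tmax above a base
temperature, truncated at zero.  The default base temperature is 0.96 °C,
a species-specific value for *Brassica rapa*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LogisticParams",
    "DerivedFVT",
    "ThermalTimeSeries",
    "BASE_TEMP_C",
    "logistic_size",
    "inflection_time",
    "duration_to_fraction",
    "derived_fvt",
    "accumulate_degree_days",
]

#: Species-specific base temperature (°C) for degree-day accumulation.
BASE_TEMP_C = 0.96


class ParameterDomainError(ValueError):
    """Raised when logistic parameters violate r > 0, Lmax > L0 > 0."""


@dataclass(frozen=True)
class LogisticParams:
    """One growth-curve parameter set.

    Parameters
    ----------
    r : float
        Intrinsic growth rate, per degree day.
    Lmax : float
        Asymptotic leaf size (mm).
    L0 : float
        Initial size at germination (mm).
    trait_label : str
        Which measurement this parameterizes (e.g. ``"leaf_width"``).
    """

    r: float
    Lmax: float
    L0: float
    trait_label: str = "leaf_width"

    def __post_init__(self) -> None:
        if not (self.r > 0):
            raise ParameterDomainError(f"r must be > 0, got {self.r}")
        if not (self.Lmax > self.L0 > 0):
            raise ParameterDomainError(
                f"need Lmax > L0 > 0, got Lmax={self.Lmax}, L0={self.L0}"
            )


@dataclass(frozen=True)
class DerivedFVT:
    """Derived duration traits: d (DD to 95% of growth) and iD (inflection DD)."""

    d: float
    iD: float
    degenerate: bool = False


@dataclass
class ThermalTimeSeries:
    """Daily degree-day increments and their running sum."""

    dates: pd.DatetimeIndex
    daily_dd: np.ndarray
    cumulative_dd: np.ndarray
    base_temp: float = BASE_TEMP_C

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "daily_dd": self.daily_dd,
                "cumulative_dd": self.cumulative_dd,
            }
        )

    @classmethod
    def from_csv(cls, path, base_temp: float = BASE_TEMP_C) -> "ThermalTimeSeries":
        """Build from a temperature CSV with columns date, tmin_c, tmax_c."""
        df = pd.read_csv(path, parse_dates=["date"])
        return accumulate_degree_days(
            df["tmin_c"].to_numpy(), df["tmax_c"].to_numpy(), base=base_temp,
            dates=pd.DatetimeIndex(df["date"]),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def logistic_size(params: LogisticParams, t):
    """Leaf size (mm) at thermal time ``t`` (DD) under the logistic law.

    Accepts scalar or array ``t``; strictly increasing in t and bounded in
    (L0, Lmax) for t in (0, inf).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("thermal time t must be >= 0")
    a = (params.Lmax - params.L0) / params.L0
    out = params.Lmax / (1.0 + a * np.exp(-params.r * t))
    return out if out.ndim else float(out)


def logistic_size_raw(r, Lmax, L0, t):
    """Vectorized logistic evaluation on raw parameter arrays (no validation).

    Broadcasts all arguments; used in samplers and simulators where
    parameters come in bulk.
    """
    a = (Lmax - L0) / L0
    return Lmax / (1.0 + a * np.exp(-r * np.asarray(t, dtype=float)))


def inflection_time(params: LogisticParams) -> float:
    """Thermal time iD at which L(t) = Lmax/2 (growth-rate inflection).

    If L0 >= Lmax/2 the inflection precedes the observation window; the
    result is reported as 0.0 (degenerate) rather than a negative time.
    """
    if params.L0 >= params.Lmax / 2:
        import warnings

        warnings.warn(
            "L0 >= Lmax/2: inflection precedes germination; reporting 0.0",
            stacklevel=2,
        )
        return 0.0
    a = (params.Lmax - params.L0) / params.L0
    return math.log(a) / params.r


def duration_to_fraction(params: LogisticParams, fraction: float = 0.95) -> float:
    """Thermal time at which the curve reaches ``fraction`` of Lmax.

    With fraction = 0.95 this is the growth-duration trait d.  Closed-form
    inversion of the logistic:

        t = ln(a * f / (1 - f)) / r,   a = (Lmax - L0)/L0,  f = fraction
    """
    f = float(fraction)
    if not (params.L0 / params.Lmax < f < 1.0):
        raise ValueError(
            f"fraction must lie in (L0/Lmax, 1) = "
            f"({params.L0 / params.Lmax:.4g}, 1), got {f}"
        )
    a = (params.Lmax - params.L0) / params.L0
    return math.log(a * f / (1.0 - f)) / params.r


def derived_fvt(params: LogisticParams, fraction: float = 0.95) -> DerivedFVT:
    """Both duration traits for one parameter set."""
    if params.L0 >= params.Lmax / 2:
        return DerivedFVT(d=duration_to_fraction(params, fraction), iD=0.0,
                          degenerate=True)
    return DerivedFVT(
        d=duration_to_fraction(params, fraction), iD=inflection_time(params)
    )


def accumulate_degree_days(
    tmin, tmax, base: float = BASE_TEMP_C, dates: pd.DatetimeIndex | None = None
) -> ThermalTimeSeries:
    """Degree-day series from daily tmin/tmax by the simple-average method.

    Daily increment = max(0, (tmin + tmax)/2 - base).
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if tmin.shape != tmax.shape:
        raise ValueError(
            f"tmin and tmax must be aligned equal-length series, "
            f"got {tmin.shape} vs {tmax.shape}"
        )
    daily = np.maximum(0.0, (tmin + tmax) / 2.0 - base)
    if dates is None:
        dates = pd.date_range("2000-01-01", periods=daily.size, freq="D")
    return ThermalTimeSeries(
        dates=dates, daily_dd=daily, cumulative_dd=np.cumsum(daily), base_temp=base
    )
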