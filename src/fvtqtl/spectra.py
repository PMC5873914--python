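"""Reflectance-spectrum binning and band-math vegetation indices.

Spectra live on a strictly increasing nanometer grid (the working grid is
350–2500 nm at one point per nanometer after interpolation, 2151 points).
The one fully specified in-house index is the reflected red : far-red
ratio, mean(655–665 nm) / mean(725–735 nm).  Other vegetation indices
(mcari, mtci, sipi2, ...) are defined in the remote-sensing literature and
are supplied as configurable band-math definitions: named wavelength
windows, each aggregated by its mean, combined by an arithmetic formula.
Window endpoints are inclusive on both sides.
"""

from __future__ import annotations

import ast
import operator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BandIndexDef",
    "bin_mean",
    "rfr_ratio",
    "evaluate_index",
    "interpolate_1nm",
    "index_defs_from_config",
]


@dataclass
class Spectrum:
    """Wavelength grid (nm, strictly increasing) and reflectance values."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance must align")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance values must be finite")


def interpolate_1nm(spectrum: Spectrum, lo: float = 350.0,
                    hi: float = 2500.0) -> Spectrum:
    """Linear interpolation to the canonical 1-nm grid (2151 points for
    350–2500 nm)."""
    grid = np.arange(lo, hi + 0.5)
    vals = np.interp(grid, spectrum.wavelengths, spectrum.reflectance)
    return Spectrum(grid, vals)


def bin_mean(spectrum: Spectrum, lo: float, hi: float) -> float:
    """Mean reflectance over the inclusive window [lo, hi] nm."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    w = spectrum.wavelengths
    sel = (w >= lo) & (w <= hi)
    if not sel.any():
        raise ValueError(f"window [{lo}, {hi}] nm contains no grid points")
    return float(spectrum.reflectance[sel].mean())


def rfr_ratio(spectrum: Spectrum) -> float:
    """Reflected red : far-red ratio, mean(655–665) / mean(725–735)."""
    red = bin_mean(spectrum, 655.0, 665.0)
    far_red = bin_mean(spectrum, 725.0, 735.0)
    if far_red <= 0:
        raise ValueError("far-red window mean must be > 0")
    return red / far_red


@dataclass(frozen=True)
class BandIndexDef:
    """A named band-math index: window means combined by a formula.

    ``bands`` maps a band name to its (lo, hi) window in nm; ``formula``
    is an arithmetic expression over band names, e.g. ``"(A - B)/(A + B)"``.
    """

    name: str
    formula: str
    bands: dict = field(default_factory=dict)


_BIN_OPS = {ast.Add: operator.add, ast.Sub: operator.sub,
            ast.Mult: operator.mul, ast.Div: operator.truediv,
            ast.Pow: operator.pow}
_UN_OPS = {ast.USub: operator.neg, ast.UAdd: operator.pos}


def _eval_node(node, env: dict) -> float:
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, env)
    if isinstance(node, ast.BinOp) and type(node.op) in _BIN_OPS:
        return _BIN_OPS[type(node.op)](
            _eval_node(node.left, env), _eval_node(node.right, env))
    if isinstance(node, ast.UnaryOp) and type(node.op) in _UN_OPS:
        return _UN_OPS[type(node.op)](_eval_node(node.operand, env))
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        return float(node.value)
    if isinstance(node, ast.Name):
        if node.id not in env:
            raise ValueError(f"unknown band {node.id!r} in formula")
        return env[node.id]
    raise ValueError(f"unsupported element in band formula: {ast.dump(node)}")


def evaluate_index(spectrum: Spectrum, definition: BandIndexDef) -> float:
    """Evaluate a band-math index: each band replaced by its window mean."""
    env = {name: bin_mean(spectrum, lo, hi)
           for name, (lo, hi) in definition.bands.items()}
    try:
        tree = ast.parse(definition.formula, mode="eval")
    except SyntaxError as exc:
        raise ValueError(f"malformed index formula {definition.formula!r}") from exc
    return float(_eval_node(tree, env))


#: The in-house red:far-red ratio as a band-math definition.
RFR_DEF = BandIndexDef(
    name="rfr", formula="RED / FAR_RED",
    bands={"RED": (655.0, 665.0), "FAR_RED": (725.0, 735.0)},
)


def index_defs_from_config(config: dict) -> list:
    """Parse index definitions from a config mapping (e.g. loaded YAML).

    Expected shape::

        indices:
          ndvi_like:
            formula: "(NIR - RED)/(NIR + RED)"
            bands: {NIR: [780, 820], RED: [655, 665]}

    Named literature indices ship with no default formulas here; supply
    their published band definitions through this config.
    """
    out = []
    for name, spec in (config.get("indices") or {}).items():
        bands = {b: (float(w[0]), float(w[1])) for b, w in spec["bands"].items()}
        out.append(BandIndexDef(name=name, formula=spec["formula"], bands=bands))
    return out


def spectra_frame_to_spectra(df: pd.DataFrame,
                             wavelength_col: str = "wavelength_nm") -> dict:
    """Split a wide spectra table (wavelength column + one column per
    plant) into named Spectrum objects."""
    w = df[wavelength_col].to_numpy(float)
    return {c: Spectrum(w, df[c].to_numpy(float))
            for c in df.columns if c != wavelength_col}
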