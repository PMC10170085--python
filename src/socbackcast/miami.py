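"""MIAMI net primary production model and carbon-input scaling.

Annual NPP is the minimum of a temperature-limited logistic and a
precipitation-limited saturating exponential, both with a 3000-unit
ceiling.  Only NPP *ratios* enter the pipeline — annual carbon inputs are
the equilibrium input scaled by NPP(t)/NPP_ref — so the (unspecified) NPP
unit cancels throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NPP_CEILING",
    "NppRecord",
    "InputSchedule",
    "npp_temperature",
    "npp_precipitation",
    "npp_annual",
    "scale_inputs",
]

NPP_CEILING = 3000.0
_T_COEFF = 0.0119
_T_OFFSET = 1.315
_P_COEFF = 0.0000664


def npp_temperature(mat):
    """Temperature-limited NPP branch: 3000 / (1 + exp(1.315 − 0.0119·T)).

    Strictly increasing in mean annual temperature, bounded in (0, 3000).
    """
    t = np.asarray(mat, dtype=float)
    out = NPP_CEILING / (1.0 + np.exp(_T_OFFSET - _T_COEFF * t))
    return float(out) if np.ndim(mat) == 0 else out


def npp_precipitation(map_mm):
    """Precipitation-limited NPP branch: 3000·(1 − exp(−0.0000664·P)).

    Zero at P = 0, saturating to the 3000 ceiling.
    """
    p = np.asarray(map_mm, dtype=float)
    if np.any(p < 0):
        raise ValueError("annual precipitation must be non-negative")
    out = NPP_CEILING * (1.0 - np.exp(-_P_COEFF * p))
    return float(out) if np.ndim(map_mm) == 0 else out


@dataclass(frozen=True)
class NppRecord:
    """Annual NPP diagnostics for one site-year."""

    year: int
    mat: float  # mean annual temperature, °C
    map: float  # annual precipitation, mm
    npp_t: float
    npp_p: float
    npp: float


def npp_annual(mat: float, map_mm: float, year: int = 0) -> NppRecord:
    """Annual NPP = min of the temperature- and precipitation-limited branches."""
    npp_t = npp_temperature(mat)
    npp_p = npp_precipitation(map_mm)
    return NppRecord(
        year=year, mat=float(mat), map=float(map_mm),
        npp_t=npp_t, npp_p=npp_p, npp=min(npp_t, npp_p),
    )


@dataclass
class InputSchedule:
    """Annual carbon inputs for one site and scenario, Mg C ha⁻¹ yr⁻¹."""

    cin_equi: float
    npp_ref: float
    years: np.ndarray
    annual_cin: np.ndarray
    annual_npp: np.ndarray
    monthly_weights: np.ndarray

    def __post_init__(self) -> None:
        self.monthly_weights = np.asarray(self.monthly_weights, dtype=float)
        if len(self.monthly_weights) != 12:
            raise ValueError("monthly_weights must have 12 entries")
        if abs(self.monthly_weights.sum() - 1.0) > 1e-12:
            raise ValueError("monthly_weights must sum to 1")
        if np.any(self.annual_cin < 0) or self.cin_equi < 0:
            raise ValueError("carbon inputs must be non-negative")

    def monthly_inputs(self) -> np.ndarray:
        """Monthly carbon input series, Mg C ha⁻¹ month⁻¹, length 12·n_years."""
        return np.outer(self.annual_cin, self.monthly_weights).ravel()


def scale_inputs(
    cin_equi: float,
    annual_mat: np.ndarray,
    annual_map: np.ndarray,
    scenario: str,
    years: np.ndarray | None = None,
    monthly_weights: np.ndarray | None = None,
    site_id: str | int | None = None,
) -> InputSchedule:
    """Build the annual carbon-input schedule for one scenario.

    ``const`` keeps the equilibrium input every year; ``var`` scales it by
    NPP(t)/NPP_ref with NPP_ref the arithmetic mean annual NPP over the
    period, so the period-mean of the ``var`` schedule equals ``cin_equi``
    by construction.
    """
    if cin_equi < 0:
        raise ValueError("cin_equi must be non-negative")
    if scenario not in ("const", "var"):
        raise ValueError(f"unknown scenario {scenario!r}; expected 'const' or 'var'")
    annual_mat = np.asarray(annual_mat, dtype=float)
    annual_map = np.asarray(annual_map, dtype=float)
    if annual_mat.shape != annual_map.shape:
        raise ValueError("annual MAT and MAP series differ in length")
    n = len(annual_mat)
    if years is None:
        years = np.arange(n)
    npp = np.minimum(npp_temperature(annual_mat), npp_precipitation(annual_map))
    npp_ref = float(npp.mean())
    if scenario == "var":
        if npp_ref <= 0:
            raise ValueError(
                f"reference NPP is zero (degenerate climate) at site {site_id!r}"
            )
        annual_cin = cin_equi * npp / npp_ref
    else:
        annual_cin = np.full(n, cin_equi)
    if monthly_weights is None:
        monthly_weights = np.full(12, 1.0 / 12.0)
    return InputSchedule(
        cin_equi=float(cin_equi),
        npp_ref=npp_ref,
        years=np.asarray(years),
        annual_cin=annual_cin,
        annual_npp=npp,
        monthly_weights=monthly_weights,
    )
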