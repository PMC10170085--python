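"""Analytical periodic steady state and equilibrium carbon-input inversion.

Because each monthly update is affine in the active pools and linear in the
carbon input, the state after one 12-month forcing cycle is
x ↦ A x + C·g, with A the product of the monthly propagators and g the
accumulated input response.  The periodic steady state is the solution of
(I − A) x = C·g — one small linear solve instead of a centuries-long
simulation — and the equilibrium input that holds a target stock follows by
dividing the IOM-corrected target by the steady stock per unit input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rothc import (
    ForcingSeries,
    PoolState,
    SoilParams,
    _decay_survival,
    _transfer_vector,
    build_forcing_series,
    iom_from_total,
)

__all__ = [
    "SpinupResult",
    "periodic_start_deficit",
    "steady_cycle",
    "mean_survival_cycle",
    "periodic_steady_pools",
    "unit_response",
    "invert_cinput",
]


@dataclass
class SpinupResult:
    """Equilibrium input and pool distribution for one site."""

    cin_equi: float  # Mg C ha⁻¹ yr⁻¹
    pools_2018: PoolState
    unit_response: float  # steady active stock (Mg C ha⁻¹) per unit annual input
    iom: float


def periodic_start_deficit(
    precip12: np.ndarray,
    pet12: np.ndarray,
    covered12: np.ndarray,
    soil: SoilParams,
    max_passes: int = 10,
    tol: float = 1e-10,
) -> float:
    """January deficit of the annually periodic moisture pattern.

    Iterates the deficit accounting over repeated years until the January
    value repeats (two passes normally suffice; the pattern is idempotent
    under repetition).
    """
    from .rothc import _step_deficit

    if not (len(precip12) == len(pet12) == len(covered12) == 12):
        raise ValueError("deficit cycle requires 12 monthly values per component")
    acc = 0.0
    for _ in range(max_passes):
        acc_next = acc
        for i in range(12):
            acc_next = _step_deficit(acc_next, precip12[i], pet12[i], bool(covered12[i]), soil)
        if abs(acc_next - acc) < tol:
            return acc_next
        acc = acc_next
    return acc


def steady_cycle(
    temp12: np.ndarray,
    precip12: np.ndarray,
    pet12: np.ndarray,
    covered12: np.ndarray,
    soil: SoilParams,
) -> ForcingSeries:
    """A 12-month forcing cycle with a self-consistent annual deficit pattern."""
    if not (len(temp12) == len(precip12) == len(pet12) == len(covered12) == 12):
        raise ValueError("steady cycle requires 12 monthly values per component")
    acc = periodic_start_deficit(precip12, pet12, covered12, soil)
    return build_forcing_series(temp12, precip12, pet12, covered12, soil, acc_tsmd0=acc)


def _cycle_survival(cycle, soil: SoilParams) -> np.ndarray:
    """Monthly survival fractions (12, 4) from a cycle specification.

    Accepts either a 12-month :class:`ForcingSeries` or a precomputed
    (12, 4) survival array (e.g. the per-calendar-month mean propagator of
    a noisy century, :func:`mean_survival_cycle`).
    """
    if isinstance(cycle, ForcingSeries):
        if len(cycle) != 12:
            raise ValueError("steady-state cycle must cover 12 months")
        return _decay_survival(cycle.abc, soil)
    d = np.asarray(cycle, dtype=float)
    if d.shape != (12, 4):
        raise ValueError(f"survival cycle must have shape (12, 4), got {d.shape}")
    return d


def mean_survival_cycle(forcing: ForcingSeries, soil: SoilParams) -> np.ndarray:
    """Per-calendar-month mean survival fractions of a multi-year series.

    The monthly propagator is linear in the survival fractions
    exp(−k·a·b·c/12), so the mean propagator of each calendar month is the
    propagator of the mean survival.  Anchoring the spin-up at the steady
    state of this mean-propagator cycle makes the equilibrium consistent
    with the *actual* noisy forcing (to the approximation that months are
    serially independent), rather than with the smoother climatological
    mean month whose moisture factor understates interannual variability.
    """
    if len(forcing) % 12:
        raise ValueError("forcing must cover whole years")
    d = _decay_survival(forcing.abc, soil)
    return d.reshape(-1, 12, 4).mean(axis=0)


def _annual_map(cycle, soil: SoilParams, monthly_weights: np.ndarray):
    """(A, g): state after one year = A x + cin_annual · g."""
    d = _cycle_survival(cycle, soil)
    co2f, h = _transfer_vector(soil)
    alloc = soil.input_allocation
    A = np.eye(4)
    g = np.zeros(4)
    for m in range(12):
        dm = d[m]
        M = np.diag(dm) + np.outer(h, 1.0 - dm)
        A = M @ A
        g = M @ (g + monthly_weights[m] * alloc)
    return A, g


def _steady_base(cycle, soil: SoilParams, monthly_weights: np.ndarray) -> np.ndarray:
    A, g = _annual_map(cycle, soil, monthly_weights)
    lhs = np.eye(4) - A
    try:
        return np.linalg.solve(lhs, g)
    except np.linalg.LinAlgError as exc:  # all modifiers zero all year
        raise np.linalg.LinAlgError(
            "annual propagator has no unique fixed point (no decomposition all year)"
        ) from exc


def _default_weights(monthly_weights) -> np.ndarray:
    if monthly_weights is None:
        return np.full(12, 1.0 / 12.0)
    w = np.asarray(monthly_weights, dtype=float)
    if len(w) != 12 or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("monthly_weights must be 12 fractions summing to 1")
    return w


def unit_response(cycle, soil: SoilParams, monthly_weights=None) -> float:
    """Steady active stock (Mg C ha⁻¹) held by one unit of annual input."""
    w = _default_weights(monthly_weights)
    return float(_steady_base(cycle, soil, w).sum())


def periodic_steady_pools(
    cin_annual: float,
    cycle,
    soil: SoilParams,
    iom: float,
    monthly_weights=None,
) -> PoolState:
    """Pool state invariant under one forcing year at the given annual input."""
    if cin_annual < 0:
        raise ValueError("cin_annual must be non-negative")
    w = _default_weights(monthly_weights)
    active = cin_annual * _steady_base(cycle, soil, w)
    return PoolState.from_active(active, iom)


def invert_cinput(
    target_soc: float,
    cycle,
    soil: SoilParams,
    monthly_weights=None,
) -> SpinupResult:
    """Equilibrium annual carbon input holding ``target_soc`` at steady state.

    IOM is fixed by the Falloon pedotransfer from the total stock; the
    remaining active stock divided by the per-unit steady response gives the
    equilibrium input in a single linear solve.
    """
    iom = iom_from_total(target_soc)
    if target_soc < iom or target_soc < 0:
        raise ValueError(
            f"target SOC {target_soc} is not above its inert fraction {iom}"
        )
    w = _default_weights(monthly_weights)
    base = _steady_base(cycle, soil, w)
    resp = float(base.sum())
    cin = (target_soc - iom) / resp
    pools = PoolState.from_active(cin * base, iom)
    return SpinupResult(cin_equi=cin, pools_2018=pools, unit_response=resp, iom=iom)
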