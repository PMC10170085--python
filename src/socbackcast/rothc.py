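"""Five-pool monthly soil organic carbon turnover engine.

Implements the classic Rothamsted (RothC-26.3) first-order kinetics: four
active pools (decomposable plant material DPM, resistant plant material RPM,
microbial biomass BIO, humified organic matter HUM) plus inert organic
matter (IOM), stepped monthly under multiplicative climate/cover rate
modifiers.  Each monthly update is affine in the pool vector and in the
carbon input, which this module exploits for exact backward (in time)
integration and, downstream, for an analytical periodic steady state.

Units: pools and fluxes in Mg C ha⁻¹ (per month where a flux), temperature
in °C, precipitation and potential evapotranspiration (PET) in mm month⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LandUse",
    "PoolState",
    "SoilParams",
    "MoistureState",
    "RateModifiers",
    "MonthlyForcing",
    "ForcingSeries",
    "RothCParams",
    "DEFAULT_PARAMS",
    "temperature_factor",
    "max_deficit",
    "rate_modifiers",
    "build_forcing_series",
    "partition_coefficients",
    "iom_from_total",
    "monthly_step",
    "run_forward",
    "run_backward",
    "forward_active",
    "backward_active",
]


class LandUse(str, Enum):
    ARABLE = "arable"
    GRASSLAND = "grassland"


@dataclass(frozen=True)
class RothCParams:
    """Model constants of the RothC-26.3 parameterisation.

    Annual decomposition rate constants (yr⁻¹), the temperature-factor
    logistic, the clay-dependent CO₂ partition, the bare-soil deficit
    divisor and the open-pan PET fraction are the published values; all are
    injectable so an alternative constant set can be supplied bit-exactly
    through the pipeline configuration.
    """

    k_dpm: float = 10.0
    k_rpm: float = 0.3
    k_bio: float = 0.66
    k_hum: float = 0.02
    # a = a_num / (1 + exp(a_scale / (T + a_shift)))
    a_num: float = 47.91
    a_scale: float = 106.06
    a_shift: float = 18.27
    # retained decomposition products: 46% to BIO, 54% to HUM
    bio_share: float = 0.46
    hum_share: float = 0.54
    cover_factor: float = 0.6
    pet_fraction: float = 0.75
    bare_deficit_divisor: float = 1.8
    b_threshold: float = 0.444
    b_min: float = 0.2
    dpm_rpm_arable: float = 1.44
    dpm_rpm_grassland: float = 0.67
    iom_coeff: float = 0.049
    iom_power: float = 1.139
    reference_depth_cm: float = 23.0

    @property
    def k(self) -> np.ndarray:
        return np.array([self.k_dpm, self.k_rpm, self.k_bio, self.k_hum])


DEFAULT_PARAMS = RothCParams()


@dataclass
class PoolState:
    """Carbon pools of one site, Mg C ha⁻¹; ``iom`` is inert."""

    dpm: float
    rpm: float
    bio: float
    hum: float
    iom: float

    @property
    def total_soc(self) -> float:
        return self.dpm + self.rpm + self.bio + self.hum + self.iom

    @property
    def active(self) -> np.ndarray:
        return np.array([self.dpm, self.rpm, self.bio, self.hum])

    @classmethod
    def from_active(cls, active: np.ndarray, iom: float) -> "PoolState":
        return cls(float(active[0]), float(active[1]), float(active[2]), float(active[3]), iom)

    def validate(self) -> None:
        vals = [self.dpm, self.rpm, self.bio, self.hum, self.iom]
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite pool values: {self}")


@dataclass(frozen=True)
class SoilParams:
    """Per-site soil and management parameters."""

    clay: float
    depth: float = 30.0
    land_use: LandUse = LandUse.ARABLE
    dpm_rpm_ratio: float | None = None
    params: RothCParams = field(default=DEFAULT_PARAMS, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.clay <= 100.0:
            raise ValueError(f"clay must be in [0, 100] %, got {self.clay}")
        if self.depth <= 0:
            raise ValueError(f"depth must be positive, got {self.depth}")
        if self.dpm_rpm_ratio is None:
            ratio = (
                self.params.dpm_rpm_arable
                if self.land_use == LandUse.ARABLE
                else self.params.dpm_rpm_grassland
            )
            object.__setattr__(self, "dpm_rpm_ratio", ratio)
        if self.dpm_rpm_ratio <= 0:
            raise ValueError("dpm_rpm_ratio must be positive")

    @property
    def input_allocation(self) -> np.ndarray:
        """Split of fresh carbon input over (DPM, RPM, BIO, HUM)."""
        f_dpm = self.dpm_rpm_ratio / (1.0 + self.dpm_rpm_ratio)
        return np.array([f_dpm, 1.0 - f_dpm, 0.0, 0.0])


@dataclass
class MoistureState:
    """Accumulated topsoil moisture deficit (TSMD) bookkeeping, mm."""

    acc_tsmd: float
    max_tsmd: float

    def __post_init__(self) -> None:
        if self.max_tsmd <= 0:
            raise ValueError(f"max_tsmd must be positive, got {self.max_tsmd}")
        if not 0.0 <= self.acc_tsmd <= self.max_tsmd + 1e-9:
            raise ValueError(
                f"acc_tsmd {self.acc_tsmd} outside [0, {self.max_tsmd}]"
            )


@dataclass(frozen=True)
class RateModifiers:
    """Multiplicative decomposition modifiers for one month."""

    a: float  # temperature factor, ≥ 0
    b: float  # moisture factor, in [b_min, 1]
    c: float  # soil-cover factor

    @property
    def abc(self) -> float:
        return self.a * self.b * self.c


@dataclass(frozen=True)
class MonthlyForcing:
    temp: float
    precip: float
    pet: float
    covered: bool
    modifiers: RateModifiers


def temperature_factor(temp, params: RothCParams = DEFAULT_PARAMS):
    """Temperature rate modifier *a*; zero at and below −``a_shift`` °C."""
    t = np.asarray(temp, dtype=float)
    out = np.zeros_like(t)
    mask = t > -params.a_shift
    with np.errstate(over="ignore"):
        out[mask] = params.a_num / (1.0 + np.exp(params.a_scale / (t[mask] + params.a_shift)))
    if np.isscalar(temp) or np.ndim(temp) == 0:
        return float(out)
    return out


def max_deficit(soil: SoilParams, covered: bool = True) -> float:
    """Maximum accumulable topsoil moisture deficit, mm.

    The 23 cm reference capacity −(20 + 1.3·clay − 0.01·clay²) is scaled by
    depth/23; for bare soil the capacity is divided by 1.8.
    """
    p = soil.params
    cap = (20.0 + 1.3 * soil.clay - 0.01 * soil.clay**2) * soil.depth / p.reference_depth_cm
    if not covered:
        cap /= p.bare_deficit_divisor
    return cap


def _moisture_factor(acc: float, cap: float, params: RothCParams) -> float:
    thr = params.b_threshold * cap
    if acc <= thr:
        return 1.0
    b = params.b_min + (1.0 - params.b_min) * (cap - acc) / (cap - thr)
    return float(min(1.0, max(params.b_min, b)))


def _step_deficit(
    acc: float, precip: float, pet: float, covered: bool, soil: SoilParams
) -> float:
    """One month of TSMD accounting (chronological).

    Excess rain (precip > 0.75·PET) pays the deficit down; otherwise the
    deficit grows, capped at the covered capacity, or at the bare capacity
    when the soil is bare (an already larger deficit persists but cannot
    grow further).
    """
    p = soil.params
    delta = precip - p.pet_fraction * pet
    if delta >= 0:
        return max(0.0, acc - delta)
    cap = max_deficit(soil, covered=True)
    if not covered:
        cap = min(cap, max(acc, max_deficit(soil, covered=False)))
    return min(acc - delta, cap)


def rate_modifiers(
    temp: float,
    precip: float,
    pet: float,
    covered: bool,
    moisture: MoistureState,
    soil: SoilParams,
) -> tuple[RateModifiers, MoistureState]:
    """Rate modifiers for one month plus the updated moisture deficit."""
    if precip < 0 or pet < 0:
        raise ValueError("precip and pet must be non-negative")
    p = soil.params
    acc = _step_deficit(moisture.acc_tsmd, precip, pet, covered, soil)
    b = _moisture_factor(acc, moisture.max_tsmd, p)
    a = temperature_factor(temp, p)
    c = p.cover_factor if covered else 1.0
    return RateModifiers(a=a, b=b, c=c), replace(moisture, acc_tsmd=acc)


@dataclass
class ForcingSeries:
    """Vectorised monthly forcing with precomputed rate modifiers."""

    temp: np.ndarray
    precip: np.ndarray
    pet: np.ndarray
    covered: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __len__(self) -> int:
        return len(self.temp)

    @property
    def abc(self) -> np.ndarray:
        return self.a * self.b * self.c

    def __getitem__(self, i: int) -> MonthlyForcing:
        return MonthlyForcing(
            temp=float(self.temp[i]),
            precip=float(self.precip[i]),
            pet=float(self.pet[i]),
            covered=bool(self.covered[i]),
            modifiers=RateModifiers(float(self.a[i]), float(self.b[i]), float(self.c[i])),
        )

    def months(self) -> list[MonthlyForcing]:
        return [self[i] for i in range(len(self))]

    def reversed(self) -> "ForcingSeries":
        """The same months visited in reverse chronological order."""
        return ForcingSeries(
            temp=self.temp[::-1], precip=self.precip[::-1], pet=self.pet[::-1],
            covered=self.covered[::-1], a=self.a[::-1], b=self.b[::-1], c=self.c[::-1],
        )


def build_forcing_series(
    temp: Sequence[float],
    precip: Sequence[float],
    pet: Sequence[float],
    covered: Sequence[bool],
    soil: SoilParams,
    acc_tsmd0: float = 0.0,
) -> ForcingSeries:
    """Thread the moisture deficit chronologically and precompute a, b, c."""
    temp = np.asarray(temp, dtype=float)
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    covered = np.asarray(covered, dtype=bool)
    n = len(temp)
    if not (len(precip) == len(pet) == len(covered) == n):
        raise ValueError("forcing component lengths differ")
    if np.any(precip < 0) or np.any(pet < 0):
        raise ValueError("precip and pet must be non-negative")
    p = soil.params
    cap = max_deficit(soil, covered=True)
    a = temperature_factor(temp, p)
    b = np.empty(n)
    c = np.where(covered, p.cover_factor, 1.0)
    acc = acc_tsmd0
    for i in range(n):
        acc = _step_deficit(acc, precip[i], pet[i], bool(covered[i]), soil)
        b[i] = _moisture_factor(acc, cap, p)
    return ForcingSeries(temp=temp, precip=precip, pet=pet, covered=covered, a=a, b=b, c=c)


def partition_coefficients(soil: SoilParams) -> tuple[float, float, float]:
    """Clay-dependent split of decomposed carbon into (CO₂, BIO, HUM).

    The CO₂/(BIO+HUM) ratio is x = 1.67·(1.85 + 1.60·exp(−0.0786·clay));
    the retained share splits 46:54 between BIO and HUM.  The three
    fractions sum to one.
    """
    p = soil.params
    x = 1.67 * (1.85 + 1.60 * np.exp(-0.0786 * soil.clay))
    co2 = x / (x + 1.0)
    retained = 1.0 - co2
    return float(co2), float(p.bio_share * retained), float(p.hum_share * retained)


def iom_from_total(total_soc: float, params: RothCParams = DEFAULT_PARAMS) -> float:
    """Inert pool from total stock via the Falloon pedotransfer 0.049·SOC^1.139."""
    if total_soc < 0:
        raise ValueError(f"total SOC must be non-negative, got {total_soc}")
    return params.iom_coeff * total_soc**params.iom_power


# ---------------------------------------------------------------------------
# Monthly affine update.  With decay survival d_i = exp(-k_i·a·b·c/12), the
# active pool vector evolves as
#     x_in = x + cin·alloc
#     x'   = D x_in + h (uᵀ x_in),   u = 1 − d,  h = (0, 0, bio_fr, hum_fr)·loss
# i.e. x' = M x_in with M = D + h uᵀ.  M is invertible (1 + uᵀD⁻¹h ≥ 1), so
# the backward step is the exact Sherman–Morrison solve.
# ---------------------------------------------------------------------------


def _decay_survival(abc: np.ndarray, soil: SoilParams) -> np.ndarray:
    """Survival fractions exp(−k·abc/12), shape (..., 4)."""
    k = soil.params.k
    return np.exp(-np.multiply.outer(np.asarray(abc, dtype=float), k) / 12.0)


def _transfer_vector(soil: SoilParams) -> tuple[float, np.ndarray]:
    co2f, bio_f, hum_f = partition_coefficients(soil)
    return co2f, np.array([0.0, 0.0, bio_f, hum_f])


def monthly_step(
    pools: PoolState,
    cin_month: float,
    forcing: MonthlyForcing,
    soil: SoilParams,
) -> tuple[PoolState, float]:
    """Advance one month; returns the new state and the CO₂ efflux.

    Mass balance: cin_month − co2 equals the change in the active pool sum.
    """
    if cin_month < 0:
        raise ValueError(f"carbon input must be non-negative, got {cin_month}")
    pools.validate()
    m = forcing.modifiers
    if not (np.isfinite(m.abc) and m.abc >= 0):
        raise ValueError(f"invalid rate modifiers {m}")
    d = _decay_survival(m.abc, soil)
    co2f, h = _transfer_vector(soil)
    x_in = pools.active + cin_month * soil.input_allocation
    loss = x_in * (1.0 - d)
    s = float(loss.sum())
    x_new = x_in * d + h * s
    return PoolState.from_active(x_new, pools.iom), co2f * s


def forward_active(
    active0: np.ndarray,
    forcings: ForcingSeries,
    inputs: np.ndarray,
    soil: SoilParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Array-core forward run: trajectory (T+1, 4) of active pools and CO₂ (T,)."""
    inputs = np.asarray(inputs, dtype=float)
    if len(inputs) != len(forcings):
        raise ValueError(
            f"forcing has {len(forcings)} months but inputs has {len(inputs)}"
        )
    if np.any(inputs < 0):
        raise ValueError("carbon inputs must be non-negative")
    d = _decay_survival(forcings.abc, soil)
    co2f, h = _transfer_vector(soil)
    alloc = soil.input_allocation
    T = len(inputs)
    traj = np.empty((T + 1, 4))
    co2 = np.empty(T)
    x = np.asarray(active0, dtype=float).copy()
    traj[0] = x
    for t in range(T):
        x_in = x + inputs[t] * alloc
        dt = d[t]
        s = x_in @ (1.0 - dt)
        x = x_in * dt + h * s
        co2[t] = co2f * s
        traj[t + 1] = x
    return traj, co2


def _exact_backward_active(
    active_end: np.ndarray,
    forcings: ForcingSeries,
    inputs: np.ndarray,
    soil: SoilParams,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Literal month-by-month algebraic inversion (Sherman–Morrison).

    Exact in real arithmetic but exponentially unstable in floating point:
    each backward month amplifies rounding error by exp(k·a·b·c/12) in the
    fast pools, so it is only usable over short horizons (a few years).
    :func:`backward_active` is the stable long-horizon reconstruction.
    """
    inputs = np.asarray(inputs, dtype=float)
    if len(inputs) != len(forcings):
        raise ValueError(
            f"forcing has {len(forcings)} months but inputs has {len(inputs)}"
        )
    d = _decay_survival(forcings.abc, soil)
    if not np.all(np.isfinite(d)) or np.any(d <= 0):
        raise FloatingPointError("singular monthly propagator (extreme a·b·c)")
    co2f, h = _transfer_vector(soil)
    alloc = soil.input_allocation
    T = len(inputs)
    traj = np.empty((T + 1, 4))
    co2 = np.empty(T)
    x = np.asarray(active_end, dtype=float).copy()
    traj[T] = x
    for t in range(T - 1, -1, -1):
        dt = d[t]
        u = 1.0 - dt
        hd = h / dt
        x0 = x / dt
        x_in = x0 - hd * ((u @ x0) / (1.0 + u @ hd))
        co2[t] = co2f * (u @ x_in)
        x = x_in - inputs[t] * alloc
        traj[t] = x
    negative = bool(np.any(traj < -1e-9))
    return traj, co2, negative


def backward_active(
    active_end: np.ndarray,
    forcings: ForcingSeries,
    inputs: np.ndarray,
    soil: SoilParams,
    reference: np.ndarray | None = None,
    rcond: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Stable inverse of :func:`forward_active` over long horizons.

    The whole-horizon forward map is affine, x_T = P x_0 + q.  Because the
    dynamics contract (fast pools forget their past within months), P has
    singular values spanning hundreds of orders of magnitude and the
    literal preimage of an arbitrary end state is astronomically large:
    month-by-month inversion amplifies floating-point rounding by
    exp(Σ k·a·b·c/12) and overflows within a few simulated years.  The
    well-posed reconstruction is the *bounded* solution of the backward
    recursion: write x_0 = x_ref + δ with x_ref a reference state (default:
    the end state itself, which in the pipeline is the reference-climate
    steady state) and solve min‖P δ − (x_T − q − P x_ref)‖ by
    singular-value-truncated least squares.  Directions the dynamics can
    still remember (slow pools) are matched exactly; directions already
    forgotten are left at the reference — their contribution to the replay
    end state is below machine precision by construction.  The returned
    trajectory is the exact forward trajectory from x_0, so
    forward∘backward reproduces any forward-attainable end state to
    rounding error, and a periodic steady end state under periodic forcing
    is reproduced exactly.

    Returns (trajectory (T+1, 4) chronological, co2 (T,), negative_flag).
    Negative reconstructed pools are flagged, never clipped.
    """
    inputs = np.asarray(inputs, dtype=float)
    if len(inputs) != len(forcings):
        raise ValueError(
            f"forcing has {len(forcings)} months but inputs has {len(inputs)}"
        )
    x_end = np.asarray(active_end, dtype=float)
    if len(inputs) == 0:
        return x_end[None, :].copy(), np.empty(0), bool(np.any(x_end < -1e-9))
    d = _decay_survival(forcings.abc, soil)
    if not np.all(np.isfinite(d)) or np.any(d <= 0):
        raise FloatingPointError("singular monthly propagator (extreme a·b·c)")
    co2f, h = _transfer_vector(soil)
    alloc = soil.input_allocation
    P = np.eye(4)
    q = np.zeros(4)
    for t in range(len(inputs)):
        dt = d[t]
        M = np.diag(dt) + np.outer(h, 1.0 - dt)
        P = M @ P
        q = M @ (q + inputs[t] * alloc)
    x_ref = x_end if reference is None else np.asarray(reference, dtype=float)
    resid = x_end - q - P @ x_ref
    delta, *_ = np.linalg.lstsq(P, resid, rcond=rcond)
    x0 = x_ref + delta
    traj, co2 = forward_active(x0, forcings, inputs, soil)
    negative = bool(np.any(traj < -1e-9))
    return traj, co2, negative


def _as_series(forcings, soil: SoilParams) -> ForcingSeries:
    if isinstance(forcings, ForcingSeries):
        return forcings
    months: list[MonthlyForcing] = list(forcings)
    return ForcingSeries(
        temp=np.array([m.temp for m in months]),
        precip=np.array([m.precip for m in months]),
        pet=np.array([m.pet for m in months]),
        covered=np.array([m.covered for m in months]),
        a=np.array([m.modifiers.a for m in months]),
        b=np.array([m.modifiers.b for m in months]),
        c=np.array([m.modifiers.c for m in months]),
    )


def run_forward(
    pools0: PoolState,
    forcings: ForcingSeries | Iterable[MonthlyForcing],
    inputs: Sequence[float],
    soil: SoilParams,
) -> list[PoolState]:
    """Chronological run; returns the state after every month (incl. start)."""
    series = _as_series(forcings, soil)
    traj, _ = forward_active(pools0.active, series, np.asarray(inputs, dtype=float), soil)
    return [PoolState.from_active(row, pools0.iom) for row in traj]


def run_backward(
    pools_end: PoolState,
    forcings: ForcingSeries | Iterable[MonthlyForcing],
    inputs: Sequence[float],
    soil: SoilParams,
) -> tuple[list[PoolState], bool]:
    """Reconstruct the past trajectory ending at ``pools_end``.

    Inverts the whole-horizon affine forward map through its bounded
    solution (see :func:`backward_active`), so that a forward replay over
    the same forcing reproduces any forward-attainable ``pools_end`` to
    rounding error.  Returns the chronological trajectory and a flag
    marking negative reconstructed pools.
    """
    series = _as_series(forcings, soil)
    traj, _, negative = backward_active(
        pools_end.active, series, np.asarray(inputs, dtype=float), soil
    )
    return [PoolState.from_active(row, pools_end.iom) for row in traj], negative
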