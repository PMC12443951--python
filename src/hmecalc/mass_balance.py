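"""Steady-state plug-flow mass balance of the HME test circuit.

The circuit is a line of compartments traversed alternately in the two
flow directions:

    P1 -- HME -- dead space (V_D) -- P2/P3 -- humidifier

During *inspiration* carrier gas of humidity ``hb`` enters at P1, picks
up the water the HME releases (exit fraction ``c_ext``), pushes the
dead-space content ahead of it past P2 (moisture-benefit sensor) and
into the humidifier.  During *expiration* the humidifier delivers gas
at the target humidity ``ha``; the dead-space residue (at ``c_ext``)
and then ha-gas enter the HME, which stores part of the water load, and
the remainder leaves at P4 (water-output sensor).

Under plug flow every quantity of one steady-state breath follows from
the rig parameters (ha, hb, V_D) plus ONE concentration measurement
(mb at P2 or wo at P4) and ONE volume measurement (V_insp, V_mb or
V_exp).  With (mb, V_mb) the stored mass is

    m_st = { [ (mb*V_mb - ha*V_D) / (1 - V_D/V_mb) ] - hb*V_mb } / (1 - hb)

with all amounts molar and concentrations molar fractions; the bracket
equals c_ext*V_mb, the water leaving the HME during inspiration.  The
remaining unknowns close via dry-gas conservation:

    V_insp (1-hb) = V_mb (1-c_ext)            (HME, inspiration)
    V_sup  (1-ha) = V_mb (1-mb)               (humidifier, full cycle)
    m_e_ent = c_ext*V_D + ha*(V_sup - V_D)    (dead-space slug)
    V_exp   = V_sup - m_st                    (moles removed by the HME)

These relations are exactly self-consistent: the four mass identities
(m_i_ext = m_i_ent + m_st; m_e_ext = m_e_ent - m_st;
m_add = m_e_ext - m_i_ent = m_sup - m_ret) and inspired/expired dry-gas
equality hold algebraically for every state this module returns.

Units: molar everywhere internally (mol gas, mol water, molar
fractions); the returned state reports water masses in mmol (multiply
by 18.015 for mg).  Interface helpers accept mg/l and ml.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .psychrometry import (
    CABINET,
    MOLAR_MASS_WATER,
    DomainError,
    GasConditions,
    absolute_to_fraction,
    fraction_to_absolute,
    volume_to_moles,
)

__all__ = [
    "Location",
    "RigParameters",
    "BreathMeasurement",
    "MassBalanceState",
    "HMEBehavior",
    "Prediction",
    "ConsistencyReport",
    "PublishedPerformance",
    "WaterLoadApprox",
    "DeadSpaceError",
    "ConvergenceError",
    "InfeasibleBehaviorError",
    "EfficiencyUndefinedError",
    "UsageError",
    "DeadSpaceRatioWarning",
    "NetAbsorptionWarning",
    "evaluate_from_mb",
    "evaluate_from_wo",
    "evaluate",
    "predict_no_hme",
    "predict_with_hme",
    "efficiency",
    "approximate_water_load",
    "consistency_residuals",
    "performance_from_published",
]

# Damped fixed-point settings for the expiratory-side closure.
_FP_DAMPING = 0.5
_FP_MAX_ITER = 200
_FP_TOL = 1e-12  # absolute, on molar fractions

#: Rule-of-thumb ceiling for dead space relative to inspired amount.
DEAD_SPACE_RATIO_LIMIT = 0.20


class DeadSpaceError(ValueError):
    """Measured volume does not exceed the dead-space content."""


class ConvergenceError(RuntimeError):
    """The expiratory fixed-point solve did not reach tolerance."""


class InfeasibleBehaviorError(ValueError):
    """Storage rule implies more water stored than the HME receives."""


class EfficiencyUndefinedError(ValueError):
    """Efficiency denominator m_e_ent - m_i_ent is not positive."""


class UsageError(ValueError):
    """Unsupported measurement combination."""


class DeadSpaceRatioWarning(UserWarning):
    """Dead space exceeds 20% of the inspired amount (rule of thumb)."""


class NetAbsorptionWarning(UserWarning):
    """Computed m_st is negative: HME net-absorbing over the interval."""


class Location(Enum):
    """Measurement positions of the rig."""

    P1_INSPIRED = "P1"
    P2_MOISTURE_BENEFIT = "P2"
    P4_WATER_OUTPUT = "P4"


@dataclass(frozen=True)
class RigParameters:
    """Target humidity, inspired humidity and dead space of one experiment.

    Parameters
    ----------
    ha : float
        Humidifier target humidity at position 3, molar fraction.
    hb : float
        Humidity of the inspired carrier gas at position 1, molar
        fraction.  Must satisfy 0 <= hb < ha < 1.
    dead_space : float
        Gas content of the dead space between HME and humidifier, mol.
    conditions : GasConditions
        Temperature/pressure at which volumes and mg/l values are
        referenced.
    """

    ha: float
    hb: float
    dead_space: float
    conditions: GasConditions = CABINET

    def __post_init__(self) -> None:
        if not (0.0 <= self.hb < self.ha < 1.0):
            raise DomainError(
                f"require 0 <= hb < ha < 1, got hb={self.hb}, ha={self.ha}"
            )
        if self.dead_space < 0:
            raise DomainError("dead space must be >= 0")

    @classmethod
    def from_practical(
        cls,
        ha_mg_l: float = 44.0,
        hb_mg_l: float = 0.0,
        dead_space_ml: float = 30.0,
        temperature_c: float = 38.0,
        pressure_kpa: float = 101.325,
    ) -> "RigParameters":
        """Build from laboratory units (mg/l, ml, degC, kPa)."""
        cond = GasConditions.from_celsius(temperature_c, pressure_kpa * 1e3)
        return cls(
            ha=absolute_to_fraction(ha_mg_l, cond),
            hb=absolute_to_fraction(hb_mg_l, cond),
            dead_space=volume_to_moles(dead_space_ml * 1e-3, cond),
            conditions=cond,
        )


@dataclass(frozen=True)
class BreathMeasurement:
    """One measurement record: a volume and optionally a concentration.

    ``volume`` is in mol of gas; ``concentration`` (when present) is a
    molar fraction.  At P1 the concentration is ``hb`` by definition
    and need not be supplied.
    """

    location: Location
    volume: float
    concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise DomainError("measured volume must be > 0")
        if self.concentration is not None and not (0.0 <= self.concentration < 1.0):
            raise DomainError("concentration must lie in [0, 1)")


@dataclass(frozen=True)
class MassBalanceState:
    """All water masses and gas amounts of one steady-state breath.

    Water masses are in mmol (multiply by 18.015 for mg); gas amounts
    in mol; ``c_ext`` is the molar water fraction of the gas leaving
    the HME during inspiration (= dead-space residue humidity);
    ``eta`` is the efficiency m_st / (m_e_ent - m_i_ent), NaN when the
    denominator vanishes.
    """

    m_i_ent: float
    m_st: float
    m_i_ext: float
    m_e_ent: float
    m_ret: float
    m_sup: float
    m_e_ext: float
    m_add: float
    V_insp: float
    V_mb: float
    V_exp: float
    V_sup: float
    c_ext: float
    eta: float
    conditions: GasConditions = CABINET

    # -- concentration views -------------------------------------------------
    @property
    def mb(self) -> float:
        """Moisture benefit at P2, molar fraction."""
        return self.m_ret * 1e-3 / self.V_mb

    @property
    def wo(self) -> float:
        """Water output at P4, molar fraction."""
        return self.m_e_ext * 1e-3 / self.V_exp

    @property
    def mb_mg_l(self) -> float:
        return fraction_to_absolute(self.mb, self.conditions)

    @property
    def wo_mg_l(self) -> float:
        return fraction_to_absolute(self.wo, self.conditions)

    @property
    def performance_mg(self) -> float:
        """HME performance: reversibly stored water per breath, mg."""
        return self.m_st * MOLAR_MASS_WATER

    def mass_mg(self, name: str) -> float:
        """A water mass field converted from mmol to mg."""
        return getattr(self, name) * MOLAR_MASS_WATER

    def identity_residuals(self) -> dict:
        """Relative residuals of the four circuit mass identities.

        Residuals are normalised by the largest water mass in the state
        so that exactly-zero masses do not inflate the ratio.
        """
        scale = max(
            abs(x)
            for x in (
                self.m_i_ent,
                self.m_st,
                self.m_i_ext,
                self.m_e_ent,
                self.m_ret,
                self.m_sup,
                self.m_e_ext,
                self.m_add,
            )
        )
        scale = scale if scale > 0 else 1.0
        dry_in = self.V_insp * 1.0 - self.m_i_ent * 1e-3
        dry_out = self.V_exp * 1.0 - self.m_e_ext * 1e-3
        return {
            "inspiration": abs(self.m_i_ext - (self.m_i_ent + self.m_st)) / scale,
            "expiration": abs(self.m_e_ext - (self.m_e_ent - self.m_st)) / scale,
            "humidifier_gain": abs(self.m_add - (self.m_e_ext - self.m_i_ent)) / scale,
            "humidifier_flux": abs(self.m_add - (self.m_sup - self.m_ret)) / scale,
            "dry_gas": abs(dry_in - dry_out) / max(dry_in, 1e-300),
        }

    def as_report(self) -> dict:
        """Flat key/value report with masses in both mmol and mg."""
        out: dict = {}
        for name in ("m_i_ent", "m_st", "m_i_ext", "m_e_ent", "m_ret", "m_sup", "m_e_ext", "m_add"):
            v = getattr(self, name)
            out[f"{name}_mmol"] = v
            out[f"{name}_mg"] = v * MOLAR_MASS_WATER
        for name in ("V_insp", "V_mb", "V_exp", "V_sup"):
            out[f"{name}_mol"] = getattr(self, name)
            out[f"{name}_l"] = getattr(self, name) / self.conditions.molar_density
        out["c_ext_fraction"] = self.c_ext
        out["eta"] = self.eta
        out["mb_mg_l"] = self.mb_mg_l
        out["wo_mg_l"] = self.wo_mg_l
        return out


# ---------------------------------------------------------------------------
# HME storage rules
# ---------------------------------------------------------------------------


@dataclass
class HMEBehavior:
    """Per-breath water storage rule of an HME.

    Three empirical classes are supported; each maps the net water load
    offered during expiration to the mass stored (and returned during
    the next inspiration):

    ``linear``      m_st = eta0 * load                 (efficiency eta0)
    ``asymptotic``  m_st = shape * ln(1 + eta0*load/shape), approaching
                    the capacity limit smoothly (saturating exponential
                    of the instantaneous absorbed fraction)
    ``constant``    m_st = min(load, capacity): the capacity is reached
                    every breath, so storage is load-independent

    ``capacity`` and ``shape`` are in mg of water; ``current_store``
    (mg) is simulator state, not part of the rule definition.
    """

    behavior_class: str
    eta0: float = 0.0
    capacity: float = math.inf
    shape: float = math.nan
    current_store: float = 0.0

    def __post_init__(self) -> None:
        if self.behavior_class not in ("linear", "asymptotic", "constant"):
            raise UsageError(f"unknown behavior class {self.behavior_class!r}")
        if not 0.0 <= self.eta0 <= 1.0:
            raise InfeasibleBehaviorError(
                f"base efficiency must lie in [0, 1], got {self.eta0}"
            )
        if self.capacity < 0:
            raise DomainError("capacity must be >= 0")
        if self.behavior_class == "asymptotic" and not self.shape > 0:
            raise DomainError("asymptotic class needs a positive shape parameter")

    # convenience constructors ------------------------------------------------
    @classmethod
    def linear(cls, eta0: float, capacity: float = math.inf) -> "HMEBehavior":
        return cls("linear", eta0=eta0, capacity=capacity)

    @classmethod
    def asymptotic(cls, eta0: float, shape: float, capacity: float = math.inf) -> "HMEBehavior":
        return cls("asymptotic", eta0=eta0, shape=shape, capacity=capacity)

    @classmethod
    def constant(cls, capacity: float) -> "HMEBehavior":
        return cls("constant", capacity=capacity)

    @classmethod
    def fixed_storage(cls, m_st_mg: float) -> "HMEBehavior":
        """Rule storing exactly ``m_st_mg`` per breath (load permitting)."""
        return cls("constant", capacity=m_st_mg)

    # rule surface -------------------------------------------------------------
    def absorbed_fraction(self, store_mg: float) -> float:
        """Instantaneous fraction of net parcel water absorbed at store S."""
        if store_mg >= self.capacity:
            return 0.0
        if self.behavior_class == "linear":
            return self.eta0
        if self.behavior_class == "asymptotic":
            return self.eta0 * math.exp(-store_mg / self.shape)
        return 1.0  # constant class: absorb everything until capacity

    def steady_storage(self, load_mg: float) -> float:
        """Stored mass per breath (mg) for a net expiratory load (mg).

        Closed-form integral of :meth:`absorbed_fraction` over one
        expiration starting from an empty (fully released) store.
        """
        if load_mg < 0:
            return 0.0
        if self.behavior_class == "linear":
            m = self.eta0 * load_mg
        elif self.behavior_class == "asymptotic":
            m = self.shape * math.log1p(self.eta0 * load_mg / self.shape)
        else:
            m = load_mg
        return min(m, self.capacity)


# ---------------------------------------------------------------------------
# Core closure
# ---------------------------------------------------------------------------


def _state_from_c(params: RigParameters, c: float, V_mb: float) -> MassBalanceState:
    """Close the full breath state from HME-exit fraction c and V_mb (mol)."""
    ha, hb, vd = params.ha, params.hb, params.dead_space
    if c >= 1.0:
        raise DomainError(f"implied HME-exit fraction c_ext = {c:.4g} >= 1")
    mb = (ha * vd + c * (V_mb - vd)) / V_mb
    if mb >= 1.0:
        raise DomainError("implied moisture benefit fraction >= 1")
    m_i_ext = c * V_mb
    m_st = V_mb * (c - hb) / (1.0 - hb)
    m_i_ent = m_i_ext - m_st
    V_insp = V_mb * (1.0 - c) / (1.0 - hb)
    m_ret = mb * V_mb
    V_sup = V_mb * (1.0 - mb) / (1.0 - ha)
    m_sup = ha * V_sup
    m_e_ent = c * vd + ha * (V_sup - vd)
    m_e_ext = m_e_ent - m_st
    V_exp = V_sup - m_st
    m_add = m_e_ext - m_i_ent
    denom = m_e_ent - m_i_ent
    eta = m_st / denom if denom > 0 else math.nan

    if m_st < 0:
        warnings.warn(
            f"computed m_st = {m_st * 1e3:.4g} mmol < 0: net-absorbing interval "
            "(HME removed water from the inspirate)",
            NetAbsorptionWarning,
            stacklevel=3,
        )
    if vd > DEAD_SPACE_RATIO_LIMIT * V_insp:
        warnings.warn(
            f"dead space ({vd:.4g} mol) exceeds 20% of the inspired amount "
            f"({V_insp:.4g} mol); plug-flow rule of thumb violated",
            DeadSpaceRatioWarning,
            stacklevel=3,
        )

    to_mmol = 1e3
    return MassBalanceState(
        m_i_ent=m_i_ent * to_mmol,
        m_st=m_st * to_mmol,
        m_i_ext=m_i_ext * to_mmol,
        m_e_ent=m_e_ent * to_mmol,
        m_ret=m_ret * to_mmol,
        m_sup=m_sup * to_mmol,
        m_e_ext=m_e_ext * to_mmol,
        m_add=m_add * to_mmol,
        V_insp=V_insp,
        V_mb=V_mb,
        V_exp=V_exp,
        V_sup=V_sup,
        c_ext=c,
        eta=eta,
        conditions=params.conditions,
    )


def evaluate_from_mb(params: RigParameters, mb: float, V_mb: float) -> MassBalanceState:
    """Evaluate the breath state from moisture benefit and its volume.

    Parameters
    ----------
    mb : float
        Flow-weighted moisture-benefit fraction at P2 (molar fraction).
    V_mb : float
        Gas amount passing P2 during inspiration, mol.  Must exceed the
        dead-space content.
    """
    if not (0.0 <= mb < 1.0):
        raise DomainError(f"mb must lie in [0, 1), got {mb}")
    if V_mb <= params.dead_space:
        raise DeadSpaceError(
            f"dead space ({params.dead_space:.4g} mol) exceeds measured "
            f"volume V_mb ({V_mb:.4g} mol)"
        )
    c = (mb * V_mb - params.ha * params.dead_space) / (V_mb - params.dead_space)
    return _state_from_c(params, c, V_mb)


def evaluate_from_wo(params: RigParameters, wo: float, V_exp: float) -> MassBalanceState:
    """Evaluate the breath state from water output and expired volume.

    Because the dead-space residue humidity c_ext appears on both sides
    of the expiratory balance, the closure is solved as a damped fixed
    point (damping 0.5, residual <= 1e-12 on molar fractions, start at
    c_ext = ha).
    """
    if not (0.0 <= wo < 1.0):
        raise DomainError(f"wo must lie in [0, 1), got {wo}")
    if V_exp <= params.dead_space:
        raise DeadSpaceError(
            f"dead space ({params.dead_space:.4g} mol) exceeds measured "
            f"volume V_exp ({V_exp:.4g} mol)"
        )
    ha, hb, vd = params.ha, params.hb, params.dead_space
    dry_flux = V_exp * (1.0 - wo)  # dry moles through P4 == through P2
    m_e_ext = wo * V_exp

    c = ha  # deterministic initialisation
    residual = math.inf
    for _ in range(_FP_MAX_ITER):
        V_sup = (dry_flux + vd * (c - ha)) / (1.0 - ha)
        m_e_ent = c * vd + ha * (V_sup - vd)
        m_st = m_e_ent - m_e_ext
        V_mb = dry_flux / (1.0 - c)
        c_new = hb + m_st * (1.0 - hb) / V_mb
        residual = abs(c_new - c)
        if residual <= _FP_TOL:
            c = c_new
            break
        c = c + _FP_DAMPING * (c_new - c)
    else:
        raise ConvergenceError(
            f"expiratory closure did not converge after {_FP_MAX_ITER} "
            f"iterations (residual {residual:.3e} on c_ext)"
        )
    return _state_from_c(params, c, dry_flux / (1.0 - c))


# ---------------------------------------------------------------------------
# Dispatch over measurement combinations
# ---------------------------------------------------------------------------


def evaluate(
    params: RigParameters,
    concentration_measurement: BreathMeasurement,
    volume_measurement: BreathMeasurement,
) -> MassBalanceState:
    """Evaluate from any admissible (concentration, volume) pair.

    The concentration must come from P2 (mb) or P4 (wo); the volume may
    come from P1, P2 or P4.  Volumes measured at other positions than
    the concentration are propagated through the circuit via dry-gas
    conservation before dispatching to :func:`evaluate_from_mb` /
    :func:`evaluate_from_wo`; on consistent inputs all six combinations
    return the same state.
    """
    cm, vm = concentration_measurement, volume_measurement
    if cm.concentration is None:
        raise UsageError("concentration measurement carries no concentration")
    if cm.location == Location.P1_INSPIRED:
        raise UsageError("inspired humidity hb is a rig parameter, not an evaluation input")
    ha, hb, vd = params.ha, params.hb, params.dead_space
    conc = cm.concentration
    vol = vm.volume

    if cm.location == Location.P2_MOISTURE_BENEFIT:
        mb = conc
        if vm.location == Location.P2_MOISTURE_BENEFIT:
            return evaluate_from_mb(params, mb, vol)
        if vm.location == Location.P1_INSPIRED:
            # Dry-gas conservation V_insp(1-hb) = V_mb(1-c_ext) yields a
            # quadratic in V_mb; the physical root exceeds V_D.
            a_dry = vol * (1.0 - hb)
            if vd == 0.0:
                return evaluate_from_mb(params, mb, a_dry / (1.0 - mb))
            qa = 1.0 - mb
            qb = -(vd * (1.0 - ha) + a_dry)
            qc = a_dry * vd
            disc = qb * qb - 4.0 * qa * qc
            if disc < 0:
                raise DomainError("no physical V_mb for the supplied (mb, V_insp)")
            v_mb = (-qb + math.sqrt(disc)) / (2.0 * qa)
            return evaluate_from_mb(params, mb, v_mb)
        if vm.location == Location.P4_WATER_OUTPUT:
            # Eliminating c_ext and m_st from V_exp = V_sup - m_st gives
            # a quadratic in V_mb; the physical root is the larger one
            # (the smaller sits just above V_D with an unphysical c_ext).
            a_fac = (1.0 - hb) * (1.0 - mb) / (1.0 - ha)
            qa = a_fac - mb + hb
            qb = -a_fac * vd + (ha - hb) * vd - (1.0 - hb) * vol
            qc = (1.0 - hb) * vol * vd
            disc = qb * qb - 4.0 * qa * qc
            if disc < 0 or qa <= 0:
                raise DomainError("no physical V_mb for the supplied (mb, V_exp)")
            v_mb = (-qb + math.sqrt(disc)) / (2.0 * qa)
            return evaluate_from_mb(params, mb, v_mb)

    if cm.location == Location.P4_WATER_OUTPUT:
        wo = conc
        if vm.location == Location.P4_WATER_OUTPUT:
            return evaluate_from_wo(params, wo, vol)
        if vm.location == Location.P1_INSPIRED:
            # dry moles at P1 equal dry moles at P4 in steady state
            v_exp = vol * (1.0 - hb) / (1.0 - wo)
            return evaluate_from_wo(params, wo, v_exp)
        if vm.location == Location.P2_MOISTURE_BENEFIT:
            # With V_mb fixed the expiratory balance is linear in c_ext.
            v_mb = vol
            num = (ha - wo) * v_mb / (1.0 - wo) - ha * vd \
                + hb * v_mb * (1.0 - ha) / (1.0 - hb)
            den = v_mb * (1.0 - ha) / (1.0 - hb) - vd \
                + (ha - wo) * v_mb / (1.0 - wo)
            if den == 0:
                raise DomainError("degenerate (wo, V_mb) combination")
            return _state_from_c(params, num / den, v_mb)

    raise UsageError(
        f"unsupported combination: concentration at {cm.location.value}, "
        f"volume at {vm.location.value}"
    )


# ---------------------------------------------------------------------------
# Prediction mode
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Prediction:
    """Predicted measurements plus the underlying full state."""

    mb: float
    wo: float
    V_mb: float
    V_exp: float
    state: MassBalanceState

    @property
    def mb_mg_l(self) -> float:
        return fraction_to_absolute(self.mb, self.state.conditions)

    @property
    def wo_mg_l(self) -> float:
        return fraction_to_absolute(self.wo, self.state.conditions)


def predict_no_hme(params: RigParameters, V_insp: float) -> Prediction:
    """Expected rig measurements without an HME in place.

    With m_st = 0 the closure is explicit: V_mb = V_insp, the moisture
    benefit is the dead-space contribution mixed into the inspirate,
    and the expired volume always exceeds V_mb because the humidifier
    tops the gas up to ha.
    """
    if not V_insp > 0:
        raise DomainError("V_insp must be > 0")
    state = _state_from_c(params, params.hb, V_insp)
    return Prediction(mb=state.mb, wo=state.wo, V_mb=state.V_mb, V_exp=state.V_exp, state=state)


def predict_with_hme(
    params: RigParameters, V_insp: float, behavior: HMEBehavior
) -> MassBalanceState:
    """Predict the steady-state breath with an HME obeying ``behavior``.

    The storage rule couples to the water load, which itself depends on
    the HME exit humidity, so the closure is solved with the same
    damped fixed point as :func:`evaluate_from_wo`.
    """
    if not V_insp > 0:
        raise DomainError("V_insp must be > 0")
    ha, hb, vd = params.ha, params.hb, params.dead_space
    m_i_ent = hb * V_insp
    mg_per_mol = MOLAR_MASS_WATER * 1e3

    c = ha  # deterministic initialisation
    residual = math.inf
    for _ in range(_FP_MAX_ITER):
        V_mb = V_insp * (1.0 - hb) / (1.0 - c)
        mb = (ha * vd + c * (V_mb - vd)) / V_mb
        V_sup = V_mb * (1.0 - mb) / (1.0 - ha)
        m_e_ent = c * vd + ha * (V_sup - vd)
        load = m_e_ent - m_i_ent
        if load < 0:
            raise DomainError("negative net water load; check ha > hb")
        m_st = behavior.steady_storage(load * mg_per_mol) / mg_per_mol
        if m_st > load * (1.0 + 1e-9):
            raise InfeasibleBehaviorError(
                "storage rule implies m_st greater than the net water load "
                "(efficiency above 1)"
            )
        c_new = hb + m_st * (1.0 - hb) / V_mb
        residual = abs(c_new - c)
        if residual <= _FP_TOL:
            c = c_new
            break
        c = c + _FP_DAMPING * (c_new - c)
    else:
        raise ConvergenceError(
            f"prediction closure did not converge after {_FP_MAX_ITER} "
            f"iterations (residual {residual:.3e} on c_ext)"
        )
    return _state_from_c(params, c, V_insp * (1.0 - hb) / (1.0 - c))


# ---------------------------------------------------------------------------
# Metrics and checks
# ---------------------------------------------------------------------------


def efficiency(state: MassBalanceState) -> float:
    """HME efficiency eta = m_st / (m_e_ent - m_i_ent)."""
    denom = state.m_e_ent - state.m_i_ent
    if denom <= 0:
        raise EfficiencyUndefinedError(
            f"net water entering the HME is {denom:.4g} mmol; efficiency undefined"
        )
    return state.m_st / denom


@dataclass(frozen=True)
class WaterLoadApprox:
    """ha*V_mb approximation of the water load, with its error vs a state."""

    value_mmol: float
    relative_deviation: Optional[float] = None

    @property
    def value_mg(self) -> float:
        return self.value_mmol * MOLAR_MASS_WATER


def approximate_water_load(
    ha: float, V_mb: float, exact_state: Optional[MassBalanceState] = None
) -> WaterLoadApprox:
    """Approximate the expiratory water load as ha * V_mb (mmol).

    This is the practical shortcut for the exact m_e_ent; when a full
    state is supplied, the relative deviation from its m_e_ent is
    reported alongside.
    """
    if not (ha > 0 and V_mb > 0):
        if ha == 0:
            return WaterLoadApprox(0.0, None if exact_state is None else _load_dev(0.0, exact_state))
        raise DomainError("ha and V_mb must be positive")
    approx = ha * V_mb * 1e3
    dev = None if exact_state is None else _load_dev(approx, exact_state)
    return WaterLoadApprox(approx, dev)


def _load_dev(approx_mmol: float, state: MassBalanceState) -> float:
    return abs(approx_mmol - state.m_e_ent) / abs(state.m_e_ent)


@dataclass(frozen=True)
class ConsistencyReport:
    """Cross-evaluation of an overdetermined measurement set."""

    pair_labels: tuple
    states: tuple
    m_st_mmol: tuple
    max_storage_discrepancy: float  # max pairwise relative m_st spread
    max_identity_residual: float
    pairwise: dict = field(default_factory=dict)

    @property
    def consistent(self) -> bool:
        return self.max_storage_discrepancy <= 1e-8 and self.max_identity_residual <= 1e-8


def consistency_residuals(
    params: RigParameters, measurements: Iterable[BreathMeasurement]
) -> ConsistencyReport:
    """Evaluate every admissible minimal pair and compare their m_st.

    Needs an overdetermined set: at least three measured quantities
    spanning at least two positions, giving two or more admissible
    (concentration, volume) pairs.
    """
    ms = list(measurements)
    n_quantities = sum(1 + (m.concentration is not None) for m in ms)
    locations = {m.location for m in ms}
    concs = [m for m in ms if m.concentration is not None and m.location != Location.P1_INSPIRED]
    pairs = [(c, v) for c in concs for v in ms]
    if n_quantities < 3 or len(locations) < 2 or len(pairs) < 2:
        raise UsageError(
            "consistency check needs >= 3 measured quantities spanning >= 2 "
            "locations (>= 2 admissible concentration/volume pairs)"
        )
    labels, states = [], []
    for c, v in pairs:
        labels.append(f"{'mb' if c.location == Location.P2_MOISTURE_BENEFIT else 'wo'}"
                      f"@{c.location.value}+V@{v.location.value}")
        states.append(evaluate(params, c, v))
    m_sts = [s.m_st for s in states]
    scale = max(max(abs(m) for m in m_sts), 1e-300)
    pairwise = {}
    worst = 0.0
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            d = abs(m_sts[i] - m_sts[j]) / scale
            pairwise[(labels[i], labels[j])] = d
            worst = max(worst, d)
    ident = max(max(s.identity_residuals().values()) for s in states)
    return ConsistencyReport(
        pair_labels=tuple(labels),
        states=tuple(states),
        m_st_mmol=tuple(m_sts),
        max_storage_discrepancy=worst,
        max_identity_residual=ident,
        pairwise=pairwise,
    )


@dataclass(frozen=True)
class PublishedPerformance:
    """Performance recomputed from literature-style mb + V_mb values."""

    performance_mg_per_breath: float
    efficiency_percent: float
    state: MassBalanceState


def performance_from_published(
    mb_mg_l: float, V_mb_litre: float, params: RigParameters
) -> PublishedPerformance:
    """Recompute HME performance from published mb (mg/l) and V_mb (l).

    Convenience wrapper for literature values reported in laboratory
    units (e.g. LE-HME moisture-output tables): converts at the rig
    conditions, runs the moisture-benefit evaluation and reports the
    stored mass in mg per breath and the efficiency in percent.
    """
    mb = absolute_to_fraction(mb_mg_l, params.conditions)
    v_mb = volume_to_moles(V_mb_litre, params.conditions)
    state = evaluate_from_mb(params, mb, v_mb)
    denom = state.m_e_ent - state.m_i_ent
    eta_pct = 100.0 * state.m_st / denom if denom > 0 else math.nan
    return PublishedPerformance(
        performance_mg_per_breath=state.performance_mg,
        efficiency_percent=eta_pct,
        state=state,
    )
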