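"""Discrete parcel-based plug-flow simulation of the HME test rig.

The rig is driven by a sinusoidal volume generator (default 15
breaths/min, I:E 1:1).  Each time step moves one gas parcel (a volume
slug with a single water fraction) along the line

    P1 -- HME -- dead-space FIFO -- P2/P3 -- humidifier

Inspiration: carrier gas at ``hb`` enters the HME, which releases the
water it stored during the previous expiration in proportion to the
dry-gas flow (so the HME exit humidity is constant over the
inspiration, the plug-flow reading of reversible storage); the exit
parcels push the dead-space content past the P2 sensor into the
humidifier.  Expiration: the humidifier emits gas at the target
fraction ``ha`` (volume expanded accordingly), the dead-space residue
and then ha-gas enter the HME, which absorbs water according to its
:class:`~hmecalc.mass_balance.HMEBehavior` rule.

The dead space is a strict FIFO of fixed molar capacity with
fractional-parcel splitting at its boundary; transport is therefore
exact, and the simulator's per-breath molar ledger closes to machine
precision.  Discretization error appears only in the *recorded
traces*: like a real ADC, each sample holds the instantaneous flow
and the humidity of the parcel at the sensor at the sample instant,
so per-breath integrals recovered from the traces approach the
analytic closure at first order in dt (the humidity step at the
dead-space boundary falls between two samples).

Zero-flow instants (the valve switch) transport nothing by
construction, since parcel sizes are exact integrals of the flow over
each step.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .breaths import BreathTrace, write_trace_csv
from .mass_balance import (
    HMEBehavior,
    InfeasibleBehaviorError,
    RigParameters,
    UsageError,
)
from .psychrometry import (
    MOLAR_MASS_WATER,
    DomainError,
    GasConditions,
    fraction_to_absolute,
    moles_to_volume,
    volume_to_moles,
)

__all__ = [
    "FlowProfile",
    "NoiseSpec",
    "BreathLedger",
    "SimResult",
    "ResolutionError",
    "simulate_rig",
    "steady_state_reached",
    "generate_fixture",
]

#: Default physics step, s (well below the 30 ml dead-space transit).
DEFAULT_DT = 0.01
#: Default recorded sample rate for fixtures, Hz (the rig's ADC rate).
FIXTURE_SAMPLE_RATE = 10.0
#: Breaths simulated by default; periodic steady state is typically
#: reached within ten breaths for every supported storage rule.
DEFAULT_N_BREATHS = 20


class ResolutionError(ValueError):
    """Time step too coarse to resolve the dead-space transit."""


@dataclass(frozen=True)
class FlowProfile:
    """Sinusoidal breathing pattern of the volume generator."""

    tidal_volume: float  # litres inspired per breath, measured at P1
    breaths_per_minute: float = 15.0
    ie_ratio: float = 1.0  # inspiration : expiration duration

    def __post_init__(self) -> None:
        if not (0.0 < self.tidal_volume <= 2.0):
            raise DomainError(f"tidal volume must lie in (0, 2] l, got {self.tidal_volume}")
        if not self.breaths_per_minute > 0:
            raise DomainError("breathing rate must be positive")
        if not self.ie_ratio > 0:
            raise DomainError("I:E ratio must be positive")

    @property
    def period(self) -> float:
        return 60.0 / self.breaths_per_minute

    @property
    def t_insp(self) -> float:
        return self.period * self.ie_ratio / (1.0 + self.ie_ratio)

    @property
    def t_exp(self) -> float:
        return self.period - self.t_insp

    @property
    def peak_flow_l_s(self) -> float:
        """Peak inspiratory volumetric flow of the half-sine, l/s."""
        return self.tidal_volume * math.pi / (2.0 * self.t_insp)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian sensor noise, applied after the physics."""

    humidity_mg_l: float = 0.0
    flow_l_min: float = 0.0


@dataclass
class BreathLedger:
    """Exact molar bookkeeping of one simulated breath (ground truth).

    Water amounts in mol, gas amounts in mol; concentrations are
    derived ratios.  ``m_st`` is the mass stored during this breath's
    expiration; ``released`` is the mass returned during its
    inspiration (the previous expiration's store).
    """

    breath_index: int
    V_insp: float = 0.0
    m_i_ent: float = 0.0
    m_i_ext: float = 0.0
    V_mb: float = 0.0
    m_ret: float = 0.0
    V_sup: float = 0.0
    m_sup: float = 0.0
    m_e_ent: float = 0.0
    V_into_hme_exp: float = 0.0
    V_exp: float = 0.0
    m_e_ext: float = 0.0
    m_st: float = 0.0
    released: float = 0.0
    store_start: float = 0.0  # HME store at breath start, mol
    store_end: float = 0.0
    ds_water_start: float = 0.0  # dead-space water content at breath start, mol
    ds_water_end: float = 0.0

    @property
    def mb(self) -> float:
        return self.m_ret / self.V_mb

    @property
    def wo(self) -> float:
        return self.m_e_ext / self.V_exp

    @property
    def eta(self) -> float:
        denom = self.m_e_ent - self.m_i_ent
        return self.m_st / denom if denom > 0 else math.nan

    def closure_residual(self) -> float:
        """Relative water-ledger imbalance of this breath.

        imported = stored-in-HME + retained-in-dead-space + exported,
        where imports are P1 inflow plus humidifier supply and exports
        are the P2 return flow plus the P4 outflow.
        """
        imported = self.m_i_ent + self.m_sup + self.released
        exported = self.m_ret + self.m_e_ext + self.m_st
        d_ds = self.ds_water_end - self.ds_water_start
        return abs(imported - exported - d_ds) / max(imported, 1e-300)


@dataclass
class SimResult:
    """Traces, per-breath ground truth and convergence info of one run."""

    p2: BreathTrace
    p4: BreathTrace
    breaths: List[BreathLedger]
    steady_state_breath_index: Optional[int]
    params: RigParameters
    behavior: Optional[HMEBehavior]
    profile: FlowProfile
    dt: float

    def steady_breaths(self) -> List[BreathLedger]:
        if self.steady_state_breath_index is None:
            return []
        return self.breaths[self.steady_state_breath_index :]

    def steady_ledger(self) -> BreathLedger:
        """The last breath: deepest into the periodic steady state."""
        return self.breaths[-1]


class _DeadSpace:
    """Bidirectional FIFO of gas parcels with fixed molar capacity."""

    __slots__ = ("parcels",)

    def __init__(self, capacity: float, fraction: float) -> None:
        # left end faces the HME, right end faces the humidifier
        self.parcels: deque = deque()
        if capacity > 0:
            self.parcels.append([capacity, fraction])

    def push_hme_side(self, moles: float, fraction: float) -> Tuple[float, float, float]:
        """Inspiration: gas in at the HME end, out at the humidifier end."""
        return self._push(moles, fraction, left=True)

    def push_humidifier_side(self, moles: float, fraction: float) -> Tuple[float, float, float]:
        """Expiration: gas in at the humidifier end, out at the HME end."""
        return self._push(moles, fraction, left=False)

    def water_content(self) -> float:
        return sum(m * c for m, c in self.parcels)

    def _push(self, moles: float, fraction: float, left: bool) -> Tuple[float, float, float]:
        """Returns (moles out, water out, concentration of the last bit out)."""
        if moles <= 0:
            return 0.0, 0.0, fraction
        if not self.parcels:  # zero-capacity dead space: pass through
            return moles, moles * fraction, fraction
        if left:
            self.parcels.appendleft([moles, fraction])
        else:
            self.parcels.append([moles, fraction])
        need = moles
        out_m = 0.0
        out_w = 0.0
        c_last = fraction
        while need > 0 and self.parcels:
            parcel = self.parcels[-1] if left else self.parcels[0]
            m, c = parcel
            c_last = c
            if m <= need * (1.0 + 1e-15):
                # take the whole parcel
                out_m += m
                out_w += m * c
                need -= m
                (self.parcels.pop if left else self.parcels.popleft)()
            else:
                # split: take exactly what is needed
                out_m += need
                out_w += need * c
                parcel[0] = m - need
                need = 0.0
        return out_m, out_w, c_last


def _phase_fractions(n_steps: int) -> np.ndarray:
    """Exact per-step volume fractions of a half-sine flow phase."""
    k = np.arange(n_steps + 1)
    c = np.cos(math.pi * k / n_steps)
    return (c[:-1] - c[1:]) / 2.0


def simulate_rig(
    params: RigParameters,
    behavior: Optional[HMEBehavior],
    profile: FlowProfile,
    n_breaths: int = DEFAULT_N_BREATHS,
    dt: float = DEFAULT_DT,
    seed: Optional[int] = None,
    noise: Optional[NoiseSpec] = None,
) -> SimResult:
    """Advance the rig breath by breath and record traces plus ledger.

    With ``noise`` unset (or zero) and a fixed seed the output is
    bit-reproducible.  Noise, when requested, is additive Gaussian on
    the recorded traces only; the ledger stays exact.
    """
    if n_breaths < 5:
        raise UsageError("need at least 5 breaths to assess steady state")
    if behavior is not None and behavior.behavior_class == "linear" and behavior.eta0 > 1.0:
        raise InfeasibleBehaviorError("base efficiency above 1")
    cond = params.conditions
    vd_l = moles_to_volume(params.dead_space, cond)
    if params.dead_space > 0 and profile.peak_flow_l_s * dt > vd_l:
        raise ResolutionError(
            f"dt = {dt} s moves up to {profile.peak_flow_l_s * dt * 1e3:.1f} ml "
            f"per step, more than the {vd_l * 1e3:.1f} ml dead space"
        )

    ha, hb = params.ha, params.hb
    n_i = max(1, round(profile.t_insp / dt))
    n_e = max(1, round(profile.t_exp / dt))
    dt_i = profile.t_insp / n_i
    dt_e = profile.t_exp / n_e
    frac_i = _phase_fractions(n_i)
    frac_e = _phase_fractions(n_e)

    dn_insp_total = volume_to_moles(profile.tidal_volume, cond)  # moles at hb
    dn_dry_total = dn_insp_total * (1.0 - hb)
    # instantaneous |sine| flow at sample (= step end) times
    sin_i = np.sin(math.pi * (np.arange(n_i) + 1) / n_i)
    sin_e = np.sin(math.pi * (np.arange(n_e) + 1) / n_e)
    rate_i_l_s = profile.tidal_volume * math.pi / (2.0 * profile.t_insp)  # peak at P1
    cap_mol = math.inf
    if behavior is not None and math.isfinite(behavior.capacity):
        cap_mol = behavior.capacity / (MOLAR_MASS_WATER * 1e3)

    ds = _DeadSpace(params.dead_space, ha)
    store = 0.0  # mol water held by the HME
    release_pool = 0.0  # previous expiration's store, returned this inspiration
    h2_last = fraction_to_absolute(ha, cond)
    h4_last = fraction_to_absolute(ha, cond)
    mg_per_mol = MOLAR_MASS_WATER * 1e3

    n_steps = n_breaths * (n_i + n_e)
    t_arr = np.empty(n_steps)
    q2 = np.zeros(n_steps)
    h2 = np.empty(n_steps)
    q4 = np.zeros(n_steps)
    h4 = np.empty(n_steps)

    ledgers: List[BreathLedger] = []
    t = 0.0
    s = 0
    for b in range(n_breaths):
        led = BreathLedger(
            breath_index=b,
            store_start=store,
            ds_water_start=ds.water_content(),
        )
        # ---- inspiration -------------------------------------------------
        release_pool = store
        released = 0.0
        # moles at P2 per mole inspired (constant over the inspiration)
        p2_ratio = 1.0 + release_pool * (1.0 - hb) / dn_dry_total
        for k in range(n_i):
            dn = dn_insp_total * frac_i[k]
            dn_dry = dn * (1.0 - hb)
            w_in = dn * hb
            r = release_pool * dn_dry / dn_dry_total
            released += r
            store -= r
            m_out = dn + r
            w_out = w_in + r
            out_m, out_w, c_last = ds.push_hme_side(m_out, w_out / m_out)
            led.V_insp += dn
            led.m_i_ent += w_in
            led.m_i_ext += w_out
            led.V_mb += out_m
            led.m_ret += out_w
            t += dt_i
            t_arr[s] = t
            if out_m > 0:
                q2[s] = rate_i_l_s * sin_i[k] * p2_ratio * 60.0
                h2_last = fraction_to_absolute(c_last, cond)
            h2[s] = h2_last
            h4[s] = h4_last
            s += 1
        led.released = released
        # ---- expiration --------------------------------------------------
        # The humidifier is a closed reservoir: it can only return the dry
        # gas it received through P2 during this breath's inspiration
        # (humidified up to ha), so the expiratory drive is that dry amount.
        dn_dry_exp_total = led.V_mb - led.m_ret
        stored_this_exp = 0.0
        hb_dry_ratio = hb / (1.0 - hb)
        exp_rate_mol_s = dn_dry_exp_total * math.pi / (2.0 * profile.t_exp)  # peak dry
        for k in range(n_e):
            dn_dry = dn_dry_exp_total * frac_e[k]
            m_sup = dn_dry / (1.0 - ha)
            w_sup = m_sup * ha
            in_m, in_w, c_last = ds.push_humidifier_side(m_sup, ha)
            # HME absorption
            dry_p = in_m - in_w
            w_net = in_w - dry_p * hb_dry_ratio
            f = behavior.absorbed_fraction(store * mg_per_mol) if behavior else 0.0
            absorb = max(0.0, min(f * w_net, in_w, cap_mol - store))
            store += absorb
            stored_this_exp += absorb
            out_m = in_m - absorb
            out_w = in_w - absorb
            led.V_sup += m_sup
            led.m_sup += w_sup
            led.m_e_ent += in_w
            led.V_into_hme_exp += in_m
            led.V_exp += out_m
            led.m_e_ext += out_w
            t += dt_e
            t_arr[s] = t
            if out_m > 0:
                q4[s] = moles_to_volume(exp_rate_mol_s * sin_e[k] * out_m / dn_dry, cond) * 60.0
                # humidity of the last parcel bit after its HME passage
                f_eff = absorb / w_net if w_net > 1e-300 else 0.0
                wn_l = c_last - (1.0 - c_last) * hb_dry_ratio
                h4_last = fraction_to_absolute(
                    (c_last - f_eff * wn_l) / (1.0 - f_eff * wn_l), cond
                )
            h2[s] = h2_last
            h4[s] = h4_last
            s += 1
        led.m_st = stored_this_exp
        led.store_end = store
        led.ds_water_end = ds.water_content()
        ledgers.append(led)

    if noise is not None and (noise.humidity_mg_l > 0 or noise.flow_l_min > 0):
        rng = np.random.default_rng(seed)
        h2 = h2 + rng.normal(0.0, noise.humidity_mg_l, n_steps)
        h4 = h4 + rng.normal(0.0, noise.humidity_mg_l, n_steps)
        q2 = q2 + rng.normal(0.0, noise.flow_l_min, n_steps)
        q4 = q4 + rng.normal(0.0, noise.flow_l_min, n_steps)

    reached, first = steady_state_reached(ledgers)
    return SimResult(
        p2=BreathTrace("P2", t_arr, q2, h2, cond),
        p4=BreathTrace("P4", t_arr, q4, h4, cond),
        breaths=ledgers,
        steady_state_breath_index=first if reached else None,
        params=params,
        behavior=behavior,
        profile=profile,
        dt=dt,
    )


def steady_state_reached(
    per_breath: Sequence,
    tolerance: float = 0.005,
    window: int = 5,
) -> Tuple[bool, Optional[int]]:
    """Detect the periodic steady state in per-breath summaries.

    ``per_breath`` may be :class:`BreathLedger` objects (their mb and
    wo are tracked), plain numbers, or tuples of numbers.  Steady means
    every tracked series varies by less than ``tolerance`` (relative
    max-min) over ``window`` consecutive breaths; the first index of
    such a window is returned.
    """
    items = list(per_breath)
    if len(items) < window:
        raise UsageError(f"need at least {window} breaths, got {len(items)}")
    if hasattr(items[0], "mb") and hasattr(items[0], "wo"):
        series = np.array([[x.mb for x in items], [x.wo for x in items]])
    elif isinstance(items[0], (tuple, list)):
        series = np.array(items, dtype=float).T
    else:
        series = np.array([items], dtype=float)
    for i in range(series.shape[1] - window + 1):
        ok = True
        for row in series:
            w = row[i : i + window]
            if np.max(w) - np.min(w) > tolerance * max(abs(float(np.mean(w))), 1e-300):
                ok = False
                break
        if ok:
            return True, i
    return False, None


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------


def _profile_from_config(cfg: dict) -> FlowProfile:
    p = cfg.get("profile", {})
    return FlowProfile(
        tidal_volume=p.get("tidal_volume_l", 0.5),
        breaths_per_minute=p.get("breaths_per_minute", 15.0),
        ie_ratio=p.get("ie_ratio", 1.0),
    )


def _params_from_config(cfg: dict) -> RigParameters:
    r = cfg.get("rig", {})
    return RigParameters.from_practical(
        ha_mg_l=r.get("ha_mg_l", 44.0),
        hb_mg_l=r.get("hb_mg_l", 0.0),
        dead_space_ml=r.get("dead_space_ml", 30.0),
        temperature_c=r.get("temperature_c", 38.0),
        pressure_kpa=r.get("pressure_kpa", 101.325),
    )


def _behavior_from_config(cfg: dict) -> Optional[HMEBehavior]:
    h = cfg.get("hme")
    if not h:
        return None
    return HMEBehavior(
        behavior_class=h["class"],
        eta0=h.get("eta0", 0.0),
        capacity=h.get("capacity_mg", math.inf),
        shape=h.get("shape_mg", math.nan),
    )


def _resample(t: np.ndarray, q: np.ndarray, h: np.ndarray, block: int):
    """Subsample a native-dt trace down to the ADC sample rate.

    Samples are instantaneous readings, so the ADC keeps every
    ``block``-th sample rather than averaging.
    """
    n = (len(t) // block) * block
    return t[block - 1 : n : block], q[block - 1 : n : block], h[block - 1 : n : block]


def generate_fixture(config: dict, seed: int, out_dir) -> dict:
    """Simulate the rig and write 10 Hz trace CSVs plus a truth sidecar.

    ``config`` keys (all optional, rig defaults otherwise): ``rig``
    (ha_mg_l, hb_mg_l, dead_space_ml, temperature_c, pressure_kpa),
    ``hme`` (class, eta0, capacity_mg, shape_mg; omit for no HME),
    ``profile`` (tidal_volume_l, breaths_per_minute, ie_ratio),
    ``noise`` (humidity_mg_l, flow_l_min), ``n_breaths``, ``dt``,
    ``sample_rate_hz``.

    Writes ``p2.csv``, ``p4.csv`` (columns time_s, flow_l_min,
    humidity_mg_l) and ``truth.json`` with the exact per-breath ledger.
    The same (config, seed) always produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = _params_from_config(config)
    profile = _profile_from_config(config)
    behavior = _behavior_from_config(config)
    ncfg = config.get("noise", {})
    noise = NoiseSpec(
        humidity_mg_l=ncfg.get("humidity_mg_l", 0.0),
        flow_l_min=ncfg.get("flow_l_min", 0.0),
    )
    dt = config.get("dt", DEFAULT_DT)
    rate = config.get("sample_rate_hz", FIXTURE_SAMPLE_RATE)
    n_breaths = config.get("n_breaths", DEFAULT_N_BREATHS)

    # noiseless physics at native dt; ADC resampling and sensor noise after
    res = simulate_rig(params, behavior, profile, n_breaths=n_breaths, dt=dt)
    block = max(1, round(1.0 / (rate * dt)))
    rng = np.random.default_rng(seed)
    paths = {}
    for name, tr in (("p2", res.p2), ("p4", res.p4)):
        t_s, q_s, h_s = _resample(tr.time, tr.flow, tr.humidity, block)
        if noise.humidity_mg_l > 0:
            h_s = h_s + rng.normal(0.0, noise.humidity_mg_l, len(h_s))
        if noise.flow_l_min > 0:
            q_s = q_s + rng.normal(0.0, noise.flow_l_min, len(q_s))
        trace = BreathTrace(tr.position, t_s, q_s, h_s, tr.conditions)
        path = out / f"{name}.csv"
        write_trace_csv(trace, path)
        paths[name] = path

    cond = params.conditions
    truth = {
        "seed": seed,
        "config": _jsonable(config),
        "steady_state_breath_index": res.steady_state_breath_index,
        "breaths": [
            {
                "breath_index": led.breath_index,
                "V_insp_l": moles_to_volume(led.V_insp, cond),
                "V_mb_l": moles_to_volume(led.V_mb, cond),
                "V_exp_l": moles_to_volume(led.V_exp, cond),
                "mb_mg_l": fraction_to_absolute(led.mb, cond),
                "wo_mg_l": fraction_to_absolute(led.wo, cond),
                "m_st_mg": led.m_st * MOLAR_MASS_WATER * 1e3,
                "eta": led.eta,
            }
            for led in res.breaths
        ],
    }
    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, allow_nan=True)
        fh.write("\n")
    paths["truth"] = truth_path
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    return obj
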