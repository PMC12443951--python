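# Methods

## Scope and model

`hmecalc` computes the humidification performance of heat-and-moisture
exchangers (HMEs) from bench measurements on a standard test rig, and
predicts rig measurements from assumed HME behaviour.  The rig is
modelled as a one-dimensional chain

    P1 — HME — dead space (V_D) — P2/P3 — humidifier

with three assumptions:

1. **Plug flow** — gas parcels traverse the chain without axial mixing;
   the dead space acts as a first-in-first-out buffer of fixed molar
   content.
2. **Periodic steady state** — every breath repeats exactly; the HME
   returns during inspiration exactly what it stored during the
   preceding expiration (reversible storage).
3. **Ideal gas** — all amounts are molar; absolute humidities (mg/l)
   and volumes (l) are converted at a stated temperature and pressure.

Water masses are tracked in mol internally and reported in mmol and mg
(`M_w` = 18.015 g/mol); gas amounts in mol; humidities as molar
fractions.

## The closure

Let `ha` be the humidifier target fraction, `hb` the inspired-gas
fraction, `c_ext` the (constant) fraction of gas leaving the HME during
inspiration.  At the start of inspiration the dead space holds gas at
`ha`; the first `V_D` moles passing P2 are therefore that residue:

    mb·V_mb = ha·V_D + c_ext·(V_mb − V_D)

Combining with dry-gas conservation through the HME during inspiration
(`V_insp(1−hb) = V_mb(1−c_ext)`) gives the stored mass

    m_st = V_mb (c_ext − hb) / (1 − hb)
         = { [ (mb·V_mb − ha·V_D) / (1 − V_D/V_mb) ] − hb·V_mb } / (1 − hb)

The rest of the state closes by dry-gas conservation through the
humidifier over a cycle (`V_sup(1−ha) = V_mb(1−mb)`), the dead-space
slug entering the HME during expiration
(`m_e_ent = c_ext·V_D + ha·(V_sup − V_D)`), and
`V_exp = V_sup − m_st` (the moles the HME removes are water).  These
relations are algebraically exact: every returned state satisfies the
four mass identities

    m_i_ext = m_i_ent + m_st        m_e_ext = m_e_ent − m_st
    m_add   = m_e_ext − m_i_ent     m_add   = m_sup − m_ret

and inspired/expired dry-gas equality, to floating-point precision
(tests assert ≤ 1e-10 relative).

**Evaluation routes.** From (`mb`, `V_mb`) the closure is explicit.
From (`wo`, `V_exp`) the residue fraction `c_ext` appears on both sides
and is solved by a damped fixed point (damping 0.5, max 200 iterations,
absolute tolerance 1e-12 on molar fractions, deterministic start at
`c_ext = ha`); non-convergence raises with the residual.  The four
cross-location combinations are closed-form: a volume measured at P1
propagates by dry-gas conservation (linear for the wo route, a
quadratic in `V_mb` for the mb route, larger root physical — the
smaller root sits just above `V_D` with an unphysical `c_ext`); a
volume at P4 with `mb` likewise yields a quadratic, and `V_mb` with
`wo` is linear in `c_ext`.  On consistent inputs all six combinations
return the same state (tested to 1e-8).

**Prediction.** Without HME, `m_st = 0` makes the closure explicit
(`V_mb = V_insp`, `mb` is the dead-space admixture, and
`V_exp > V_mb` always, since the humidifier tops the gas up to `ha`).
With HME, a storage rule couples `m_st` to the water load, and the same
damped fixed point is used.  A rule implying `m_st` above the net load
(efficiency > 1) raises an infeasibility error.

**Overdetermined sets.** With three or more measured quantities
spanning two or more positions, every admissible (concentration,
volume) pair is evaluated and the pairwise spread of `m_st` plus the
per-identity residuals are reported; noise-free consistent data give
residuals at solver precision.

## Storage rules (HME behaviour classes)

Bench data show three qualitative classes of per-breath storage versus
water load `L` (net water entering during expiration).  The package
parameterises them by an instantaneous absorbed fraction `f(S)` of the
net water in each passing parcel, where `S` is the current store:

| class | `f(S)` | steady per-breath storage |
| --- | --- | --- |
| linear | `eta0` | `m_st = eta0·L` |
| asymptotic | `eta0·exp(−S/shape)` | `m_st = shape·ln(1 + eta0·L/shape)` |
| constant | `1` until capacity | `m_st = min(L, capacity)` |

`eta0` is dimensionless in [0, 1]; `shape` and `capacity` are in mg.
The closed forms are the exact integrals of `f` over one expiration
from an empty store and are what prediction mode uses; the simulator
applies `f` parcel by parcel, so its emergent storage matches the
closed form to O(dt).  For the linear class the emergent efficiency
equals `eta0` exactly, because the absorbed amount is defined against
the same net-water baseline as the efficiency denominator.

## The plug-flow simulator

The simulator advances volume slugs through the chain at a fixed time
step (default dt = 0.01 s), with a sinusoidal drive (defaults: 15
breaths/min, I:E 1:1, tidal volume 0.2–0.8 l; parcel sizes are exact
integrals of the sine over each step, so zero-flow instants transport
nothing).  The dead space is a deque of parcels with fractional
splitting at the boundary, so transport is exact and the per-breath
molar ledger closes to ≤ 1e-9 relative.  Two modelling points matter:

- **Closed-reservoir humidifier.** During expiration the humidifier
  returns exactly the dry gas it received through P2 during that
  breath's inspiration, humidified to `ha`.  Driving the expiration
  with the full inspired dry amount instead would leak dry gas out of
  the humidifier every cycle and bias `V_exp` and `wo` by ~`ha·V_D`.
- **Instantaneous sensors.** Each recorded sample holds the flow and
  the humidity of the parcel at the sensor *at the sample instant*,
  like a fast sensor behind an ADC.  Trace-derived per-breath integrals
  therefore differ from the exact ledger at first order in the sample
  interval, dominated by the humidity step where the dead-space residue
  boundary passes the sensor between two samples.  Tests verify the
  grid-mean gap halves when dt halves; the per-cell ratio fluctuates
  around 2 because the step's phase within the sampling grid moves
  non-monotonically with dt.

Sensor noise is additive Gaussian on humidity (mg/l) and flow (l/min),
applied to the recorded samples after the physics with a seeded
generator; the ledger stays exact.  Fixture generation resamples the
native-dt record to 10 Hz by keeping every k-th instantaneous sample
and writes CSVs (`time_s, flow_l_min, humidity_mg_l`) plus a
ground-truth JSON sidecar; identical (config, seed) gives byte-identical
files.  The simulator reaches its periodic steady state within about
ten breaths for all three storage classes (detected as < 0.5% relative
variation of mb and wo over five consecutive breaths).

What the generator does **not** emulate: turbulent mixing and axial
diffusion, sensor response time and drift, valve leakage, thermal
gradients.  Passing tests therefore demonstrate correctness of the
mass-balance algebra and of the processing chain under plug-flow
conditions, not robustness to those real-rig effects (the bench
literature reports a few-percent scatter attributable to them).

## Trace processing

Breaths are detected on |flow| with hysteresis (enter at 0.5 l/min,
leave at half that), bridging sub-threshold dropouts shorter than
0.3 s and discarding bursts shorter than 0.5 s or touching the record
edges.  Each detected burst is then widened to the foot of its flow
ramp (first sample at ≤ 5% of the threshold, never past the midpoint
of the gap to a neighbouring burst): the threshold only locates
breaths, and truncating at it would systematically clip the low-flow
edges of every breath.

Per breath, volume is the trapezoidal integral of |flow| at native
sampling, and the mean concentration is **flow-weighted**,
∫c·|q|dt / ∫|q|dt — the target quantity is transported water per
transported volume, and samples taken while no gas moves carry no
mass.  (Time-weighted averaging would mix in the stagnant-gas readings
between breaths.)  Steady-state selection averages the tail of the
per-breath series from the first window (default 5 breaths) whose
relative spread is below tolerance.  The default tolerance of 0.5% is
a drift detector for noiseless records; with noisy sensors the caller
should set it above the noise floor (e.g. 2% for 0.3 mg/l humidity
noise, which alone produces 0.5–0.7% window spread) — warm-up
transients are an order of magnitude larger and remain excluded.

## Defaults and units

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| temperature | 38 | °C | cabinet temperature of the rig; also the assumed reference of interface mg/l values |
| pressure | 101.325 | kPa | standard atmosphere |
| target humidity `ha` | 44 | mg/l | saturation near 37 °C (the other bench level is 37 mg/l ≈ 34 °C saturation) |
| carrier humidity `hb` | 0 | mg/l | dry central gas supply (10 mg/l emulates ambient air for stoma HMEs) |
| dead space `V_D` | 30 | ml | rig tubing/connector volume; a warning (not an error) fires when `V_D` exceeds 20% of the inspired amount |
| breathing rate / I:E | 15 / 1:1 | min⁻¹ | bench protocol |
| tidal volume | 0.2–0.8 | l | bench protocol range |
| simulator dt | 0.01 | s | resolves the 30 ml dead space (≥ ~75 parcels per transit at 0.5 l); a resolution error fires when one step moves more than `V_D` |
| ADC rate | 10 | Hz | rig data-acquisition rate |
| hysteresis threshold | 0.5 | l/min | breath detection |
| fixed-point settings | 0.5 / 200 / 1e-12 | — | damping, max iterations, residual tolerance |

Saturation vapour pressure uses the Magnus form
`e_s = 610.94·exp(17.625·t/(t + 243.04))` Pa (t in °C,
Alduchov–Eskridge coefficients), accepted over 253–373 K.  This gives
6.27 kPa at 37 °C, i.e. saturated absolute humidities of 43.81 mg/l at
37 °C and 37.48 mg/l at 34 °C, consistent with the humidifier output
windows the rig specification quotes (43.7–44.2 and 37.0–37.5 mg/l).

## Numerical and design choices

- The mg/l reference state is taken to be the cabinet (38 °C, 1 atm)
  unless the caller supplies conditions; the alternative (sensor
  temperature) is exposed through `GasConditions` everywhere.
- Supersaturated humidity inputs warn and proceed (sensor noise can
  exceed saturation); negative computed `m_st` warns ("net-absorbing
  interval") and is returned unclamped, so noisy data are not silently
  biased.
- Zero-flow ties in the simulator resolve to "no transport"; in
  segmentation, zero-flow gaps belong to no breath.
- The water-load shortcut `ha·V_mb` is provided as an explicit
  approximation object that reports its own relative deviation from
  the exact `m_e_ent` (< 10% across the bench grid).
- Problem sizes in the test suite: the simulator grid runs 3
  efficiencies × 3 tidal volumes × 2 target humidities at dt = 0.01 s
  for 14 breaths per cell, and the noisy end-to-end check uses 20 noise
  seeds at 0.5 l; these sizes give stable statistics while keeping the
  suite fast.

## Known limitations

- Plug flow only; the scatter seen on real rigs from turbulence and
  mixing is outside the model.
- Heat balance is not modelled — humidity only.
- Clinical selection criteria (dead-space penalty, flow resistance,
  filtration, cost) are out of scope.
- The dead space is lumped on the humidifier side of the measurement
  tee; rigs whose valve geometry splits it asymmetrically will show
  small systematic deviations.
- Published-literature recomputations inherit the stated rig
  parameters; if a source does not state tidal volume or dead space,
  those must be assumed.
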