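# Methods

## Scope and conventions

`ceflux` analyses continuous ethanol/carboxylate chain-elongation reactors
operated as retentostats: constant working volume V (default 1 L), biomass
retained on a carrier, liquid leaving by overflow so Q_out = Q_feed +
Q_base. The canonical concentration unit is mCmol/L; mg/L, g/L, mmol/L and
mol/L are converted on input through the compound registry (standard atomic
masses; molar masses validated against atom counts to 0.01 g/mol). Acids
are balanced in undissociated form; pH chemistry enters only through the
base-dosing flow, keeping elemental balances charge-free.

Gas volumes are "normal" millilitres. The reference state is configurable
and defaults to 273.15 K / 101.325 kPa (22.414 NmL/mmol), the common
convention when a normal state is left unspecified; this is flagged here
because reported NmL figures are only interpretable once that convention is
fixed.

## Electron accounting

One electron unit is used everywhere: electron equivalents per mol, γ·n_C,
with γ = (4n_C + n_H − 2n_O − 3n_N)/n_C the generalized degree of reduction
per Cmol (CO2/H2O/NH3 references). H2 carries 2 electron equivalents per
mol — its combustion electron content on the same scale — and CO2, N2, H2O
carry none. The anchor identity is the hydrogenogenic ethanol oxidation
EtOH + H2O → acetate + 2 H2, which is exactly electron-neutral under this
convention (12 = 8 + 2·2); a test asserts it, and every reaction in the
simulator's set is checked for elemental and electron closure.

Biomass, when enabled, is CH1.8O0.5N0.2 (γ = 4.2, configurable). Default
balances exclude biomass and yeast-extract carbon: neither is tracked by
broth GC measurements, so including a modeled sink would fabricate closure.
Consequently a real dataset with growth is expected to close a few percent
below 100; the simulator, which has no biomass sink, closes at 100 exactly.

## Rates

Per sampling interval [t₀, t₁]:

    r_i = (C̄_i·Q̄_out − C_feed,i·Q̄_feed)/V + (C_i(t₁) − C_i(t₀))/(t₁ − t₀)

with trapezoidal (interval-mean) concentrations and flows. The interval-mean
form is second-order accurate in the sampling step; using the right-endpoint
concentration instead is first-order and visibly biases rates during
transients at practical sampling cadence, which is why the mean is the
default. The accumulation term is kept because these reactors are often not
at steady state; a flag provides the pure flow-through estimate. Records
attach to the interval's right endpoint.

CO2 is tracked as dosed gas in, off-gas out (measured outflow × headspace
mole fraction), and dissolved effluent carbon DIC·Q_out/V with DIC =
K_H·pCO2·(1 + K_a1/[H⁺]). Defaults K_H = 0.026 mol/L/atm and pK_a1 = 6.31
are apparent constants at the 35 °C operating temperature; both are
configurable, and speciation can be disabled to count only free CO2(aq),
since whether reported dissolved-CO2 figures include bicarbonate is usually
ambiguous. CO2 utilization is defined as in − out_gas − out_dissolved, an
identity of the record by construction; negative values mean net CO2
production. H2 export is flow × fraction × 1440/V_m/V in mmol/L/d.

## EEO and step counting

EEO% = 100·(E_cons − S − E_red − S/5)/E_cons on a molar ethanol basis (the
ratio is identical in Cmol since every term is ethanol). The full
allocation {elongation, expected oxidation, reduction exchange, excess} is
reported and sums to total consumption. E_cons ≤ 0 makes the statistic
undefined; `None` is returned rather than a sign-flipped number.

The elongation step count S is not identifiable from net rates alone, so
the rule is a strategy:

- `acceptor_routing` (default): one 2-carbon elongation consuming one
  ethanol per step; net-consumed lower acids route to the next chain length
  up at 1 step/mol before residual production is charged from acetate
  (C6-from-C2 = 2 steps, C8 analogously; odd chains base on propionate).
  Alcohols fold into their precursor acid for step accounting and book one
  ethanol each under reduction (carboxyl–hydroxyl exchange), which also
  credits the co-produced acetate.
- `from_acetate`: every product charged its full from-acetate step count,
  ignoring acceptor routing.

Branched acids count as isomerization (0 steps) by default — treating i-C4
as an elongation product instead would require evidence the community built
it from C2 rather than rearranging n-C4. Routing mis-attributes steps when
net butyrate consumption is actually isomerization or hydrogenotrophic
reduction (H2RED4); the shipped scenarios keep those fluxes at or near zero
so the ground-truth comparison stays interpretable, and H2RED4 is off in
all presets.

## Steady-state rule

A window qualifies when it spans ≥ `window_span` HRTs (default 3), holds
≥ 3 samples, and every tracked compound's coefficient of variation over the
window is ≤ `max_cv` (default 0.10; tracked defaults to caproate, butyrate,
acetate, ethanol, hexanol, butanol). Qualifying windows merge only when
they share a sample, so two stable plateaus separated by a jump remain
separate intervals. The CV rule is scale-invariant, and tightening `max_cv`
can only shrink the steady set. The criterion is deliberately configurable:
published steady-state definitions for such reactors vary, and the defaults
are a conservative, unit-free choice.

## Simulator

Liquid species follow dC_i/dt = (Q_feed·C_feed,i − Q_out·C_i)/V +
n_C,i·Σ_j S_ij·r_j(t), integrated with LSODA at rtol 1e-9. Reaction rates
r_j(t) are prescribed per scenario (constants or logistic ingrowth curves)
rather than emerging from growth kinetics: no kinetic parameters exist for
these communities, and prescribed extents make the ground truth exact,
which is the point of the simulator. Ground truth per sampling interval is
the time-averaged rate vector, the net species rates S·r̄ (exact by
construction), tagged EEO components, and true selectivities.

Gas phase: quasi-steady headspace (days-scale sampling ≫ gas residence
time), off-gas = dosed + net production. The gaseous/dissolved CO2 split is
solved self-consistently (u + DIC(u/(u+g))·Q_out/V = supply, monotone in u,
Brent's method) with the same equilibrium model the analysis uses, so
analysis-side dissolved-CO2 estimates are consistent with the simulated
truth. CO2 demand beyond supply clamps off-gas at zero and flags an
underpressure event; net H2 consumption beyond production aborts as
infeasible (H2 is never dosed — an intentional limitation). H2 solubility
in the liquid is neglected (sparingly soluble).

Base dosing is proportional to net acid production, Q_base =
gain·r_acid·V/molarity (gain 1.0, KOH molarity 2.0 by default), mimicking
pH-stat lye demand and its feedback on HRT.

Measurement noise is multiplicative Gaussian, truncated at zero, applied to
broth concentrations, headspace fractions (renormalized if the sum exceeds
1) and off-gas flow; deterministic under a fixed seed. It emulates GC and
flow-meter scatter only — no drift, no autocorrelated bias, no detection
limits, no sampling-time jitter. Recovery tests passing under this model
therefore demonstrate correctness of the stoichiometric pipeline, not
robustness to every failure mode of real instrumentation.

### Scenario presets

Study conditions: feed 600 mMC n-butyrate + 50 mMC acetate + 1200 mMC
ethanol (acetate:ethanol 1:24 Cmol) at 522 mL/d into 1 L; four CO2-dosing
regimes at 0, 2.0, 6.0 (+6.0 N2) and 0.5 NmL L⁻¹ min⁻¹; sampling three
times a week (2–2–3 day pattern). Each preset runs one regime standalone
from its algebraic steady state (the logistic-ingrowth scenario starts at
the t=0 rates):

| preset | regime | character | nominal EEO fraction |
|---|---|---|---|
| `phaseI` | no CO2 | CE-dominant, C6 ≈ 99 Cmol%, net C4 consumption, H2-rich off-gas | −0.16 |
| `phaseII` | 2.0 | logistic ingrowth of EO + homoacetogenesis, alcohol uptick | 0.10 |
| `phaseIII_R2` | 6.0 + N2 | heavy EEO, CO2 fixation, acetate spike, H2 drawn down | 0.50 |
| `phaseIV` | 0.5 | C6-dominant with alcohols ≈ 5.7 Cmol%, EEO = 0 | 0.00 |

Rate magnitudes were chosen once so that steady states are feasible
(acetate stays positive under acetate limitation, homoacetogenesis never
overdraws the H2 produced) and the headline outputs sit in the regimes the
phases are named after (e.g. `phaseIV` caproate ≈ 300 mCmol L⁻¹ d⁻¹ with
net butyrate consumption). The negative-EEO scenario includes a small
ethanol-oxidation flux below the 1-per-5 expectation, so hydrogen still
appears in its off-gas.

Problem sizes throughout (tests and the acceptance script) are single
scenarios of 23–42 simulated days with ≤ 57 samples — ample for every
statistic here, since recovery is limited by time-discretization, not
sample count.

## Known limitations

- Prescribed rates mean no feedback from concentrations to kinetics; a
  scenario can be infeasible (negative concentration) and is then rejected
  with a diagnostic instead of silently clipped.
- The quasi-steady headspace has no storage term, so rapid gas transients
  (the underpressure events proper) are flagged, not resolved.
- Step counting from net rates is an attribution model; its `strategy`
  option exists precisely because alternative published definitions of an
  "elongation event" can be slotted in.
- Dissolved CO2 assumes gas–liquid equilibrium with the measured headspace
  (no kLa); systems far from equilibrium will bias the dissolved term.
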