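# Methods

## Model and assumptions

`ureakin` implements a purely kinetic, steady-state description of an
enzyme-modified pH sensor. The enzyme layer is treated as a well-mixed
compartment exchanging every species with the bulk at first-order rates
(transport constant k_X per species) instead of resolving diffusion
profiles. The assumptions inherited by every computation are:

- steady state: all layer concentrations are time-invariant, so the
  kinetic ODEs reduce to algebraic balances (no transient modelling);
- Michaelis–Menten kinetics for the enzymatic conversion;
- dissociation constants identical in the layer and the bulk;
- equal bidirectional transport constants for all species, which makes the
  normalised constants k̄_H = k_H/k_S and k̄_W = k_W/k_S equal to 1 by
  default (both are configurable for sensitivity studies);
- layer geometry enters only through the optional conversion
  k_S = D/(l·t) used to express the fitted normalised rate k̄_V = V_max/k_S
  as an absolute V_max.

This is appropriate for thin (≲ 1 µm), homogeneous enzyme coatings where
transport across the film is fast relative to catalysis. It is *not*
appropriate for thick membranes where diffusion limits the response.

The preset product chemistry is urea hydrolysis: one carbonic
acid/bicarbonate unit (n_A = 1) and two ammonium/ammonia units (n_B = 2)
per urea. The carbonate system is treated as a single dissociation step
(H2CO3/HCO3⁻); the second deprotonation to CO3²⁻ is ~4 pH units away from
the working range and is neglected. Hydroxide produced by the hydrolysis is
not a separate balance term: water autoionisation is subsumed in the proton
balance.

## Parameters and defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| c_WB | total buffer concentration | 0.33 (PBS preset) / 2.0 (AU preset) | mM |
| pKa_W | buffer couple (H2PO4⁻/HPO4²⁻) | 7.21 | — |
| pH_B | bulk pH | 7.4 | — |
| pKa_A | acid product (H2CO3/HCO3⁻) | 6.35 | — |
| pKa_B | base product (NH4⁺/NH3) | 9.25 | — |
| k̄_H, k̄_W | normalised transport constants | 1 | — |
| D | substrate diffusion constant | 9.3×10⁻⁵ | cm²/s |
| l, t | layer length, thickness | 1, 10⁻⁷ | cm |
| K_M, k̄_V | fitted kinetic parameters | bounded to [10⁻¹⁴, 1] | mol/L |

All internal concentrations are mol/L; CSV and CLI interfaces use mM and
convert on ingest. k̄_V is dimensionally a concentration in this framework
(V_max divided by a first-order rate constant).

The dissociation constants are standard 25 °C tabulated values; the
framework requires only that each couple has a single effective constant.
The AU (artificial-urine-like) preset is an *effective-medium*
approximation: the multicomponent matrix is represented by one
phosphate-like buffer couple at an effective 2 mM — the phosphate content
of common artificial-urine recipes after tenfold dilution — with the
matrix effect on the enzyme carried by a much smaller fitted k̄_V rather
than by the buffer block.

## Numerics

**Substrate balance.** The closed-form root of the steady-state quadratic
is evaluated with the cancellation-free branch (rationalised numerator when
K_M + k̄_V > S_B), so the balance residual stays at machine precision over
the full parameter box; property tests assert < 10⁻¹⁰ relative.

**Proton balance.** The residual is strictly decreasing in H for any valid
chemistry, so its root is unique. It is bracketed by a 200-point
log-spaced scan of H over the physical window [10⁻¹⁴, 1] mol/L (pH 0–14)
and refined by Brent's method at machine relative tolerance. The scan
doubles as a guard: zero sign changes, or more than one, raise a solver
error naming the endpoint residuals instead of silently picking a root —
multiplicity would indicate a misconfigured chemistry.

**Polynomial oracle.** Multiplying the residual by
(H+Ka_W)(H+Ka_A)(H+Ka_B) yields a degree-4 polynomial whose real positive
roots (companion-matrix eigenvalues, polished by damped Newton on the
unexpanded residual) must contain the bracketed root. Clearing
denominators can introduce spurious roots at the pole locations; a root is
accepted only if the unexpanded residual there is below 10⁻⁸ of the natural
magnitude scale of its additive terms. Solver/oracle agreement to 10⁻⁸
relative is asserted on randomised chemistries.

**Fitting.** The objective Φ = Σ [log₁₀(Ha_model/Ha_obs)]² is identically
the sum of squared pH residuals (the Ha normalisation constant cancels in
the log ratio — asserted numerically). Because the parameter box spans 14
decades, optimisation runs in log₁₀ space with out-of-box excursions
clamped under a quadratic penalty. Two optimisers are provided:
Nelder–Mead restarted from a deterministic 5×5 log-grid of starting points
(best of 25 reported), and differential evolution with a fixed default
seed (population 20, up to 200 generations, local polish). On noise-free
data the two agree to well under 1%; both are exposed because local and
global searches fail differently on poor data.

**Goodness of fit.** χ² is computed in Pearson form on the pH values,
Σ (pH_obs − pH_model)²/pH_model, with an upper-tail p-value at n − 2
degrees of freedom. This is a documented package convention — squared pH
deviations scaled by pH ≈ 7–9 — chosen because it is well defined for any
calibration table; the scale-free Φ is always reported alongside so no
information rests on the convention.

**Degenerate inputs.** S_B = 0 is computed exactly (it is the
zero-substrate fixed point pH_surface = pH_B, to 10⁻⁹ pH in the solver);
datasets with duplicate concentrations are rejected with the duplicates
listed; fits require ≥ 3 points for the 2 parameters; linearisations
reject non-positive rates or concentrations and skip S = 0 grid values
with a log notice.

## Preprocessing conventions

Constant-capacitance voltage traces are reduced to a plateau voltage as
the arithmetic mean of the last 100 samples — the pseudo-steady-state
operationalised, with an optional drift warning if the window's linear
slope exceeds a threshold, and a hard error (never a silent window
shrink) for shorter traces. Voltage maps to pH linearly,
pH = pH0 + (V0 − Vx)/S_pH, with S_pH stored in V per pH unit and the sign
convention that alkalinisation (the urease response) lowers the measured
voltage; the trace generator and the reader share this convention. When no
explicit calibration is supplied, the zero-concentration trace defines V0
and the chemistry's bulk pH defines pH0.

## Synthetic data: what it emulates and what it does not

The generator produces (a) calibration tables, pHᵢ = pH_model(S_Bᵢ) + εᵢ
with εᵢ ~ N(0, σ_pH) seeded, and (b) raw settling traces
V(t) = V_target + (V0 − V_target)·e^(−t/τ) + η(t) whose plateau encodes the
model pH through the inverse voltage map. Defaults mirror the intended
experimental design: grid {0, 0.1, 0.3, 1, 3, 10, 30, 50} mM, bulk pH 7.4,
σ_pH = 0.02, sensitivity 33 mV/pH (midpoint of typical 30–35 mV readouts),
τ = 50 s with 600 s traces at 2 Hz (twelve settling times, so the
100-sample plateau window sits past 10τ and its transient bias is below
e⁻¹⁰ of the step), voltage noise 0.5 mV.

The generator draws its curves from the same model family the fit assumes;
passing recovery tests therefore demonstrates that the estimation machinery
is correct and well-conditioned under the stated noise, *not* that the
model is adequate for any particular real sensor. Real data add effects
the generator omits: sensor drift and hysteresis, non-Nernstian and
pH-dependent sensitivity, enzyme inactivation over a measurement series,
matrix components that inhibit the enzyme mechanistically, and deviations
from the thin-layer transport assumption.

With the AU-like parameter scale (k̄_V ~ 10⁻⁶ M and stronger buffering)
the predicted pH shifts are of order 10⁻³ pH units — far below a 0.02 pH
noise floor — so AU-preset tests compare noise-free model outputs (e.g.
uniformly smaller voltage shifts than PBS); recovering such parameters
from realistically noisy data would require a more sensitive readout than
the emulated one.

## Problem sizes

Randomised-property checks use 100–1000 draws; the noisy recovery study
uses 20 seeded replicates of a 12-point curve spanning 0.1–50 mM, fitted
with the Nelder–Mead multi-start (the noise-free branch exercises both
optimisers). These sizes give stable medians while keeping the default
suite fast.

## Known limitations

- No time-dependent response: settling traces are an empirical
  exponential, not an integration of the kinetic ODEs.
- No electrostatics of the insulator surface (site-binding/double-layer),
  no temperature dependence of constants, no multi-step carbonate
  speciation.
- Uncertainty on fitted parameters is limited to cross-method agreement;
  no confidence intervals are produced.
- The linearisation estimators are unweighted least squares by design —
  they are qualitative cross-checks, and on noisy data they re-weight
  errors differently from the primary fit.
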