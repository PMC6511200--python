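# Methods

## FAME profiles and saturation summaries

A FAME profile maps fatty-acid species — identified by the triple (chain
length, double bonds, omega class), so 18:1n9 and 18:1n7 are distinct — to
mass percent of total fatty acids.  Species printed as "–" in composition
tables are treated as exactly 0.  Profiles may total below 100 % (the
remainder being unidentified fatty acids) and are **never renormalized**:
class sums and the average unsaturation use the printed mass fractions as
weights.  This choice is validated by the reference data, where the
published fuel properties are reproduced from the published profiles only
under absent-as-zero, no-renormalization arithmetic.  The average
unsaturation is

    ACU = sum_i (double_bonds_i * percent_i) / 100,

a dimensionless mean double-bond count weighted by mass fraction.  Totals
up to 105 % are accepted on input because published tables occasionally
overshoot through mis-printed entries; such columns load, are flagged in
the fixture notes, and are excluded from reproduction tests (never
special-cased in analysis code).

## Fuel-property model

The six biodiesel properties are linear in ACU, with the coefficients of
the Hoekman et al. (2012) cross-feedstock regressions (kinematic viscosity
5.2065 − 0.6316·ACU mm²/s; specific gravity 0.8726 + 0.0055·ACU kg/L;
cloud point 19.994 − 13.356·ACU °C; cetane number 62.876 − 6.6684·ACU;
iodine value 12.71 + 74.373·ACU g I₂/100 g; HHV 38.534 + 1.7601·ACU
MJ/kg).  The coefficients live in a registrable `PropertyModel` constant,
not in logic, so alternative models can be swapped in.  Because all six
properties share the single covariate, each is invertible back to the
generating ACU; the test suite uses this for consistency checks.
Compliance with ASTM D6751 (KV 1.9–6.0 mm²/s, CN ≥ 47) and EN 14214 (KV
3.5–5.0, SG 0.85–0.90, CN ≥ 51, IV ≤ 120) is evaluated on unrounded
values; limits a standard does not define are skipped, not failed.
Rounding (0.1 for most properties, 0.01 for specific gravity) happens only
in the reporting layer.

A reproduction caveat: with input fractions printed to 0.1 %, the ACU of a
column is only determined to a few 10⁻³, which the iodine value — slope
74.373 — amplifies to ~0.3 g I₂/100 g.  Recomputed IV can therefore sit
~0.2–0.4 from published values even for perfectly transcribed columns,
while the other five properties reproduce to ~0.1.

## Steady-state productivity

Steady state in a semi-continuous culture is operationalized as *both*
conditions, with neither given priority: at least three reactor-volume
turnovers (3/D days) elapsed since the switch from batch operation, *and*
averaging over the last three sampled days.  A window whose biomass CV
exceeds 10 % triggers a warning (not an error) flagging possible
non-convergence.  Productivities are P_b = D·X_ss (g/L/day) and
P_lip = 10·P_b·w_lip (mg/L/day) with w in % of dry weight; composition
fractions attach to steady-state records, not daily records, because
composition is measured at steady state only.  The optimum dilution rate
is the argmax of the chosen productivity (lipid, FAME, biomass, or a
combined score summing min–max-normalized biomass and lipid
productivities), ties broken toward smaller D since slower medium turnover
is cheaper.  Washout is flagged at the smallest D whose X_ss falls below a
configurable fraction (default 15 %) of the sweep maximum — an invented
operational threshold, since "washing-out" is otherwise only a qualitative
label.

## PAM fluorescence and rapid light curves

Fv/Fm = (Fm − F0)/Fm and QY = (Fm′ − F)/Fm′ are plain ratios and hence
invariant to the arbitrary fluorescence unit.  NPQ = (Fm − Fm′)/Fm′.  For
qP = (Fm′ − F)/(Fm′ − F0′) the dark level under actinic light, F0′, is
rarely measured; when absent it is estimated with the Oxborough–Baker
relation F0′ = F0/(Fv/Fm + F0/Fm′) and the result is flagged as estimated.
rETR = PAR·a·QY·0.5, where 0.5 splits absorbed photons between the
photosystems and the absorptance factor a defaults to 1.0 (relative ETR);
the 0.84 instrument convention is available as an override.  The choice
rescales rETRmax and Ik but cancels in ratios of alpha.

Rapid light curves are fitted with the Platt photoinhibition form
rETR(E) = Ps(1 − exp(−αE/Ps))exp(−βE/Ps) by bounded trust-region least
squares (α, Ps > 0, β ≥ 0; parameter/function tolerances 1e−12; no random
restarts, so fits are deterministic).  Initial guesses: α from the secant
through the first lit points, Ps from the maximum observed rETR,
β = 0.01·α₀.  Non-convergence is reported in the result, not raised.
Derived quantities: rETRmax = Ps·[α/(α+β)]·[β/(α+β)]^(β/α) for β > 0 (Ps
for β = 0) and Ik = rETRmax/α, exact by construction.  The maximal quantum
yield MQY is the measured yield of the first (lowest-light) step, not a
fit product.  Stress time-courses are summarized per parameter by the time
of the minimum and the recovery time, defined as the first time after the
minimum at which the value re-enters a 5 % band around its initial value;
trajectories that never leave the band have no change-point.

## Synthetic data

The generators emulate the statistical structure the analyses assume, not
any particular instrument:

* **Chemostat sweeps.**  Growth is a Hill function of the column-averaged
  Beer–Lambert irradiance, μ(I) = μ_max·Iⁿ/(Ik_growthⁿ + Iⁿ) with
  Iav(X) = I0(1 − e^(−Ka·X·L))/(Ka·X·L).  At steady state μ(Iav(X)) = D is
  solved for X by bisection (Brent), washout returned as X = 0 when D
  exceeds μ at full light.  Defaults (μ_max 0.9 1/day, Ka 200 m²/kg, light
  path 0.07 m, I0 1000 µmol/m²/s, Ik_growth 250, n 1.4) represent a
  lab-scale bubble column: steady states near 2 g/L at low D, productivity
  peaking around 0.25 1/day, washout inside a 0.05–0.9 1/day grid.  The
  Hill-on-average-irradiance form is a standard choice for light-limited
  column cultures and reproduces the qualitative signature (X falling with
  D, unimodal P_b, washout); n > 1 makes P_b genuinely unimodal.  Daily
  series relax exponentially to X_ss with a time constant of at most
  2.5 days so the steady-state window samples a converged culture, and
  observations carry unit-mean multiplicative lognormal noise (default
  CV 5 %, typical of optical-density biomass proxies) — lognormal to
  preserve positivity.  Circadian light modulation is not simulated; the
  series are daily means.
* **Rapid light curves.**  rETR from the Platt form on a typical 12-step
  0–1500 µmol/m²/s ladder with multiplicative Gaussian noise (default
  5 %), realized as (F, Fm′) pairs on a smoothly declining Fm′ envelope;
  the dark step carries the low-light yield limit 2α.  Parameter sets
  implying QY > 1 are rejected.
* **Stress courses** are piecewise-linear templates (heat: dip and
  recovery, by default bottoming at 60 min and re-entering the 5 % band at
  155 min; cold: slow alpha decline to 215 min then rebound; high light:
  sharp Fv/Fm drop within 5 min) with optional additive noise and stored
  change-points.
* **FAME profiles** are Dirichlet draws over the 15-species reference
  alphabet with class-level mean weights, scaled to a total drawn from
  80–100 %, with the realized ACU stored.

Identical configuration and seed give bit-identical output.  What passing
tests on these generators show is that the estimators recover the
generating process under its stated noise; they do not certify behaviour
under real-world artefacts the generators omit (instrument drift,
biofouling, adhesion/clumping of benthic diatoms, nutrient limitation).

## Test and acceptance problem sizes

The suite fits 200 noisy rapid light curves, scans 10⁶-point grids for the
chemostat-solver cross-check, and evaluates 18-point dilution grids —
sizes chosen so the full suite runs in seconds while the stochastic
recovery statistics are stable to the asserted tolerances.  Optimum
recovery is asserted on the noise-free simulator against the continuous
model optimum (one grid step), which is the deterministic content of the
claim; noisy paths are exercised separately through steady-state
detection.

## Known limitations

* The fuel-property model is a single-covariate linear surrogate; it knows
  nothing of chain length at fixed unsaturation, so two profiles with
  equal ACU get identical properties.
* Several reference-table columns are internally inconsistent as published
  (see `src/algafuel/data/FIXTURE_NOTES.md`); their published property
  values cannot be reproduced from their published profiles, and tests
  exclude them rather than special-casing the analysis.
* The chemostat generator is a steady-state model with a phenomenological
  relaxation, not a dynamic mass balance; it is meant to exercise the
  analysis code, not to predict reactor behaviour.
* qP/NPQ with imputed F0′ inherit the Oxborough–Baker approximation error.
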