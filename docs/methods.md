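# Methods

## Model structure

The simulator describes an ideally mixed tank with a liquid volume `V_w` and
a headspace `V_g`. The liquid phase carries 26 components: 14 dissolved
(sugars, amino acids, long-chain fatty acids, valerate, butyrate,
propionate, acetate, dissolved H₂ and CH₄, inorganic carbon, inorganic
nitrogen, soluble inerts, strong cations and anions), 5 particulate pools
(raw composite, carbohydrates, proteins, lipids, particulate inerts) and 7
microbial guilds (degraders of sugars, amino acids, LCFA,
valerate/butyrate, propionate, acetate and hydrogen). Organics are in
kgCOD/m³; inorganic carbon, nitrogen and the strong ions in kmol/m³;
headspace gases in mol/m³.

Nineteen biochemical processes connect them: disintegration of the composite
into the four feedstock-defined pools, three first-order hydrolyses, eight
Monod uptakes and seven first-order decays (decayed biomass returns to the
composite pool). All constants not specific to this plant are the
Rosen & Jeppsson mesophilic ADM1 benchmark values. The stoichiometric matrix
conserves COD exactly by construction, and the inorganic-carbon and
-nitrogen rows are computed as elemental closures of each column, so C and N
are conserved for *any* feedstock fractionation. The carbon content of the
composite is likewise the fraction-weighted carbon of its products, making
disintegration exactly carbon-neutral; this replaces a fixed literature
value because the composite's composition is feedstock-specific here.

Inhibition follows ADM1 convention: Hill-type pH switches (window
5.5/4 for acidogenesis/acetogenesis, 7/6 for acetoclastic methanogens, 6/5
for hydrogenotrophs), non-competitive dissolved-H₂ inhibition of the
syntrophic steps, free-ammonia inhibition of acetate uptake
(K_I = 1.8 mmol/L), and a nitrogen-limitation factor on all growth.

## Temperature dependence

Only the three plant-estimated constants scale with temperature,
k(T) = k(T₀)·e^{θ(T−T₀)}, T₀ = 35 °C: propionate uptake (7.19 d⁻¹,
θ = +0.02615 °C⁻¹), acetate uptake (14.27 d⁻¹, θ = +0.00434 °C⁻¹),
disintegration (1.105 d⁻¹, θ = −0.06879 °C⁻¹). Taken literally, the negative
θ makes disintegration *slower* at 55 °C (0.279 d⁻¹) — the sign runs against
the usual expectation that heat aids hydrolysis, and against the positive-θ
uptake rates being described as favouring the cooler stage. The
implementation applies the printed law and signs as given; with them, the
thermophilic first stage still out-produces the classical plant (+8.5 % for
case 1) because the faster acetate/propionate turnover at 55 °C outweighs
the slower disintegration at a 32 d retention, and the undigested composite
is finished in the mesophilic second stage. Acid–base equilibria (CO₂,
NH₄⁺, water) use van 't Hoff corrections; the two VFA constants and all
Henry constants are treated as temperature-independent.

## Gas phase

Partial pressures follow the ideal gas law from the headspace
concentrations; water vapour contributes an Antoine-type saturation pressure
(0.0313·e^{5290(1/298.15−1/T)} bar, switchable off). Transfer is the linear
two-film law lgt_i = k_La(S_liq,i − K_H,i·p_i) with k_La = 200 d⁻¹ by
default and Henry constants K_H = 0.0016 (CH₄), 0.318 (CO₂) and 0.00078
(H₂) mol/L/bar. The CO₂ constant is the value the reference study reports;
it is an order of magnitude above the usual 25 °C literature value, which
makes the pressure mechanism (CO₂ retained in the liquid, CH₄ enriched in
the gas) correspondingly stronger — consistent with the very low (~20 %)
methane content that study attributes to the depressurised second stage,
where the carried-over carbonate flashes out.

The vent law F = k_p·V_g·(P_tot−P_OP)·P_tot/P_OP is clamped at zero below
the setpoint (no backflow). The default pipe-resistance constant is
k_p = 10⁴ (d·bar)⁻¹, which holds an atmospheric tank within a few millibar
of its setpoint at this plant's production rate; fluxes are converted to
normal conditions via F_N = F·P_OP·273.15 K/(T·1.01325·10⁵ Pa).

## Geometry and operating points

The reference plant has two 3 300 m³ tanks, 87.5 m³/d of feed and a stated
retention of 32 d. Those three numbers are mutually inconsistent if the full
3 300 m³ were liquid (3300/87.5 = 37.7 d), so the default geometry is
V_w = 2 800 m³ (preserving HRT = 32 d) plus a 500 m³ headspace (preserving
total volume); both are configurable. Configurations: classical — both
tanks 39 °C, 1.013 bar, free pH; AHPD — first tank vents at 20.27 bar with
pH clamped to the corresponding classical steady-state value (7.37, 7.36,
7.45, 7.44 for cases 1–4), second tank atmospheric; TPAD — 55 °C then
39 °C, free pH. The pH clamp is an ideal-dosing abstraction: the clamped
value feeds both the inhibition terms and the carbonate speciation, with no
explicit titrant species. Combined pressure + temperature phasing is out of
scope.

The dissolved CH₄/CO₂ load of the first tank's effluent is carried into the
second tank, whose own equilibrium then outgasses it; this is what produces
the CO₂-rich second-stage gas under AHPD.

## Numerics

The 29 coupled ODEs are stiff (dissolved H₂ turns over in minutes,
particulates in weeks) and are integrated with BDF at rtol 10⁻⁸,
atol 10⁻¹². Rates are evaluated on the state clipped at zero; with these
tolerances excursions stay below 10⁻¹⁰. pH is solved each step by
safeguarded Brent iteration on the charge balance bracketed at pH 0–14 (the
residual is monotone in H⁺, so the root is unique). Steady state is declared
when max_i |dC_i/dt|·HRT/max(C_i, 10⁻⁸) < 10⁻⁶; the horizon is walked in
blocks of 10 HRT (up to 60 HRT) and after each block a Newton polish of the
right-hand side is attempted, accepted only if it lands on a non-negative
state meeting the criterion. In practice every reported run converges within
the first 10 HRT ≈ 320 d block and the whole three-configuration study
simulates in seconds. Fluxes and compositions are evaluated at the converged
fixed point (at the stated criterion this is indistinguishable from a
trailing-window average). The two tanks are solved sequentially — the
coupling is strictly feed-forward, so co-integration would change nothing.

Start-up is initialised as inoculation with active digestate: 10 kgCOD/m³
of each guild, an established ammonium/bicarbonate buffer (0.2 / 0.1
kmol/m³) and composite at 10 % of the feeding value. This matters: the fed
steady state coexists with an acidified washout state, and a sparse inoculum
(≈1 kgCOD/m³ per guild) acidifies irreversibly under this feeding strength,
exactly as an under-inoculated full-scale tank would. The converged steady
state is independent of the inoculum within numerical tolerance for any
start that stays on the healthy branch (verified by two-seed comparison).

## Feedstock representation and the synthetic generator

A feedstock is one composite COD concentration X_c plus four fractionation
factors; the feed stream carries no pre-hydrolysed material. The bundled
cases' printed fraction sets sum to 1.0010/1.0007 (rounding) and are
renormalized on load so disintegration conserves COD. The synthetic
generator draws X_c uniformly (default 250–350 kgCOD/m³, bracketing the
bundled cases) and fractions from a Dirichlet weighted towards carbohydrate
as in silage-based feeds; it reproduces the *structure* of real feed
records, not their correlations (e.g. protein–nitrogen coupling across real
manures), so property tests built on it exercise invariants, not predictive
accuracy.

## Calibration

Only three lumped constants are identifiable from a single steady-state
flux/composition pair, so `adsim.calibrate` fits (k_dis, k_m_ac, k_La)
within bounded windows by relative least squares against one classical
case. The validation-band checks in the test suite deliberately use the
*uncalibrated* defaults (all four classical cases land within ±12.3 % of the
reference model fluxes).

## Known limitations

* The reference study's complete parameter set is unpublished; with ADM1
  defaults the absolute per-reactor figures differ from its tables by up to
  ~12 %, and comparisons are therefore asserted directionally and via the
  published-table arithmetic rather than bit-wise.
* Henry constants are pressure- and temperature-independent; no fugacity
  corrections at 20 bar.
* No spatial gradients, foaming, mixing energetics or membrane gas-holder
  dynamics; no recycle streams or more than two tanks.
* The pH clamp assumes ideal instantaneous dosing with no ionic-strength
  feedback from the titrant.
* Carbonate is modelled as CO₂/HCO₃⁻ only (no CO₃²⁻), adequate below pH ≈ 9.
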