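# Methods

This note documents the thermodynamic model, the parameter defaults,
the numerical choices, and what the synthetic test data do and do not
establish.

## 1. Solvation from a cubic equation of state

The solvation Gibbs energy of a solute *i* at infinite dilution is the
free-energy change of transferring one molecule from the ideal-gas
state into the liquid solvent at equal molar concentration (Ben-Naim
convention).  Writing the liquid-phase fugacity through a fugacity
coefficient and the gas-phase fugacity through the ideal-gas law, the
concentration-matched ratio gives

    Δ_solv ḡ_i∞ = RT ln( φ_i,liq∞ · P · v_liq / (RT) ),

which depends only on quantities a cubic EoS computes directly: the
solvent liquid molar volume v_liq and the solute's infinite-dilution
fugacity coefficient.  For an ideal gas φ = 1 and v = RT/P, so the
logarithm vanishes — this reduction is asserted in the tests.
Evaluations default to P = P_sat(solvent, T), which guarantees a liquid
root below the solvent critical point; liquid-phase solvation energies
are insensitive to pressure in this regime, but the EoS needs a
definite state point.

## 2. The tc-PR equation of state

Pressure-explicit Peng–Robinson in the untranslated volume w = v + c:

    P = RT/(w − b) − a(T)/(w(w + b) + b(w − b)),

with Ω_a = 0.45724, Ω_b = 0.07780, R = 8.31446 J/(mol·K).  The
translation c shifts every volume root by a constant and multiplies
fugacity coefficients by exp(−cP/RT); vapour–liquid equilibrium is
untouched.  α-functions:

* Soave: α = [1 + m(1 − √Tr)]², with m from the 1976 PR correlation
  m = 0.37464 + 1.54226ω − 0.26992ω² when built from (Tc, Pc, ω).
* Twu-91: α = Tr^{N(M−1)} exp[L(1 − Tr^{MN})].  When fitted L, M, N are
  unavailable, generalized quadratics in ω are used
  (L = 0.1290ω² + 0.6039ω + 0.0877, M = 0.1760ω² − 0.2600ω + 0.8884,
  N = 2); these agree with the Soave form to a few tenths of a percent
  at ordinary ω.

Volume translation, when not fitted, comes from the Péneloux-type
generalized correlation for PR

    c = 0.50033 (R Tc/Pc)(0.25969 − Z_RA),  Z_RA = 0.29056 − 0.08775 ω.

This form was chosen over steeper linear-in-ω candidates because the
PR liquid-volume defect it must absorb is only a few cm³/mol at
Tr = 0.8 (measured directly with this implementation: ≈ −3 cm³/mol for
n-hexane), which fixes the magnitude scale.

**Roots and phases.** The untranslated cubic is solved as the
compressibility polynomial via the companion matrix; real roots above
the covolume are kept.  The smallest root is labelled liquid, the
largest vapour, a middle root unstable; a lone root is labelled by its
density relative to RT/3P.

**Saturation pressure.** The three-root pressure window is bounded by
the two spinodal extrema of the isotherm (found by a sign-scan plus
Brent refinement of dP/dw = 0).  Bisection on ln φ_L − ln φ_V inside
that window, then Newton polish with the exact derivative
(w_L − w_V)/RT.  Robustness was preferred over speed; the tests check
agreement with an independent plain bisection to 1e-8 relative on 20
randomized components.

## 3. COSMO-RS residual activities

Molecules are σ-profiles: 61-bin histograms of the screening charge
density on the COSMO cavity, on the fixed grid −3.0 … +3.0 e/nm²
(step 0.1).  Mixture profiles are mole-fraction-weighted sums of bin
areas.  A contact of two segments (effective area a_eff) costs

    E(σ_m, σ_n) = (α′/2)(σ_m + σ_n)²
                + c_hb(T) · min(0, min(0, σ_don + σ_hb) · max(0, σ_acc − σ_hb)),

σ in e/Å² (1 e/Å² = 100 e/nm²; converted once at the boundary).
Defaults (BP-TZVPD-FINE parametrization): a_eff = 4.73 Å²,
α′ = 10 473, c_hb = 48 321, σ_hb = 0.011 e/Å².  The published unit
labels for α′ and c_hb are mutually inconsistent; the convention
adopted here treats both as kJ/mol **per contact of area a_eff** with σ
in e/Å² (the effective area absorbed into the fitted constants).  This
is the only reading that reproduces the documented worked value of the
hydrogen-bond term and yields contact energies of a few to ~20 kJ/mol —
the scale at which the fixed point below is well-behaved.  Dispersion
is omitted (identical in liquid and conductor reference, so it cancels
from activities), and hydrogen bonds are nonspecific (one constant for
all donor/acceptor element pairs).

The hydrogen-bond constant is damped with temperature,

    c_hb(T) = c_hb · max(0, 1 + 1.5 (298.15/T − 1)),

an empirical linear-in-1/T law normalized to the base constant at
298.15 K, positive and decreasing over the 298–398 K working range.
The damping slope 1.5 is a fixed model constant of this implementation.

σ-potentials solve the implicit equation

    μ(σ_m) = −(RT/a_eff) ln Σ_n p(σ_n) exp[(a_eff μ(σ_n) − E(σ_m, σ_n))/RT]

by damped successive substitution (damping 0.5, start μ ≡ 0, max 500
iterations).  The update is evaluated with a log-sum-exp over occupied
bins for overflow safety.  Convergence tolerance is 1e-12 kJ/mol/Å²
(max-norm update) — far below the 1e-9 contract — so that activity
coefficients carry no solver noise at the 1e-8 level where tests
compare them with independently coded oracles.  The iteration is
deterministic; identical inputs give bit-identical potentials.

Residual activity coefficient (no combinatorial part, by
construction):

    ln γ_i^res = (A_i/RT) Σ_σ p_i(σ) [μ_S(σ) − μ_i(σ)],

a plain sum over the 61 bins.  μ stored per unit area makes the
(A_i/a_eff) segment-count scaling implicit.  Pure-compound and
identical-profile cases short-circuit to exactly zero (the same
potential would be subtracted from itself).

## 4. Huron–Vidal coupling and mixture fugacities

    b_m = Σ x_i b_i,   c_m = Σ x_i c_i,
    a_m/b_m = Σ x_i a_i(T)/b_i − g^E_res/Λ,   Λ = ln((2+√2)/(2−√2))/(2√2) ≈ 0.62323.

The minus sign is the infinite-pressure Huron–Vidal matching result
for the PR form: positive deviations from ideality (g^E > 0, weaker
cross-interactions) weaken the mixture attraction.  Because b_m is
linear, the partial-molar attraction term is closed-form,
D_i = a_i/(b_i RT) − ln γ_i^res/Λ, and

    ln φ_i = (b_i/b_m)(Z − 1) − ln(Z − B)
             − D_i/(2√2) · ln[(Z + (1+√2)B)/(Z + (1−√2)B)] − c_i P/(RT),

which satisfies Σ x_i ln φ_i = ln φ_total exactly (Euler) and is
verified against Richardson-extrapolated mole-number derivatives.

**Infinite dilution** is analytic: as x_solute → 0 the mixture
collapses to the pure solvent (b_m → b_solv, Z and B from the pure
solvent liquid root) and ln γ^∞ uses the pure-solvent σ-potential.
No extrapolation in composition is needed; numerical evaluation at
x = 1e-10 agrees to ~1e-4 J/mol and is kept as a test-side
cross-check.  The solute's volume translation is irrelevant at
infinite dilution (the −c_i P/RT reporting term is the only place it
could enter) and is set to zero for GC solutes.

## 5. Group-contribution parametrization

First-order GC with additivity in a transformed domain:

    a_c^0.67 = Σ_g n_g A_c,[g],  b^0.80 = Σ_g n_g B_[g],  a_0^0.48 = Σ_g n_g A_0,[g],

with universal exponents β_ac = 0.67, β_b = 0.80, β_a0 = 0.48.  The
placement of the exponents (property-side, not contribution-side) was
validated on homologous alkane series built from experimental critical
constants: a_c^0.67 and a_0^0.48 are additive in carbon number to ~1%
between C6 and C10, while the alternative placement is not.
σ-profiles are plainly additive per bin, p_i(σ_m)·A_i = Σ n_g
P_[g](σ_m); negative bin artifacts from the sum are clipped to zero,
the total area recomputed, and the clipped mass reported as a warning
(area densities cannot be negative; the choice only matters for poorly
covered chemistries).

a_0 is the Soave attraction at the T → 0 limit, where α → (1+m)², so
m = √(a_0/a_c) − 1.  The PR critical relations invert to
T_c = (Ω_b/Ω_a)·a_c/(R b) and P_c = Ω_b R T_c/b, and ω comes from
inverting the 1976 correlation on the branch through (m = 0.37464,
ω = 0), rejecting results outside [−0.5, 1.5] with a warning.
Species whose GC sums give a_0 < a_c are flagged as errors rather than
silently clamped — a negative m would make α grow with temperature.

**Decomposition.** SMARTS patterns matched most-specific-first
(priority order, ties by catalogue order) with no atom reuse; every
heavy atom must be covered or the decomposition fails listing the
residual atoms.  Whole-molecule groups (methanol, water — congeneric
outliers promoted to their own group) only match when they cover the
entire molecule.  Radical centres are located by the radical-electron
count and typed in code into the 12-type taxonomy (primary/secondary/
tertiary C, vinyl, acetylenic, aryl, benzyl, acyl, acyloxyl, hydroxyl,
alkoxyl, peroxyl); the category annotation on the input is validated
against the structure.  Transition states are not SMILES-expressible,
so they use a labeled syntax
`TS[class=RO_abstraction|ROO_abstraction; rh=<SMILES>; ro=<SMILES>; site=primary|secondary|tertiary]`:
the counts are those of R–H plus those of the radical, minus one
paraffinic site group (CH3/CH2/CH according to the abstracted-H class),
minus the radical's own group, plus one TS-moiety group representing
the C··H··O(–O) reacting core.  `site` defaults to primary.  This
realizes the reacting-moiety-as-group idea with spectator fragments
keeping their ordinary groups.

## 6. Parameter identification

**IQR filter.**  Tukey fences Q1 − 1.5·IQR, Q3 + 1.5·IQR per chemical
family, linear-interpolation ("type 7") quartiles; families smaller
than 4 pass through.  The multiplier and the per-family grouping are
exposed as arguments.  One pass; idempotent.

**GC-LR.**  Ordinary least squares in the transformed domain, one
problem per property plus 61 independent per-bin problems sharing the
occurrence design matrix.  Rank deficiency raises an error naming the
unidentifiable groups (null-space support).  Diagnostics: signed MPE
(pred − ref)/ref and R² per property.

**GC-NM.**  Nelder–Mead (scipy, standard 1/2/0.5/0.5 coefficients) on
the mean squared deviation in (kcal/mol)², parameters scaled to unit
magnitude, simplex spread tolerance 1e-10, max 2000 iterations.  Only
scoped group/property entries move.  Infeasible trial points (e.g.
driving a_0 below a_c) are penalized, and the result is guarded to
never exceed the starting objective.  Repeated evaluations cache the
solvent state per (solvent, T) and the solute state by a content hash
of the table rows the solute actually uses, so trial steps that leave
a solute's groups untouched cost nothing.

## 7. Benchmarking

Compounds classify as NA / HA / HD / SA by hydrogen-bond capability
(detected from SMARTS donor/acceptor patterns, or set explicitly); a
solvent/solute pair maps to a Binary Association Code 1–9 through the
printed lower-triangle table, with mirror pairs folded onto it (the
folding can be disabled).  Note the table maps both HA–HA and HD–HD to
code 4.  The runner predicts every record at P_sat(solvent, T),
aggregates MUE by BAC, by solvent, and by temperature band
([298,323), [323,348), [348,373), [373,398] K — bands chosen to tile
the radical/TS reference range evenly), and accounts every skipped
record: loaded = evaluated + skipped always holds.

## 8. Synthetic data: what it shows and what it does not

The fixtures module generates Gaussian-mixture σ-profiles (with
apolar "alkane" and hydrogen-bonding "hydroxyl" presets), planted GC
tables with group contributions sized like real CH2/CH3-type groups,
exactly additive property datasets with optional Gaussian noise, and
solvation references computed by the model itself on a discrete set of
isotherms spanning 298–398 K.  All generators are pure functions of
their seed.

Passing the recovery suites establishes that the estimators are
correct and self-consistent: GC-LR reproduces a planted table from
noise-free data at machine precision, GC-NM pulls a perturbed
contribution back to the truth from model-generated records, and the
benchmark runner scores the model at zero error against its own
predictions.  It does **not** establish accuracy against laboratory
data: synthetic profiles lack quantum-level fine structure, the
planted tables are not the published group parameters, and real
reference databases (experimental solvation compilations, QM-derived
σ-profiles) would be needed for that.  The problem sizes used in the
tests and the acceptance script (60-species regressions, 50-record
refinements, 20-30-record benchmarks) were chosen as the smallest
sizes at which the statistical claims are meaningful.

## 9. Known limitations

* No dispersion contact term and a single nonspecific hydrogen-bond
  constant; strongly associating systems (water, polyols) inherit the
  known weaknesses of this simplification.
* First-order GC only: no nearest-neighbour corrections, no
  conformational sensitivity.
* Pure solvents only; the solvent side always uses one compound.
* The shipped group catalogue covers C/H/O chemistry (plus the radical
  and TS taxonomies); other elements require an external catalogue
  CSV, which the loader accepts verbatim.
* The c_hb temperature damping slope (1.5) and the absorbed-a_eff unit
  convention are fixed model choices of this implementation; refitting
  the universal constants under a different convention would change
  them together.
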