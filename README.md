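# cosmopr

Predictive **tc-PR/COSMO-RS** solvation: a translated-consistent
Peng–Robinson equation of state coupled to a COSMO-RS residual activity
model through Huron–Vidal mixing rules, with first-order
group-contribution (GC) parametrization.  It computes infinite-dilution
solvation Gibbs energies of closed-shell molecules, C/H/O free radicals
and H-abstraction transition states in liquid solvents, and uses them to
convert gas-phase rate constants to the liquid phase.

## Who this is for

Kineticists building liquid-phase oxidation mechanisms need
Δ<sub>solv</sub>ḡ for species that have no experimental data — free
radicals and transition states.  This package makes the whole chain
predictive: a SMILES (or a labeled transition-state species) is
decomposed into functional groups, the groups supply the EoS parameters
and the σ-profile, and the EoS supplies the solvation energy at any
temperature and at the solvent's own vapour pressure.

## The model

For a solute *i* infinitely diluted in a liquid solvent at (*T*, *P*),

```
Δ_solv ḡ_i∞ = RT ln( φ_i,liq∞ · P · v_liq / (RT) )
```

where *v*<sub>liq</sub> is the solvent liquid molar volume and
φ<sub>i,liq</sub><sup>∞</sup> the solute fugacity coefficient, both from
the tc-PR EoS

```
P = RT/(v + c − b) − a(T) / [(v + c)(v + c + b) + b(v + c − b)]
```

with a Soave or Twu-91 α-function and a Péneloux volume translation
*c*.  Mixtures use the Huron–Vidal rules: `b` and `c` combine linearly
and

```
a_m/b_m = Σ x_i a_i/b_i − g^E_res/Λ ,   Λ = ln((2+√2)/(2−√2))/(2√2)
```

with the residual excess Gibbs energy `g^E_res = RT Σ x_i ln γ_i^res`
from COSMO-RS: 61-bin σ-profiles, misfit + hydrogen-bond contact
energies, and self-consistent σ-potentials μ(σ).

GC parametrization is additive in a transformed domain,
`a_c^0.67 = Σ n_g A_c,[g]`, `b^0.80 = Σ n_g B_[g]`,
`a_0^0.48 = Σ n_g A_0,[g]`, plus one additive model per σ-bin; the
chain `m = √(a_0/a_c) − 1 → (T_c, P_c) → ω` then yields a full
Soave-α component.  Two fitting stages identify group parameters:
**GC-LR** (IQR outlier pruning per chemical family, then least squares
in the transformed domain) and **GC-NM** (Nelder–Mead refinement of
scoped groups against reference solvation energies, minimizing the mean
squared deviation in kcal/mol).

The H-abstraction rate correction is
`k_liq = k_gas · exp(−ΔΔ_solv G‡ / RT)` with
`ΔΔ_solv G‡ = Δ_solv g(TS) − Δ_solv g(RH) − Δ_solv g(X·)`.

## Worked example

```python
from cosmopr import PureComponent, solvation_free_energy, liquid_rate_constant
from cosmopr.fixtures import synthetic_sigma_profile

hexane = PureComponent.from_critical("hexane", 507.6, 3.025e6, 0.301)
water  = PureComponent.from_critical("water", 647.1, 22.064e6, 0.345)
p_alk = synthetic_sigma_profile(2002, "alkane",   total_area=150.0)
p_hyd = synthetic_sigma_profile(2003, "hydroxyl", total_area=60.0)

r1 = solvation_free_energy((hexane, p_alk), (hexane, p_alk), 298.15)
r2 = solvation_free_energy((hexane, p_alk), (water,  p_hyd), 298.15)
print(f"self:  Psat = {r1.p:.0f} Pa   v_liq = {r1.v_liq*1e6:.1f} cm3/mol   "
      f"dG_solv = {r1.dg_solv_kcal:.2f} kcal/mol")
print(f"cross: Psat = {r2.p:.0f} Pa   v_liq = {r2.v_liq*1e6:.1f} cm3/mol   "
      f"dG_solv = {r2.dg_solv_kcal:.2f} kcal/mol")
```

prints (σ-profiles here are synthetic stand-ins generated by the
fixtures module, not quantum-derived):

```
self:  Psat = 20308 Pa   v_liq = 133.4 cm3/mol   dG_solv = -4.05 kcal/mol
cross: Psat = 2667 Pa   v_liq = 21.3 cm3/mol   dG_solv = -9.21 kcal/mol
```

The self-solvation line says: at 298.15 K the EoS puts hexane's vapour
pressure at 20.3 kPa and its liquid molar volume at 133 cm³/mol, and
transferring a hexane molecule from the ideal-gas state into liquid
hexane releases 4.05 kcal/mol — right in the experimental range for
alkane self-solvation.  The cross line uses a hydroxylic synthetic
solvent profile, so its absolute value tracks the synthetic profile,
not real water.

GC parametrization from structure:

```python
from cosmopr import decompose
decompose("CCO").counts                    # {'ch3': 1, 'ch2': 1, 'oh': 1}
decompose("CC[O]", category="radical").counts
                                           # {'rad_alkoxyl': 1, 'ch3': 1, 'ch2': 1}
decompose("TS[class=RO_abstraction; rh=CC; ro=C[O]; site=primary]",
          category="ts").counts            # {'ch3': 2, 'ts_ro_abstraction': 1}
```

A CLI wraps the same functionality: `cosmopr param`, `gsolv`, `ddg`,
`fit-lr`, `fit-nm`, `bench`, `convert`, `fixtures` (see `cosmopr --help`).

## Layout

| module | contents |
| --- | --- |
| `cosmopr.eos` | tc-PR pure-compound EoS, α-functions, cubic solver, fugacities, saturation pressure, GC→(m, T_c, P_c, ω) chain |
| `cosmopr.cosmors` | σ-profiles, contact energies, σ-potential fixed point, residual activities |
| `cosmopr.solvation` | Huron–Vidal mixing, mixture fugacities, Δ_solv ḡ∞, ΔΔG‡, rate correction |
| `cosmopr.groups` | group catalogue, SMILES/radical/TS decomposition, GC property prediction |
| `cosmopr.fitting` | IQR filter, GC-LR regression, GC-NM refinement, MUE/MPE/R² |
| `cosmopr.bench` | association classes, binary association codes, dataset IO, benchmark runner |
| `cosmopr.fixtures` | seeded synthetic σ-profiles, GC datasets, solvation references |
| `cosmopr.cli` | command-line interface |

See `docs/methods.md` for the model documentation, parameter defaults
and the design decisions behind the numerical choices.
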