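"""Huron-Vidal EoS/gE coupling, solvation free energies, rate correction.

The advanced mixing rules inject the COSMO-RS residual excess Gibbs
energy into the PR attractive parameter::

    a_m / b_m = sum_i x_i a_i(T)/b_i  -  gE_res / Lambda
    b_m = sum_i x_i b_i,   c_m = sum_i x_i c_i

with the PR infinite-pressure constant Lambda = 0.62323.  Positive
deviations from ideality (gE_res > 0, weaker cross-interactions)
reduce the mixture attraction, and the rules collapse to the pure
compound EoS at every composition vertex.

The solvation Gibbs energy of a solute at infinite dilution follows
from quantities a cubic EoS computes directly::

    dG_solv = R T ln( phi_inf * P * v_liq / (R T) )

where ``phi_inf`` is the solute's infinite-dilution fugacity
coefficient in the liquid solvent and ``v_liq`` the (translated)
solvent liquid molar volume.  For an ideal gas both factors collapse
and dG_solv = 0.  The difference of solvation energies between a
transition state and its reactants converts gas-phase H-abstraction
rate constants to the liquid phase:
``k_liq = k_gas exp(-ddG / (R T))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import R, LAMBDA_HV, KCAL_PER_KJ
from .cosmors import (
    CosmoRsConstants,
    SigmaProfile,
    ln_gamma_residual,
    g_excess_residual,
    sigma_potentials,
)
from .eos import (
    Phase,
    PureComponent,
    attractive_a,
    saturation_pressure,
    solve_volumes,
)

__all__ = [
    "Mixture",
    "SolvationResult",
    "HAbstractionReaction",
    "mix_parameters",
    "ln_phi_mixture",
    "solvation_free_energy",
    "activation_solvation",
    "liquid_rate_constant",
]

SQRT2 = math.sqrt(2.0)


@dataclass
class Mixture:
    """N-component liquid mixture state: components, composition, T, P."""

    components: list[PureComponent]
    profiles: list[SigmaProfile]
    x: np.ndarray
    t: float
    p: float
    constants: CosmoRsConstants = field(default_factory=CosmoRsConstants)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        n = len(self.components)
        if len(self.profiles) != n or self.x.size != n:
            raise ValueError("components, profiles and x must align")
        if abs(self.x.sum() - 1.0) > 1e-12:
            raise ValueError("molar fractions must sum to 1")


def mix_parameters(mixture: Mixture) -> tuple[float, float, float]:
    """Mixture (a_m, b_m, c_m) under the advanced mixing rules."""
    comps, x, t = mixture.components, mixture.x, mixture.t
    if any(c.b <= 0 for c in comps):
        raise ValueError("every component needs a positive covolume")
    b_m = float(x @ np.array([c.b for c in comps]))
    c_m = float(x @ np.array([c.c for c in comps]))
    ab = float(x @ np.array([attractive_a(c, t) / c.b for c in comps]))
    if len(comps) == 1:
        ge = 0.0
    else:
        ge = g_excess_residual(mixture.profiles, x, t, mixture.constants)
    a_m = b_m * (ab - ge / LAMBDA_HV)
    return a_m, b_m, c_m


def _ln_phi_hv(
    i: int,
    mixture: Mixture,
    phase: Phase | str = Phase.LIQUID,
    ln_gammas: Optional[np.ndarray] = None,
) -> float:
    """ln phi_i under Huron-Vidal mixing at the requested phase root.

    Closed form for linear b_m: the partial-molar attraction term is
    ``D_i = a_i/(b_i R T) - ln gamma_i^res / Lambda`` and

        ln phi_i = (b_i/b_m)(Z-1) - ln(Z-B)
                   - D_i/(2 sqrt2) ln[(Z+(1+sqrt2)B)/(Z+(1-sqrt2)B)]
                   - c_i P/(R T)

    with Z evaluated at the untranslated mixture root.  Satisfies
    ``sum_i x_i ln phi_i = ln phi_total`` by Euler's theorem.
    """
    comps, x, t, p = mixture.components, mixture.x, mixture.t, mixture.p
    if all(
        attractive_a(c, t) == 0.0 and c.b == 0.0 and c.c == 0.0 for c in comps
    ):
        return 0.0    # ideal-gas degenerate mixture
    a_m, b_m, c_m = mix_parameters(mixture)
    sol = solve_volumes(t, p, a_m, b_m, 0.0)
    w = sol.volume(phase)
    z = p * w / (R * t)
    B = b_m * p / (R * t)
    if ln_gammas is None:
        if len(comps) == 1:
            lg_i = 0.0
        else:
            lg_i = ln_gamma_residual(
                i, mixture.profiles, x, t, mixture.constants
            )
    else:
        lg_i = float(ln_gammas[i])
    ci = comps[i]
    d_i = attractive_a(ci, t) / (ci.b * R * t) - lg_i / LAMBDA_HV
    return (
        (ci.b / b_m) * (z - 1.0)
        - math.log(z - B)
        - d_i / (2.0 * SQRT2)
        * math.log((z + (1.0 + SQRT2) * B) / (z + (1.0 - SQRT2) * B))
        - ci.c * p / (R * t)
    )


def ln_phi_mixture(
    i: int, mixture: Mixture, phase: Phase | str = Phase.LIQUID
) -> float:
    """Fugacity coefficient (ln phi) of component i in the mixture."""
    return _ln_phi_hv(i, mixture, phase)


@dataclass
class SolvationResult:
    """Infinite-dilution solvation Gibbs energy and its EoS ingredients."""

    dg_solv: float      # J/mol
    ln_phi_inf: float
    v_liq: float        # m^3/mol, translated solvent liquid volume
    t: float            # K
    p: float            # Pa
    solute: str = ""
    solvent: str = ""

    @property
    def dg_solv_kj(self) -> float:
        return self.dg_solv * 1e-3

    @property
    def dg_solv_kcal(self) -> float:
        return self.dg_solv * 1e-3 * KCAL_PER_KJ

    def __post_init__(self) -> None:
        recomputed = R * self.t * (
            self.ln_phi_inf + math.log(self.p * self.v_liq / (R * self.t))
        )
        if abs(recomputed - self.dg_solv) > 1e-10 * max(1.0, abs(self.dg_solv)):
            raise ValueError("inconsistent solvation result")


def solvation_free_energy(
    solute: tuple[PureComponent, SigmaProfile],
    solvent: tuple[PureComponent, SigmaProfile],
    t: float,
    p: Optional[float] = None,
    constants: CosmoRsConstants = CosmoRsConstants(),
) -> SolvationResult:
    """Solvation Gibbs energy of a solute at infinite dilution.

    ``p=None`` evaluates at the solvent vapour pressure (guaranteeing a
    liquid phase below Tc).  The infinite-dilution limit is analytic:
    the solvent properties are those of the pure solvent, and the
    solute fugacity coefficient uses its infinite-dilution residual
    activity coefficient in the pure solvent.  The solute volume
    translation is irrelevant at infinite dilution and is ignored.
    """
    comp_u, prof_u = solute
    comp_s, prof_s = solvent
    if comp_u.a_c == 0.0 and comp_u.b == 0.0 and comp_s.a_c == 0.0 \
            and comp_s.b == 0.0:
        # perfect-gas degenerate pair: phi = 1, v_liq = RT/P, dG = 0
        if p is None:
            raise ValueError("degenerate solvent has no vapour pressure")
        return SolvationResult(
            dg_solv=0.0, ln_phi_inf=0.0, v_liq=R * t / p, t=t, p=p,
            solute=comp_u.name, solvent=comp_s.name,
        )
    if p is None:
        if t >= comp_s.tc:
            raise ValueError(
                f"T={t} K is not below the solvent critical temperature"
            )
        p = saturation_pressure(comp_s, t)
    a_s = attractive_a(comp_s, t)
    sol = solve_volumes(t, p, a_s, comp_s.b, 0.0)
    if not sol.has_liquid:
        raise RuntimeError(
            f"no liquid phase of {comp_s.name} at T={t} K, P={p} Pa"
        )
    w = sol.volume(Phase.LIQUID)           # untranslated solvent root
    v_liq = w - comp_s.c                   # physical liquid volume
    z = p * w / (R * t)
    B = comp_s.b * p / (R * t)
    if np.allclose(prof_u.p, prof_s.p, rtol=0.0, atol=1e-15):
        lg_inf = 0.0
    else:
        mu_solv = sigma_potentials(prof_s, t, constants).mu
        mu_pure = sigma_potentials(prof_u, t, constants).mu
        lg_inf = float(
            prof_u.total_area * (prof_u.p @ (mu_solv - mu_pure))
            / (R * 1e-3 * t)
        )
    d_inf = attractive_a(comp_u, t) / (comp_u.b * R * t) - lg_inf / LAMBDA_HV
    ln_phi_inf = (
        (comp_u.b / comp_s.b) * (z - 1.0)
        - math.log(z - B)
        - d_inf / (2.0 * SQRT2)
        * math.log((z + (1.0 + SQRT2) * B) / (z + (1.0 - SQRT2) * B))
    )
    dg = R * t * (ln_phi_inf + math.log(p * v_liq / (R * t)))
    return SolvationResult(
        dg_solv=dg, ln_phi_inf=ln_phi_inf, v_liq=v_liq, t=t, p=p,
        solute=comp_u.name, solvent=comp_s.name,
    )


@dataclass
class HAbstractionReaction:
    """R-H + X. -> [R..H..X]‡ species triple for one H-abstraction."""

    rh: str
    radical: str
    ts: str
    label: str = ""

    def __post_init__(self) -> None:
        if len({self.rh, self.radical, self.ts}) != 3:
            raise ValueError("rh, radical and ts must be three distinct species")


def activation_solvation(
    reaction: HAbstractionReaction,
    species: dict[str, tuple[PureComponent, SigmaProfile]],
    solvent: tuple[PureComponent, SigmaProfile],
    t: float,
    p: Optional[float] = None,
    constants: CosmoRsConstants = CosmoRsConstants(),
) -> float:
    """Solvation free energy of activation ddG‡, J/mol.

    ``dG_solv(TS) - dG_solv(RH) - dG_solv(X.)`` at a common (T, P);
    with ``p=None`` all three use the solvent vapour pressure.
    """
    if p is None:
        p = saturation_pressure(solvent[0], t)
    parts = {}
    for key in ("ts", "rh", "radical"):
        sid = getattr(reaction, key)
        if sid not in species:
            raise KeyError(f"species {sid!r} not parametrized")
        parts[key] = solvation_free_energy(
            species[sid], solvent, t, p, constants
        ).dg_solv
    return parts["ts"] - parts["rh"] - parts["radical"]


def liquid_rate_constant(k_gas: float, ddg: float, t: float) -> float:
    """Gas-to-liquid rate correction k_liq = k_gas exp(-ddG/(R T)).

    ``ddg`` in J/mol.  A negative activation solvation energy (the TS
    better solvated than the reactants) accelerates the reaction.
    """
    if t <= 0:
        raise ValueError("temperature must be positive")
    return k_gas * math.exp(-ddg / (R * t))
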