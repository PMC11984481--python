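"""COSMO-RS residual activity model on discretized sigma-profiles.

A molecule is represented by its sigma-profile: a 61-bin histogram of
the screening charge density sigma on its COSMO cavity surface, on the
fixed grid -3.0 .. +3.0 e/nm^2 (step 0.1).  Surface segments of a
liquid pair up; each contact of effective area ``a_eff`` costs a misfit
(electrostatic) energy and, between a strong donor and a strong
acceptor, gains a hydrogen-bond energy.  The self-consistent segment
chemical potentials (sigma-potentials) then yield residual activity
coefficients and the residual excess Gibbs energy that the
Huron-Vidal mixing rules consume.

Unit convention: the grid is stored in e/nm^2 as published, but all
energies are evaluated with sigma in e/A^2 (1 e/A^2 = 100 e/nm^2), the
unit the universal constants were fitted in.  Contact energies are
kJ/mol per contact of area ``a_eff`` (the effective area is absorbed
into the fitted constants); sigma-potentials are stored per unit
cavity area, kJ/mol/A^2.

The combinatorial/entropic activity contribution is deliberately
absent: only the residual part enters the mixing rules.  Dispersion is
likewise omitted (identical in the liquid and the conductor reference
state, so it cancels from activities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .constants import R_KJ, T_REF_HB

__all__ = [
    "N_BINS",
    "SIGMA_GRID",
    "SigmaProfile",
    "SigmaPotential",
    "CosmoRsConstants",
    "mixture_sigma_profile",
    "chb_temperature",
    "contact_energy",
    "contact_energy_matrix",
    "sigma_potentials",
    "ln_gamma_residual",
    "g_excess_residual",
    "read_sigma_profile",
    "write_sigma_profile",
]

N_BINS = 61

#: The sigma grid, e/nm^2: -3.0 .. +3.0 inclusive, step 0.1.
SIGMA_GRID = np.round(np.linspace(-3.0, 3.0, N_BINS), 10)

#: Same grid in e/A^2 (unit of the universal constants).
_SIGMA_A2 = SIGMA_GRID / 100.0


@dataclass(frozen=True)
class CosmoRsConstants:
    """Universal COSMO-RS constants (BP-TZVPD-FINE parametrization).

    ``alpha_prime`` and ``c_hb`` carry kJ/mol per contact per (e/A^2)^2;
    ``sigma_hb`` is in e/A^2; ``a_eff`` in A^2.
    """

    a_eff: float = 4.73
    alpha_prime: float = 10473.0
    c_hb: float = 48321.0
    sigma_hb: float = 0.011

    def __post_init__(self) -> None:
        if min(self.a_eff, self.alpha_prime, self.c_hb, self.sigma_hb) <= 0:
            raise ValueError("all COSMO-RS constants must be positive")


class ProfileContext(str, Enum):
    MIXTURE = "mixture"
    PURE = "pure"


@dataclass
class SigmaProfile:
    """61-bin surface-charge histogram: area per bin (A^2) on the grid."""

    area_per_bin: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.area_per_bin, dtype=float)
        if arr.shape != (N_BINS,):
            raise ValueError(
                f"sigma-profile must have exactly {N_BINS} bins, got {arr.shape}"
            )
        if np.any(arr < 0):
            raise ValueError("sigma-profile areas must be non-negative")
        if arr.sum() <= 0:
            raise ValueError("sigma-profile has zero total area")
        self.area_per_bin = arr

    @property
    def grid(self) -> np.ndarray:
        return SIGMA_GRID

    @property
    def total_area(self) -> float:
        """Total cavity area A_i, A^2."""
        return float(self.area_per_bin.sum())

    @property
    def p(self) -> np.ndarray:
        """Normalized distribution p(sigma); sums to 1."""
        return self.area_per_bin / self.total_area


@dataclass
class SigmaPotential:
    """Sigma-potential mu(sigma), kJ/mol per A^2, on the 61-node grid."""

    mu: np.ndarray
    temperature: float
    context: ProfileContext = ProfileContext.PURE
    residual: float = 0.0
    iterations: int = 0

    @property
    def grid(self) -> np.ndarray:
        return SIGMA_GRID


def mixture_sigma_profile(
    profiles: Sequence[SigmaProfile], x: Sequence[float]
) -> SigmaProfile:
    """Mole-fraction-weighted sigma-profile of a mixture.

    Bin areas combine linearly, ``area_S(sigma) = sum_i x_i area_i(sigma)``,
    so the total area is ``sum_i x_i A_i`` and the normalized profile is
    the area-weighted average of the components'.
    """
    x = np.asarray(x, dtype=float)
    if len(profiles) != x.size:
        raise ValueError("one molar fraction per profile required")
    if np.any(x < 0):
        raise ValueError("molar fractions must be non-negative")
    if abs(x.sum() - 1.0) > 1e-12:
        raise ValueError(f"molar fractions must sum to 1, got {x.sum()!r}")
    areas = np.stack([p.area_per_bin for p in profiles])
    return SigmaProfile(area_per_bin=x @ areas, name="mixture")


def chb_temperature(t: float, constants: CosmoRsConstants) -> float:
    """Temperature-damped hydrogen-bond constant c_hb(T).

    Empirical damping normalized to the base constant at 298.15 K:
    ``c_hb(T) = c_hb * max(0, 1 + 1.5 (298.15/T - 1))`` — continuous,
    equal to the fitted constant at the parametrization reference
    temperature, and decreasing as thermal motion disrupts hydrogen
    bonds.
    """
    if t <= 0:
        raise ValueError("temperature must be positive")
    return constants.c_hb * max(0.0, 1.0 + 1.5 * (T_REF_HB / t - 1.0))


def _hb_factor(sig_m: np.ndarray, sig_n: np.ndarray, sigma_hb: float) -> np.ndarray:
    """Hydrogen-bond activation factor, <= 0, in (e/A^2)^2.

    Active only when the donor density falls below -sigma_hb and the
    acceptor above +sigma_hb.
    """
    don = np.minimum(sig_m, sig_n)
    acc = np.maximum(sig_m, sig_n)
    return np.minimum(
        0.0,
        np.minimum(0.0, don + sigma_hb) * np.maximum(0.0, acc - sigma_hb),
    )


def contact_energy(
    sigma_m: float, sigma_n: float, t: float, constants: CosmoRsConstants
) -> float:
    """Contact energy of two segments, kJ/mol per a_eff-contact.

    ``sigma`` arguments in e/nm^2 (the grid unit).  Misfit term
    ``(alpha'/2)(sigma_m + sigma_n)^2`` plus the attractive
    hydrogen-bond term ``c_hb(T) * hb_factor``; symmetric under segment
    exchange.
    """
    sm, sn = sigma_m / 100.0, sigma_n / 100.0
    misfit = 0.5 * constants.alpha_prime * (sm + sn) ** 2
    hb = chb_temperature(t, constants) * float(
        _hb_factor(np.asarray(sm), np.asarray(sn), constants.sigma_hb)
    )
    return misfit + hb


def contact_energy_matrix(t: float, constants: CosmoRsConstants) -> np.ndarray:
    """61 x 61 matrix E(sigma_m, sigma_n) on the grid, kJ/mol/contact."""
    sm = _SIGMA_A2[:, None]
    sn = _SIGMA_A2[None, :]
    misfit = 0.5 * constants.alpha_prime * (sm + sn) ** 2
    hb = chb_temperature(t, constants) * _hb_factor(sm, sn, constants.sigma_hb)
    return misfit + hb


def sigma_potentials(
    profile: SigmaProfile,
    t: float,
    constants: CosmoRsConstants = CosmoRsConstants(),
    *,
    context: ProfileContext | str = ProfileContext.PURE,
    tol: float = 1e-12,
    max_iter: int = 500,
    damping: float = 0.5,
) -> SigmaPotential:
    """Solve the implicit sigma-potential equation on the 61-node grid.

    Damped successive substitution of::

        mu(s_m) = -(RT/a_eff) ln sum_n p(s_n)
                    exp[ (a_eff mu(s_n) - E(s_m, s_n)) / RT ]

    starting from mu = 0, until the max-norm update falls below ``tol``
    (kJ/mol/A^2; the default leaves generous margin under the 1e-9
    contract so that downstream activity coefficients are solver-noise
    free).  Deterministic: no randomness anywhere.
    """
    if t <= 0:
        raise ValueError("temperature must be positive")
    rt = R_KJ * t
    a_eff = constants.a_eff
    p = profile.p
    e_mat = contact_energy_matrix(t, constants)
    mu = np.zeros(N_BINS)
    active = p > 0.0
    resid = math.inf
    for it in range(1, max_iter + 1):
        # log-sum-exp over the occupied bins, row per sigma_m
        expo = (a_eff * mu[None, :] - e_mat) / rt
        expo = expo[:, active]
        m = expo.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(expo - m) @ p[active])
        mu_new = -(rt / a_eff) * lse
        resid = float(np.max(np.abs(mu_new - mu)))
        mu = damping * mu_new + (1.0 - damping) * mu
        if resid < tol:
            mu = mu_new
            return SigmaPotential(
                mu=mu, temperature=t, context=ProfileContext(context),
                residual=resid, iterations=it,
            )
    raise RuntimeError(
        f"sigma-potential iteration did not converge in {max_iter} steps "
        f"(last max-norm residual {resid:.3e} kJ/mol/A^2)"
    )


def ln_gamma_residual(
    i: int,
    profiles: Sequence[SigmaProfile],
    x: Sequence[float],
    t: float,
    constants: CosmoRsConstants = CosmoRsConstants(),
) -> float:
    """Residual activity coefficient ln gamma_i in the mixture.

    ``A_i/(RT) * sum_sigma p_i(sigma) [mu_S(sigma) - mu_i(sigma)]``,
    a plain sum over the 61 bins.  Identically zero for a pure
    compound, and for any mixture whose combined profile equals the
    compound's own (the same potential is subtracted).
    """
    mix = mixture_sigma_profile(profiles, x)
    prof_i = profiles[i]
    if np.allclose(
        mix.p, prof_i.p, rtol=0.0, atol=1e-15
    ):
        return 0.0
    mu_s = sigma_potentials(mix, t, constants, context=ProfileContext.MIXTURE).mu
    mu_i = sigma_potentials(prof_i, t, constants).mu
    return float(prof_i.total_area * (prof_i.p @ (mu_s - mu_i)) / (R_KJ * t))


def g_excess_residual(
    profiles: Sequence[SigmaProfile],
    x: Sequence[float],
    t: float,
    constants: CosmoRsConstants = CosmoRsConstants(),
) -> float:
    """Residual excess Gibbs energy R T sum_i x_i ln gamma_i, J/mol."""
    x = np.asarray(x, dtype=float)
    if x.size == 1:
        return 0.0
    mix = mixture_sigma_profile(profiles, x)
    mu_s = None
    total = 0.0
    for i, (xi, prof) in enumerate(zip(x, profiles)):
        if xi == 0.0:
            continue
        if np.allclose(mix.p, prof.p, rtol=0.0, atol=1e-15):
            continue
        if mu_s is None:
            mu_s = sigma_potentials(
                mix, t, constants, context=ProfileContext.MIXTURE
            ).mu
        mu_i = sigma_potentials(prof, t, constants).mu
        total += xi * prof.total_area * (prof.p @ (mu_s - mu_i))
    # total is in kJ/mol (A^2 times kJ/mol/A^2); report J/mol
    return float(total) * 1e3


def read_sigma_profile(path, name: str = "") -> SigmaProfile:
    """Read the two-column profile file (sigma_e_per_nm2, area_A2).

    Exactly 61 rows in ascending sigma; an optional header line
    ``# total_area_A2=<value>`` is cross-checked against the column sum.
    """
    declared = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "total_area_A2=" in line:
                    declared = float(line.split("total_area_A2=")[1])
                continue
            parts = line.replace(",", " ").split()
            rows.append((float(parts[0]), float(parts[1])))
    if len(rows) != N_BINS:
        raise ValueError(f"expected {N_BINS} rows, got {len(rows)}")
    sig = np.array([r[0] for r in rows])
    if not np.allclose(sig, SIGMA_GRID, atol=1e-9):
        raise ValueError("sigma column does not match the -3..3 (0.1) grid")
    areas = np.array([r[1] for r in rows])
    prof = SigmaProfile(area_per_bin=areas, name=name or str(path))
    if declared is not None and not math.isclose(
        declared, prof.total_area, rel_tol=1e-6, abs_tol=1e-9
    ):
        raise ValueError(
            f"declared total area {declared} != column sum {prof.total_area}"
        )
    return prof


def write_sigma_profile(profile: SigmaProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# total_area_A2={profile.total_area:.10g}\n")
        for s, a in zip(SIGMA_GRID, profile.area_per_bin):
            fh.write(f"{s:.1f} {a:.10g}\n")
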