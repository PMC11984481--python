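"""Pure-compound translated Peng-Robinson (tc-PR) equation of state.

The pressure-explicit form, written in the *untranslated* volume
``w = v + c`` (``v`` is the physical, translated molar volume)::

    P = R T / (w - b)  -  a(T) / (w (w + b) + b (w - b))

with ``a(T) = a_c * alpha(T/Tc)``.  Two alpha-functions are supported:
Soave (one parameter ``m``) and Twu-91 (three parameters ``L, M, N``).
The volume translation ``c`` shifts every root by a constant and
multiplies the fugacity coefficient by ``exp(-c P / (R T))``; it
improves liquid densities without touching vapour-liquid equilibrium.

Units are SI throughout: K, Pa, m^3/mol, Pa·m^6/mol^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import R, OMEGA_A, OMEGA_B

__all__ = [
    "AlphaKind",
    "Phase",
    "PureComponent",
    "EosVolumeSolution",
    "alpha_soave",
    "alpha_twu",
    "attractive_a",
    "solve_volumes",
    "pure_fugacity_coeff",
    "saturation_pressure",
    "derive_soave_m",
    "derive_tc_pc",
    "derive_omega",
    "translation_from_correlation",
    "soave_m_from_omega",
    "twu_generalized",
    "load_component_table",
    "save_component_table",
]

SQRT2 = math.sqrt(2.0)

#: Peng & Robinson (1976) correlation m(omega).
PR76 = (0.37464, 1.54226, -0.26992)


class AlphaKind(str, Enum):
    SOAVE = "soave"
    TWU91 = "twu91"


class Phase(str, Enum):
    LIQUID = "liquid"
    VAPOR = "vapor"
    UNSTABLE = "unstable"


def alpha_soave(tr: float, m: float) -> float:
    """Soave alpha-function ``[1 + m (1 - sqrt(Tr))]^2``.

    Equals 1 at ``Tr = 1`` and ``(1+m)^2`` in the ``Tr -> 0`` limit (the
    latter is what the group-contribution parameter ``a_0`` encodes).
    """
    if tr <= 0:
        raise ValueError(f"reduced temperature must be positive, got {tr}")
    return (1.0 + m * (1.0 - math.sqrt(tr))) ** 2


def alpha_twu(tr: float, L: float, M: float, N: float) -> float:
    """Twu-91 alpha-function ``Tr^(N(M-1)) * exp(L (1 - Tr^(M N)))``."""
    if tr <= 0:
        raise ValueError(f"reduced temperature must be positive, got {tr}")
    return tr ** (N * (M - 1.0)) * math.exp(L * (1.0 - tr ** (M * N)))


def soave_m_from_omega(omega: float) -> float:
    """Peng-Robinson 1976 correlation for the Soave shape parameter."""
    c0, c1, c2 = PR76
    return c0 + c1 * omega + c2 * omega * omega


def twu_generalized(omega: float) -> tuple[float, float, float]:
    """Generalized Twu-91 parameters (L, M, N) for the PR EoS.

    Acentric-factor correlations for compounds without fitted Twu
    parameters; N is fixed at 2.  Consistent with the Soave-1976 alpha
    to a few tenths of a percent over ordinary omega values.
    """
    L = 0.1290 * omega**2 + 0.6039 * omega + 0.0877
    M = 0.1760 * omega**2 - 0.2600 * omega + 0.8884
    return L, M, 2.0


@dataclass
class PureComponent:
    """Pure-compound tc-PR parameter bundle.

    Either construct directly (all parameters known) or via
    :meth:`from_critical` (from ``Tc, Pc, omega``) /
    :meth:`from_gc` (from group-contribution ``a_c, b, a_0``).
    """

    name: str
    tc: float                      # K
    pc: float                      # Pa
    omega: float
    alpha_kind: AlphaKind = AlphaKind.SOAVE
    soave_m: Optional[float] = None
    twu_L: Optional[float] = None
    twu_M: Optional[float] = None
    twu_N: Optional[float] = None
    a_c: float = field(default=0.0)     # Pa m^6 mol^-2
    b: float = field(default=0.0)       # m^3 mol^-1
    c: float = 0.0                      # m^3 mol^-1 (volume translation)
    source: str = "experimental"

    def __post_init__(self) -> None:
        if self.tc <= 0 or self.pc <= 0:
            raise ValueError(f"{self.name}: Tc and Pc must be positive")
        if self.source == "ideal":
            # degenerate perfect-gas limit (a = b = c = 0): used to check
            # that every reduction collapses to v = RT/P and ln phi = 0
            self.alpha_kind = AlphaKind(self.alpha_kind)
            if self.soave_m is None:
                self.soave_m = 0.0
            return
        if self.a_c == 0.0:
            self.a_c = OMEGA_A * R**2 * self.tc**2 / self.pc
        if self.b == 0.0:
            self.b = OMEGA_B * R * self.tc / self.pc
        if self.a_c <= 0 or self.b <= 0:
            raise ValueError(f"{self.name}: a_c and b must be positive")
        self.alpha_kind = AlphaKind(self.alpha_kind)
        if self.alpha_kind is AlphaKind.SOAVE and self.soave_m is None:
            raise ValueError(f"{self.name}: soave_m required for Soave alpha")
        if self.alpha_kind is AlphaKind.TWU91 and None in (
            self.twu_L, self.twu_M, self.twu_N
        ):
            raise ValueError(f"{self.name}: twu_L/M/N required for Twu-91 alpha")
        if self.source == "experimental":
            ac_cr = OMEGA_A * R**2 * self.tc**2 / self.pc
            b_cr = OMEGA_B * R * self.tc / self.pc
            if (
                abs(self.a_c - ac_cr) / ac_cr > 1e-10
                or abs(self.b - b_cr) / b_cr > 1e-10
            ):
                raise ValueError(
                    f"{self.name}: (a_c, b) inconsistent with (Tc, Pc) "
                    "through the PR critical relations"
                )

    # -- constructors -------------------------------------------------

    @classmethod
    def ideal_gas(cls, name: str = "ideal") -> "PureComponent":
        """Perfect-gas degenerate component (a_c = b = c = 0)."""
        return cls(name=name, tc=1.0, pc=1.0, omega=0.0, soave_m=0.0,
                   source="ideal")

    @classmethod
    def from_critical(
        cls,
        name: str,
        tc: float,
        pc: float,
        omega: float,
        alpha_kind: AlphaKind | str = AlphaKind.SOAVE,
        twu: Optional[tuple[float, float, float]] = None,
        c: Optional[float] = None,
        generalized_twu: bool = False,
    ) -> "PureComponent":
        """Build from critical constants and the acentric factor.

        ``c=None`` uses the generalized translation correlation;
        pass ``c=0.0`` explicitly to disable translation.
        """
        alpha_kind = AlphaKind(alpha_kind)
        kw: dict = {}
        if alpha_kind is AlphaKind.SOAVE:
            kw["soave_m"] = soave_m_from_omega(omega)
        else:
            if twu is None:
                if not generalized_twu:
                    raise ValueError(
                        "Twu parameters missing; pass twu=(L,M,N) or "
                        "generalized_twu=True"
                    )
                twu = twu_generalized(omega)
            kw["twu_L"], kw["twu_M"], kw["twu_N"] = twu
        if c is None:
            c = translation_from_correlation(tc, pc, omega)
        return cls(
            name=name, tc=tc, pc=pc, omega=omega, alpha_kind=alpha_kind,
            c=c, source="experimental", **kw,
        )

    @classmethod
    def from_gc(
        cls, name: str, a_c: float, b: float, a_0: float
    ) -> "PureComponent":
        """Build from group-contribution predictions (a_c, b, a_0).

        Chains ``m = sqrt(a_0/a_c) - 1``, the PR critical relations for
        (Tc, Pc), the inverted 1976 correlation for omega, and the
        dilute-solute policy ``c = 0``.
        """
        m = derive_soave_m(a_c, a_0)
        tc, pc = derive_tc_pc(a_c, b)
        omega = derive_omega(m)
        return cls(
            name=name, tc=tc, pc=pc, omega=omega,
            alpha_kind=AlphaKind.SOAVE, soave_m=m,
            a_c=a_c, b=b, c=0.0, source="gc",
        )

    # -- behaviour ----------------------------------------------------

    def alpha(self, t: float) -> float:
        tr = t / self.tc
        if self.alpha_kind is AlphaKind.SOAVE:
            return alpha_soave(tr, self.soave_m)
        return alpha_twu(tr, self.twu_L, self.twu_M, self.twu_N)

    def a(self, t: float) -> float:
        """Attractive parameter a(T) = a_c * alpha(T/Tc)."""
        return attractive_a(self, t)


def attractive_a(component: PureComponent, t: float) -> float:
    """Temperature-dependent attractive parameter, Pa m^6 mol^-2."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    return component.a_c * component.alpha(t)


@dataclass
class EosVolumeSolution:
    """Real roots of the translated PR pressure equation at (T, P)."""

    temperature: float
    pressure: float
    volumes: np.ndarray          # translated molar volumes, ascending
    phase_labels: list[Phase]

    def volume(self, phase: Phase | str) -> float:
        phase = Phase(phase)
        for v, lab in zip(self.volumes, self.phase_labels):
            if lab is phase:
                return float(v)
        raise ValueError(
            f"no {phase.value} root at T={self.temperature} K, "
            f"P={self.pressure} Pa"
        )

    @property
    def has_liquid(self) -> bool:
        return Phase.LIQUID in self.phase_labels

    @property
    def has_vapor(self) -> bool:
        return Phase.VAPOR in self.phase_labels


def _dp_dw(w: float, t: float, a: float, b: float) -> float:
    """dP/dw of the untranslated PR pressure equation."""
    denom = w * (w + b) + b * (w - b)
    return -R * t / (w - b) ** 2 + a * (2.0 * w + 2.0 * b) / denom**2


def solve_volumes(
    t: float, p: float, a: float, b: float, c: float = 0.0
) -> EosVolumeSolution:
    """All real molar-volume roots of the translated PR EoS at (t, p).

    Solves the untranslated cubic in ``w``, keeps roots with ``w > b``,
    classifies them by mechanical stability (``dP/dw < 0``: smallest is
    liquid, largest vapor, middle unstable), then applies the constant
    shift ``v = w - c``.
    """
    if t <= 0 or p <= 0:
        raise ValueError("t and p must be positive")
    if b < 0:
        raise ValueError("covolume must be non-negative")
    if a == 0.0 and b == 0.0:
        w = np.array([R * t / p])
    else:
        A = a * p / (R * t) ** 2
        B = b * p / (R * t)
        # compressibility cubic: Z^3 - (1-B) Z^2 + (A - 3B^2 - 2B) Z
        #                        - (A B - B^2 - B^3) = 0
        z = np.roots(
            [1.0, -(1.0 - B), A - 3.0 * B**2 - 2.0 * B,
             -(A * B - B**2 - B**3)]
        )
        z = z[np.abs(z.imag) < 1e-10 * np.maximum(1.0, np.abs(z.real))].real
        w = np.sort(z) * R * t / p
        w = w[w > b * (1.0 + 1e-12)]
    if w.size == 0:
        raise RuntimeError(
            f"no physical volume root at T={t} K, P={p} Pa (all below covolume)"
        )
    if w.size == 1:
        slope = _dp_dw(float(w[0]), t, a, b)
        # single root: call it liquid if clearly denser than ~RT/3P,
        # vapor otherwise; it is the only stable phase either way.
        lab = Phase.LIQUID if w[0] < R * t / (3.0 * p) else Phase.VAPOR
        labels = [lab if slope < 0 else Phase.UNSTABLE]
    else:
        labels = [Phase.UNSTABLE] * w.size
        labels[0] = Phase.LIQUID
        labels[-1] = Phase.VAPOR
    return EosVolumeSolution(
        temperature=t, pressure=p, volumes=w - c, phase_labels=labels
    )


def _ln_phi_untranslated(w: float, t: float, p: float, a: float, b: float) -> float:
    """Closed-form PR fugacity coefficient at an untranslated root w."""
    z = p * w / (R * t)
    if a == 0.0 and b == 0.0:
        return 0.0
    B = b * p / (R * t)
    A = a * p / (R * t) ** 2
    if b == 0.0:
        # b -> 0 limit of the attraction term: -A/Z... use series:
        # ln phi = Z - 1 - ln Z - a p/(R T)^2 / Z
        return z - 1.0 - math.log(z) - A / z
    return (
        z - 1.0
        - math.log(z - B)
        - A / (2.0 * SQRT2 * B)
        * math.log((z + (1.0 + SQRT2) * B) / (z + (1.0 - SQRT2) * B))
    )


def pure_fugacity_coeff(
    component: PureComponent, t: float, p: float, phase: Phase | str
) -> float:
    """ln(phi) of a pure compound at the requested phase root.

    Includes the translation factor ``-c P / (R T)``, which cancels in
    liquid/vapour *ratios* and therefore leaves phase equilibrium
    untouched.
    """
    a = attractive_a(component, t)
    sol = solve_volumes(t, p, a, component.b, component.c)
    v = sol.volume(phase)
    w = v + component.c
    return (
        _ln_phi_untranslated(w, t, p, a, component.b)
        - component.c * p / (R * t)
    )


def _spinodal_window(t: float, a: float, b: float) -> Optional[tuple[float, float]]:
    """Pressure window (P_lo, P_hi) in which three roots can coexist.

    The window is bounded by the local extrema of the isotherm P(w):
    dP/dw = 0.  Returns None if the isotherm is monotone (T >= Tc-like).
    """
    # dP/dw = 0  <=>  R T (w^2 + 2 b w - b^2)^2 = a * 2 (w + b) (w - b)^2
    # Solve numerically on a dense log grid in w.
    w = b * (1.0 + np.logspace(-6, 8, 4000))
    dp = np.array([_dp_dw(float(x), t, a, b) for x in w])
    sign = np.sign(dp)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size < 2:
        return None

    from scipy.optimize import brentq

    extrema = [
        brentq(_dp_dw, float(w[i]), float(w[i + 1]), args=(t, a, b),
               xtol=1e-300, rtol=1e-14)
        for i in idx[:2]
    ]

    def pres(x: float) -> float:
        return R * t / (x - b) - a / (x * (x + b) + b * (x - b))

    p_at = sorted(pres(x) for x in extrema)
    return p_at[0], p_at[1]


def saturation_pressure(component: PureComponent, t: float) -> float:
    """Vapour pressure from equality of liquid and vapour fugacities.

    Brackets the root inside the spinodal pressure window, bisects the
    sign change of ``ln(phi_L) - ln(phi_V)`` and polishes with Newton
    steps using the exact derivative ``(v_L - v_V)/(R T)``.  Converges
    to a relative residual below 1e-10.
    """
    if t >= component.tc:
        raise ValueError(
            f"{component.name}: T={t} K is not below Tc={component.tc} K"
        )
    a = attractive_a(component, t)
    b = component.b
    window = _spinodal_window(t, a, b)
    if window is None:
        raise RuntimeError(f"{component.name}: isotherm monotone at T={t} K")
    p_lo = max(window[0], 1e-300)
    p_hi = window[1]
    if p_hi <= p_lo:
        raise RuntimeError(f"{component.name}: cannot bracket Psat at T={t} K")

    def resid(p: float) -> float:
        sol = solve_volumes(t, p, a, b, 0.0)
        wl = sol.volume(Phase.LIQUID)
        wv = sol.volume(Phase.VAPOR)
        return (
            _ln_phi_untranslated(wl, t, p, a, b)
            - _ln_phi_untranslated(wv, t, p, a, b)
        )

    # nudge inside the window so both roots exist
    span = p_hi - p_lo
    lo, hi = p_lo + 1e-9 * span, p_hi - 1e-9 * span
    f_lo, f_hi = resid(lo), resid(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"{component.name}: fugacity residual does not change sign in "
            f"({lo:.6g}, {hi:.6g}) Pa at T={t} K"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = resid(mid)
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
        if hi - lo < 1e-13 * mid:
            break
    p = 0.5 * (lo + hi)
    # Newton polish: d(ln phiL - ln phiV)/dP = (wL - wV)/(R T)
    for _ in range(50):
        sol = solve_volumes(t, p, a, b, 0.0)
        if not (sol.has_liquid and sol.has_vapor):
            break
        wl, wv = sol.volume(Phase.LIQUID), sol.volume(Phase.VAPOR)
        f = (
            _ln_phi_untranslated(wl, t, p, a, b)
            - _ln_phi_untranslated(wv, t, p, a, b)
        )
        step = -f * R * t / (wl - wv)
        p_new = p + step
        if not (p_lo < p_new < p_hi):
            break
        p = p_new
        if abs(f) < 1e-12:
            break
    return float(p)


def derive_soave_m(a_c: float, a_0: float) -> float:
    """Soave shape parameter from a_c and the T->0 attraction a_0.

    The Soave alpha tends to ``(1+m)^2`` as ``T -> 0``, hence
    ``m = sqrt(a_0/a_c) - 1``.
    """
    if a_c <= 0:
        raise ValueError("a_c must be positive")
    if a_0 < a_c:
        raise ValueError(
            f"a_0 ({a_0}) < a_c ({a_c}): would give negative m; "
            "species must be flagged, not clamped"
        )
    return math.sqrt(a_0 / a_c) - 1.0


def derive_tc_pc(a_c: float, b: float) -> tuple[float, float]:
    """Invert the PR critical relations: (a_c, b) -> (Tc, Pc)."""
    if a_c <= 0 or b <= 0:
        raise ValueError("a_c and b must be positive")
    tc = (OMEGA_B / OMEGA_A) * a_c / (R * b)
    pc = OMEGA_B * R * tc / b
    return tc, pc


def derive_omega(m: float) -> float:
    """Invert the 1976 PR correlation m(omega) on the physical branch.

    Takes the smaller quadratic root (the branch through omega=0 at
    m=0.37464); warns outside [-0.5, 1.5].
    """
    c0, c1, c2 = PR76
    disc = c1 * c1 - 4.0 * c2 * (c0 - m)
    if disc < 0:
        raise ValueError(f"m={m} outside the invertible range of the correlation")
    omega = (-c1 + math.sqrt(disc)) / (2.0 * c2)
    if not (-0.5 <= omega <= 1.5):
        warnings.warn(
            f"derived acentric factor {omega:.4f} outside [-0.5, 1.5]",
            stacklevel=2,
        )
    return omega


def translation_from_correlation(tc: float, pc: float, omega: float) -> float:
    """Generalized Peneloux-type volume translation for the PR EoS.

    ``c = 0.50033 (R Tc / Pc) (0.25969 - Z_RA)`` with the
    Rackett compressibility ``Z_RA = 0.29056 - 0.08775 omega``;
    m^3/mol, linear in ``R Tc / Pc`` at fixed omega.
    """
    if tc <= 0 or pc <= 0:
        raise ValueError("tc and pc must be positive")
    z_ra = 0.29056 - 0.08775 * omega
    return 0.50033 * (R * tc / pc) * (0.25969 - z_ra)


# -- component table I/O ---------------------------------------------

_TABLE_COLS = [
    "name", "tc_K", "pc_Pa", "omega", "alpha_kind",
    "soave_m", "twu_L", "twu_M", "twu_N", "c_m3mol", "source",
]


def save_component_table(
    components: Sequence[PureComponent], path_or_buf
) -> None:
    rows = []
    for comp in components:
        rows.append({
            "name": comp.name, "tc_K": comp.tc, "pc_Pa": comp.pc,
            "omega": comp.omega, "alpha_kind": comp.alpha_kind.value,
            "soave_m": comp.soave_m, "twu_L": comp.twu_L,
            "twu_M": comp.twu_M, "twu_N": comp.twu_N,
            "c_m3mol": comp.c, "source": comp.source,
        })
    pd.DataFrame(rows, columns=_TABLE_COLS).to_csv(path_or_buf, index=False)


def load_component_table(path_or_buf) -> list[PureComponent]:
    """Read the pure-component CSV (header per the documented schema)."""
    df = pd.read_csv(path_or_buf)
    missing = set(_TABLE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"component table missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        kind = AlphaKind(r["alpha_kind"])
        kw: dict = {}
        if kind is AlphaKind.SOAVE:
            kw["soave_m"] = float(r["soave_m"])
        else:
            kw["twu_L"] = float(r["twu_L"])
            kw["twu_M"] = float(r["twu_M"])
            kw["twu_N"] = float(r["twu_N"])
        out.append(PureComponent(
            name=str(r["name"]), tc=float(r["tc_K"]), pc=float(r["pc_Pa"]),
            omega=float(r["omega"]), alpha_kind=kind,
            c=float(r["c_m3mol"]), source=str(r["source"]), **kw,
        ))
    return out
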