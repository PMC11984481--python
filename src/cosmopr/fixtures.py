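"""Seeded synthetic-data generators.

Everything downstream of the quantum-chemistry and database inputs can
be exercised without downloads: Gaussian-mixture sigma-profiles stand
in for COSMO cavities, planted group-parameter tables generate exactly
additive GC datasets, and the full model generates its own solvation
reference records.  Every generator is a pure function of its spec
(seeded numpy Generator, no global state), so identical specs give
bit-identical output.

These profiles emulate the shape of real sigma-profiles (smooth
multimodal histograms, areas of tens to hundreds of A^2, hydroxyl-like
mass beyond the hydrogen-bond cutoff) but none of their quantum-level
fine structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cosmors import N_BINS, SIGMA_GRID, SigmaProfile
from .eos import PureComponent
from .groups import Decomposition, GroupParameterTable

__all__ = [
    "synthetic_sigma_profile",
    "synthetic_gc_dataset",
    "synthetic_solvation_dataset",
    "toy_components",
    "SolvationRecord",
]


def synthetic_sigma_profile(
    seed: int,
    preset: str = "generic",
    total_area: Optional[float] = None,
    name: str = "",
) -> SigmaProfile:
    """Random Gaussian-mixture sigma-profile on the 61-node grid.

    Presets: ``generic`` (1-4 Gaussians anywhere on the grid),
    ``alkane`` (apolar: all mass within \\|sigma\\| <= 1.1 e/nm^2, so no
    hydrogen-bond-active segments exist), ``hydroxyl`` (adds donor and
    acceptor mass beyond the +-1.1 e/nm^2 cutoff).  Total areas fall in
    [50, 500] A^2.
    """
    rng = np.random.default_rng(seed)
    if total_area is None:
        total_area = float(rng.uniform(80.0, 400.0))
    if not 50.0 <= total_area <= 500.0:
        raise ValueError("total_area must lie in [50, 500] A^2")
    bins = np.zeros(N_BINS)

    def add_gauss(center: float, width: float, weight: float) -> None:
        nonlocal bins
        bins = bins + weight * np.exp(
            -0.5 * ((SIGMA_GRID - center) / width) ** 2
        )

    if preset == "alkane":
        for _ in range(rng.integers(1, 3)):
            add_gauss(rng.uniform(-0.6, 0.6), rng.uniform(0.15, 0.3),
                      rng.uniform(0.5, 1.0))
        bins[np.abs(SIGMA_GRID) > 1.1] = 0.0
    elif preset == "hydroxyl":
        add_gauss(rng.uniform(-0.5, 0.5), rng.uniform(0.2, 0.4), 1.0)
        add_gauss(rng.uniform(-2.2, -1.5), rng.uniform(0.15, 0.3),
                  rng.uniform(0.15, 0.35))       # polar H: donor, sigma < -s_hb
        add_gauss(rng.uniform(1.5, 2.2), rng.uniform(0.15, 0.3),
                  rng.uniform(0.15, 0.35))       # lone pairs: acceptor side
    elif preset == "generic":
        for _ in range(rng.integers(1, 5)):
            add_gauss(rng.uniform(-2.0, 2.0), rng.uniform(0.15, 0.5),
                      rng.uniform(0.3, 1.0))
    else:
        raise ValueError(f"unknown preset {preset!r}")
    bins = np.clip(bins, 0.0, None)
    bins *= total_area / bins.sum()
    return SigmaProfile(
        area_per_bin=bins, name=name or f"{preset}-{seed}"
    )


def _random_table(
    rng: np.random.Generator, group_ids: Sequence[str]
) -> GroupParameterTable:
    """Planted parameter table with physically plausible magnitudes."""
    n = len(group_ids)
    # per-group contributions sized like real CH2/CH3-type groups, so
    # that species of 1-20 occurrences give a_c ~ O(1) Pa m6/mol2,
    # b ~ O(1e-4) m3/mol and a Soave m inside the invertible range of
    # the omega correlation
    a_c = rng.uniform(0.28, 0.38, n)         # additive in a_c^0.67
    b = rng.uniform(0.9e-4, 1.4e-4, n)       # additive in b^0.80
    a_0 = rng.uniform(0.50, 0.60, n)         # additive in a_0^0.48
    p_sigma = np.zeros((n, N_BINS))
    for k in range(n):
        prof = synthetic_sigma_profile(
            int(rng.integers(0, 2**31 - 1)), "generic", total_area=50.0
        )
        p_sigma[k] = prof.area_per_bin
    return GroupParameterTable.from_arrays(group_ids, a_c, b, a_0, p_sigma)


def synthetic_gc_dataset(
    seed: int,
    n_species: int = 60,
    group_ids: Optional[Sequence[str]] = None,
    noise: float = 0.0,
) -> tuple[dict[str, dict[str, float]], dict[str, Decomposition],
           GroupParameterTable]:
    """Exactly additive GC dataset from a planted table.

    Returns ``(records, decomps, true_table)``: per-species property
    values {a_c, b, a_0, sigma (61-vector)} computed from the planted
    table (additive in the transformed domain) plus i.i.d. Gaussian
    noise of relative scale ``noise`` in that same domain.
    """
    rng = np.random.default_rng(seed)
    if group_ids is None:
        group_ids = [f"g{k}" for k in range(8)]
    table = _random_table(rng, group_ids)
    records: dict[str, dict] = {}
    decomps: dict[str, Decomposition] = {}
    for s in range(n_species):
        counts = {}
        n_groups = rng.integers(1, min(5, len(group_ids)) + 1)
        chosen = rng.choice(len(group_ids), size=n_groups, replace=False)
        for gi in chosen:
            counts[group_ids[gi]] = int(rng.integers(1, 5))
        name = f"species_{s}"
        decomp = Decomposition(counts=counts, species=name)
        decomps[name] = decomp
        rec: dict = {}
        for which in ("a_c", "b", "a_0"):
            tsum = sum(
                n * table.contribution(g, which) for g, n in counts.items()
            )
            tsum *= 1.0 + noise * rng.standard_normal()
            rec[which] = max(tsum, 1e-12) ** (1.0 / table.betas[which])
        sig = np.zeros(N_BINS)
        for g, n in counts.items():
            sig += n * table.sigma_row(g)
        sig = sig * (1.0 + noise * rng.standard_normal(N_BINS))
        rec["sigma"] = np.clip(sig, 0.0, None)
        records[name] = rec
    return records, decomps, table


@dataclass
class SolvationRecord:
    """One (solute, solvent, T) solvation free energy reference point."""

    solute_id: str
    solvent_id: str
    temperature: float           # K
    dg_solv_ref: float           # kcal/mol
    source: str = "synthetic"
    solute_class: str = "closed_shell"
    bac: Optional[int] = None


def toy_components(
    seed: int, n: int = 6
) -> list[tuple[PureComponent, SigmaProfile]]:
    """Random but physically sensible (component, profile) pairs."""
    rng = np.random.default_rng(seed)
    out = []
    presets = ["alkane", "generic", "hydroxyl"]
    for k in range(n):
        tc = float(rng.uniform(400.0, 650.0))
        pc = float(rng.uniform(2.0e6, 5.0e6))
        omega = float(rng.uniform(0.05, 0.6))
        comp = PureComponent.from_critical(
            f"toy{k}", tc, pc, omega, alpha_kind="soave"
        )
        prof = synthetic_sigma_profile(
            int(rng.integers(0, 2**31 - 1)), presets[k % 3],
            name=f"toy{k}",
        )
        out.append((comp, prof))
    return out


def synthetic_solvation_dataset(
    seed: int,
    table: GroupParameterTable,
    decomps: dict[str, Decomposition],
    solvents: Sequence[tuple[PureComponent, SigmaProfile]],
    n_records: int = 50,
    t_range: tuple[float, float] = (298.0, 398.0),
    n_isotherms: int = 5,
    noise_kcal: float = 0.0,
) -> list[SolvationRecord]:
    """Solvation reference records computed by the full model itself.

    Samples (solute, solvent, T) triples — temperatures from
    ``n_isotherms`` evenly spaced isotherms spanning ``t_range``, the
    way benchmark compilations are measured — parametrizes each solute
    from the given table, evaluates the EoS at the solvent vapour
    pressure and optionally perturbs the result with Gaussian noise
    (kcal/mol).  Records are tagged ``source='synthetic'``.
    """
    from .groups import parametrize_solute
    from .solvation import solvation_free_energy

    rng = np.random.default_rng(seed)
    solute_ids = sorted(decomps)
    isotherms = np.linspace(*t_range, n_isotherms)
    records = []
    cache: dict[str, tuple] = {}
    for _ in range(n_records):
        sid = solute_ids[int(rng.integers(0, len(solute_ids)))]
        sv = int(rng.integers(0, len(solvents)))
        t = float(isotherms[int(rng.integers(0, n_isotherms))])
        if sid not in cache:
            cache[sid] = parametrize_solute(decomps[sid], table, name=sid)
        solvent = solvents[sv]
        res = solvation_free_energy(cache[sid], solvent, t)
        dg = res.dg_solv_kcal + noise_kcal * rng.standard_normal()
        records.append(SolvationRecord(
            solute_id=sid, solvent_id=solvent[0].name,
            temperature=t, dg_solv_ref=float(dg),
        ))
    return records
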