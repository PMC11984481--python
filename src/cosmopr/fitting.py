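"""Parameter identification: outlier pruning, GC-LR, GC-NM, metrics.

Two-stage workflow.  GC-LR: after an interquartile-range outlier pass
per chemical family, the group contributions are obtained by ordinary
least squares in the transformed property domain (the domain in which
first-order GC is exactly additive), one regression per EoS property
plus 61 independent regressions for the sigma-profile bins.  GC-NM:
the contributions of a scoped subset of groups (radicals, TS moieties)
are then refined against reference solvation free energies by
Nelder-Mead, minimizing the mean quadratic deviation

    F_obj = (1/N) sum_k (dG_ref,k - dG_EoS,k)^2     [(kcal/mol)^2]

with the GC-LR result as the mandated starting point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cosmors import N_BINS, sigma_potentials, CosmoRsConstants
from .constants import LAMBDA_HV, R, KCAL_PER_KJ
from .eos import Phase, attractive_a, saturation_pressure, solve_volumes
from .fixtures import SolvationRecord
from .groups import (
    Decomposition,
    GroupParameterTable,
    parametrize_solute,
)

__all__ = [
    "iqr_filter",
    "fit_gc_lr",
    "fit_gc_nm",
    "metrics",
    "FitResult",
    "GcLrResult",
]

import math


def iqr_filter(
    values: Sequence[float],
    family_labels: Sequence,
    multiplier: float = 1.5,
    min_family: int = 4,
) -> np.ndarray:
    """Tukey-fence outlier mask, applied independently per family.

    Within each chemical family with at least ``min_family`` members,
    values outside ``[Q1 - k IQR, Q3 + k IQR]`` (linear-interpolation
    quartiles) are flagged False; smaller families pass through
    untouched.  One pass; idempotent because removing interior points
    never widens the fences past the survivors.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(family_labels)
    if values.shape != labels.shape:
        raise ValueError("values and family_labels must align")
    keep = np.ones(values.size, dtype=bool)
    for fam in np.unique(labels):
        idx = np.nonzero(labels == fam)[0]
        if idx.size < min_family:
            continue
        q1, q3 = np.percentile(values[idx], [25.0, 75.0])
        iqr = q3 - q1
        lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
        keep[idx] = (values[idx] >= lo) & (values[idx] <= hi)
    return keep


@dataclass
class GcLrResult:
    table: GroupParameterTable
    diagnostics: pd.DataFrame     # per property: MPE %, R^2

    def __iter__(self):           # allow tuple-unpacking
        return iter((self.table, self.diagnostics))


def _design_matrix(
    decomps: Sequence[Decomposition], group_ids: Sequence[str]
) -> np.ndarray:
    X = np.zeros((len(decomps), len(group_ids)))
    pos = {g: j for j, g in enumerate(group_ids)}
    for i, d in enumerate(decomps):
        for g, n in d.counts.items():
            if g not in pos:
                raise KeyError(f"{d.species}: group {g!r} not being fitted")
            X[i, pos[g]] = n
    return X


def fit_gc_lr(
    records: dict[str, dict],
    decomps: dict[str, Decomposition],
    betas: Optional[dict[str, float]] = None,
) -> GcLrResult:
    """Least-squares group contributions from per-species property data.

    ``records[species]`` holds ``a_c``, ``b``, ``a_0`` (SI) and
    optionally ``sigma`` (61 bin areas, A^2).  Each EoS property is
    regressed in its transformed domain ``prop^beta``; the 61
    sigma-bins are 61 independent least-squares problems sharing one
    design matrix.  Raises on rank deficiency, naming the
    unidentifiable groups.
    """
    from .constants import BETA_AC, BETA_B, BETA_A0

    betas = betas or {"a_c": BETA_AC, "b": BETA_B, "a_0": BETA_A0}
    species = sorted(records)
    dlist = [decomps[s] for s in species]
    group_ids = sorted({g for d in dlist for g in d.counts})
    X = _design_matrix(dlist, group_ids)
    rank = np.linalg.matrix_rank(X)
    if rank < len(group_ids):
        # name groups whose column lies in the span of the others
        _, s, vt = np.linalg.svd(X)
        null = vt[rank:]
        bad = [
            group_ids[j]
            for j in range(len(group_ids))
            if np.abs(null[:, j]).max() > 1e-8
        ]
        raise np.linalg.LinAlgError(
            f"design matrix rank {rank} < {len(group_ids)} groups; "
            f"unidentifiable groups: {bad}"
        )

    diag_rows = []
    sol = {}
    for which in ("a_c", "b", "a_0"):
        y = np.array([records[s][which] for s in species], dtype=float)
        yt = y ** betas[which]
        coef, *_ = np.linalg.lstsq(X, yt, rcond=None)
        sol[which] = coef
        pred = (X @ coef).clip(min=1e-300) ** (1.0 / betas[which])
        diag_rows.append({
            "property": which,
            "mpe_percent": metrics(pred, y, "mpe"),
            "r2": metrics(pred, y, "r2") if y.size >= 2 else np.nan,
        })

    have_sigma = all("sigma" in records[s] for s in species)
    if have_sigma:
        Y = np.stack([np.asarray(records[s]["sigma"]) for s in species])
        p_coef, *_ = np.linalg.lstsq(X, Y, rcond=None)   # 61 regressions
        pred = X @ p_coef
        diag_rows.append({
            "property": "sigma_area",
            "mpe_percent": metrics(
                pred.sum(axis=1), Y.sum(axis=1), "mpe"
            ),
            "r2": metrics(pred.ravel(), Y.ravel(), "r2"),
        })
    else:
        p_coef = np.zeros((len(group_ids), N_BINS))

    table = GroupParameterTable.from_arrays(
        group_ids, sol["a_c"], sol["b"], sol["a_0"], p_coef,
        beta_ac=betas["a_c"], beta_b=betas["b"], beta_a0=betas["a_0"],
    )
    return GcLrResult(table=table, diagnostics=pd.DataFrame(diag_rows))


@dataclass
class FitResult:
    """Outcome of a GC-NM refinement."""

    table: GroupParameterTable
    objective_initial: float     # (kcal/mol)^2
    objective_final: float
    n_iterations: int
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.objective_final > self.objective_initial * (1 + 1e-12):
            raise ValueError("refinement increased the objective")


class _SolvationEvaluator:
    """Fast repeated dG_solv evaluation with per-(solvent, T) caching.

    The solvent side (vapour pressure, liquid root, sigma-potential)
    never changes during a refit, so it is computed once per distinct
    (solvent, T); only the solute side is re-evaluated per trial table.
    """

    def __init__(
        self,
        records: Sequence[SolvationRecord],
        decomps: dict[str, Decomposition],
        solvents: dict[str, tuple],
        constants: CosmoRsConstants = CosmoRsConstants(),
    ) -> None:
        self.records = list(records)
        self.decomps = decomps
        self.constants = constants
        self._solvent_state: dict[tuple[str, float], tuple] = {}
        for rec in self.records:
            key = (rec.solvent_id, rec.temperature)
            if key in self._solvent_state:
                continue
            comp, prof = solvents[rec.solvent_id]
            t = rec.temperature
            p = saturation_pressure(comp, t)
            a_s = attractive_a(comp, t)
            solroots = solve_volumes(t, p, a_s, comp.b, 0.0)
            w = solroots.volume(Phase.LIQUID)
            mu = sigma_potentials(prof, t, constants).mu
            self._solvent_state[key] = (comp, prof, p, w, mu)

    def _solute_digest(self, sid: str, table: GroupParameterTable) -> int:
        """Content hash of the table rows this solute actually uses."""
        parts = []
        for g, n in sorted(self.decomps[sid].counts.items()):
            row = table.frame.loc[g]
            parts.append((g, n, row.drop(labels="category", errors="ignore")
                          .to_numpy(dtype=float).tobytes()))
        return hash(tuple(parts))

    def predict(self, table: GroupParameterTable) -> np.ndarray:
        """dG_solv (kcal/mol) per record under a trial table.

        Solute states are cached across calls keyed by a content hash
        of the relevant table rows: trial tables that leave a solute's
        groups untouched reuse its parametrization and potentials.
        """
        if not hasattr(self, "_mu_cache"):
            self._mu_cache: dict = {}
        out = np.empty(len(self.records))
        sqrt2 = math.sqrt(2.0)
        digests = {
            sid: self._solute_digest(sid, table)
            for sid in {r.solute_id for r in self.records}
        }
        if len(self._mu_cache) > 20000:
            self._mu_cache.clear()
        for k, rec in enumerate(self.records):
            comp_s, prof_s, p, w, mu_s = self._solvent_state[
                (rec.solvent_id, rec.temperature)
            ]
            t = rec.temperature
            key = (rec.solute_id, t, digests[rec.solute_id])
            if key not in self._mu_cache:
                pkey = (rec.solute_id, digests[rec.solute_id])
                if pkey not in self._mu_cache:
                    self._mu_cache[pkey] = parametrize_solute(
                        self.decomps[rec.solute_id], table,
                        name=rec.solute_id,
                    )
                comp_u, prof_u = self._mu_cache[pkey]
                self._mu_cache[key] = (
                    comp_u, prof_u,
                    sigma_potentials(prof_u, t, self.constants).mu,
                )
            comp_u, prof_u, mu_u = self._mu_cache[key]
            lg = float(
                prof_u.total_area * (prof_u.p @ (mu_s - mu_u))
                / (R * 1e-3 * t)
            )
            z = p * w / (R * t)
            B = comp_s.b * p / (R * t)
            d_inf = (
                attractive_a(comp_u, t) / (comp_u.b * R * t) - lg / LAMBDA_HV
            )
            ln_phi = (
                (comp_u.b / comp_s.b) * (z - 1.0)
                - math.log(z - B)
                - d_inf / (2.0 * sqrt2)
                * math.log(
                    (z + (1.0 + sqrt2) * B) / (z + (1.0 - sqrt2) * B)
                )
            )
            v_liq = w - comp_s.c
            dg = R * t * (ln_phi + math.log(p * v_liq / (R * t)))
            out[k] = dg * 1e-3 * KCAL_PER_KJ
        return out

    def objective(self, table: GroupParameterTable) -> float:
        ref = np.array([r.dg_solv_ref for r in self.records])
        return float(np.mean((ref - self.predict(table)) ** 2))


def fit_gc_nm(
    initial: GroupParameterTable,
    records: Sequence[SolvationRecord],
    decomps: dict[str, Decomposition],
    solvents: dict[str, tuple],
    scope: Sequence[str],
    properties: Sequence[str] = ("A_c", "B", "A_0"),
    max_iter: int = 2000,
    ftol: float = 1e-10,
    constants: CosmoRsConstants = CosmoRsConstants(),
) -> FitResult:
    """Nelder-Mead refinement of scoped group contributions.

    Only the ``properties`` columns of the ``scope`` groups move; the
    rest of the table is frozen.  Parameters are scaled to unit
    magnitude before optimization (standard simplex coefficients
    1, 2, 0.5, 0.5); convergence when the simplex objective spread
    falls below ``ftol`` (kcal/mol)^2 or after ``max_iter`` iterations.
    The returned objective never exceeds the initial one.
    """
    scope = list(scope)
    missing = [g for g in scope if g not in initial]
    if missing:
        raise KeyError(f"scoped groups missing from table: {missing}")
    ev = _SolvationEvaluator(records, decomps, solvents, constants)

    x0 = np.array([
        initial.frame.loc[g, prop] for g in scope for prop in properties
    ], dtype=float)
    scale = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)

    def build(xs: np.ndarray) -> GroupParameterTable:
        tab = initial.copy()
        vals = xs * scale
        k = 0
        for g in scope:
            for prop in properties:
                tab.frame.loc[g, prop] = vals[k]
                k += 1
        return tab

    def fun(xs: np.ndarray) -> float:
        try:
            return ev.objective(build(xs))
        except (ValueError, KeyError, RuntimeError):
            return 1e6      # infeasible trial point (e.g. a_0 < a_c)

    f0 = fun(x0 / scale)
    if not np.isfinite(f0):
        raise ValueError("objective non-finite at the starting table")

    res = minimize(
        fun, x0 / scale, method="Nelder-Mead",
        options={
            "maxiter": max_iter, "fatol": ftol, "xatol": 1e-10,
            "initial_simplex": None,
        },
    )
    # monotone acceptance: NM never reports worse than the start,
    # but guard against pathological returns anyway
    if res.fun <= f0:
        best_x, best_f = res.x, float(res.fun)
    else:
        best_x, best_f = x0 / scale, f0
    table = build(best_x)
    pred = ev.predict(table)
    ref = np.array([r.dg_solv_ref for r in records])
    diag = pd.DataFrame([{
        "n_records": len(records),
        "mue_kcal": metrics(pred, ref, "mue"),
        "mpe_percent": metrics(pred, ref, "mpe"),
        "r2": metrics(pred, ref, "r2"),
    }])
    return FitResult(
        table=table,
        objective_initial=f0,
        objective_final=best_f,
        n_iterations=int(res.nit),
        diagnostics=diag,
    )


def metrics(pred, ref, kind: str) -> float:
    """MUE, signed MPE (%) or R^2 between predictions and references.

    MPE excludes (with a warning) reference entries equal to zero.
    R^2 of a constant predictor on varying references is <= 0, which is
    returned as-is.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.size == 0:
        raise ValueError("pred and ref must be equal-length, non-empty")
    if kind == "mue":
        return float(np.mean(np.abs(pred - ref)))
    if kind == "mpe":
        mask = ref != 0
        if not mask.all():
            warnings.warn(
                f"MPE: excluded {int((~mask).sum())} zero-reference entries",
                stacklevel=2,
            )
        if not mask.any():
            raise ValueError("MPE undefined: all references are zero")
        return float(np.mean(100.0 * (pred[mask] - ref[mask]) / ref[mask]))
    if kind == "r2":
        if pred.size < 2:
            raise ValueError("R^2 needs at least 2 points")
        ss_res = float(np.sum((ref - pred) ** 2))
        ss_tot = float(np.sum((ref - ref.mean()) ** 2))
        if ss_tot == 0.0:
            return 1.0 if ss_res == 0.0 else -np.inf
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown metric {kind!r}")
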