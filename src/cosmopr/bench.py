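"""Dataset ingestion, association classification and benchmark runner.

Solvent/solute pairs are classified by the hydrogen-bond association
pattern they can form.  Compounds fall in four classes:

* NA — nonassociating, nonpolar (alkanes)
* HA — hydrogen-acceptor, polar but nonassociating (ketones,
  aldehydes, ethers)
* HD — hydrogen-donor, polar but nonassociating (di-/trihalogenated
  compounds)
* SA — self-associating (water, alcohols, carboxylic acids)

The pair (solvent class, solute class) maps to a Binary Association
Code, BAC 1-9: 1-4 no association, 5 self-association only, 6
cross-association only, 7-9 cross plus self.  The benchmark runner
evaluates the model's infinite-dilution solvation free energies
against reference records at the solvent vapour pressure and
aggregates mean unsigned errors by BAC, solvent and temperature band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fixtures import SolvationRecord
from .solvation import solvation_free_energy

__all__ = [
    "AssociationClass",
    "ScenarioConfig",
    "classify_association",
    "assign_bac",
    "load_reference_dataset",
    "save_reference_dataset",
    "run_benchmark",
    "BenchmarkReport",
    "TEMPERATURE_BANDS",
]


class AssociationClass(str, Enum):
    NA = "NA"
    HA = "HA"
    HD = "HD"
    SA = "SA"


#: The printed lower-triangle (solvent row, solute column) BAC map.
_BAC_TABLE = {
    ("NA", "NA"): 1,
    ("HA", "NA"): 2,
    ("HD", "NA"): 3,
    ("HA", "HA"): 4,
    ("HD", "HD"): 4,
    ("HD", "HA"): 6,
    ("SA", "NA"): 5,
    ("SA", "HA"): 8,
    ("SA", "HD"): 7,
    ("SA", "SA"): 9,
}

#: Temperature bands (K) for temperature-resolved error aggregation.
TEMPERATURE_BANDS = [(298.0, 323.0), (323.0, 348.0), (348.0, 373.0),
                     (373.0, 398.0)]

_DONOR_SMARTS = ["[OX2H]", "[OX2H2]", "[#6X4;!c][F,Cl,Br,I]"]
_ACCEPTOR_SMARTS = ["[OX1]", "[OX2]"]


def classify_association(
    compound: str,
    donor: Optional[bool] = None,
    acceptor: Optional[bool] = None,
) -> AssociationClass:
    """Association class of a compound from its SMILES (or explicit flags).

    Donor+acceptor -> SA (water, alcohols, acids); acceptor only -> HA
    (ketones, aldehydes, ethers); donor only -> HD (e.g. polyhalogenated
    C-H donors, flagged explicitly since the C/H/O catalogue has no
    halogens); neither -> NA (alkanes and other nonpolars).
    """
    if donor is None or acceptor is None:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(compound)
        if mol is None:
            raise ValueError(
                f"cannot classify {compound!r}: bad SMILES and no flags"
            )
        if donor is None:
            donor = any(
                mol.HasSubstructMatch(Chem.MolFromSmarts(s))
                for s in _DONOR_SMARTS[:2]
            )
            # di-/tri-halogenated C-H acids donate without accepting
            patt = Chem.MolFromSmarts("[CX4H]([F,Cl,Br,I])[F,Cl,Br,I]")
            donor = donor or mol.HasSubstructMatch(patt)
        if acceptor is None:
            acceptor = any(
                mol.HasSubstructMatch(Chem.MolFromSmarts(s))
                for s in _ACCEPTOR_SMARTS
            )
    if donor and acceptor:
        return AssociationClass.SA
    if acceptor:
        return AssociationClass.HA
    if donor:
        return AssociationClass.HD
    return AssociationClass.NA


def assign_bac(
    solvent: AssociationClass | str,
    solute: AssociationClass | str,
    fold_mirror: bool = True,
) -> int:
    """Binary Association Code (1-9) of a solvent/solute pair.

    The printed table populates a lower triangle; with
    ``fold_mirror=True`` (default) the mirror pairs map to the same
    code, making the function total on all 16 class pairs.
    """
    sv = AssociationClass(solvent).value
    su = AssociationClass(solute).value
    if (sv, su) in _BAC_TABLE:
        return _BAC_TABLE[(sv, su)]
    if fold_mirror and (su, sv) in _BAC_TABLE:
        return _BAC_TABLE[(su, sv)]
    raise KeyError(f"no BAC defined for solvent={sv}, solute={su}")


@dataclass
class ScenarioConfig:
    """Input-provenance scenario for solute parametrization.

    The four combinations of (EoS inputs, sigma-profile source) define
    scenarios 1-4: experimental/qm is the most accurate, gc/gc the
    fully predictive one.  Solvents always use experimental inputs and
    qm profiles.
    """

    solute_pr_inputs: str = "gc"     # experimental | gc
    solute_sigma: str = "gc"         # qm | gc

    def __post_init__(self) -> None:
        if self.solute_pr_inputs not in ("experimental", "gc"):
            raise ValueError("solute_pr_inputs must be experimental|gc")
        if self.solute_sigma not in ("qm", "gc"):
            raise ValueError("solute_sigma must be qm|gc")

    @property
    def number(self) -> int:
        return {
            ("experimental", "qm"): 1,
            ("experimental", "gc"): 2,
            ("gc", "qm"): 3,
            ("gc", "gc"): 4,
        }[(self.solute_pr_inputs, self.solute_sigma)]


_REF_COLS = [
    "solute_id", "solvent_id", "T_K", "dgsolv_kcal", "source",
    "solute_class", "bac",
]

_T_SPAN = {"compsol": (102.0, 653.0), "cosmotherm": (298.0, 398.0),
           "synthetic": (1.0, 1e4)}


def load_reference_dataset(
    path, dialect: str = "csv"
) -> tuple[list[SolvationRecord], pd.DataFrame]:
    """Read reference records; returns (records, rejected-rows frame).

    ``dialect='csv'`` expects the canonical schema; ``'xlsx'`` reads the
    first sheet of a supplementary-style workbook with the same
    columns.  Unparseable or out-of-range rows are collected in the
    second return value, never silently dropped.
    """
    if dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = set(_REF_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"reference file missing columns: {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{path}: empty reference file", stacklevel=2)
        return [], df
    records, bad = [], []
    for i, row in df.iterrows():
        try:
            t = float(row["T_K"])
            dg = float(row["dgsolv_kcal"])
            source = str(row["source"])
            lo, hi = _T_SPAN.get(source, (0.0, np.inf))
            if not lo <= t <= hi:
                raise ValueError(
                    f"T={t} K outside the {source} span [{lo}, {hi}]"
                )
            bac = row["bac"]
            bac = None if pd.isna(bac) or bac == "none" else int(bac)
            if bac is not None and not 1 <= bac <= 9:
                raise ValueError(f"BAC {bac} outside 1..9")
            records.append(SolvationRecord(
                solute_id=str(row["solute_id"]),
                solvent_id=str(row["solvent_id"]),
                temperature=t, dg_solv_ref=dg, source=source,
                solute_class=str(row["solute_class"]), bac=bac,
            ))
        except (ValueError, TypeError) as err:
            bad.append({"row": i, "error": str(err)})
    rejected = pd.DataFrame(bad)
    if len(bad):
        warnings.warn(
            f"{path}: rejected {len(bad)} of {len(df)} rows", stacklevel=2
        )
    return records, rejected


def save_reference_dataset(records: Sequence[SolvationRecord], path) -> None:
    pd.DataFrame([
        {
            "solute_id": r.solute_id, "solvent_id": r.solvent_id,
            "T_K": r.temperature, "dgsolv_kcal": r.dg_solv_ref,
            "source": r.source, "solute_class": r.solute_class,
            "bac": r.bac if r.bac is not None else "none",
        }
        for r in records
    ], columns=_REF_COLS).to_csv(path, index=False)


@dataclass
class BenchmarkReport:
    """Aggregated benchmark errors plus the per-record detail."""

    per_record: pd.DataFrame
    by_bac: pd.DataFrame
    by_solvent: pd.DataFrame
    by_temperature: pd.DataFrame
    mue_total: float
    n_evaluated: int
    n_skipped: int
    skipped: list[str] = field(default_factory=list)
    scenario: Optional[ScenarioConfig] = None


def run_benchmark(
    records: Sequence[SolvationRecord],
    solutes: dict[str, tuple],
    solvents: dict[str, tuple],
    scenario: Optional[ScenarioConfig] = None,
    solutes_alt: Optional[dict[str, dict[str, tuple]]] = None,
) -> BenchmarkReport:
    """Predict every record and aggregate mean unsigned errors.

    ``solutes``/``solvents`` map species ids to (PureComponent,
    SigmaProfile) pairs; ``solutes_alt`` optionally provides
    per-provenance solute inputs keyed ``'experimental'``/``'gc'`` and
    ``'qm'``/``'gc'`` for scenario studies (EoS inputs and profile
    drawn per the scenario).  Records whose solvent or solute inputs
    are missing are skipped and accounted for, never silently lost.
    """
    rows, skipped = [], []
    psat_cache: dict[tuple[str, float], float] = {}
    for rec in records:
        if rec.solvent_id not in solvents:
            skipped.append(f"{rec.solvent_id}: no solvent inputs")
            continue
        solute = _scenario_solute(rec.solute_id, solutes, solutes_alt, scenario)
        if solute is None:
            skipped.append(f"{rec.solute_id}: no solute inputs")
            continue
        solvent = solvents[rec.solvent_id]
        key = (rec.solvent_id, rec.temperature)
        if key not in psat_cache:
            from .eos import saturation_pressure

            psat_cache[key] = saturation_pressure(solvent[0], rec.temperature)
        res = solvation_free_energy(
            solute, solvent, rec.temperature, psat_cache[key]
        )
        band = _band(rec.temperature)
        rows.append({
            "solute_id": rec.solute_id, "solvent_id": rec.solvent_id,
            "T_K": rec.temperature, "bac": rec.bac,
            "solute_class": rec.solute_class,
            "dg_ref_kcal": rec.dg_solv_ref,
            "dg_pred_kcal": res.dg_solv_kcal,
            "abs_err_kcal": abs(res.dg_solv_kcal - rec.dg_solv_ref),
            "t_band": band,
        })
    detail = pd.DataFrame(rows)
    if detail.empty:
        raise ValueError("no record could be evaluated")

    def agg(key: str) -> pd.DataFrame:
        g = detail.groupby(key, dropna=False)["abs_err_kcal"]
        out = g.agg(["mean", "count"]).reset_index()
        return out.rename(columns={"mean": "mue_kcal", "count": "n"})

    return BenchmarkReport(
        per_record=detail,
        by_bac=agg("bac"),
        by_solvent=agg("solvent_id"),
        by_temperature=agg("t_band"),
        mue_total=float(detail["abs_err_kcal"].mean()),
        n_evaluated=len(detail),
        n_skipped=len(skipped),
        skipped=skipped,
        scenario=scenario,
    )


def _band(t: float) -> str:
    for lo, hi in TEMPERATURE_BANDS:
        if lo <= t < hi or (hi == TEMPERATURE_BANDS[-1][1] and t == hi):
            return f"[{lo:.0f},{hi:.0f})"
    return "outside"


def _scenario_solute(solute_id, solutes, solutes_alt, scenario):
    if scenario is None or solutes_alt is None:
        return solutes.get(solute_id)
    eos_pool = solutes_alt.get(scenario.solute_pr_inputs, {})
    sig_pool = solutes_alt.get(
        {"qm": "qm", "gc": "gc_sigma"}.get(scenario.solute_sigma, "qm"), {}
    )
    if solute_id not in eos_pool or solute_id not in sig_pool:
        return None
    comp = eos_pool[solute_id][0]
    prof = sig_pool[solute_id][1]
    return comp, prof
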