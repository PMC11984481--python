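"""First-order group decomposition and GC property prediction.

Molecules, C/H/O free radicals and H-abstraction transition states are
split into first-order functional groups; each group carries additive
contributions to the EoS parameters and to every bin of the
sigma-profile.  The GC combinations are additive in a transformed
domain::

    a_c^beta_ac = sum_g n_g A_c,[g]        (beta_ac = 0.67)
    b^beta_b    = sum_g n_g B_[g]          (beta_b  = 0.80)
    a_0^beta_a0 = sum_g n_g A_0,[g]        (beta_a0 = 0.48)
    p_i(s_m) A_i = sum_g n_g P_[g](s_m)    (per bin, plain sum)

From (a_c, b, a_0) the full Soave-alpha Peng-Robinson parametrization
follows: m = sqrt(a_0/a_c) - 1, (Tc, Pc) from the PR critical
relations, omega by inverting the 1976 m(omega) correlation, and c = 0
for dilute solutes.

Decomposition is deterministic: substructure patterns are matched
most-specific-first (priority order, ties by catalogue order) with no
atom reuse; whole-molecule groups (e.g. methanol) outrank fragment
groups.  Radical centres are located from the radical-electron count
and typed by their bonding environment; transition states use a
labeled-species syntax because their reacting moiety is not
SMILES-expressible.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .constants import BETA_AC, BETA_B, BETA_A0
from .cosmors import N_BINS, SigmaProfile
from .eos import PureComponent

__all__ = [
    "GroupDef",
    "GroupCatalogue",
    "Decomposition",
    "GroupParameterTable",
    "DecompositionError",
    "default_catalogue",
    "decompose",
    "radical_type",
    "gc_eos_parameter",
    "gc_sigma_profile",
    "parametrize_solute",
]


class DecompositionError(ValueError):
    """Structure cannot be covered by the catalogue's groups."""


@dataclass(frozen=True)
class GroupDef:
    group_id: str
    pattern: str          # SMARTS; empty for code-matched (radical/TS) groups
    category: str         # closed_shell | radical | ts_moiety
    priority: int
    description: str = ""

    @property
    def whole_molecule(self) -> bool:
        return self.group_id.startswith("whole_")


@dataclass
class GroupCatalogue:
    """Ordered collection of group definitions."""

    groups: list[GroupDef]

    def __post_init__(self) -> None:
        ids = [g.group_id for g in self.groups]
        if len(ids) != len(set(ids)):
            raise ValueError("group ids must be unique")

    def __iter__(self):
        return iter(self.groups)

    def __contains__(self, gid: str) -> bool:
        return any(g.group_id == gid for g in self.groups)

    def by_category(self, category: str) -> list[GroupDef]:
        return [g for g in self.groups if g.category == category]

    def matchable(self) -> list[GroupDef]:
        """SMARTS-matched groups, most specific (highest priority) first."""
        pats = [g for g in self.groups if g.pattern]
        return sorted(
            pats, key=lambda g: (-g.priority, self.groups.index(g))
        )

    # CSV round trip: (group_id, pattern, category, priority, description)
    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "group_id": g.group_id, "pattern": g.pattern,
                    "category": g.category, "priority": g.priority,
                    "description": g.description,
                }
                for g in self.groups
            ]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GroupCatalogue":
        df = pd.read_csv(path, keep_default_na=False)
        return cls([
            GroupDef(
                group_id=str(r.group_id), pattern=str(r.pattern),
                category=str(r.category), priority=int(r.priority),
                description=str(r.description),
            )
            for r in df.itertuples()
        ])


#: Table-4 radical taxonomy: group id -> description.
RADICAL_TYPES = {
    "rad_c_primary": "primary carbon radical RCH2.",
    "rad_c_secondary": "secondary carbon radical RCH.R'",
    "rad_c_tertiary": "tertiary carbon radical RC.(R')2",
    "rad_vinyl": "vinyl radical RC=CH.",
    "rad_acetylenic": "acetylenic radical RC#C.",
    "rad_aryl": "aryl radical Ar.",
    "rad_benzyl": "benzyl radical Ar-CH.R",
    "rad_acyl": "acyl radical RC.=O",
    "rad_acyloxyl": "acyloxyl radical RC(=O)O.",
    "rad_hydroxyl": "hydroxyl radical HO.",
    "rad_alkoxyl": "alkoxyl radical RO.",
    "rad_peroxyl": "peroxyl radical ROO.",
}

TS_TYPES = {
    "ts_ro_abstraction": "C..H..O reacting moiety of RH + RO. abstraction",
    "ts_roo_abstraction": "C..H..O-O reacting moiety of RH + ROO. abstraction",
}


def default_catalogue() -> GroupCatalogue:
    """Built-in C/H/O first-order catalogue.

    Fragment groups are SMARTS-matched; whole-molecule groups (prefix
    ``whole_``) only count when the single match covers every heavy
    atom.  Radical and TS-moiety groups carry no SMARTS: their centres
    are located and typed in code from the bonding environment.
    """
    cs = [
        # whole-molecule outliers of congeneric series
        GroupDef("whole_methanol", "[OX2H1][CX4H3]", "closed_shell", 1000,
                 "methanol, whole molecule"),
        GroupDef("whole_water", "[OX2H2]", "closed_shell", 1000,
                 "water, whole molecule"),
        GroupDef("cooh", "[CX3](=[OX1])[OX2H1]", "closed_shell", 60,
                 "carboxylic acid -COOH"),
        GroupDef("ester", "[CX3](=[OX1])[OX2H0]", "closed_shell", 55,
                 "ester -COO-"),
        GroupDef("cho", "[CX3H1]=[OX1]", "closed_shell", 50,
                 "aldehyde -CHO"),
        GroupDef("co", "[CX3H0]=[OX1]", "closed_shell", 45,
                 "ketone >C=O"),
        GroupDef("oh", "[OX2H1]", "closed_shell", 40, "alcohol -OH"),
        GroupDef("o_ether", "[OX2H0]", "closed_shell", 35, "ether -O-"),
        GroupDef("ach", "[cH1]", "closed_shell", 30, "aromatic CH"),
        GroupDef("ac", "[cH0]", "closed_shell", 30, "substituted aromatic C"),
        GroupDef("dch2", "[CX3H2]", "closed_shell", 25, "alkene =CH2"),
        GroupDef("dch", "[CX3H1]", "closed_shell", 25, "alkene =CH-"),
        GroupDef("dc", "[CX3H0]", "closed_shell", 25, "alkene =C<"),
        GroupDef("tch", "[CX2H1]", "closed_shell", 24, "alkyne #CH"),
        GroupDef("tc", "[CX2H0]", "closed_shell", 24, "alkyne #C-"),
        GroupDef("ch3", "[CX4H3]", "closed_shell", 20, "paraffinic CH3"),
        GroupDef("ch2", "[CX4H2]", "closed_shell", 20, "paraffinic CH2"),
        GroupDef("ch", "[CX4H1]", "closed_shell", 20, "paraffinic CH"),
        GroupDef("c_quart", "[CX4H0]", "closed_shell", 20, "quaternary C"),
    ]
    rads = [
        GroupDef(gid, "", "radical", 10, desc)
        for gid, desc in RADICAL_TYPES.items()
    ]
    ts = [
        GroupDef(gid, "", "ts_moiety", 10, desc)
        for gid, desc in TS_TYPES.items()
    ]
    return GroupCatalogue(cs + rads + ts)


@dataclass
class Decomposition:
    """Group occurrence counts covering every heavy atom of a species."""

    counts: dict[str, int]
    residual_atoms: list[int] = field(default_factory=list)
    species: str = ""

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.counts.values()):
            raise ValueError("occurrence counts must be positive")

    @property
    def complete(self) -> bool:
        return not self.residual_atoms


def radical_type(mol: Chem.Mol, atom_idx: int) -> str:
    """Classify a radical centre into the 12-type taxonomy."""
    atom = mol.GetAtomWithIdx(atom_idx)
    nbrs = list(atom.GetNeighbors())
    if atom.GetSymbol() == "O":
        if not nbrs:
            return "rad_hydroxyl"
        o_nbrs = [n for n in nbrs if n.GetSymbol() == "O"]
        if o_nbrs:
            return "rad_peroxyl"
        c = nbrs[0]
        if c.GetSymbol() == "C" and any(
            b.GetBondTypeAsDouble() == 2.0
            and b.GetOtherAtom(c).GetSymbol() == "O"
            for b in c.GetBonds()
        ):
            return "rad_acyloxyl"
        return "rad_alkoxyl"
    if atom.GetSymbol() == "C":
        if atom.GetIsAromatic():
            return "rad_aryl"
        if any(
            b.GetBondTypeAsDouble() == 2.0
            and b.GetOtherAtom(atom).GetSymbol() == "O"
            for b in atom.GetBonds()
        ):
            return "rad_acyl"
        if any(
            b.GetBondTypeAsDouble() == 3.0
            and b.GetOtherAtom(atom).GetSymbol() == "C"
            for b in atom.GetBonds()
        ):
            return "rad_acetylenic"
        if any(
            b.GetBondTypeAsDouble() == 2.0
            and b.GetOtherAtom(atom).GetSymbol() == "C"
            for b in atom.GetBonds()
        ):
            return "rad_vinyl"
        if any(n.GetIsAromatic() for n in nbrs):
            return "rad_benzyl"
        n_c = sum(1 for n in nbrs if n.GetSymbol() == "C")
        if n_c >= 3:
            return "rad_c_tertiary"
        if n_c == 2:
            return "rad_c_secondary"
        return "rad_c_primary"
    raise DecompositionError(
        f"unsupported radical centre element {atom.GetSymbol()}"
    )


def _radical_moiety_atoms(mol: Chem.Mol, atom_idx: int, rtype: str) -> set[int]:
    """Heavy atoms consumed by a radical group."""
    atom = mol.GetAtomWithIdx(atom_idx)
    atoms = {atom_idx}
    if rtype == "rad_peroxyl":
        atoms |= {
            n.GetIdx() for n in atom.GetNeighbors() if n.GetSymbol() == "O"
        }
    elif rtype in ("rad_acyl",):
        for b in atom.GetBonds():
            other = b.GetOtherAtom(atom)
            if b.GetBondTypeAsDouble() == 2.0 and other.GetSymbol() == "O":
                atoms.add(other.GetIdx())
    elif rtype == "rad_acyloxyl":
        c = next(n for n in atom.GetNeighbors() if n.GetSymbol() == "C")
        atoms.add(c.GetIdx())
        for b in c.GetBonds():
            other = b.GetOtherAtom(c)
            if b.GetBondTypeAsDouble() == 2.0 and other.GetSymbol() == "O":
                atoms.add(other.GetIdx())
    return atoms


_TS_RE = re.compile(r"^TS\[(.*)\]$")

#: abstracted-H site class -> paraffinic group removed from R-H
_SITE_GROUP = {"primary": "ch3", "secondary": "ch2", "tertiary": "ch"}


def _parse_ts_label(structure: str) -> dict[str, str]:
    m = _TS_RE.match(structure.strip())
    if not m:
        raise DecompositionError(f"not a TS label: {structure!r}")
    fields: dict[str, str] = {}
    for part in m.group(1).split(";"):
        if not part.strip():
            continue
        key, _, val = part.partition("=")
        fields[key.strip()] = val.strip()
    for req in ("class", "rh", "ro"):
        if req not in fields:
            raise DecompositionError(f"TS label missing field {req!r}")
    if fields["class"] not in ("RO_abstraction", "ROO_abstraction"):
        raise DecompositionError(f"unknown TS class {fields['class']!r}")
    fields.setdefault("site", "primary")
    if fields["site"] not in _SITE_GROUP:
        raise DecompositionError(f"unknown abstraction site {fields['site']!r}")
    return fields


def _decompose_mol(
    mol: Chem.Mol, catalogue: GroupCatalogue, species: str
) -> Decomposition:
    counts: dict[str, int] = {}
    n_heavy = mol.GetNumAtoms()
    assigned = [False] * n_heavy

    # radical centres first: located by electron count, typed in code
    for atom in mol.GetAtoms():
        if atom.GetNumRadicalElectrons() > 0:
            rtype = radical_type(mol, atom.GetIdx())
            if rtype not in catalogue:
                raise DecompositionError(
                    f"{species}: radical group {rtype} not in catalogue"
                )
            for idx in _radical_moiety_atoms(mol, atom.GetIdx(), rtype):
                assigned[idx] = True
            counts[rtype] = counts.get(rtype, 0) + 1

    for gdef in catalogue.matchable():
        patt = Chem.MolFromSmarts(gdef.pattern)
        if patt is None:
            raise DecompositionError(f"bad SMARTS for group {gdef.group_id}")
        for match in mol.GetSubstructMatches(patt):
            if any(assigned[i] for i in match):
                continue
            if gdef.whole_molecule and (
                len(match) != n_heavy or any(assigned)
            ):
                continue
            for i in match:
                assigned[i] = True
            counts[gdef.group_id] = counts.get(gdef.group_id, 0) + 1

    residual = [i for i, used in enumerate(assigned) if not used]
    if residual:
        syms = [mol.GetAtomWithIdx(i).GetSymbol() for i in residual]
        raise DecompositionError(
            f"{species}: atoms not covered by any group: "
            f"{list(zip(residual, syms))}"
        )
    return Decomposition(counts=counts, species=species)


def decompose(
    structure: str,
    catalogue: Optional[GroupCatalogue] = None,
    category: str = "closed_shell",
) -> Decomposition:
    """Decompose a SMILES or TS-labeled species into group counts.

    ``category`` annotates the expected species class (``closed_shell``,
    ``radical`` or ``ts``) and is validated against the structure: a
    radical annotation requires at least one radical centre, a
    closed-shell annotation forbids them, and TS species must use the
    ``TS[class=...; rh=...; ro=...]`` labeled syntax.
    """
    catalogue = catalogue or default_catalogue()
    if structure.strip().startswith("TS["):
        if category not in ("ts", "closed_shell"):
            raise DecompositionError("TS label requires category 'ts'")
        return _decompose_ts(structure, catalogue)
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise DecompositionError(f"unparseable SMILES: {structure!r}")
    n_rad = sum(a.GetNumRadicalElectrons() for a in mol.GetAtoms())
    if category == "radical" and n_rad == 0:
        raise DecompositionError(
            f"{structure!r} annotated as radical but has no radical centre"
        )
    if category == "closed_shell" and n_rad > 0:
        raise DecompositionError(
            f"{structure!r} annotated as closed-shell but has "
            f"{n_rad} radical electron(s)"
        )
    if category == "ts":
        raise DecompositionError("TS species must use the TS[...] syntax")
    return _decompose_mol(mol, catalogue, structure)


def _decompose_ts(structure: str, catalogue: GroupCatalogue) -> Decomposition:
    """Group counts of an H-abstraction TS from its labeled species.

    The reacting C..H..O(-O) core replaces one paraffinic site group of
    R-H (CH3/CH2/CH by abstracted-H class) and the abstracting
    radical's own group; every spectator fragment keeps its ordinary
    groups.
    """
    fields = _parse_ts_label(structure)
    rh = decompose(fields["rh"], catalogue, "closed_shell")
    ro = decompose(fields["ro"], catalogue, "radical")
    rad_group = (
        "rad_alkoxyl" if fields["class"] == "RO_abstraction" else "rad_peroxyl"
    )
    ts_group = (
        "ts_ro_abstraction"
        if fields["class"] == "RO_abstraction"
        else "ts_roo_abstraction"
    )
    if ro.counts.get(rad_group, 0) < 1:
        raise DecompositionError(
            f"TS class {fields['class']} requires a {rad_group} radical, "
            f"got {sorted(ro.counts)}"
        )
    site_group = _SITE_GROUP[fields["site"]]
    if rh.counts.get(site_group, 0) < 1:
        raise DecompositionError(
            f"R-H {fields['rh']!r} has no {site_group} group for a "
            f"{fields['site']} abstraction"
        )
    if ts_group not in catalogue:
        raise DecompositionError(f"{ts_group} not in catalogue")
    counts: dict[str, int] = {}
    for src in (rh.counts, ro.counts):
        for gid, n in src.items():
            counts[gid] = counts.get(gid, 0) + n
    for gid in (site_group, rad_group):
        counts[gid] -= 1
        if counts[gid] == 0:
            del counts[gid]
    counts[ts_group] = counts.get(ts_group, 0) + 1
    return Decomposition(counts=counts, species=structure)


_BETAS = {"a_c": BETA_AC, "b": BETA_B, "a_0": BETA_A0}
_PROP_COLS = {"a_c": "A_c", "b": "B", "a_0": "A_0"}
_SIGMA_COLS = [f"P_sigma_{k:02d}" for k in range(1, N_BINS + 1)]


class GroupParameterTable:
    """Per-group contributions A_c, B, A_0 and the 61 sigma-bin rows.

    Backed by a DataFrame indexed by group_id; universal beta exponents
    attached.  Round-trips losslessly through CSV with columns
    (group_id, category, A_c, B, A_0, P_sigma_01 .. P_sigma_61).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        beta_ac: float = BETA_AC,
        beta_b: float = BETA_B,
        beta_a0: float = BETA_A0,
    ) -> None:
        need = {"A_c", "B", "A_0", *_SIGMA_COLS}
        missing = need - set(frame.columns)
        if missing:
            raise ValueError(f"parameter table missing columns: {sorted(missing)[:4]}...")
        if min(beta_ac, beta_b, beta_a0) <= 0:
            raise ValueError("beta constants must be positive")
        if "category" not in frame.columns:
            frame = frame.assign(category="closed_shell")
        self.frame = frame
        self.betas = {"a_c": beta_ac, "b": beta_b, "a_0": beta_a0}

    def __contains__(self, gid: str) -> bool:
        return gid in self.frame.index

    @property
    def group_ids(self) -> list[str]:
        return list(self.frame.index)

    def contribution(self, gid: str, which: str) -> float:
        return float(self.frame.loc[gid, _PROP_COLS[which]])

    def sigma_row(self, gid: str) -> np.ndarray:
        return self.frame.loc[gid, _SIGMA_COLS].to_numpy(dtype=float)

    def copy(self) -> "GroupParameterTable":
        return GroupParameterTable(self.frame.copy(), **{
            "beta_ac": self.betas["a_c"],
            "beta_b": self.betas["b"],
            "beta_a0": self.betas["a_0"],
        })

    def to_csv(self, path) -> None:
        out = self.frame.reset_index(names="group_id")
        cols = ["group_id", "category", "A_c", "B", "A_0", *_SIGMA_COLS]
        out[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **betas) -> "GroupParameterTable":
        df = pd.read_csv(path).set_index("group_id")
        return cls(df, **betas)

    @classmethod
    def from_arrays(
        cls,
        group_ids: Sequence[str],
        a_c: Sequence[float],
        b: Sequence[float],
        a_0: Sequence[float],
        p_sigma: np.ndarray,
        categories: Optional[Sequence[str]] = None,
        **betas,
    ) -> "GroupParameterTable":
        p_sigma = np.asarray(p_sigma, dtype=float)
        if p_sigma.shape != (len(group_ids), N_BINS):
            raise ValueError("p_sigma must be (n_groups, 61)")
        df = pd.DataFrame(
            {"A_c": a_c, "B": b, "A_0": a_0},
            index=pd.Index(group_ids, name="group_id"),
        )
        for k, col in enumerate(_SIGMA_COLS):
            df[col] = p_sigma[:, k]
        if categories is not None:
            df["category"] = list(categories)
        return cls(df, **betas)


def gc_eos_parameter(
    decomp: Decomposition, table: GroupParameterTable, which: str
) -> float:
    """GC-predicted EoS parameter: ``(sum_g n_g X_g)^(1/beta)``."""
    if which not in _BETAS:
        raise ValueError(f"unknown property {which!r}")
    if not decomp.counts:
        raise DecompositionError("empty decomposition")
    missing = [g for g in decomp.counts if g not in table]
    if missing:
        raise KeyError(f"groups without parameters: {missing}")
    total = sum(
        n * table.contribution(g, which) for g, n in decomp.counts.items()
    )
    if total <= 0:
        raise ValueError(
            f"non-positive transformed GC sum ({total}) for {which}"
        )
    return total ** (1.0 / table.betas[which])


def gc_sigma_profile(
    decomp: Decomposition, table: GroupParameterTable
) -> SigmaProfile:
    """GC-predicted sigma-profile: per-bin sum of group rows.

    Negative bin artifacts from the additive combination are clipped to
    zero (area densities must be non-negative) and the total area
    recomputed from the clipped bins; the clipped mass is reported as a
    warning.
    """
    if not decomp.counts:
        raise DecompositionError("empty decomposition")
    missing = [g for g in decomp.counts if g not in table]
    if missing:
        raise KeyError(f"groups without parameters: {missing}")
    raw = np.zeros(N_BINS)
    for gid, n in decomp.counts.items():
        raw += n * table.sigma_row(gid)
    clipped = np.clip(raw, 0.0, None)
    lost = float((clipped - raw).sum())
    if lost > 0:
        warnings.warn(
            f"{decomp.species or 'species'}: clipped {lost:.4g} A^2 of "
            "negative sigma-profile mass",
            stacklevel=2,
        )
    return SigmaProfile(area_per_bin=clipped, name=decomp.species)


def parametrize_solute(
    structure: str | Decomposition,
    table: GroupParameterTable,
    catalogue: Optional[GroupCatalogue] = None,
    category: str = "closed_shell",
    name: Optional[str] = None,
) -> tuple[PureComponent, SigmaProfile]:
    """Full GC parametrization chain for one solute.

    (a_c, b, a_0) -> Soave m -> (Tc, Pc) -> omega -> c = 0, plus the GC
    sigma-profile.  The resulting component always uses the Soave
    alpha-function and is tagged ``source='gc'``.
    """
    if isinstance(structure, Decomposition):
        decomp = structure
    else:
        decomp = decompose(structure, catalogue, category)
    a_c = gc_eos_parameter(decomp, table, "a_c")
    b = gc_eos_parameter(decomp, table, "b")
    a_0 = gc_eos_parameter(decomp, table, "a_0")
    if a_0 < a_c:
        raise ValueError(
            f"{decomp.species}: GC gives a_0 < a_c (alpha would grow with T); "
            "species flagged"
        )
    comp = PureComponent.from_gc(
        name=name or decomp.species, a_c=a_c, b=b, a_0=a_0
    )
    prof = gc_sigma_profile(decomp, table)
    return comp, prof
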