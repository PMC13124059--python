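"""Structure I/O, atom typing, ideal hydrogen placement, and parameter tables.

Coordinates are in Å throughout. Atom typing is deliberately coarse: the
distance-distribution analyses downstream only distinguish methyl carbons,
apolar hydrogens, backbone oxygens, and sidechain carbons split by the polarity
of the residue they belong to.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "TypedStructure",
    "LJParameterSet",
    "EnergyTable",
    "TypingScheme",
    "ATOM_TYPES",
    "CANONICAL_RESIDUES",
    "NONPOLAR_RESIDUES",
    "DEFAULT_ENERGY_GROUPS",
    "read_pdb",
    "write_pdb",
    "assign_atom_types",
    "place_aliphatic_hydrogens",
    "group_energy_terms",
    "load_parameter_set",
    "baseline_parameters",
    "refit_parameters",
    "read_energy_table",
]


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed or contains no atoms."""


class AtomTypingError(KeyError):
    """Raised in strict mode when a residue is not recognized."""


ATOM_TYPES = (
    "CH3",
    "Hapo",
    "OCbb",
    "C_nonpolar_sc",
    "C_polar_sc",
    "CAbb",
    "Npol",
    "OH",
    "other",
)

CANONICAL_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Residues whose sidechains are treated as nonpolar (hydrophobic). GLY and PRO
#: are included because their (absent/cyclic) sidechains carry no polar atoms.
NONPOLAR_RESIDUES = frozenset("ALA VAL LEU ILE MET PHE TRP PRO GLY CYS".split())

#: (residue, atom) pairs labelled as methyl carbons.
METHYL_CARBONS = {
    ("ALA", "CB"),
    ("VAL", "CG1"),
    ("VAL", "CG2"),
    ("LEU", "CD1"),
    ("LEU", "CD2"),
    ("ILE", "CD1"),
    ("ILE", "CG2"),
    ("THR", "CG2"),
    ("MET", "CE"),
}

HYDROXYL_OXYGENS = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class Atom:
    """A single atom as read from a coordinate file."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.atom_name} has empty element")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.atom_name} has non-finite coordinates")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """Disambiguating key (chain, residue index, insertion code)."""
        return (self.chain_id, self.residue_index, self.insertion_code)

    @property
    def is_canonical(self) -> bool:
        return self.residue_name in CANONICAL_RESIDUES


@dataclass
class TypedStructure:
    """An ordered list of atoms plus one coarse type label per atom."""

    atoms: list[Atom]
    atom_types: list[str] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.atom_types:
            self.atom_types = ["other"] * len(self.atoms)
        if len(self.atom_types) != len(self.atoms):
            raise ValueError("atom_types length must match atoms length")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "TypedStructure":
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=tuple(map(float, xyz))) for a, xyz in zip(self.atoms, coords)]
        return TypedStructure(atoms, list(self.atom_types), self.source_id)

    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Atom indices grouped by residue, in file order."""
        out: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def indices_of_type(self, label: str) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.atom_types) if t == label], dtype=int)


@dataclass(frozen=True)
class LJParameterSet:
    """Per-atom-type Lennard-Jones radius (Å) and well depth (kcal/mol).

    ``w_rep`` is the dimensionless weight on the repulsive branch of the
    potential. Two named instances (a baseline and a refit set) ship with the
    package as synthetic placeholder tables; quantitative comparisons against
    published energy functions require supplying real parameter files.
    """

    name: str
    types: Mapping[str, tuple[float, float]]  # label -> (radius, well_depth)
    w_rep: float = 1.0

    def __post_init__(self) -> None:
        for label, (r, eps) in self.types.items():
            if r <= 0:
                raise ValueError(f"radius for {label} must be positive")
            if eps < 0:
                raise ValueError(f"well depth for {label} must be non-negative")
        if self.w_rep < 0:
            raise ValueError("w_rep must be non-negative")

    def radius(self, label: str) -> float:
        return self.types[label][0]

    def well_depth(self, label: str) -> float:
        return self.types[label][1]

    def radius_sum(self, a: str, b: str) -> float:
        return self.radius(a) + self.radius(b)

    def epsilon(self, a: str, b: str) -> float:
        """Geometric-mean combination of well depths."""
        return math.sqrt(self.well_depth(a) * self.well_depth(b))

    def with_radius(self, label: str, radius: float) -> "LJParameterSet":
        types = dict(self.types)
        types[label] = (float(radius), types[label][1])
        return LJParameterSet(self.name, types, self.w_rep)

    @classmethod
    def from_json(cls, path: str | Path) -> "LJParameterSet":
        blob = json.loads(Path(path).read_text())
        types = {k: (float(v["radius"]), float(v["well_depth"])) for k, v in blob["types"].items()}
        return cls(blob["name"], types, float(blob.get("w_rep", 1.0)))

    def to_json(self, path: str | Path) -> None:
        blob = {
            "name": self.name,
            "types": {k: {"radius": r, "well_depth": e} for k, (r, e) in self.types.items()},
            "w_rep": self.w_rep,
        }
        Path(path).write_text(json.dumps(blob, indent=2))


def _data_path(fname: str) -> Path:
    return Path(__file__).parent / "data" / fname


def load_parameter_set(path: str | Path) -> LJParameterSet:
    return LJParameterSet.from_json(path)


def baseline_parameters() -> LJParameterSet:
    """Synthetic placeholder stand-in for a pre-refit parameter table."""
    return LJParameterSet.from_json(_data_path("lj_baseline_synthetic.json"))


def refit_parameters() -> LJParameterSet:
    """Synthetic placeholder stand-in for a post-refit parameter table."""
    return LJParameterSet.from_json(_data_path("lj_refit_synthetic.json"))


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------


def read_pdb(path: str | Path) -> TypedStructure:
    """Read a PDB file into a :class:`TypedStructure` (types all ``other``).

    Atoms are kept in file order. Alternate locations other than blank or 'A'
    are dropped. Only the first model is read.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models")
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                el = atom.element.name or _element_from_name(atom.name)
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        residue_index=residue.seqid.num,
                        residue_name=residue.name.strip(),
                        atom_name=atom.name.strip(),
                        element=el,
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        insertion_code=(residue.seqid.icode or "").strip(),
                    )
                )
    if not atoms:
        raise StructureFormatError(f"{path}: no ATOM records")
    return TypedStructure(atoms, source_id=path.stem)


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def write_pdb(s: TypedStructure, path: str | Path) -> None:
    """Write a structure back out as PDB, preserving order and names."""
    # gemmi's add_* methods copy, so the hierarchy is built bottom-up
    chain_order: list[str] = []
    residues: dict[str, list[tuple[tuple[str, int, str], gemmi.Residue]]] = {}
    for atom in s.atoms:
        if atom.chain_id not in residues:
            residues[atom.chain_id] = []
            chain_order.append(atom.chain_id)
        chain_res = residues[atom.chain_id]
        if not chain_res or chain_res[-1][0] != atom.residue_key:
            res = gemmi.Residue()
            res.name = atom.residue_name
            res.seqid = gemmi.SeqId(atom.residue_index, atom.insertion_code or " ")
            chain_res.append((atom.residue_key, res))
        ga = gemmi.Atom()
        ga.name = atom.atom_name
        ga.element = gemmi.Element(atom.element)
        ga.pos = gemmi.Position(*atom.coords)
        chain_res[-1][1].add_atom(ga)
    st = gemmi.Structure()
    st.name = s.source_id or "packfail"
    model = gemmi.Model("1")
    for cid in chain_order:
        chain = gemmi.Chain(cid)
        for _, res in residues[cid]:
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TypingScheme:
    """Configuration for coarse atom typing.

    ``nonpolar_residues`` controls the C_nonpolar_sc / C_polar_sc split, which
    is per-residue: every non-methyl sidechain carbon inherits the polarity of
    its residue.
    """

    nonpolar_residues: frozenset[str] = NONPOLAR_RESIDUES
    strict: bool = False


def _hydrogen_parent(residue_atoms: set[str], h_name: str) -> str | None:
    """Guess the heavy-atom parent of a hydrogen from PDB naming conventions."""
    name = h_name.strip()
    if name and name[0].isdigit():  # e.g. 1HB -> HB1
        name = name[1:] + name[0]
    rem = name[1:]
    candidates = [rem]
    while rem and rem[-1].isdigit():
        rem = rem[:-1]
        candidates.append(rem)
    for cand in candidates:
        for el in ("C", "N", "O", "S"):
            if el + cand in residue_atoms:
                return el + cand
    return None


def _type_one_atom(atom: Atom, residue_atoms: set[str], scheme: TypingScheme) -> str:
    res, name, el = atom.residue_name, atom.atom_name, atom.element.upper()
    if res not in CANONICAL_RESIDUES:
        if scheme.strict:
            raise AtomTypingError(f"unknown residue {res} at {atom.residue_key}")
        return "other"
    if el == "H":
        parent = _hydrogen_parent(residue_atoms, name)
        return "Hapo" if parent is not None and parent.startswith("C") else "other"
    if name in ("O", "OXT"):
        return "OCbb"
    if name == "CA":
        return "CAbb"
    if name in ("N", "C"):
        return "Npol" if name == "N" else "other"
    if (res, name) in METHYL_CARBONS:
        return "CH3"
    if (res, name) in HYDROXYL_OXYGENS:
        return "OH"
    if el == "C":
        return "C_nonpolar_sc" if res in scheme.nonpolar_residues else "C_polar_sc"
    if el == "N":
        return "Npol"
    return "other"


def assign_atom_types(s: TypedStructure, scheme: TypingScheme | None = None) -> TypedStructure:
    """Label every atom with one of :data:`ATOM_TYPES`.

    Typing is a pure function of (residue name, atom name) and the scheme.
    """
    scheme = scheme or TypingScheme()
    residues = s.residues()
    names_by_res = {
        key: {s.atoms[i].atom_name for i in idx} for key, idx in residues.items()
    }
    labels = [
        _type_one_atom(a, names_by_res[a.residue_key], scheme) for a in s.atoms
    ]
    return TypedStructure(list(s.atoms), labels, s.source_id)


# ---------------------------------------------------------------------------
# Ideal hydrogen placement
# ---------------------------------------------------------------------------

_SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [],
    "VAL": [("CB", "CG1"), ("CB", "CG2")],
    "LEU": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "ILE": [("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "MET": [("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "TYR": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")],
    "TRP": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"),
            ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "HIS": [("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CD2", "NE2"), ("CE1", "NE2")],
    "SER": [("CB", "OG")],
    "THR": [("CB", "OG1"), ("CB", "CG2")],
    "CYS": [("CB", "SG")],
    "ASP": [("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "ASN": [("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "GLU": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLN": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "LYS": [("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "ARG": [("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")],
    "PRO": [("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "GLY": [],
}

#: sp3 carbons that receive ideal hydrogens, per residue.
_SP3_CARBONS: dict[str, tuple[str, ...]] = {
    "GLY": ("CA",),
    "ALA": ("CA", "CB"),
    "VAL": ("CA", "CB", "CG1", "CG2"),
    "LEU": ("CA", "CB", "CG", "CD1", "CD2"),
    "ILE": ("CA", "CB", "CG1", "CG2", "CD1"),
    "MET": ("CA", "CB", "CG", "CE"),
    "PHE": ("CA", "CB"),
    "TYR": ("CA", "CB"),
    "TRP": ("CA", "CB"),
    "HIS": ("CA", "CB"),
    "SER": ("CA", "CB"),
    "THR": ("CA", "CB", "CG2"),
    "CYS": ("CA", "CB"),
    "ASP": ("CA", "CB"),
    "ASN": ("CA", "CB"),
    "GLU": ("CA", "CB", "CG"),
    "GLN": ("CA", "CB", "CG"),
    "LYS": ("CA", "CB", "CG", "CD", "CE"),
    "ARG": ("CA", "CB", "CG", "CD"),
    "PRO": ("CA", "CB", "CG", "CD"),
}

_CH_BOND = 1.09  # Å
_TET = math.radians(109.4712206)  # ideal tetrahedral angle


def _residue_bonds(resname: str) -> list[tuple[str, str]]:
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    if resname != "GLY":
        bonds.append(("CA", "CB"))
    bonds.extend(_SIDECHAIN_BONDS.get(resname, []))
    return bonds


def _heavy_neighbors(resname: str, carbon: str) -> list[str]:
    out = []
    for a, b in _residue_bonds(resname):
        if a == carbon:
            out.append(b)
        elif b == carbon:
            out.append(a)
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate geometry")
    return v / n


def _methyl_hydrogens(x: np.ndarray, nbr: np.ndarray, ref: np.ndarray | None) -> list[np.ndarray]:
    """Three staggered hydrogens on a methyl carbon ``x`` bonded to ``nbr``.

    ``ref`` is a heavy atom bonded to ``nbr`` defining the dihedral reference;
    hydrogens are placed at dihedrals 180°, 60°, −60° (staggered).
    """
    u = _unit(nbr - x)
    if ref is not None:
        vr = ref - nbr
        perp = vr - np.dot(vr, u) * u
        e1 = _unit(perp) if np.linalg.norm(perp) > 1e-6 else _arbitrary_perp(u)
    else:
        e1 = _arbitrary_perp(u)
    e2 = np.cross(u, e1)
    out = []
    for phi_deg in (180.0, 60.0, -60.0):
        phi = math.radians(phi_deg)
        direction = (
            math.cos(_TET) * u
            + math.sin(_TET) * (math.cos(phi) * e1 + math.sin(phi) * e2)
        )
        out.append(x + _CH_BOND * direction)
    return out


def _arbitrary_perp(u: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, trial))


def _methylene_hydrogens(x: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> list[np.ndarray]:
    u1, u2 = _unit(n1 - x), _unit(n2 - x)
    bis = _unit(-(u1 + u2))
    axis = _unit(np.cross(u1, u2))
    half = _TET / 2.0
    return [
        x + _CH_BOND * (math.cos(half) * bis + math.sin(half) * axis),
        x + _CH_BOND * (math.cos(half) * bis - math.sin(half) * axis),
    ]


def _methine_hydrogen(x: np.ndarray, nbrs: list[np.ndarray]) -> np.ndarray:
    s = np.zeros(3)
    for n in nbrs:
        s += _unit(n - x)
    return x + _CH_BOND * _unit(-s)


def _h_names(carbon: str, count: int, resname: str) -> list[str]:
    rem = carbon[1:]  # strip leading C
    if count == 1:
        return [f"H{rem}"]
    if count == 2:
        return [f"H{rem}2", f"H{rem}3"]
    return [f"H{rem}{i}" for i in (1, 2, 3)]


def place_aliphatic_hydrogens(s: TypedStructure) -> TypedStructure:
    """Add ideal-geometry hydrogens to sp3 carbons (1.09 Å C–H bonds).

    Methyl rotamers are staggered relative to the upstream heavy-atom branch.
    Carbons that already carry hydrogens are left untouched, as are existing
    hydrogens, so the operation is idempotent. Missing parent heavy atoms
    produce a per-residue warning instead of an error.
    """
    new_atoms: list[Atom] = []
    new_types: list[str] = []
    for key, idx in s.residues().items():
        res_atoms = [s.atoms[i] for i in idx]
        res_types = [s.atom_types[i] for i in idx]
        new_atoms.extend(res_atoms)
        new_types.extend(res_types)
        resname = res_atoms[0].residue_name
        if resname not in _SP3_CARBONS:
            continue
        pos = {a.atom_name: np.array(a.coords) for a in res_atoms}
        existing_h_parents = {
            _hydrogen_parent(set(pos), a.atom_name)
            for a in res_atoms
            if a.element.upper() == "H"
        }
        for carbon in _SP3_CARBONS[resname]:
            if carbon not in pos or carbon in existing_h_parents:
                continue
            nbr_names = [n for n in _heavy_neighbors(resname, carbon) if n in pos]
            expected = _heavy_neighbors(resname, carbon)
            if len(nbr_names) < len(expected):
                warnings.warn(
                    f"residue {key}: missing neighbors of {carbon}, no H placed",
                    stacklevel=2,
                )
                continue
            x = pos[carbon]
            n_h = 4 - len(nbr_names)
            if n_h <= 0:
                continue
            if n_h == 3:
                nbr = pos[nbr_names[0]]
                ref_names = [
                    n for n in _heavy_neighbors(resname, nbr_names[0])
                    if n != carbon and n in pos
                ]
                ref = pos[ref_names[0]] if ref_names else None
                hs = _methyl_hydrogens(x, nbr, ref)
            elif n_h == 2:
                hs = _methylene_hydrogens(x, pos[nbr_names[0]], pos[nbr_names[1]])
            else:
                hs = _methine_hydrogen(x, [pos[n] for n in nbr_names])
                hs = [hs]
            proto = res_atoms[0]
            for name, h in zip(_h_names(carbon, n_h, resname), hs):
                new_atoms.append(
                    Atom(
                        chain_id=proto.chain_id,
                        residue_index=proto.residue_index,
                        residue_name=resname,
                        atom_name=name,
                        element="H",
                        coords=tuple(map(float, h)),
                        insertion_code=proto.insertion_code,
                    )
                )
                new_types.append("Hapo")
    return TypedStructure(new_atoms, new_types, s.source_id)


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------

#: Grouping of per-term energies into energetically related categories.
DEFAULT_ENERGY_GROUPS: dict[str, tuple[str, ...]] = {
    "LJ": ("fa_atr", "fa_rep", "fa_intra_atr_xover4", "fa_intra_rep_xover4"),
    "solvation": ("fa_sol", "lk_ball", "lk_ball_iso", "lk_ball_bridge",
                  "lk_ball_bridge_uncpl", "fa_intra_sol_xover4"),
    "electrostatics": ("fa_elec", "fa_intra_elec"),
    "H-bond": ("hbond_sc", "hbond_bb_sc", "hbond_lr_bb", "hbond_sr_bb"),
    "covalent bonding": ("cart_bonded",),
    "backbone torsion": ("omega", "p_aa_pp", "rama_prepro"),
    "sidechain rotamer": ("fa_dun_rot", "fa_dun_dev", "fa_dun_semi", "hxl_tors"),
}


@dataclass
class EnergyTable:
    """Per-term energies (kcal/mol) for one structure."""

    structure_id: str
    terms: dict[str, float]


def read_energy_table(path: str | Path) -> list[EnergyTable]:
    """Read energy tables from CSV with columns structure_id, term, value."""
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("structure_id", sort=False):
        if grp["term"].duplicated().any():
            raise ValueError(f"duplicate term names for {sid}")
        out.append(EnergyTable(str(sid), dict(zip(grp["term"], grp["value"].astype(float)))))
    return out


def group_energy_terms(
    t: EnergyTable,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, float]:
    """Sum per-term energies into non-overlapping groups plus ``total``.

    Terms not covered by the grouping config land in ``ungrouped`` (they still
    count toward ``total``).
    """
    groups = groups or DEFAULT_ENERGY_GROUPS
    term_to_group: dict[str, str] = {}
    for gname, terms in groups.items():
        for term in terms:
            term_to_group[term] = gname
    out = {g: 0.0 for g in groups}
    out["ungrouped"] = 0.0
    total = 0.0
    for term, value in t.terms.items():
        total += value
        out[term_to_group.get(term, "ungrouped")] += value
    out["total"] = total
    return out
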