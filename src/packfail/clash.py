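"""Pairwise distance extraction, clash detection, and design-vs-crystal ratios.

A *clash* is an interatomic distance strictly smaller than the sum of the two
atoms' van der Waals radii (taken from the active LJ parameter set). Distance
distributions are truncated 0.5 Å above the radius sum, so each distribution
captures only close contacts around the clash boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import BACKBONE_ATOMS, LJParameterSet, TypedStructure, _residue_bonds

__all__ = [
    "PairDistanceDistribution",
    "ClashReport",
    "ExclusionConfig",
    "UndefinedClashRatio",
    "SequenceMismatchError",
    "TRUNCATION_MARGIN",
    "pair_distances",
    "count_clashes",
    "clash_fraction",
    "clash_report",
    "clash_ratio",
    "align_pair_sequences",
    "write_distribution_tsv",
    "read_distribution_tsv",
]

#: Distributions extend this far (Å) beyond the radius sum.
TRUNCATION_MARGIN = 0.5


class UndefinedClashRatio(ArithmeticError):
    """The design has zero clashes, so the crystal/design ratio is undefined."""


class SequenceMismatchError(ValueError):
    """Design and crystal disagree at internal (non-terminal) sites."""


@dataclass(frozen=True)
class ExclusionConfig:
    """Which atom pairs are excluded from distance distributions.

    ``mode='residue'`` (default) excludes pairs within the same residue and
    backbone–backbone pairs between sequence-adjacent residues of the same
    chain. ``mode='bonds'`` excludes atoms separated by at most
    ``max_bond_separation`` covalent bonds on an inferred bond graph.
    """

    mode: Literal["residue", "bonds"] = "residue"
    max_bond_separation: int = 3


@dataclass
class PairDistanceDistribution:
    """Observed distances (Å) for one unordered atom-type pair."""

    type_pair: tuple[str, str]
    distances: np.ndarray
    r_sum: float
    truncation: float = 0.0

    def __post_init__(self) -> None:
        self.type_pair = tuple(sorted(self.type_pair))  # type: ignore[assignment]
        self.distances = np.asarray(self.distances, dtype=float)
        if self.truncation == 0.0:
            self.truncation = self.r_sum + TRUNCATION_MARGIN
        if self.distances.size and self.distances.max() > self.truncation + 1e-9:
            raise ValueError("distances exceed truncation cutoff")

    @property
    def N(self) -> int:
        return int(self.distances.size)


@dataclass
class ClashReport:
    structure_id: str
    type_pair: tuple[str, str]
    n_pairs_within_cutoff: int
    n_clashing: int


def _residue_serials(s: TypedStructure) -> np.ndarray:
    """Integer residue id per atom, consecutive residues differ by 1."""
    serial = {}
    out = np.empty(len(s), dtype=int)
    for i, a in enumerate(s.atoms):
        key = a.residue_key
        if key not in serial:
            serial[key] = len(serial)
        out[i] = serial[key]
    return out


def _bond_graph(s: TypedStructure) -> dict[int, set[int]]:
    """Covalent bond graph inferred from residue templates plus peptide bonds."""
    adj: dict[int, set[int]] = {i: set() for i in range(len(s))}
    residues = list(s.residues().items())
    for r, (key, idx) in enumerate(residues):
        resname = s.atoms[idx[0]].residue_name
        by_name = {s.atoms[i].atom_name: i for i in idx}
        for a, b in _residue_bonds(resname):
            if a in by_name and b in by_name:
                adj[by_name[a]].add(by_name[b])
                adj[by_name[b]].add(by_name[a])
        # hydrogens: attach to nearest heavy atom in the residue
        for i in idx:
            if s.atoms[i].element.upper() == "H":
                heavy = [j for j in idx if s.atoms[j].element.upper() != "H"]
                if heavy:
                    xi = np.array(s.atoms[i].coords)
                    j = min(heavy, key=lambda j: np.sum((np.array(s.atoms[j].coords) - xi) ** 2))
                    adj[i].add(j)
                    adj[j].add(i)
        # peptide bond C(r) - N(r+1)
        if r + 1 < len(residues):
            nkey, nidx = residues[r + 1]
            if nkey[0] == key[0]:
                nxt = {s.atoms[i].atom_name: i for i in nidx}
                if "C" in by_name and "N" in nxt:
                    adj[by_name["C"]].add(nxt["N"])
                    adj[nxt["N"]].add(by_name["C"])
    return adj


def _bond_separation_ok(adj: dict[int, set[int]], i: int, j: int, max_sep: int) -> bool:
    """True if i and j are more than max_sep bonds apart (BFS from i)."""
    frontier = {i}
    seen = {i}
    for _ in range(max_sep):
        nxt = set()
        for u in frontier:
            nxt |= adj[u]
        nxt -= seen
        if j in nxt:
            return False
        seen |= nxt
        frontier = nxt
    return True


def pair_distances(
    s: TypedStructure,
    type_a: str,
    type_b: str,
    params: LJParameterSet,
    exclusion: ExclusionConfig | None = None,
) -> PairDistanceDistribution:
    """All unordered ``(type_a, type_b)`` atom-pair distances ≤ R_sum + 0.5 Å.

    Symmetric in the two type labels. Uses a k-d tree for candidate pairing;
    a brute-force scan gives identical pair sets (tested property).
    """
    exclusion = exclusion or ExclusionConfig()
    r_sum = params.radius_sum(type_a, type_b)
    cutoff = r_sum + TRUNCATION_MARGIN
    types = np.asarray(s.atom_types, dtype=object)
    mask_a = types == type_a
    mask_b = types == type_b
    if not mask_a.any() or not mask_b.any():
        return PairDistanceDistribution(tuple(sorted((type_a, type_b))), np.array([]), r_sum)

    coords = s.coords
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return PairDistanceDistribution(tuple(sorted((type_a, type_b))), np.array([]), r_sum)
    i, j = pairs[:, 0], pairs[:, 1]
    keep = (mask_a[i] & mask_b[j]) | (mask_b[i] & mask_a[j])
    i, j = i[keep], j[keep]

    res = _residue_serials(s)
    same_res = res[i] == res[j]
    keep = ~same_res
    if exclusion.mode == "residue":
        chain = np.asarray([a.chain_id for a in s.atoms], dtype=object)
        is_bb = np.asarray([a.atom_name in BACKBONE_ATOMS for a in s.atoms], dtype=bool)
        adjacent = (np.abs(res[i] - res[j]) == 1) & (chain[i] == chain[j])
        keep &= ~(adjacent & is_bb[i] & is_bb[j])
        i, j = i[keep], j[keep]
    else:
        i, j = i[keep], j[keep]
        adj = _bond_graph(s)
        sep_ok = np.array(
            [_bond_separation_ok(adj, int(a), int(b), exclusion.max_bond_separation)
             for a, b in zip(i, j)],
            dtype=bool,
        ) if i.size else np.array([], dtype=bool)
        i, j = i[sep_ok], j[sep_ok]

    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    d = np.sort(d[d <= cutoff + 1e-12])
    return PairDistanceDistribution(tuple(sorted((type_a, type_b))), d, r_sum)


def count_clashes(d: PairDistanceDistribution) -> int:
    """Number of pairs strictly closer than the radius sum (ties are not clashes)."""
    return int(np.sum(d.distances < d.r_sum))


def clash_fraction(d: PairDistanceDistribution) -> float:
    """Clashing fraction among pairs within the truncation cutoff."""
    if d.N == 0:
        return float("nan")
    return count_clashes(d) / d.N


def clash_report(
    s: TypedStructure,
    type_a: str,
    type_b: str,
    params: LJParameterSet,
    exclusion: ExclusionConfig | None = None,
) -> ClashReport:
    d = pair_distances(s, type_a, type_b, params, exclusion)
    return ClashReport(s.source_id, d.type_pair, d.N, count_clashes(d))


def clash_ratio(
    design: TypedStructure,
    crystal: TypedStructure,
    type_pair: tuple[str, str],
    params: LJParameterSet,
    exclusion: ExclusionConfig | None = None,
) -> float:
    """Ratio of clash counts: crystal / design, for one atom-type pair.

    Values below 1 mean the experimentally determined structure relieves
    clashes present in the design model.
    """
    a, b = type_pair
    n_design = count_clashes(pair_distances(design, a, b, params, exclusion))
    n_crystal = count_clashes(pair_distances(crystal, a, b, params, exclusion))
    if n_design == 0:
        raise UndefinedClashRatio(
            f"design {design.source_id} has no {a}:{b} clashes; ratio undefined"
        )
    return n_crystal / n_design


# ---------------------------------------------------------------------------
# Design/crystal sequence harmonization
# ---------------------------------------------------------------------------

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _chain_residues(s: TypedStructure) -> dict[str, list[tuple[tuple[str, int, str], str]]]:
    out: dict[str, list[tuple[tuple[str, int, str], str]]] = {}
    for key, idx in s.residues().items():
        out.setdefault(key[0], []).append((key, s.atoms[idx[0]].residue_name))
    return out


def _subset(s: TypedStructure, keep_keys: set[tuple[str, int, str]]) -> TypedStructure:
    atoms, types = [], []
    for a, t in zip(s.atoms, s.atom_types):
        if a.residue_key in keep_keys:
            atoms.append(a)
            types.append(t)
    return TypedStructure(atoms, types, s.source_id)


def align_pair_sequences(
    design: TypedStructure, crystal: TypedStructure
) -> tuple[TypedStructure, TypedStructure]:
    """Trim a design/crystal pair so both carry the same sites and sequence.

    Residues unresolved in the crystal are deleted from the design (matching
    on chain + residue number); terminal residues with non-identical amino
    acids are deleted from both. An internal mismatch raises
    :class:`SequenceMismatchError` naming the sites.
    """
    d_chains = _chain_residues(design)
    c_chains = _chain_residues(crystal)
    keep_d: set[tuple[str, int, str]] = set()
    keep_c: set[tuple[str, int, str]] = set()
    for chain in d_chains:
        if chain not in c_chains:
            continue
        c_keys = {k: name for k, name in c_chains[chain]}
        d_keys = {k: name for k, name in d_chains[chain]}
        shared = [(k, name) for k, name in d_chains[chain] if k in c_keys]
        # trim terminal mismatches
        lo, hi = 0, len(shared)
        while lo < hi and shared[lo][1] != c_keys[shared[lo][0]]:
            lo += 1
        while hi > lo and shared[hi - 1][1] != c_keys[shared[hi - 1][0]]:
            hi -= 1
        internal_mismatch = [
            k for k, name in shared[lo:hi] if name != c_keys[k]
        ]
        if internal_mismatch:
            raise SequenceMismatchError(
                f"chain {chain}: internal sequence mismatch at sites "
                + ", ".join(str(k[1]) for k in internal_mismatch)
            )
        keep_d |= {k for k, _ in shared[lo:hi]}
        keep_c |= {k for k, _ in shared[lo:hi]}
    return _subset(design, keep_d), _subset(crystal, keep_c)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_distribution_tsv(dists: Iterable[PairDistanceDistribution], path) -> None:
    rows = []
    for d in dists:
        for x in d.distances:
            rows.append((d.type_pair[0], d.type_pair[1], x, d.r_sum))
    pd.DataFrame(rows, columns=["type_a", "type_b", "distance", "r_sum"]).to_csv(
        path, sep="\t", index=False
    )


def read_distribution_tsv(path) -> list[PairDistanceDistribution]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (a, b, r_sum), grp in df.groupby(["type_a", "type_b", "r_sum"], sort=False):
        out.append(
            PairDistanceDistribution((a, b), grp["distance"].to_numpy(), float(r_sum))
        )
    return out
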