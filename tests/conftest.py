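"""Shared fixtures: tiny in-memory structures and PDB files built on the fly."""

from __future__ import annotations

import numpy as np
import pytest

from packfail.structio import Atom, LJParameterSet, TypedStructure, baseline_parameters


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    element: str,
    altloc: str = " ",
    icode: str = " ",
) -> str:
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:>5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:>4d}{icode}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{1.0:>6.2f}{0.0:>6.2f}"
        f"          {element:>2s}"
    )


def make_atom(
    chain: str,
    resseq: int,
    resname: str,
    name: str,
    element: str,
    xyz: tuple[float, float, float],
) -> Atom:
    return Atom(chain, resseq, resname, name, element, xyz)


def ch3_pair(separation: float, radius: float = 1.7) -> tuple[TypedStructure, LJParameterSet]:
    """Two methyl carbons in different residues, a configurable distance apart."""
    atoms = [
        make_atom("A", 1, "VAL", "CG1", "C", (0.0, 0.0, 0.0)),
        make_atom("A", 5, "VAL", "CG1", "C", (separation, 0.0, 0.0)),
    ]
    s = TypedStructure(atoms, ["CH3", "CH3"])
    params = LJParameterSet("test", {"CH3": (radius, 0.1)})
    return s, params


@pytest.fixture
def params() -> LJParameterSet:
    return baseline_parameters()


@pytest.fixture
def gly_pdb(tmp_path):
    """Single glycine with five heavy atoms (backbone + terminal oxygen)."""
    lines = [
        pdb_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_line(2, "CA", "GLY", "A", 1, 1.458, 0.0, 0.0, "C"),
        pdb_line(3, "C", "GLY", "A", 1, 2.009, 1.42, 0.0, "C"),
        pdb_line(4, "O", "GLY", "A", 1, 1.251, 2.39, 0.0, "O"),
        pdb_line(5, "OXT", "GLY", "A", 1, 3.246, 1.541, 0.0, "O"),
        "END",
    ]
    path = tmp_path / "gly.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def dipeptide() -> TypedStructure:
    """ALA-GLY dipeptide with idealized-ish backbone geometry."""
    atoms = [
        make_atom("A", 1, "ALA", "N", "N", (0.0, 0.0, 0.0)),
        make_atom("A", 1, "ALA", "CA", "C", (1.458, 0.0, 0.0)),
        make_atom("A", 1, "ALA", "C", "C", (2.009, 1.42, 0.0)),
        make_atom("A", 1, "ALA", "O", "O", (1.251, 2.39, 0.0)),
        make_atom("A", 1, "ALA", "CB", "C", (2.01, -0.77, 1.21)),
        make_atom("A", 2, "GLY", "N", "N", (3.32, 1.54, 0.0)),
        make_atom("A", 2, "GLY", "CA", "C", (4.04, 2.79, 0.0)),
        make_atom("A", 2, "GLY", "C", "C", (5.52, 2.62, 0.0)),
        make_atom("A", 2, "GLY", "O", "O", (6.19, 3.63, 0.0)),
    ]
    return TypedStructure(atoms)


def random_typed_cluster(
    n: int, rng: np.random.Generator, labels: tuple[str, ...] = ("CH3",)
) -> TypedStructure:
    """Random atom cloud with each atom in its own residue."""
    coords = rng.uniform(0.0, max(6.0, n ** (1 / 3) * 4.0), size=(n, 3))
    types = [labels[i % len(labels)] for i in range(n)]
    atoms = [
        make_atom("A", i + 1, "UNK", types[i], types[i][0], tuple(map(float, coords[i])))
        for i in range(n)
    ]
    return TypedStructure(atoms, types)
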