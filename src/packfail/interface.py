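"""Interface-prediction benchmark machinery.

Starting from a two-chain crystal structure, rigid-body "jitter" perturbations
generate decoy complexes; an external energy function supplies per-decoy
complex and single-chain energies (over several replicate optimization runs),
from which a binding ΔG = E_complex − (E_chainA + E_chainB) is computed.
After replicate-stability and chain-energy QC filters, decoys are binned by
Cα RMSD to the crystal, a fixed-size low-ΔG subset is selected round-robin
across bins, and the energy function is scored by the Boltzmann-weighted
probability mass it places on near-native decoys.

This module never computes physical interface energies itself — energies are
inputs (externally produced or synthetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structio import TypedStructure

__all__ = [
    "DecoyRecord",
    "Landscape",
    "QCThresholds",
    "jitter",
    "ca_rmsd",
    "qc_filter",
    "decoys_from_table",
    "select_landscape",
    "discrimination_score",
    "landscape_flags",
    "NEAR_NATIVE_CUTOFF",
    "DEFAULT_KT",
]

NEAR_NATIVE_CUTOFF = 2.0  # Å, the first RMSD bin
DEFAULT_KT = 1.0          # energy units
_JOBS = ("complex", "chainA", "chainB")


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control thresholds, in energy units per residue."""

    replicate_spread: float = 0.1
    chain_outlier: float = 0.1
    min_replicates: int = 2
    max_filtered_fraction: float = 0.15   # landscape-level exclusion
    min_surviving_decoys: int = 1000


@dataclass
class DecoyRecord:
    """One rigid-body decoy with replicate energies for the three jobs."""

    decoy_id: str
    ca_rmsd: float
    replicate_energies: dict[str, list[float]]
    n_residues: int
    qc_flags: set[str] = field(default_factory=set)

    def job_min(self, job: str) -> float:
        return float(min(self.replicate_energies[job]))

    @property
    def e_complex(self) -> float:
        return self.job_min("complex")

    @property
    def e_chain_a(self) -> float:
        return self.job_min("chainA")

    @property
    def e_chain_b(self) -> float:
        return self.job_min("chainB")

    @property
    def dg(self) -> float:
        """Binding ΔG = E_complex − (E_chainA + E_chainB)."""
        return self.e_complex - (self.e_chain_a + self.e_chain_b)

    @property
    def passes_qc(self) -> bool:
        return not self.qc_flags


@dataclass
class Landscape:
    crystal_id: str
    decoys: list[DecoyRecord]
    selected: list[DecoyRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Decoy generation
# ---------------------------------------------------------------------------


def jitter(
    complex_structure: TypedStructure,
    moving_chain: str,
    seed: int | np.random.Generator = 0,
    max_translation: float = 2.0,
    max_rotation_deg: float = 10.0,
) -> TypedStructure:
    """Rigid-body perturbation of one chain of a two-chain complex.

    The moving chain is rotated by an angle uniform on [0, max_rotation_deg]
    about a uniformly random axis through its centroid, then translated by a
    magnitude uniform on [0, max_translation] Å in a uniformly random 3D
    direction. The other chain is untouched and the moving chain stays
    internally rigid.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chains = {a.chain_id for a in complex_structure.atoms}
    if moving_chain not in chains:
        raise KeyError(f"chain {moving_chain!r} not in structure (has {sorted(chains)})")
    mask = np.array([a.chain_id == moving_chain for a in complex_structure.atoms])
    coords = complex_structure.coords
    moving = coords[mask]
    centroid = moving.mean(axis=0)

    axis = _random_unit(rng)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    rot = Rotation.from_rotvec(angle * axis)
    direction = _random_unit(rng)
    magnitude = rng.uniform(0.0, max_translation)

    moved = rot.apply(moving - centroid) + centroid + magnitude * direction
    new_coords = coords.copy()
    new_coords[mask] = moved
    return complex_structure.with_coords(new_coords)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def ca_rmsd(decoy: TypedStructure, native: TypedStructure) -> float:
    """Cα RMSD in the fixed frame (no re-superposition).

    Cα atoms are matched by (chain, residue number, insertion code); a
    mismatch in the matched sets is an error.
    """
    def ca_map(s: TypedStructure) -> dict:
        return {
            a.residue_key: np.array(a.coords)
            for a in s.atoms
            if a.atom_name == "CA"
        }

    d_map, n_map = ca_map(decoy), ca_map(native)
    if set(d_map) != set(n_map):
        raise ValueError("decoy and native have different Cα residue sets")
    if not d_map:
        raise ValueError("no Cα atoms found")
    keys = sorted(d_map)
    diff = np.array([d_map[k] - n_map[k] for k in keys])
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def qc_filter(
    d: DecoyRecord,
    landscape_chain_medians: dict[str, float],
    thresholds: QCThresholds | None = None,
) -> set[str]:
    """Flags a decoy's energies as unusable when replicate optimization runs
    disagree or a chain energy is an outlier within its landscape.

    - TOO_FEW_REPLICATES: fewer than ``min_replicates`` replicates in any job.
    - UNSTABLE_REPLICATES: |median − min| of any job's replicates exceeds
      ``replicate_spread`` per residue.
    - CHAIN_ENERGY_OUTLIER: a chain's minimum energy exceeds the landscape
      median for that chain by more than ``chain_outlier`` per residue.
    """
    thresholds = thresholds or QCThresholds()
    flags: set[str] = set()
    budget = thresholds.replicate_spread * d.n_residues
    for job in _JOBS:
        reps = d.replicate_energies.get(job, [])
        if len(reps) < thresholds.min_replicates:
            flags.add("TOO_FEW_REPLICATES")
            continue
        if abs(np.median(reps) - min(reps)) > budget:
            flags.add("UNSTABLE_REPLICATES")
    chain_budget = thresholds.chain_outlier * d.n_residues
    for job in ("chainA", "chainB"):
        if job in d.replicate_energies and job in landscape_chain_medians:
            if d.job_min(job) > landscape_chain_medians[job] + chain_budget:
                flags.add("CHAIN_ENERGY_OUTLIER")
    d.qc_flags = flags
    return flags


def decoys_from_table(
    table: pd.DataFrame, thresholds: QCThresholds | None = None
) -> list[DecoyRecord]:
    """Build and QC-filter decoys from a long-format energy table.

    Expected columns: decoy_id, ca_rmsd, job ∈ {complex, chainA, chainB},
    replicate, energy, n_residues.
    """
    decoys = []
    for decoy_id, grp in table.groupby("decoy_id", sort=False):
        reps = {
            job: sub["energy"].astype(float).tolist()
            for job, sub in grp.groupby("job", sort=False)
        }
        decoys.append(
            DecoyRecord(
                decoy_id=str(decoy_id),
                ca_rmsd=float(grp["ca_rmsd"].iloc[0]),
                replicate_energies=reps,
                n_residues=int(grp["n_residues"].iloc[0]),
            )
        )
    medians = {
        job: float(np.median([d.job_min(job) for d in decoys if job in d.replicate_energies]))
        for job in ("chainA", "chainB")
    }
    for d in decoys:
        qc_filter(d, medians, thresholds)
    return decoys


def landscape_flags(
    decoys: Sequence[DecoyRecord], thresholds: QCThresholds | None = None
) -> set[str]:
    """Landscape-level exclusion flags based on QC attrition."""
    thresholds = thresholds or QCThresholds()
    n = len(decoys)
    n_pass = sum(d.passes_qc for d in decoys)
    flags = set()
    if n and (n - n_pass) / n > thresholds.max_filtered_fraction:
        flags.add("HIGH_FILTER_FRACTION")
    if n_pass < thresholds.min_surviving_decoys:
        flags.add("TOO_FEW_DECOYS")
    return flags


# ---------------------------------------------------------------------------
# Selection and discrimination
# ---------------------------------------------------------------------------


def select_landscape(
    decoys: Sequence[DecoyRecord],
    bin_width: float = 2.0,
    target: int = 150,
    crystal_id: str = "",
) -> Landscape:
    """Select up to ``target`` low-ΔG decoys, balanced across RMSD bins.

    Decoys are binned by Cα RMSD (fixed ``bin_width``); the selection goes
    round-robin across occupied bins, each time taking the bin's next-lowest
    ΔG decoy, until the target is reached or decoys run out. Only QC-passing
    decoys participate. Ties break on decoy_id, so the result is invariant to
    input order.
    """
    passing = [d for d in decoys if d.passes_qc]
    bins: dict[int, list[DecoyRecord]] = {}
    for d in passing:
        bins.setdefault(int(d.ca_rmsd // bin_width), []).append(d)
    for b in bins.values():
        b.sort(key=lambda d: (d.dg, d.decoy_id))
    order = sorted(bins)
    selected: list[DecoyRecord] = []
    cursors = {b: 0 for b in order}
    while len(selected) < target:
        progressed = False
        for b in order:
            if len(selected) >= target:
                break
            if cursors[b] < len(bins[b]):
                selected.append(bins[b][cursors[b]])
                cursors[b] += 1
                progressed = True
        if not progressed:
            break
    return Landscape(crystal_id, list(decoys), selected)


def discrimination_score(
    landscape: Landscape | Sequence[DecoyRecord],
    kT: float = DEFAULT_KT,
    near_native_cutoff: float = NEAR_NATIVE_CUTOFF,
) -> float:
    """Boltzmann-weighted probability of near-native decoys in the selection.

    Q = Σ_{rmsd < cutoff} w_i / Σ_all w_i with w_i = exp(−(ΔG_i − ΔG_min)/kT).
    Invariant to adding a constant to all ΔGs; tends to the near-native count
    fraction as kT → ∞ and to an argmin indicator as kT → 0.
    """
    decoys = landscape.selected if isinstance(landscape, Landscape) else list(landscape)
    if not decoys:
        raise ValueError("empty selected decoy set")
    dg = np.array([d.dg for d in decoys])
    rmsd = np.array([d.ca_rmsd for d in decoys])
    w = np.exp(-(dg - dg.min()) / kT)
    return float(np.sum(w[rmsd < near_native_cutoff]) / np.sum(w))
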