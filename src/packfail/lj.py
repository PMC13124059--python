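"""12-6 Lennard-Jones evaluation, cluster minimization, and radius refitting.

The pair potential for atom types *i*, *j* uses the combination rules
``R = r_i + r_j`` and ``ε = √(ε_i ε_j)``. The plain 12-6 form is

    lj(d) = ε[(R/d)^12 − 2(R/d)^6]

with minimum −ε at d = R. The repulsive weight ``w_rep`` scales only the
positive excess of the potential inside the minimum (the repulsive branch),

    E(d) = lj(d)                      for d ≥ R
    E(d) = −ε + w_rep·(lj(d) + ε)     for d < R

which is continuous, keeps the minimum at (R, −ε) for every ``w_rep``, and
reduces to pure 12-6 at ``w_rep = 1``. The attractive/repulsive split reported
alongside the total is the conventional −2ε(R/d)^6 / ε(R/d)^12 decomposition.

Short-range linearization and switching functions used by production
molecular-modelling packages are deliberately not reproduced; this module is a
desk-scale surrogate for studying how radius changes move packing distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence
import warnings

import numpy as np
from scipy.optimize import minimize

from .distributions import BinnedDistribution, bin_distribution, kl_divergence
from .structio import Atom, LJParameterSet, TypedStructure

__all__ = [
    "LJEnergy",
    "LJLandscape",
    "MinimizationResult",
    "RefitResult",
    "lj_energy",
    "pair_landscape",
    "landscape_shift",
    "minimize_cluster",
    "cluster_pair_distances",
    "surrogate_refit_radius",
]


class LJEnergy(NamedTuple):
    total: float | np.ndarray
    attractive: float | np.ndarray
    repulsive: float | np.ndarray


def lj_energy(
    d: float | np.ndarray,
    r_i: float,
    r_j: float,
    eps_i: float,
    eps_j: float,
    w_rep: float = 1.0,
) -> LJEnergy:
    """Evaluate the pair potential at distance(s) ``d`` (Å), in kcal/mol.

    Returns the total energy together with the attractive (−2ε(R/d)^6) and
    repulsive (ε(R/d)^12) components. Raises on non-positive distances.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise ValueError("distance must be positive")
    R = r_i + r_j
    eps = np.sqrt(eps_i * eps_j)
    x6 = (R / d_arr) ** 6
    attractive = -2.0 * eps * x6
    repulsive = eps * x6 * x6
    lj = attractive + repulsive
    total = np.where(d_arr < R, -eps + w_rep * (lj + eps), lj)
    if np.isscalar(d) or d_arr.ndim == 0:
        return LJEnergy(float(total), float(attractive), float(repulsive))
    return LJEnergy(total, attractive, repulsive)


@dataclass
class LJLandscape:
    """Pair energy evaluated on a distance grid for one parameter set."""

    type_pair: tuple[str, str]
    distances: np.ndarray
    energies: np.ndarray
    attractive: np.ndarray
    repulsive: np.ndarray
    params_name: str


def pair_landscape(
    type_pair: tuple[str, str],
    params: LJParameterSet,
    grid: np.ndarray | Sequence[float],
) -> LJLandscape:
    a, b = type_pair
    if a not in params.types or b not in params.types:
        raise KeyError(f"parameter set {params.name} lacks {a} or {b}")
    grid = np.asarray(grid, dtype=float)
    e = lj_energy(grid, params.radius(a), params.radius(b),
                  params.well_depth(a), params.well_depth(b), params.w_rep)
    return LJLandscape(tuple(type_pair), grid, e.total, e.attractive, e.repulsive,
                       params.name)


def landscape_shift(l1: LJLandscape, l2: LJLandscape) -> float:
    """Minimum-location shift (Å) of ``l2`` relative to ``l1`` on their grids.

    Positive values mean the second landscape's minimum sits at larger
    distances (a more repulsive short range).
    """
    d1 = float(l1.distances[np.argmin(l1.energies)])
    d2 = float(l2.distances[np.argmin(l2.energies)])
    return d2 - d1


# ---------------------------------------------------------------------------
# Cluster minimization
# ---------------------------------------------------------------------------


@dataclass
class MinimizationResult:
    structure: TypedStructure
    initial_energy: float
    final_energy: float
    converged: bool
    n_iter: int


def _pair_tables(s: TypedStructure, params: LJParameterSet) -> tuple[np.ndarray, np.ndarray]:
    radii = np.array([params.radius(t) for t in s.atom_types])
    eps = np.array([params.well_depth(t) for t in s.atom_types])
    R = radii[:, None] + radii[None, :]
    E = np.sqrt(eps[:, None] * eps[None, :])
    return R, E


def _cluster_energy_grad(
    x: np.ndarray, R: np.ndarray, eps: np.ndarray, w_rep: float
) -> tuple[float, np.ndarray]:
    n = R.shape[0]
    coords = x.reshape(n, 3)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    iu = np.triu_indices(n, 1)
    dij = np.maximum(d[iu], 1e-6)
    Rij = R[iu]
    eij = eps[iu]
    x6 = (Rij / dij) ** 6
    lj = eij * (x6 * x6 - 2.0 * x6)
    wmask = np.where(dij < Rij, w_rep, 1.0)
    energy = float(np.sum(np.where(dij < Rij, -eij + w_rep * (lj + eij), lj)))
    # dlj/dd = (12 eps / d) (x6 - x12)
    dlj = (12.0 * eij / dij) * (x6 - x6 * x6) * wmask
    grad = np.zeros((n, 3))
    gvec = (dlj / dij)[:, None] * diff[iu]
    np.add.at(grad, iu[0], gvec)
    np.add.at(grad, iu[1], -gvec)
    return energy, grad.ravel()


def cluster_energy(s: TypedStructure, params: LJParameterSet) -> float:
    """Total pairwise LJ energy of a structure (all unordered pairs)."""
    R, eps = _pair_tables(s, params)
    e, _ = _cluster_energy_grad(s.coords.ravel(), R, eps, params.w_rep)
    return e


def minimize_cluster(
    s: TypedStructure,
    params: LJParameterSet,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> MinimizationResult:
    """Gradient-based local minimization of the cluster's total LJ energy.

    Quasi-Newton (L-BFGS-B) with analytic gradients. The returned structure
    never has higher energy than the input; non-convergence within
    ``max_iter`` produces a warning and returns the best iterate.
    """
    if len(s) < 2:
        raise ValueError("need at least two atoms to minimize")
    R, eps = _pair_tables(s, params)
    x0 = s.coords.ravel()
    e0, _ = _cluster_energy_grad(x0, R, eps, params.w_rep)
    res = minimize(
        _cluster_energy_grad,
        x0,
        args=(R, eps, params.w_rep),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter
        warnings.warn(f"minimization did not converge: {res.message}", stacklevel=2)
    elif res.status == 1:
        warnings.warn("minimization hit the iteration limit", stacklevel=2)
    final = min(float(res.fun), e0)
    coords = res.x.reshape(-1, 3) if res.fun <= e0 else s.coords
    return MinimizationResult(
        structure=s.with_coords(coords),
        initial_energy=e0,
        final_energy=final,
        converged=bool(res.success),
        n_iter=int(res.nit),
    )


def cluster_pair_distances(s: TypedStructure, cutoff: float) -> np.ndarray:
    """All unordered interatomic distances ≤ cutoff (no exclusions)."""
    coords = s.coords
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    iu = np.triu_indices(len(s), 1)
    dij = d[iu]
    return np.sort(dij[dij <= cutoff])


# ---------------------------------------------------------------------------
# Surrogate radius refitting
# ---------------------------------------------------------------------------


def _random_cluster(
    n_atoms: int, label: str, spacing: float, rng: np.random.Generator
) -> TypedStructure:
    """Random homogeneous cluster with a minimum-separation guarantee."""
    side = spacing * max(2.0, n_atoms ** (1.0 / 3.0) * 1.3)
    coords: list[np.ndarray] = []
    while len(coords) < n_atoms:
        cand = rng.uniform(0.0, side, size=3)
        if all(np.linalg.norm(cand - c) > 0.7 * spacing for c in coords):
            coords.append(cand)
    atoms = [
        Atom("A", i + 1, "UNK", label, label[0], tuple(map(float, c)))
        for i, c in enumerate(coords)
    ]
    return TypedStructure(atoms, [label] * n_atoms)


@dataclass
class RefitResult:
    radius: float
    grid: np.ndarray
    kl_values: np.ndarray
    type_label: str


def surrogate_refit_radius(
    target: BinnedDistribution,
    type_label: str,
    params: LJParameterSet,
    grid: Sequence[float],
    seed: int = 0,
    n_clusters: int = 4,
    n_atoms: int = 16,
    pseudocount: float = 0.5,
) -> RefitResult:
    """Grid-search refit of one atom type's LJ radius against a target
    distance distribution.

    For each candidate radius, seeded random clusters are LJ-minimized, their
    pooled pair distances are histogrammed on the target's bin edges, and the
    KL divergence of the target from the candidate distribution is scored.
    The candidate with minimal KL wins. This is an explicit, desk-scale
    stand-in for full multi-benchmark parameter optimization.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty candidate grid")
    cutoff = float(target.edges[-1])
    kls = np.empty(grid.size)
    # identical seeded starting clusters across candidates to reduce noise
    rngs = [np.random.default_rng((seed, k)) for k in range(n_clusters)]
    inits = [
        _random_cluster(n_atoms, type_label, 2.0 * params.radius(type_label), rng)
        for rng in rngs
    ]
    for gi, r_cand in enumerate(grid):
        cand_params = params.with_radius(type_label, float(r_cand))
        pooled: list[np.ndarray] = []
        for init in inits:
            relaxed = minimize_cluster(init, cand_params).structure
            pooled.append(cluster_pair_distances(relaxed, cutoff))
        distances = np.concatenate(pooled)
        if distances.size == 0:
            kls[gi] = np.inf
            continue
        q = bin_distribution(distances, pseudocount=pseudocount, edges=target.edges)
        kls[gi] = kl_divergence(target, q)
    best = int(np.argmin(kls))
    return RefitResult(float(grid[best]), grid, kls, type_label)
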