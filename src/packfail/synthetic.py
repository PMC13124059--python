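"""Seeded generators for every input the analysis stages consume.

Each generator emits both the data table (in the exact dialect the analysis
modules read) and a truth table, so downstream recovery tests can compare
estimates with known ground truth. All randomness flows through a single seed
per generator call; a fixed seed yields bit-identical output.

The generators emulate the statistical structure of the real experiments —
sigmoidal protease-survival count data, LJ-packed atom clusters with a known
native/overpacked contrast, funnel-shaped decoy energy landscapes, and
ΔΔG datasets with known class labels — not their full biological complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ddg import MUTATION_CATEGORIES, dg_to_kd, kd_to_dg
from .dms import DEFAULT_DILUTION_RATIO, DEFAULT_HILL, NONPOLAR_AA
from .lj import minimize_cluster, _random_cluster
from .structio import LJParameterSet, TypedStructure, baseline_parameters

__all__ = [
    "DmsSimSpec",
    "ClusterSimSpec",
    "FunnelSimSpec",
    "simulate_dms",
    "simulate_packed_cluster",
    "simulate_landscape",
    "simulate_ddg",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DmsSimSpec:
    """Conditions of a simulated deep-mutational-scanning selection.

    Mutational effects are a point mass at zero (neutral) plus stabilizing
    and destabilizing tails with the stated weights; roughly matching the
    observed pattern where about 1% of mutations to unstable designs are
    strongly stabilizing and the positive tail outweighs the negative one.
    """

    n_designs: int = 1
    n_sites: int = 20
    mutants_per_site: int = 10
    dilution_ratio: float = DEFAULT_DILUTION_RATIO
    unmutated_ec50: float = 3.0
    neutral_weight: float = 0.96
    stabilizing_weight: float = 0.01
    destabilizing_weight: float = 0.03
    # destabilizing effects are floor-limited: a design with almost no folding
    # stability has little left to lose, so the negative tail stays short
    stabilizing_effect: float = 2.0
    destabilizing_effect: float = -0.75
    hill: float = DEFAULT_HILL
    read_depth: int = 1000            # expected reads per variant per column
    n_replicates: int = 2
    n_proteases: int = 2
    n_concentrations: int = 6
    overdispersion: float = 0.0       # negative-binomial knob; 0 = multinomial
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.neutral_weight + self.stabilizing_weight + self.destabilizing_weight
        if abs(w - 1.0) > 1e-9:
            raise ValueError("effect-class weights must sum to 1")
        if self.read_depth <= 0:
            raise ValueError("read depth must be positive")


def simulate_dms(spec: DmsSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate protease-selection count tables with known EC50s.

    Returns ``(counts, truth)``. ``counts`` is the long-format table the DMS
    pipeline reads (design_id, site, mutant_aa, protease, conc_index,
    replicate, count); ``truth`` carries each variant's true EC50 and true
    stability-score change relative to the unmutated design.
    """
    rng = np.random.default_rng(spec.seed)
    proteases = ["trypsin", "chymotrypsin"][: spec.n_proteases]
    counts_rows = []
    truth_rows = []
    for d in range(spec.n_designs):
        design = f"design_{d:03d}"
        wt_aa = rng.choice(list(_AA), size=spec.n_sites)
        variants: list[tuple[int, str, str]] = [(0, "WT", "")]
        effects = [0.0]
        classes = ["neutral"]
        for s in range(spec.n_sites):
            pool = [a for a in _AA if a != wt_aa[s]]
            muts = rng.choice(pool, size=min(spec.mutants_per_site, len(pool)),
                              replace=False)
            for m in muts:
                cls = rng.choice(
                    ["neutral", "stabilizing", "destabilizing"],
                    p=[spec.neutral_weight, spec.stabilizing_weight,
                       spec.destabilizing_weight],
                )
                eff = {"neutral": 0.0,
                       "stabilizing": spec.stabilizing_effect,
                       "destabilizing": spec.destabilizing_effect}[cls]
                variants.append((s + 1, m, wt_aa[s]))
                effects.append(eff)
                classes.append(cls)
        effects_arr = np.array(effects)
        true_ec50 = spec.unmutated_ec50 + effects_arr
        n_var = len(variants)
        # library composition: mildly uneven initial frequencies
        f0 = rng.lognormal(0.0, 0.3, size=n_var)
        f0 /= f0.sum()
        total_reads = spec.read_depth * n_var
        concs = np.arange(0, spec.n_concentrations + 1)
        for protease in proteases:
            for rep in range(1, spec.n_replicates + 1):
                for x in concs:
                    if x == 0:
                        probs = f0
                        n_reads = total_reads
                    else:
                        expo = spec.hill * (x - true_ec50) * np.log(spec.dilution_ratio)
                        surv = 1.0 / (1.0 + np.exp(np.clip(expo, -500, 500)))
                        mass = f0 * surv
                        # sequencing depth tracks the surviving material, so
                        # counts carry absolute (not just relative) survival
                        n_reads = int(rng.poisson(total_reads * mass.sum()))
                        probs = mass / mass.sum()
                    if spec.overdispersion > 0:
                        lam = rng.gamma(1.0 / spec.overdispersion,
                                        spec.overdispersion, size=n_var)
                        probs = probs * lam
                        probs /= probs.sum()
                    draws = rng.multinomial(n_reads, probs)
                    for (site, mut, _wt), c in zip(variants, draws):
                        counts_rows.append(
                            (design, site, mut, protease, int(x), rep, int(c))
                        )
        for (site, mut, wt), eff, cls, ec in zip(variants, effects, classes, true_ec50):
            truth_rows.append((design, site, mut, wt, cls, float(ec), float(eff)))
    counts = pd.DataFrame(
        counts_rows,
        columns=["design_id", "site", "mutant_aa", "protease", "conc_index",
                 "replicate", "count"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["design_id", "site", "mutant_aa", "wt_aa", "effect_class",
                 "true_ec50", "true_delta_score"],
    )
    return counts, truth


# ---------------------------------------------------------------------------
# Packed atom clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterSimSpec:
    """A relaxed ("native-like") cluster and an overpacked ("design-like") copy.

    The overpack factor uniformly shrinks coordinates about the centroid,
    reproducing the qualitative contrast where design models pack atoms
    tighter than experimentally determined structures.
    """

    n_atoms: Mapping[str, int] = field(default_factory=lambda: {"CH3": 24})
    params: LJParameterSet | None = None
    overpack_factor: float = 0.9
    contact_margin: float = 1.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.overpack_factor <= 1.0):
            raise ValueError("overpack factor must be in (0, 1]")
        if self.contact_margin < 1.0:
            raise ValueError("contact margin must be >= 1")


def simulate_packed_cluster(spec: ClusterSimSpec) -> tuple[TypedStructure, TypedStructure]:
    """Return ``(relaxed, overpacked)`` synthetic atom clusters.

    Atoms are placed randomly, LJ-minimized (the native-like surrogate), then
    copied with coordinates scaled by the overpack factor about the centroid.
    Native contact distances concentrate at or slightly beyond the van der
    Waals radius sum, so the relaxation runs with radii inflated by
    ``contact_margin``; clash counting against the unscaled parameter set then
    sees near-native packing with few strict clashes, while the overpacked
    copy clashes heavily. Each atom sits in its own residue so pair-distance
    exclusion rules do not remove any pair.
    """
    params = spec.params or baseline_parameters()
    # nature is plain 12-6 (w_rep = 1); softened repulsion is an energy-function
    # trait, not a property of the native packing being emulated
    relax_params = LJParameterSet(
        params.name + "_margin",
        {k: (r * spec.contact_margin, e) for k, (r, e) in params.types.items()},
        1.0,
    )
    rng = np.random.default_rng(spec.seed)
    # build a mixed-type cluster; reuse the homogeneous placer per type
    atoms = []
    types = []
    for label, n in spec.n_atoms.items():
        sub = _random_cluster(n, label, 2.0 * params.radius(label), rng)
        for a, t in zip(sub.atoms, sub.atom_types):
            atoms.append(a)
            types.append(t)
    merged = TypedStructure(atoms, types, source_id="synthetic_cluster")
    # reindex residues so every atom is its own residue
    from dataclasses import replace as _replace
    merged.atoms = [
        _replace(a, residue_index=i + 1) for i, a in enumerate(merged.atoms)
    ]
    relaxed = minimize_cluster(merged, relax_params).structure
    coords = relaxed.coords
    centroid = coords.mean(axis=0)
    shrunk = centroid + spec.overpack_factor * (coords - centroid)
    overpacked = relaxed.with_coords(shrunk)
    overpacked.source_id = "synthetic_cluster_overpacked"
    return relaxed, overpacked


# ---------------------------------------------------------------------------
# Funnel landscapes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FunnelSimSpec:
    """A funnel-shaped decoy energy landscape with replicate noise.

    ΔG decreases linearly toward RMSD 0 inside ``funnel_radius`` at slope
    ``funnel_depth`` (kcal/mol per Å) and is flat outside, plus Gaussian decoy
    noise; replicate energies add one-sided (half-normal) noise so the
    replicate minimum approximates the underlying value. A ``corrupt_fraction``
    of decoys get deliberately broken replicates or chain energies to exercise
    both QC filters.
    """

    n_decoys: int = 300
    rmsd_max: float = 20.0
    funnel_radius: float = 5.0
    funnel_depth: float = 2.0       # kcal/mol per Å
    noise_sd: float = 0.5
    replicate_noise_sd: float = 0.3
    n_replicates: int = 3
    n_residues: int = 200
    corrupt_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_decoys <= 0:
            raise ValueError("need at least one decoy")


def simulate_landscape(spec: FunnelSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a decoy energy table plus its truth table.

    Returns ``(table, truth)`` where ``table`` has the long format read by
    :func:`packfail.interface.decoys_from_table` and ``truth`` records each
    decoy's noise-free ΔG and corruption status.
    """
    rng = np.random.default_rng(spec.seed)
    rmsd = rng.uniform(0.0, spec.rmsd_max, size=spec.n_decoys)
    dg_true = -spec.funnel_depth * np.maximum(0.0, spec.funnel_radius - rmsd)
    dg = dg_true + rng.normal(0.0, spec.noise_sd, size=spec.n_decoys)
    e_chain_a = -1.0 * spec.n_residues / 2
    e_chain_b = -1.2 * spec.n_residues / 2
    n_corrupt = int(round(spec.corrupt_fraction * spec.n_decoys))
    corrupt_idx = rng.choice(spec.n_decoys, size=n_corrupt, replace=False)
    corrupt_mode = {
        int(i): ("replicates" if k % 2 == 0 else "chain")
        for k, i in enumerate(corrupt_idx)
    }
    rows = []
    truth_rows = []
    for i in range(spec.n_decoys):
        decoy_id = f"decoy_{i:05d}"
        base = {
            "complex": e_chain_a + e_chain_b + dg[i],
            "chainA": e_chain_a,
            "chainB": e_chain_b,
        }
        mode = corrupt_mode.get(i)
        if mode == "chain":
            base["chainA"] = base["chainA"] + 0.3 * spec.n_residues
        for job, e0 in base.items():
            for rep in range(1, spec.n_replicates + 1):
                e = e0 + abs(rng.normal(0.0, spec.replicate_noise_sd))
                if mode == "replicates" and job == "complex" and rep > 1:
                    e = e0 + 0.3 * spec.n_residues  # blow up the replicate spread
                rows.append((decoy_id, float(rmsd[i]), job, rep, float(e),
                             spec.n_residues))
        truth_rows.append((decoy_id, float(rmsd[i]), float(dg_true[i]),
                           mode or "clean"))
    table = pd.DataFrame(
        rows, columns=["decoy_id", "ca_rmsd", "job", "replicate", "energy",
                       "n_residues"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["decoy_id", "ca_rmsd", "dg_true", "corruption"],
    )
    return table, truth


# ---------------------------------------------------------------------------
# ΔΔG datasets
# ---------------------------------------------------------------------------


def simulate_ddg(
    n: int = 600,
    noise_sd: float = 1.0,
    class_weights: tuple[float, float, float] = (0.25, 0.5, 0.25),
    seed: int = 0,
    temperature: float = 298.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate SKEMPI-style binding records with known ΔΔG classes.

    True ΔΔGs are drawn per class (stabilizing, neutral, destabilizing with
    the given weights); wildtype and mutant Kd values are back-computed from
    the ΔGs so the Kd→ΔG→ΔΔG path round-trips exactly. Predictions are the
    truth plus Gaussian noise. Returns ``(records, truth)``.
    """
    if abs(sum(class_weights) - 1.0) > 1e-9:
        raise ValueError("class weights must sum to 1")
    rng = np.random.default_rng(seed)
    cls = rng.choice(["stabilizing", "neutral", "destabilizing"], size=n,
                     p=list(class_weights))
    ddg_true = np.where(
        cls == "stabilizing", rng.uniform(-3.0, -1.2, size=n),
        np.where(cls == "destabilizing", rng.uniform(1.2, 3.0, size=n),
                 rng.uniform(-0.8, 0.8, size=n)),
    )
    dg_wt = rng.uniform(-14.0, -6.0, size=n)
    dg_mut = dg_wt + ddg_true
    kd_wt = dg_to_kd(dg_wt, temperature)
    kd_mut = dg_to_kd(dg_mut, temperature)
    category = rng.choice(MUTATION_CATEGORIES, size=n)
    # a pool of structures, each hosting many mutations
    complex_ids = [f"cplx_{i % max(1, n // 20):03d}" for i in range(n)]
    records = pd.DataFrame(
        {
            "complex_id": complex_ids,
            "mutation": [f"mut_{i:05d}" for i in range(n)],
            "kd_wt": kd_wt,
            "kd_mut": kd_mut,
            "temperature": temperature,
            "category": category,
            "single_mutant": True,
            "temperature_known": True,
            "predicted_ddg": ddg_true + rng.normal(0.0, noise_sd, size=n),
        }
    )
    truth = pd.DataFrame(
        {
            "mutation": records["mutation"],
            "ddg_true": ddg_true,
            "class_true": cls,
        }
    )
    return records, truth
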