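# packfail

Diagnostics for steric-packing failure modes of protein-design energy
functions.

Energy functions built on classical mechanics — a Lennard-Jones (LJ) term for
van der Waals interactions plus solvation, electrostatics, and hydrogen
bonding — are used both to *design* new proteins and to *refine* experimental
structures. When such an energy function under-penalizes atomic overlap, it
quietly packs sidechains too tightly: design models accumulate **steric
clashes** (atom pairs closer than the sum of their van der Waals radii,
d < r_i + r_j) that real structures relieve, and refinement drags native
structures toward the same overpacked geometry. `packfail` implements the
computational machinery to detect, quantify, and help fix this failure mode:

- **Clash analysis** — typed atom-pair distance distributions from PDB
  structures (methyl carbons, apolar hydrogens, backbone oxygens, polar vs
  nonpolar sidechain carbons), strict clash counting, and design-vs-crystal
  clash ratios.
- **Distance-distribution benchmark** — per-pair Kullback–Leibler divergence
  between before/after-optimization distributions, aggregated as a √N-weighted
  score `Σ √N_i · KL_i / Σ √N_i` over pairs with ≥ 100 instances, with a
  paired sign-flip randomization test for score differences.
- **DMS rescue analysis** — EC50 inference from protease-selection deep
  sequencing via a Poisson count likelihood on the sigmoidal survival curve
  `f(c) = 1 / (1 + (c/EC50)^h)`, stability scores (observed − unfolded-state
  EC50 on the log-dilution scale), min-over-proteases / mean-over-replicates
  aggregation, and calling of *rescue mutations* (Δ stability score > 1.0)
  with polarity- and size-transition classes.
- **Interface discrimination** — rigid-body jitter decoys (0–2 Å translation,
  0–10° rotation), binding ΔG = E_complex − (E_chainA + E_chainB), replicate
  and chain-energy QC filters (0.1 energy units per residue), RMSD-binned
  low-ΔG selection (2 Å bins, 150 structures), and the Boltzmann-weighted
  near-native discrimination score
  `Q = Σ_{rmsd<2Å} e^{−ΔG_i/kT} / Σ_all e^{−ΔG_i/kT}`.
- **ΔΔG classification** — Kd→ΔG conversion (ΔG = 1.987·10⁻³·T·ln Kd),
  stabilizing / neutral / destabilizing classes at ±1 kcal/mol, McNemar's
  test for paired classifier comparison, and SKEMPI-style category-balanced
  downsampling.
- **LJ surrogate refitting** — 12-6 pair landscapes, gradient-based cluster
  minimization, and a grid-search refit that recovers an atom type's LJ
  radius from a target distance distribution.
- **Synthetic data** — seeded generators (with truth tables) for every input
  above, so the full pipeline runs and validates without any downloads.

## Worked example

Simulate a deep mutational scan of one unstable miniprotein design (two
proteases, two replicates), fit EC50s and stability scores, and call rescue
mutations:

```console
$ packfail simulate dms --seed 11 --out sim
wrote synthetic dms data to sim
$ packfail dms-scores --counts sim/counts.tsv --out scores
wrote 201 variant scores to scores/scores.csv
$ packfail rescue --scores scores/scores.csv --out rescues
1 rescue mutations
$ head -2 rescues/rescues.csv
design_id,site,mutant_aa,score,score_chymotrypsin,score_trypsin,delta_score
design_000,14,A,5.000000000000006,5.000000000000006,5.060000000000006,1.98...
```

The one called rescue raises the design's stability score by Δ = 1.98
dilution-index units above the unmutated design — a strongly stabilizing
point mutation of the kind that reveals what the design protocol got wrong.
The same CLI drives the other stages; for instance a funnel-shaped decoy
landscape scores high discrimination:

```console
$ packfail simulate landscape --seed 11 --out land
$ packfail discriminate --decoys land/decoys.csv --out disc
discrimination score: 0.969
```

i.e. 96.9% of the Boltzmann probability mass of the selected landscape sits
on near-native (< 2 Å) decoys. Every subcommand writes a `manifest.json`
recording the configuration, seed, package version, and input checksums.

## Layout

| module | role |
| --- | --- |
| `packfail.structio` | PDB I/O (via gemmi), atom typing, ideal hydrogen placement, LJ parameter tables, energy-term grouping |
| `packfail.clash` | pair distances, clash counting, design/crystal comparison |
| `packfail.distributions` | binning, KL, benchmark score, randomization test |
| `packfail.lj` | 12-6 evaluation, cluster minimization, radius refit |
| `packfail.dms` | enrichment, EC50 fits, stability scores, rescue calls |
| `packfail.interface` | jitter decoys, RMSD, QC, selection, discrimination |
| `packfail.ddg` | Kd→ΔG, classification, McNemar, downsampling |
| `packfail.synthetic` | seeded generators + truth tables |
| `packfail.cli` | `packfail` subcommands and run manifests |

See `docs/methods.md` for the underlying models, parameter defaults, and the
limits of what the synthetic benchmarks demonstrate.
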