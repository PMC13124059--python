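# Methods

This note documents the models behind each `packfail` stage, the parameter
defaults and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Clash detection and atom typing

A *clash* is an atom pair at distance strictly less than the sum of the two
atoms' van der Waals radii; a pair at exactly the radius sum is not a clash.
Radii always come from the active `LJParameterSet` (a JSON config); the two
tables shipped in `packfail/data/` are **synthetic placeholders** with
literature-plausible values, not any published energy function's parameters,
and must be replaced for quantitative comparisons against published work.

Distance distributions are truncated 0.5 Å above the radius sum, so each
distribution describes only the close-contact region around the clash
boundary. Pairs within the same residue are always excluded; the default
exclusion additionally removes backbone–backbone pairs of sequence-adjacent
residues (these are covalently constrained, not packing contacts). A stricter
mode excludes atoms within ≤ 3 covalent bonds using a bond graph inferred
from residue templates plus peptide bonds. Production pairing uses a k-d tree
(`scipy.spatial.cKDTree`); tests hold it to exact agreement with a brute-force
all-pairs scan.

Atom typing is coarse and per-residue for the polar/nonpolar carbon split:
every non-methyl sidechain carbon inherits its residue's polarity. The default
nonpolar set is {ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, GLY, CYS} and is
configurable. Methyl carbons (VAL CG1/CG2, LEU CD1/CD2, ILE CD1/CG2, ALA CB,
THR CG2, MET CE) are typed `CH3`; backbone carbonyl/terminal oxygens `OCbb`;
hydrogens bonded to carbon `Hapo` (parent inferred from PDB naming
conventions).

Aliphatic hydrogens are placed with ideal geometry: 1.09 Å C–H bonds,
tetrahedral (109.47°) angles, methyl rotamers staggered against the upstream
heavy-atom branch. Placement is idempotent and never moves existing
hydrogens. Polar-hydrogen optimization is out of scope.

## Distance-distribution benchmark

For each atom-type pair, distances observed before and after a structure
optimization step are histogrammed on shared fixed-width bins (default
0.05 Å — finer than the tenths-of-Ångström shifts the benchmark must
resolve) with a pseudocount of 0.5 per bin, and compared by KL divergence
`Σ P ln(P/Q)` in nats. **Direction convention:** P is the before
(reference) distribution and Q the after distribution; the benchmark
definition does not force this choice, so it is documented here and swapped
simply by swapping arguments. The aggregate benchmark score is the mean KL
over pairs with at least 100 observed instances, weighted by √N.

Score differences between two energy functions are tested by a paired
sign-flip randomization: each item's pair of scores is swapped with
probability ½ per iterate (default 1,000 iterates, seeded). The p-value is
reported with the +1 correction (k+1)/(n+1), which can never be exactly
zero, together with the raw fraction k/n for comparison with values printed
as "x/1000". Under exchangeable null scores the +1-corrected p-value is
approximately uniform (the acceptance suite checks the rejection rate at
0.05 stays within [0.03, 0.07]).

## Lennard-Jones model and surrogate refit

Pair potential with combination rules R = r_i + r_j, ε = √(ε_i ε_j):

    lj(d) = ε[(R/d)^12 − 2(R/d)^6]

The repulsive weight `w_rep` scales only the positive excess inside the
minimum:

    E(d) = lj(d)                      d ≥ R
    E(d) = −ε + w_rep·(lj(d) + ε)     d < R

This branch-weighted form is continuous, keeps the minimum at (R, −ε) for
every `w_rep`, and reduces to plain 12-6 at `w_rep = 1`. (Scaling the
ε(R/d)^12 component alone would shift the minimum and break continuity at R;
the attractive/repulsive split reported to callers is nonetheless the
conventional −2ε(R/d)^6 / ε(R/d)^12 decomposition.) Short-range
linearization and switching functions used by production packages are
deliberately not reproduced — this module is a desk-scale surrogate for
studying how radius changes move packing distances, not a drop-in energy
function.

Cluster minimization is quasi-Newton (L-BFGS-B) with analytic gradients,
gradient tolerance 10⁻⁶ kcal/mol/Å, at most 2,000 iterations; the returned
structure never has higher energy than the input.

The radius refit is an explicit grid search standing in for full
multi-benchmark parameter optimization: for each candidate radius, seeded
random clusters (default 4 clusters × 16 atoms) are LJ-minimized, their
pooled pair distances histogrammed on the target's bin edges, and
KL(target ‖ candidate) scored; the minimal-KL candidate wins. Because a
minimized cluster's modal neighbor distance tracks the pair-minimum R, a
radius planted in the target generator is recovered to within the grid
step (the acceptance suite demands a median error < 0.1 Å over 20 seeds on
a 1.6–2.2 Å grid with 0.05 Å steps).

## DMS pipeline

The emulated experiment displays a saturation-mutagenesis library on yeast,
digests unstable variants with a protease at six concentrations forming a
geometric dilution series (ratio ρ = 3 by default; index 0 = unselected),
and deep-sequences before and after selection. Survival follows
`f(x) = 1/(1 + ρ^{h(x − EC50)})` on the concentration-index scale with a
shared Hill slope (default h = 2). The stability score is the difference, in
index units, between a variant's observed EC50 and the predicted EC50 of its
unfolded chain; the unfolded-state predictor is an external input (a
constant baseline serves for synthetic work). Scores aggregate as the
minimum across proteases within a replicate (the harsher protease wins),
then the mean across replicates. A *rescue mutation* raises the unmutated
design's score by strictly more than 1.0.

**EC50 likelihood.** Counts are modelled as Poisson with mean
λ·f0_v·f(x; EC50_v), where λ is the unselected column total and f0_v the
variant's unselected frequency (pseudocount 0.5). This absolute-abundance
model requires sequencing depth to track the amount of surviving material
across concentrations, and the synthetic generator produces exactly that.
The point matters: counts re-normalized to a fixed per-column depth are
invariant under a uniform shift of every variant's EC50 (a nearly uniform
library has no internal anchor for absolute survival), so only EC50
*differences* would be identifiable. Real implementations of this assay
anchor the scale with cell-sorting bookkeeping (the fraction of cells
collected); that machinery is out of scope here, and depth-tracks-survival
is this package's stated stand-in. Estimation maximizes the Poisson log
likelihood on a fixed EC50 grid (−2 to 10, step 0.04); 95% CIs are
profile-likelihood intervals from the same grid; estimates outside the
tested range [1, 6] are clamped to the boundary and flagged censored.

## Interface discrimination

Decoys perturb one chain rigidly: rotation by an angle uniform on [0°, 10°]
about a uniformly random axis through the moving chain's centroid, then
translation by a magnitude uniform on [0, 2] Å in a uniformly random 3D
direction. The rotation centre is a documented choice (the convention is not
forced by the benchmark definition). Cα RMSD to the starting crystal is
computed in the fixed-chain frame with no re-superposition, so the fixed
chain contributes zero.

Energies are external inputs, one list of replicate optimization energies per
job (complex, chain A, chain B); each job's energy is the minimum over
replicates and ΔG = E_complex − (E_chainA + E_chainB). QC discards a decoy
when any job has fewer than 2 replicates, when any job's |median − min|
exceeds 0.1 energy units per residue, or when a chain minimum exceeds the
landscape median for that chain by more than 0.1 per residue. Landscape-level
flags mark > 15% filtered decoys or < 1,000 survivors (both configurable).

Selection bins QC-passing decoys by Cα RMSD (2 Å bins) and takes each bin's
next-lowest-ΔG decoy round-robin until 150 structures are selected; ties
break on decoy id, so selection is invariant to input order. The
discrimination score is the Boltzmann probability mass on near-native decoys,
`Q = Σ_{rmsd<cutoff} e^{−(ΔG−ΔG_min)/kT} / Σ_all e^{−(ΔG−ΔG_min)/kT}`, with
near-native cutoff 2.0 Å (the first bin) and kT = 1.0 energy unit — both
mandatory config with these documented defaults, since the benchmark
literature leaves them to convention. Q is invariant to constant ΔG shifts,
tends to the near-native count fraction as kT → ∞, and to an argmin
indicator as kT → 0.

## ΔΔG statistics

ΔG = 1.987·10⁻³ · T · ln(Kd) kcal/mol with T in Kelvin and Kd in molar;
ΔΔG = ΔG_mut − ΔG_wt. Classes: stabilizing (< −1), destabilizing (> +1),
neutral (the closed interval [−1, 1] — the boundary convention is a
documented choice). McNemar's test on the discordant cells of the paired
2×2 table uses the exact two-sided binomial at p = ½ for b + c ≤ 25 and the
continuity-corrected χ² above (standard small-sample practice).
Category-balanced downsampling filters to records from structures with ≥ 10
measurements, measured in a single-mutant context, with known (not assumed)
temperature, then samples toward target/4 per polarity-transition category,
taking everything from smaller categories and redistributing the shortfall.

## Synthetic generators

All generators are deterministic under a fixed seed and emit truth tables
alongside the data, in the exact file dialects the analysis stages read.

- **DMS**: effects are a point mass at zero plus a stabilizing tail
  (weight 0.01, +2.0 index units — so roughly 1% of mutations are true
  rescues) and a destabilizing tail (weight 0.03, −0.75). The destabilizing
  magnitude is deliberately sub-threshold: a design with almost no folding
  stability has little left to lose, so the negative tail stays short and
  the fitted Δ-score distribution shows the heavier positive tail
  characteristic of rescue screens on unstable designs. Default conditions:
  1 design, 6 concentrations + unselected, dilution ratio 3, Hill slope 2,
  2 proteases, 2 replicates, read depth 1,000 per variant (the recovery
  analyses also run at 10,000). Count noise is multinomial; a
  negative-binomial overdispersion knob exists for robustness tests.
- **Packed clusters**: atoms placed randomly with a minimum-separation
  guarantee, then LJ-minimized under plain 12-6 physics (w_rep = 1 — the
  softened repulsion is an energy-function trait, not a property of the
  native packing being emulated) with radii inflated by a contact margin of
  1.05. The margin encodes the empirical fact that native contact distances
  concentrate at or slightly beyond the nominal radius sum; without it, the
  ~1% many-body compression of minimized clusters would put half of all
  nearest neighbors infinitesimally inside the strict clash line. The
  overpacked copy scales coordinates by 0.9 about the centroid. Against the
  unscaled parameter table, the native-like cluster shows < 5% clashing
  close pairs and the overpacked copy > 30% — the qualitative
  design-vs-native contrast.
- **Funnel landscapes**: RMSDs uniform on [0, 20] Å; ΔG decreases linearly
  toward RMSD 0 inside a 5 Å funnel at the stated depth (kcal/mol per Å)
  plus N(0, 0.5) decoy noise; replicate energies add half-normal (σ = 0.3)
  one-sided noise so the replicate minimum approximates the underlying
  value. A configurable fraction of decoys receive deliberately broken
  replicates or chain energies sized to trip each QC filter.
- **ΔΔG records**: true ΔΔGs drawn per class (stabilizing U(−3, −1.2),
  neutral U(−0.8, 0.8), destabilizing U(1.2, 3)); Kd pairs back-computed
  through the inverse of the ΔG formula so the conversion round-trips
  exactly; predictions are truth + Gaussian noise.

**What passing the synthetic benchmarks does and does not show.** The
generators reproduce the *statistical structure* each stage assumes —
sigmoidal count depletion, funnel-plus-noise landscapes, near-minimum
packing — not real data's complications: no sequencing error or index
hopping, no position-dependent mutational biases, no real protein backbones
or crystal-packing contacts, no correlated replicate failures, and survival
curves share a single Hill slope. Recovery results therefore validate the
estimators and the plumbing, not performance on any particular experimental
dataset. Analyses of real structure sets and published benchmark tables run
through the same operations but require those external inputs.

## Numerical conventions

- Strict inequality for clashes; ties at the radius sum are non-clashes.
- KL requires identical bin edges; pseudocount smoothing guarantees
  positive probabilities in every bin.
- Randomization, selection, and sampling are seeded; selection tie-breaks on
  decoy id; downsampling sorts indices before `rng.choice`.
- EC50 grid resolution 0.04 index units bounds the quantization error of
  estimates and CIs; censoring clamps to the tested boundary.
- Minimization accepts the best iterate on non-convergence and warns.

## Known limitations

- The shipped LJ parameter tables are synthetic placeholders; every
  radius-dependent number changes with a real table.
- The EC50 model omits the cell-sorting selection step of the real assay
  and assumes depth proportional to surviving material (see above).
- `align_pair_sequences` matches residues by chain and author numbering; it
  does not perform sequence alignment and rejects internal mismatches
  rather than resolving them.
- No mmCIF input, no crystal-symmetry contact expansion, no disulfide
  detection; single-model PDB files only.
- The refit searches one radius at a time; joint multi-type refits and
  well-depth fitting are out of scope.
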