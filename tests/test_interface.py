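"""Decoy jitter, RMSD, QC filters, landscape selection, and discrimination."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist

from packfail.interface import (
    DecoyRecord,
    QCThresholds,
    ca_rmsd,
    decoys_from_table,
    discrimination_score,
    jitter,
    landscape_flags,
    qc_filter,
    select_landscape,
)
from packfail.structio import TypedStructure
from packfail.synthetic import FunnelSimSpec, simulate_landscape

from conftest import make_atom


def two_chain_complex(n_per_chain=8, seed=0):
    rng = np.random.default_rng(seed)
    atoms = []
    for ci, chain in enumerate("AB"):
        base = np.array([ci * 15.0, 0.0, 0.0])
        for i in range(n_per_chain):
            xyz = base + rng.uniform(0, 8, size=3)
            atoms.append(make_atom(chain, i + 1, "GLY", "CA", "C", tuple(xyz)))
    return TypedStructure(atoms)


def decoy(decoy_id, rmsd, dg, n_res=100, reps=None):
    energies = reps or {
        "complex": [-200.0 + dg, -199.5 + dg],
        "chainA": [-100.0, -99.7],
        "chainB": [-100.0, -99.8],
    }
    return DecoyRecord(decoy_id, rmsd, energies, n_res)


class TestJitter:
    def test_moving_chain_stays_rigid(self):
        s = two_chain_complex()
        j = jitter(s, "B", seed=1)
        mask = np.array([a.chain_id == "B" for a in s.atoms])
        before = pdist(s.coords[mask])
        after = pdist(j.coords[mask])
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_fixed_chain_untouched(self):
        s = two_chain_complex()
        j = jitter(s, "B", seed=2)
        mask = np.array([a.chain_id == "A" for a in s.atoms])
        np.testing.assert_allclose(j.coords[mask], s.coords[mask])

    def test_centroid_displacement_bounded(self):
        s = two_chain_complex()
        mask = np.array([a.chain_id == "B" for a in s.atoms])
        for seed in range(50):
            j = jitter(s, "B", seed=seed)
            shift = np.linalg.norm(
                j.coords[mask].mean(axis=0) - s.coords[mask].mean(axis=0)
            )
            assert shift <= 2.0 + 1e-9

    def test_translation_magnitudes_uniform(self):
        s = two_chain_complex()
        mask = np.array([a.chain_id == "B" for a in s.atoms])
        rng = np.random.default_rng(0)
        mags = []
        for _ in range(2000):
            j = jitter(s, "B", seed=rng)
            mags.append(np.linalg.norm(
                j.coords[mask].mean(axis=0) - s.coords[mask].mean(axis=0)))
        p = stats.kstest(np.array(mags) / 2.0, "uniform").pvalue
        assert p > 0.01

    def test_missing_chain_error(self):
        with pytest.raises(KeyError):
            jitter(two_chain_complex(), "Z", seed=0)


class TestCaRmsd:
    def test_identical_structures_zero(self):
        s = two_chain_complex()
        assert ca_rmsd(s, s) == 0.0

    def test_half_translated_closed_form(self):
        s = two_chain_complex(n_per_chain=10)
        mask = np.array([a.chain_id == "B" for a in s.atoms])
        coords = s.coords.copy()
        coords[mask] += np.array([1.0, 0.0, 0.0])
        moved = s.with_coords(coords)
        assert ca_rmsd(moved, s) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_invariant_to_atom_order(self):
        s = two_chain_complex()
        reordered = TypedStructure(list(reversed(s.atoms)),
                                   list(reversed(s.atom_types)))
        moved = s.with_coords(s.coords + 0.5)
        assert ca_rmsd(moved, s) == pytest.approx(ca_rmsd(moved, reordered))

    def test_residue_mismatch_error(self):
        s = two_chain_complex()
        shorter = TypedStructure(s.atoms[:-1], s.atom_types[:-1])
        with pytest.raises(ValueError):
            ca_rmsd(shorter, s)


class TestQCFilter:
    def test_unstable_replicates_flagged(self):
        d = DecoyRecord("x", 1.0, {
            "complex": [100.0, 112.0, 112.0],   # median 112, min 100 -> 12 > 10
            "chainA": [0.0, 0.0],
            "chainB": [0.0, 0.0],
        }, n_residues=100)
        flags = qc_filter(d, {"chainA": 0.0, "chainB": 0.0})
        assert "UNSTABLE_REPLICATES" in flags

    def test_single_replicate_flagged(self):
        d = DecoyRecord("x", 1.0, {
            "complex": [-10.0, -10.0],
            "chainA": [-5.0],
            "chainB": [-5.0, -5.0],
        }, n_residues=100)
        flags = qc_filter(d, {"chainA": -5.0, "chainB": -5.0})
        assert "TOO_FEW_REPLICATES" in flags

    def test_chain_outlier_flagged(self):
        d = DecoyRecord("x", 1.0, {
            "complex": [-10.0, -10.0],
            "chainA": [20.0, 20.1],   # 20 > median 0 + 0.1*100
            "chainB": [0.0, 0.0],
        }, n_residues=100)
        flags = qc_filter(d, {"chainA": 0.0, "chainB": 0.0})
        assert "CHAIN_ENERGY_OUTLIER" in flags

    def test_clean_decoy_passes(self):
        d = decoy("x", 1.0, 0.0)
        assert qc_filter(d, {"chainA": -100.0, "chainB": -100.0}) == set()
        assert d.passes_qc

    def test_dg_identity(self):
        d = decoy("x", 1.0, -3.0)
        assert d.dg == pytest.approx(d.e_complex - (d.e_chain_a + d.e_chain_b))

    def test_landscape_level_flags(self):
        clean = [decoy(f"c{i}", 1.0, 0.0) for i in range(8)]
        bad = [DecoyRecord(f"b{i}", 1.0, {"complex": [0.0]}, 100) for i in range(2)]
        for d in clean + bad:
            qc_filter(d, {"chainA": -100.0, "chainB": -100.0})
        flags = landscape_flags(clean + bad,
                                QCThresholds(min_surviving_decoys=5))
        assert "HIGH_FILTER_FRACTION" in flags  # 20% > 15%
        assert "TOO_FEW_DECOYS" not in flags


class TestSelectLandscape:
    def test_round_robin_across_four_bins(self):
        decoys = []
        for b in range(4):
            for i in range(75):
                decoys.append(decoy(f"d{b}_{i:03d}", b * 2.0 + 1.0, float(i)))
        land = select_landscape(decoys, bin_width=2.0, target=150)
        assert len(land.selected) == 150
        per_bin = {}
        for d in land.selected:
            per_bin[int(d.ca_rmsd // 2)] = per_bin.get(int(d.ca_rmsd // 2), 0) + 1
        assert all(37 <= v <= 38 for v in per_bin.values())

    def test_fewer_decoys_than_target_takes_all(self):
        decoys = [decoy(f"d{i}", float(i % 8), 0.0) for i in range(80)]
        land = select_landscape(decoys, target=150)
        assert len(land.selected) == 80

    def test_single_bin_takes_lowest_dg(self):
        decoys = [decoy(f"d{i:03d}", 1.0, float(i)) for i in range(200)]
        land = select_landscape(decoys, target=150)
        assert len(land.selected) == 150
        assert max(d.dg for d in land.selected) < 150.0

    def test_selection_stable_under_reordering(self):
        rng = np.random.default_rng(0)
        decoys = [decoy(f"d{i:03d}", float(rng.uniform(0, 10)),
                        float(rng.normal())) for i in range(300)]
        sel1 = [d.decoy_id for d in select_landscape(decoys).selected]
        shuffled = list(decoys)
        rng.shuffle(shuffled)
        sel2 = [d.decoy_id for d in select_landscape(shuffled).selected]
        assert sel1 == sel2


class TestDiscriminationScore:
    def test_two_decoy_closed_form(self):
        decoys = [decoy("near", 1.0, 0.0), decoy("far", 5.0, 1.0)]
        q = discrimination_score(decoys, kT=1.0)
        assert q == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-9)
        assert q == pytest.approx(0.731, abs=5e-4)

    def test_uniform_energies_give_count_fraction(self):
        decoys = [decoy(f"d{i}", 1.0 if i < 3 else 5.0, 2.0) for i in range(10)]
        assert discrimination_score(decoys) == pytest.approx(0.3)

    def test_invariant_to_constant_energy_shift(self):
        rng = np.random.default_rng(1)
        decoys = [decoy(f"d{i}", float(rng.uniform(0, 8)), float(rng.normal()))
                  for i in range(50)]
        shifted = [decoy(d.decoy_id, d.ca_rmsd, d.dg + 7.5) for d in decoys]
        assert discrimination_score(decoys) == pytest.approx(
            discrimination_score(shifted))

    def test_kt_limits(self):
        decoys = [decoy("near", 1.0, 0.5), decoy("far", 5.0, 0.0)]
        # argmin is far, so kT -> 0 gives 0; kT -> inf gives 1/2
        assert discrimination_score(decoys, kT=1e-6) == pytest.approx(0.0, abs=1e-9)
        assert discrimination_score(decoys, kT=1e6) == pytest.approx(0.5, abs=1e-4)

    def test_lowering_near_native_dg_never_decreases_q(self):
        rng = np.random.default_rng(2)
        decoys = [decoy(f"d{i}", float(rng.uniform(0, 8)), float(rng.normal()))
                  for i in range(40)]
        q0 = discrimination_score(decoys)
        lowered = [
            decoy(d.decoy_id, d.ca_rmsd, d.dg - (2.0 if d.ca_rmsd < 2.0 else 0.0))
            for d in decoys
        ]
        assert discrimination_score(lowered) >= q0

    def test_empty_selection_error(self):
        with pytest.raises(ValueError):
            discrimination_score([])

    def test_deeper_funnels_score_higher(self):
        means = {}
        for depth in (0.5, 2.0):
            qs = []
            for seed in range(20):
                table, _ = simulate_landscape(FunnelSimSpec(
                    n_decoys=300, funnel_depth=depth, seed=seed))
                land = select_landscape(decoys_from_table(table))
                qs.append(discrimination_score(land))
            means[depth] = np.mean(qs)
        assert means[2.0] > means[0.5]
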