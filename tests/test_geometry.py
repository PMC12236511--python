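"""Geometry: superposition, rotations, twist, RMSF, distances, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stn
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from loopstate import geometry as G
from loopstate.structures import AtomSelection, Ensemble, StructureError
from loopstate.synthetic import (
    LoopEnsembleConfig,
    RingConfig,
    gen_loop_ensemble,
    gen_ring_assembly,
)

from conftest import RING1, RING2, ring_selection, rotation_z


# ---------------------------------------------------------------------------
# Superposition and rotation angles
# ---------------------------------------------------------------------------


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(30, 3))
        tr = G.superpose(pts, pts)
        assert tr.angle == pytest.approx(0.0, abs=1e-5)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_constructed_26_degrees(self, rng):
        pts = rng.normal(size=(50, 3)) * 10
        rotated = pts @ rotation_z(26.0).T + np.array([1.0, -2.0, 3.0])
        tr = G.superpose(pts, rotated)
        assert tr.angle == pytest.approx(26.0, abs=1e-6)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(np.abs(tr.axis[2]), 1.0, atol=1e-8)

    def test_agrees_with_scipy_align_vectors(self, rng):
        """Independent route: scipy's quaternion-based alignment."""
        for _ in range(20):
            a = rng.normal(size=(100, 3))
            b = rng.normal(size=(100, 3))
            tr = G.superpose(a, b)
            rot, _ = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
            ref_angle = np.degrees(
                np.arccos(np.clip((np.trace(rot.as_matrix()) - 1) / 2, -1, 1)))
            assert tr.angle == pytest.approx(ref_angle, abs=1e-6)

    def test_reflection_never_returned(self, rng):
        pts = rng.normal(size=(40, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        tr = G.superpose(pts, mirrored)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0)
        assert tr.rmsd > 0

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(StructureError, match="collinear"):
            G.superpose(line, line)
        with pytest.raises(StructureError):
            G.superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_noisy_angle_recovery(self, rng):
        pts = rng.normal(size=(100, 3)) * 20
        rot = pts @ rotation_z(14.0).T + rng.normal(0, 0.1, size=pts.shape)
        tr = G.superpose(pts, rot)
        assert tr.angle == pytest.approx(14.0, abs=0.1)


class TestRotationAngle:
    def _transform(self, deg):
        R = rotation_z(deg)
        return G.RigidTransform(rotation=R, translation=np.zeros(3),
                                angle=abs(deg) % 360, axis=np.array([0, 0, 1.0]),
                                rmsd=0.0)

    def test_identity_mod5(self):
        assert G.rotation_angle(self._transform(0.0), 5) == pytest.approx(0.0)

    def test_46_reduces_to_26_mod5(self):
        tr = self._transform(46.0)
        assert G.rotation_angle(tr, 5) == pytest.approx(26.0)

    def test_random_angles_match_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 8))
            deg = float(rng.uniform(0, 180))
            tr = self._transform(deg)
            got = G.rotation_angle(tr, n)
            brute = min(
                abs(deg - k * 360.0 / n) for k in range(-n - 1, n + 2))
            assert got == pytest.approx(brute, abs=1e-9)


# ---------------------------------------------------------------------------
# Twist, interface rotation, domain rotation
# ---------------------------------------------------------------------------


class TestFilamentTwist:
    def test_constructed_26(self):
        model, truth = gen_ring_assembly(RingConfig(twist_deg=26.0, rise=40.0))
        twist, rise = G.filament_twist(model, ring_selection(RING1),
                                       ring_selection(RING2))
        assert twist == pytest.approx(26.0, abs=0.1)
        assert rise == pytest.approx(40.0, abs=0.1)

    def test_eclipsed_rings(self):
        model, _ = gen_ring_assembly(RingConfig(twist_deg=0.0))
        twist, _ = G.filament_twist(model, ring_selection(RING1),
                                    ring_selection(RING2))
        assert twist == pytest.approx(0.0, abs=1e-5)

    def test_round_trip_over_random_twists(self, rng):
        for twist_true in rng.uniform(0, 36, size=10):
            model, _ = gen_ring_assembly(RingConfig(twist_deg=float(twist_true)))
            twist, _ = G.filament_twist(model, ring_selection(RING1),
                                        ring_selection(RING2))
            assert twist == pytest.approx(float(twist_true), abs=0.1)

    def test_explicit_chain_map(self):
        model, _ = gen_ring_assembly(RingConfig(twist_deg=20.0))
        cmap = dict(zip(RING1, RING2))
        twist, _ = G.filament_twist(model, ring_selection(RING1),
                                    ring_selection(RING2), chain_map=cmap)
        assert twist == pytest.approx(20.0, abs=0.1)
        with pytest.raises(StructureError):
            G.filament_twist(model, ring_selection(RING1),
                             ring_selection(RING2), chain_map={"A": "Z"})


def _decamer_pair(delta_deg: float):
    """Two decamers differing by a rigid rotation of the upper ring."""
    model_a, _ = gen_ring_assembly(RingConfig(twist_deg=0.0, rise=40.0))
    xyz = model_a.coords.copy()
    upper = np.isin(model_a.chain, list(RING2))
    xyz[upper] = xyz[upper] @ rotation_z(delta_deg).T
    return model_a, model_a.with_coords(xyz)


class TestInterfaceAndDomainRotation:
    def test_self_comparison_is_zero(self):
        model, _ = gen_ring_assembly(RingConfig())
        ang = G.interpentamer_rotation(model, model, ring_selection(RING1),
                                       ring_selection(RING2))
        assert ang == pytest.approx(0.0, abs=1e-9)

    def test_constructed_1p2_degree_ring_rotation(self):
        ma, mb = _decamer_pair(1.2)
        ang = G.interpentamer_rotation(ma, mb, ring_selection(RING1),
                                       ring_selection(RING2))
        assert ang == pytest.approx(1.2, abs=0.05)

    def test_constructed_5_degree_hinge(self):
        model, _ = gen_ring_assembly(RingConfig(two_rings=False))
        fixed = AtomSelection.parse("A:1-12")
        mobile = AtomSelection.parse("A:13-24")
        xyz = model.coords.copy()
        sel = mobile.resolve(model)
        pivot = xyz[sel].mean(axis=0)
        hinge = Rotation.from_euler("y", 5.0, degrees=True).as_matrix()
        xyz[sel] = (xyz[sel] - pivot) @ hinge.T + pivot
        moved = model.with_coords(xyz)
        assert G.domain_rotation(model, moved, fixed, mobile) == pytest.approx(
            5.0, abs=0.1)

    def test_invariant_to_global_transform_of_model_b(self, rng):
        ma, mb = _decamer_pair(1.2)
        Rg = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        mb_moved = mb.with_coords(mb.coords @ Rg.T + rng.normal(size=3) * 30)
        ang = G.interpentamer_rotation(ma, mb_moved, ring_selection(RING1),
                                       ring_selection(RING2))
        assert ang == pytest.approx(1.2, abs=0.05)


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------


def _loop_selections():
    align = AtomSelection.parse(
        ",".join(f"{c}:1-8" for c in RING1 + RING2)
        + "," + ",".join(f"{c}:15-24" for c in RING1 + RING2))
    report = AtomSelection.parse(",".join(f"{c}:9-14" for c in RING1 + RING2))
    return align, report


class TestRMSF:
    def test_identical_conformations_zero(self):
        model, _ = gen_ring_assembly(RingConfig())
        ens = Ensemble(topology=model,
                       coords=np.stack([model.coords] * 4))
        align, report = _loop_selections()
        prof = G.rmsf(ens, align, report)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-9)

    @pytest.mark.parametrize("occupancy,displacement,expected", [
        (0.5, 10.0, 5.0),
        (0.2, 10.0, 4.0),  # 10 * sqrt(0.2 * 0.8)
    ])
    def test_two_state_closed_form(self, occupancy, displacement, expected):
        ens, truth = gen_loop_ensemble(LoopEnsembleConfig(
            seed=7, occupancy=occupancy, displacement=displacement,
            jitter=0.0, n_conformations=20))
        align, report = _loop_selections()
        prof = G.rmsf(ens, align, report)
        assert prof.max() == pytest.approx(expected, rel=0.01)

    def test_single_conformation_rejected(self):
        model, _ = gen_ring_assembly(RingConfig())
        with pytest.raises(StructureError):
            Ensemble(topology=model, coords=model.coords[None])


# ---------------------------------------------------------------------------
# Distances and distributions
# ---------------------------------------------------------------------------


class TestMinDistance:
    def test_two_single_atom_residues(self):
        model, _ = gen_ring_assembly(RingConfig(two_rings=False))
        ens, _ = gen_loop_ensemble(LoopEnsembleConfig(
            seed=3, jitter=0.0, occupancy=0.0,
            ring=RingConfig(two_rings=False)))
        # each residue has one CA: distance equals the plain CA-CA distance
        d = G.min_distance_distribution(ens, 1, 2)
        topo = ens.topology
        for j, (ca, _) in enumerate(d.chains):
            i1 = np.flatnonzero((topo.chain == ca) & (topo.resid == 1))
            i2 = np.flatnonzero((topo.chain == ca) & (topo.resid == 2))
            ref = np.linalg.norm(topo.coords[i1[0]] - topo.coords[i2[0]])
            np.testing.assert_allclose(d.samples[:, j], ref, atol=1e-9)

    def test_matches_brute_force_all_pairs(self, rng):
        """Multi-atom residues vs. an O(n^2) double loop oracle."""
        ens, _ = gen_loop_ensemble(LoopEnsembleConfig(
            seed=9, occupancy=0.5, n_conformations=5, jitter=0.5))
        d = G.min_distance_distribution(ens, 10, 20)
        topo = ens.topology
        for m in range(5):
            for j, (ca, cb) in enumerate(d.chains):
                ia = np.flatnonzero((topo.chain == ca) & (topo.resid == 10))
                ib = np.flatnonzero((topo.chain == cb) & (topo.resid == 20))
                best = min(
                    np.linalg.norm(ens.coords[m][p] - ens.coords[m][q])
                    for p in ia for q in ib)
                assert d.samples[m, j] == pytest.approx(best, abs=1e-12)

    def test_invariant_under_global_rotation(self, rng):
        ens, _ = gen_loop_ensemble(LoopEnsembleConfig(seed=5))
        d0 = G.min_distance_distribution(ens, 11, 20)
        Rg = Rotation.random(random_state=np.random.RandomState(8)).as_matrix()
        rotated = Ensemble(topology=ens.topology,
                           coords=ens.coords @ Rg.T + 12.5)
        d1 = G.min_distance_distribution(rotated, 11, 20)
        np.testing.assert_allclose(d1.samples, d0.samples, atol=1e-9)

    def test_missing_residue_names_chain(self):
        ens, _ = gen_loop_ensemble(LoopEnsembleConfig(seed=5))
        with pytest.raises(StructureError, match="chain A"):
            G.min_distance_distribution(ens, 99, 20)

    def test_ten_chains_give_ten_distances_per_conformation(self):
        ens, _ = gen_loop_ensemble(LoopEnsembleConfig(seed=5))
        d = G.min_distance_distribution(ens, 10, 20)
        assert d.samples.shape == (ens.n_conformations, 10)


class TestKDE:
    def test_zero_variance_rejected(self):
        with pytest.raises(StructureError, match="histogram"):
            G.kde_density(np.zeros(10))

    def test_standard_normal_density_at_zero(self, rng):
        x = rng.normal(size=10000)
        grid, dens = G.kde_density(x)
        at0 = np.interp(0.0, grid, dens)
        assert at0 == pytest.approx(0.3989, rel=0.05)

    def test_integrates_to_one(self, rng):
        x = rng.gamma(3.0, 2.0, size=500)
        grid, dens = G.kde_density(x)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_bandwidth_adjust_scales_smoothness(self, rng):
        x = np.concatenate([rng.normal(0, 0.3, 400), rng.normal(8, 0.3, 400)])
        _, dens_narrow = G.kde_density(x, bandwidth_adjust=0.5)
        _, dens_wide = G.kde_density(x, bandwidth_adjust=3.0)
        assert dens_narrow.max() > dens_wide.max()


class TestHistogram:
    def test_one_sample_per_bin(self):
        x = np.arange(150) + 0.5
        counts, edges = G.histogram(x, bins=150)
        np.testing.assert_array_equal(counts, 1)
        assert len(edges) == 151

    @settings(max_examples=30, deadline=None)
    @given(stn.lists(stn.floats(0.1, 100.0), min_size=1, max_size=400))
    def test_counts_conserved(self, values):
        counts, _ = G.histogram(np.array(values), bins=150)
        assert counts.sum() == len(values)

    def test_matches_naive_assignment_loop(self, rng):
        x = rng.uniform(2, 9, size=300)
        counts, edges = G.histogram(x, bins=17)
        naive = np.zeros(17, int)
        for v in x:
            for b in range(17):
                last = b == 16
                if edges[b] <= v < edges[b + 1] or (last and v == edges[-1]):
                    naive[b] += 1
                    break
        np.testing.assert_array_equal(counts, naive)


# ---------------------------------------------------------------------------
# Distance-difference matrices and single pair distances
# ---------------------------------------------------------------------------


class TestDistanceDifference:
    def test_identical_models_zero_matrix(self):
        model, _ = gen_ring_assembly(RingConfig())
        ddm = G.ca_distance_difference(model, model, "A")
        np.testing.assert_allclose(ddm.matrix, 0.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(ddm.matrix), 0.0)

    def test_rigid_transform_invariance(self, rng):
        model, _ = gen_ring_assembly(RingConfig())
        other = model.with_coords(model.coords * 1.0)
        sel = other.mask(chains="A", residues=range(13, 25))
        xyz = other.coords.copy()
        xyz[sel] += np.array([0.0, 0.0, 2.5])
        other = other.with_coords(xyz)
        ddm0 = G.ca_distance_difference(model, other, "A")
        Rg = Rotation.random(random_state=np.random.RandomState(1)).as_matrix()
        moved = other.with_coords(other.coords @ Rg.T - 7.0)
        ddm1 = G.ca_distance_difference(model, moved, "A")
        np.testing.assert_allclose(ddm1.matrix, ddm0.matrix, atol=1e-9)
        assert np.abs(ddm0.matrix).max() > 0.1

    def test_hand_computed_toy(self):
        from loopstate.structures import StructureModel

        def tiny(coords):
            n = len(coords)
            return StructureModel(
                chain=np.array(["A"] * n), resid=np.arange(1, n + 1),
                resname=np.array(["GLY"] * n),
                atom_name=np.array(["CA"] * n),
                element=np.array(["C"] * n), coords=np.array(coords, float),
                occupancy=np.ones(n))

        a = tiny([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0]])
        b = tiny([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [5, 0, 0]])
        ddm = G.ca_distance_difference(a, b, "A")
        # only pairs involving residue 5 change: |4-i| - |5-i| = -1
        expected = np.zeros((5, 5))
        expected[4, :4] = -1.0
        expected[:4, 4] = -1.0
        np.testing.assert_allclose(ddm.matrix, expected, atol=1e-12)
        assert ddm.max_pair[2] == pytest.approx(-1.0)

    def test_exclusions_and_mismatch(self):
        model, _ = gen_ring_assembly(RingConfig())
        ddm = G.ca_distance_difference(model, model, "A",
                                       exclusions=[(9, 14)])
        assert len(ddm.residues) == 18
        assert 10 not in ddm.residues
        # mismatched residue sets after exclusion
        trimmed = model.with_coords(model.coords)
        keep = ~((trimmed.chain == "A") & (trimmed.resid == 3))
        from loopstate.structures import StructureModel
        trimmed = StructureModel(
            chain=trimmed.chain[keep], resid=trimmed.resid[keep],
            resname=trimmed.resname[keep], atom_name=trimmed.atom_name[keep],
            element=trimmed.element[keep], coords=trimmed.coords[keep],
            occupancy=trimmed.occupancy[keep])
        with pytest.raises(StructureError, match=r"\[3\]"):
            G.ca_distance_difference(model, trimmed, "A")


class TestCrossPentamerDistance:
    def test_constructed_distance(self):
        from loopstate.structures import StructureModel

        model = StructureModel(
            chain=np.array(["A", "B"]), resid=np.array([74, 263]),
            resname=np.array(["ASN", "GLU"]),
            atom_name=np.array(["CA", "CA"]), element=np.array(["C", "C"]),
            coords=np.array([[0.0, 0, 0], [10.0, 0, 0]]),
            occupancy=np.ones(2))
        d = G.cross_pentamer_ca_distance(model, ("A", 74), ("B", 263))
        assert d == pytest.approx(10.0)

    def test_equals_cross_chain_matrix_entry(self):
        model, _ = gen_ring_assembly(RingConfig())
        d = G.cross_pentamer_ca_distance(model, ("A", 4), ("B", 20))
        ia = np.flatnonzero(model.mask(chains="A", residues=4,
                                       atom_names="CA"))
        ib = np.flatnonzero(model.mask(chains="B", residues=20,
                                       atom_names="CA"))
        full = cdist(model.coords[ia], model.coords[ib])
        assert d == pytest.approx(full[0, 0])

    def test_missing_residue_rejected(self):
        model, _ = gen_ring_assembly(RingConfig())
        with pytest.raises(StructureError):
            G.cross_pentamer_ca_distance(model, ("A", 74), ("B", 263))
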