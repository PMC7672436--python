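import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_rotation, transform_atoms
from pairscape import constants as C
from pairscape.errors import ContractError, FitError, StructuralInputError
from pairscape.nucleic_geometry import (AtomRecord, BaseFrame, BasePairParams,
                                        StepParams, build_pair_frames,
                                        build_step_frame, classify_glycosidic,
                                        compute_step_params, detect_hbonds,
                                        dihedral, fit_base_frame, kabsch,
                                        pair_frames, wrap_angle)
from pairscape.synthetic_data import build_base_pair


def residue(atoms, idx):
    return [a for a in atoms if a.residue_index == idx]


def measure_pair(atoms):
    fa = fit_base_frame(residue(atoms, 1))
    fb = fit_base_frame(residue(atoms, 2))
    return pair_frames(fa, fb)


class TestFitBaseFrame:
    def test_self_fit_is_identity(self, standard_guanine):
        f = fit_base_frame(standard_guanine)
        assert np.allclose(f.origin, 0.0, atol=1e-12)
        assert np.allclose(f.axes, np.eye(3), atol=1e-12)
        assert not f.syn_transformed

    def test_rigid_transform_recovered(self, standard_guanine, rng):
        R = random_rotation(rng)
        t = np.array([1.0, 2.0, 3.0])
        moved = transform_atoms(standard_guanine, R, t)
        f = fit_base_frame(moved)
        assert np.allclose(f.origin, t, atol=1e-10)
        # axes rows are the frame vectors in lab coordinates = R columns^T
        assert np.allclose(f.axes, R.T, atol=1e-10)

    def test_30deg_z_rotation_example(self, standard_guanine):
        c, s = np.cos(np.radians(30)), np.sin(np.radians(30))
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        moved = transform_atoms(standard_guanine, R, np.array([1.0, 2.0, 3.0]))
        f = fit_base_frame(moved)
        assert np.allclose(f.origin, [1, 2, 3], atol=1e-10)
        assert np.allclose(f.axes @ f.axes.T, np.eye(3), atol=1e-12)
        assert np.allclose(f.axes.T, R, atol=1e-10)

    def test_noise_stability_against_kabsch_oracle(self, standard_guanine, rng):
        # 0.01 A iid noise must keep the frame within 0.05 A / 1 deg
        ring = [a for a in standard_guanine if a.name in C.RING_ATOMS["DG"]]
        for _ in range(100):
            noisy = transform_atoms(ring, np.eye(3), np.zeros(3))
            for a in noisy:
                a.position = a.position + rng.normal(0, 0.01, 3)
            f = fit_base_frame(noisy)
            assert np.linalg.norm(f.origin) < 0.05
            ang = np.degrees(np.arccos(np.clip(
                (np.trace(f.axes) - 1) / 2, -1, 1)))
            assert ang < 1.0
            # independent oracle: direct Kabsch on the same points
            ref = C.standard_base_coords("DG", C.RING_ATOMS["DG"])
            obs = np.array([a.position for a in noisy])
            R, t = kabsch(ref, obs)
            assert np.allclose(f.axes, R.T, atol=1e-10)
            assert np.allclose(f.origin, t, atol=1e-10)

    def test_missing_ring_atom_named(self, standard_guanine):
        broken = [a for a in standard_guanine if a.name != "N7"]
        with pytest.raises(StructuralInputError, match="N7"):
            fit_base_frame(broken)

    def test_collinear_coordinates_raise(self):
        atoms = [AtomRecord(n, "C", np.array([float(i), 0, 0]), 1, "DC")
                 for i, n in enumerate(C.RING_ATOMS["DC"])]
        with pytest.raises(FitError):
            fit_base_frame(atoms)

    def test_syn_transform_flips_x_and_y(self, standard_guanine):
        f = fit_base_frame(standard_guanine, orientation="syn")
        assert f.syn_transformed
        assert np.allclose(f.axes[0], [-1, 0, 0], atol=1e-12)
        assert np.allclose(f.axes[1], [0, -1, 0], atol=1e-12)
        assert np.allclose(f.axes[2], [0, 0, 1], atol=1e-12)
        assert np.linalg.det(f.axes) == pytest.approx(1.0)


class TestPairFrames:
    def test_ideal_pair_all_zero(self, ideal_gc_pair):
        _, p = measure_pair(ideal_gc_pair)
        assert np.abs(p.as_array()).max() < 1e-8
        assert p.simple

    def test_opening_rotation_by_construction(self):
        p = BasePairParams(0, 0, 0, 0, 0, 20.0)
        atoms = build_base_pair("G", "C", p)
        _, q = measure_pair(atoms)
        assert q.opening == pytest.approx(20.0, abs=1e-9)
        assert abs(q.shear) < 1e-6

    def test_shear_translation_by_construction(self):
        p = BasePairParams(1.5, 0, 0, 0, 0, 0)
        atoms = build_base_pair("G", "C", p)
        _, q = measure_pair(atoms)
        assert q.shear == pytest.approx(1.5, abs=1e-9)
        assert q.opening == pytest.approx(0.0, abs=1e-9)

    def test_non_orthonormal_frame_rejected(self):
        with pytest.raises(ContractError):
            BaseFrame(np.zeros(3), np.eye(3) * 1.001)

    def test_round_trip_200_random_parameter_sets(self, rng):
        for _ in range(200):
            t = rng.uniform(-3, 3, 3)
            ang = rng.uniform(-60, 60, 3)
            p = BasePairParams(*t, *ang)
            atoms = build_base_pair("A", "C", p)
            _, q = measure_pair(atoms)
            assert np.abs(q.as_array() - p.as_array()).max() < 1e-6

    def test_strand_swap_parity(self, rng):
        # Under base exchange the mean-frame axes transform with parities
        # (x: even, y: odd, z: odd) and the relative rotation/translation
        # invert, so shear and buckle negate while stretch, stagger,
        # propeller and opening are preserved.  (No right-handed intrinsic
        # scheme can negate opening together with this signature: negating
        # opening needs an even z, which with odd y forces odd x and would
        # make shear symmetric.)
        for _ in range(25):
            p = BasePairParams(*rng.uniform(-2, 2, 3), *rng.uniform(-45, 45, 3))
            atoms = build_base_pair("G", "T", p)
            fa = fit_base_frame(residue(atoms, 1))
            fb = fit_base_frame(residue(atoms, 2))
            _, q1 = pair_frames(fa, fb)
            _, q2 = pair_frames(fb, fa)
            assert q2.shear == pytest.approx(-q1.shear, abs=1e-8)
            assert q2.buckle == pytest.approx(-q1.buckle, abs=1e-8)
            assert q2.stretch == pytest.approx(q1.stretch, abs=1e-8)
            assert q2.stagger == pytest.approx(q1.stagger, abs=1e-8)
            assert q2.propeller == pytest.approx(q1.propeller, abs=1e-8)
            assert q2.opening == pytest.approx(q1.opening, abs=1e-8)

    def test_frame_orthonormality_preserved(self, rng):
        p = BasePairParams(*rng.uniform(-2, 2, 3), *rng.uniform(-50, 50, 3))
        fa, fb = build_pair_frames(p)
        mean, _ = pair_frames(fa, fb)
        for f in (fa, fb, mean):
            assert np.abs(f.axes @ f.axes.T - np.eye(3)).max() < 1e-8

    def test_syn_pair_round_trip(self, rng):
        p = BasePairParams(0.4, -0.2, 0.1, 10.0, -15.0, -30.0)
        atoms = build_base_pair("G", "T", p, orientations=("anti", "syn"))
        fa = fit_base_frame(residue(atoms, 1), orientation="anti")
        fb = fit_base_frame(residue(atoms, 2), orientation="syn")
        _, q = pair_frames(fa, fb)
        assert np.abs(q.as_array() - p.as_array()).max() < 1e-6


class TestStepParams:
    def test_pure_rise(self):
        f1 = BaseFrame(np.zeros(3), np.eye(3))
        f2 = BaseFrame(np.array([0, 0, 3.4]), np.eye(3))
        _, s = compute_step_params(f1, f2)
        assert s.rise == pytest.approx(3.4)
        assert np.abs([s.shift, s.slide, s.tilt, s.roll, s.twist]).max() < 1e-10

    def test_twist_36(self):
        f1 = BaseFrame(np.zeros(3), np.eye(3))
        c, sn = np.cos(np.radians(36)), np.sin(np.radians(36))
        R = np.array([[c, -sn, 0], [sn, c, 0], [0, 0, 1.0]])
        f2 = BaseFrame(np.array([0, 0, 3.4]), R.T)
        _, s = compute_step_params(f1, f2)
        assert s.twist == pytest.approx(36.0, abs=1e-9)
        assert s.rise == pytest.approx(3.4)

    def test_round_trip_random_steps(self, rng):
        for _ in range(50):
            step = StepParams(*rng.uniform(-2, 2, 2), rng.uniform(2.5, 4.5),
                              *rng.uniform(-25, 25, 2), rng.uniform(-40, 40))
            base = BaseFrame(rng.normal(0, 5, 3), random_rotation(rng).T)
            nxt = build_step_frame(base, step)
            _, rec = compute_step_params(base, nxt)
            assert np.abs(rec.as_array() - step.as_array()).max() < 1e-6


class TestGlycosidic:
    def _residue_with_chi(self, chi_deg):
        # O4'-C1'-N9-C4 dihedral built directly from four points: rotating
        # O4' by -chi about the C1'->N9 axis realizes the requested torsion
        d = np.radians(-chi_deg)
        pts = {
            "C1'": np.array([0.0, 0.0, 0.0]),
            "N9": np.array([1.47, 0.0, 0.0]),
            "C4": np.array([1.97, 1.0, 0.0]),
            "O4'": np.array([-0.5, np.cos(d), np.sin(d)]),
        }
        return [AtomRecord(n, n[0], p, 1, "DA") for n, p in pts.items()]

    @pytest.mark.parametrize("chi,label", [(-120.0, "anti"), (70.0, "syn"),
                                           (180.0, "anti"), (89.9, "syn"),
                                           (-90.0, "anti")])
    def test_classification(self, chi, label):
        atoms = self._residue_with_chi(chi)
        g = classify_glycosidic(atoms)
        assert g.chi == pytest.approx(chi, abs=1e-8)
        assert g.label == label

    def test_rigid_motion_invariance(self, rng):
        atoms = self._residue_with_chi(-120.0)
        R = random_rotation(rng)
        moved = transform_atoms(atoms, R, rng.normal(0, 10, 3))
        assert classify_glycosidic(moved).chi == pytest.approx(-120.0, abs=1e-8)

    def test_built_duplex_residues_are_anti(self, class_i_duplex):
        for idx in (1, 7, 20, 26):
            res = [a for a in class_i_duplex if a.residue_index == idx]
            g = classify_glycosidic(res)
            assert g.label == "anti"
            assert g.chi == pytest.approx(-120.0, abs=0.5)

    def test_missing_atom(self):
        atoms = self._residue_with_chi(50.0)
        with pytest.raises(StructuralInputError, match="O4'"):
            classify_glycosidic([a for a in atoms if a.name != "O4'"])


class TestHydrogenBonds:
    def test_gc_has_three(self, ideal_gc_pair):
        assert len(detect_hbonds(ideal_gc_pair)) == 3

    def test_at_has_two(self, ideal_at_pair):
        bonds = detect_hbonds(ideal_at_pair)
        assert len(bonds) == 2
        names = {(b.donor.residue_name, b.donor.name, b.acceptor.name)
                 for b in bonds}
        assert names == {("DA", "N6", "O4"), ("DT", "N3", "N1")}

    def test_distant_bases_have_none(self, ideal_at_pair):
        from dataclasses import replace
        far = [a if a.residue_index == 1 else
               replace(a, position=a.position + np.array([15.0, 0, 0]))
               for a in ideal_at_pair]
        assert detect_hbonds(far) == []

    def test_with_hydrogens_angle_criterion(self):
        atoms = build_base_pair("G", "C", include_hydrogens=True)
        bonds = detect_hbonds(atoms)
        assert len(bonds) == 3
        assert all(b.hydrogen is not None and b.angle >= 135.0 for b in bonds)

    def test_empty_role_table_rejected(self, ideal_gc_pair):
        from pairscape.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            detect_hbonds(ideal_gc_pair, donors={}, acceptors={})

    def test_cutoffs_configurable(self, ideal_gc_pair):
        assert detect_hbonds(ideal_gc_pair, distance_cutoff=2.0) == []


class TestAngles:
    @given(st.floats(-1000, 1000))
    def test_wrap_angle_range(self, x):
        w = wrap_angle(x)
        assert -180.0 < w <= 180.0

    @settings(max_examples=25)
    @given(st.floats(-179.9, 179.9))
    def test_wrap_identity_in_range(self, x):
        assert wrap_angle(x) == pytest.approx(x, abs=1e-9)

    def test_dihedral_sign_convention(self):
        # positive torsion: clockwise rotation of the far bond viewed along b1
        p = [np.array([1.0, 1, 0]), np.array([0.0, 0, 0]),
             np.array([0.0, 0, 1]), np.array([1.0, -1, 1])]
        assert dihedral(*p) < 0
        p[3] = np.array([1.0, 1, 1])
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-9)
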