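"""Geometry layer: chain construction, torsion round-trips, helix metrology.

The construction is cross-checked two independent ways: torsions of built
chains are re-measured with mdtraj (an external dihedral implementation),
and the ideal helix's rise/twist are recovered from CA–CA distance closed
forms for a regular helix, without using the package's axis fit.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixweaver import geometry as geo
from helixweaver.geometry import (BackboneChain, GeometryError, SegmentSpan,
                                  abego_label, abego_string,
                                  append_motif_then_helix, build_ideal_helix,
                                  fit_helix_axis, helix_rise_and_twist,
                                  measure_torsions, torsions_to_backbone)

from conftest import random_rigid_transform


def random_torsions(rng, n, omega_jitter=5.0):
    return np.column_stack([
        rng.uniform(-179.0, 179.0, n),
        rng.uniform(-179.0, 179.0, n),
        np.clip(rng.normal(180.0, omega_jitter, n), -180.0, 180.0),
    ])


def mdtraj_torsions(chain: BackboneChain):
    """Independent phi/psi/omega measurement via mdtraj."""
    import mdtraj as md
    top = md.Topology()
    ch = top.add_chain()
    for i in range(chain.n_residues):
        res = top.add_residue("ALA", ch)
        top.add_atom("N", md.element.nitrogen, res)
        top.add_atom("CA", md.element.carbon, res)
        top.add_atom("C", md.element.carbon, res)
        top.add_atom("O", md.element.oxygen, res)
    xyz = chain.all_coords()[None] / 10.0  # Å → nm
    traj = md.Trajectory(xyz, top)
    _, phi = md.compute_phi(traj)
    _, psi = md.compute_psi(traj)
    _, omega = md.compute_omega(traj)
    return (np.degrees(phi[0]), np.degrees(psi[0]), np.degrees(omega[0]))


class TestConstruction:
    def test_roundtrip_random_torsions(self, rng):
        """Building then re-measuring reproduces inputs to 1e-6 degrees."""
        for _ in range(100):
            n = int(rng.integers(2, 15))
            t = random_torsions(rng, n)
            chain = torsions_to_backbone(t)
            back = measure_torsions(chain)
            defined = np.isfinite(chain.torsions)
            assert np.allclose(back[defined], chain.torsions[defined], atol=1e-6)

    def test_agrees_with_mdtraj_measurement(self, rng):
        """External dihedral implementation recovers the input torsions."""
        t = random_torsions(rng, 10)
        chain = torsions_to_backbone(t)
        phi, psi, omega = mdtraj_torsions(chain)

        def circdiff(a, b):
            return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)

        assert np.max(circdiff(phi, t[1:, 0])) < 1e-3
        assert np.max(circdiff(psi, t[:-1, 1])) < 1e-3
        assert np.max(circdiff(omega, t[:-1, 2])) < 1e-3

    def test_ideal_bond_geometry(self):
        chain = build_ideal_helix(6)
        for i in range(5):
            d_cn = np.linalg.norm(chain.n[i + 1] - chain.c[i])
            assert d_cn == pytest.approx(geo.BOND_C_N, abs=1e-9)
            assert 1.2 <= d_cn <= 1.5  # chemically connected chain
        for i in range(6):
            assert np.linalg.norm(chain.ca[i] - chain.n[i]) == pytest.approx(
                geo.BOND_N_CA, abs=1e-9)
            assert np.linalg.norm(chain.o[i] - chain.c[i]) == pytest.approx(
                geo.BOND_C_O, abs=1e-9)

    def test_single_residue(self):
        chain = torsions_to_backbone([(np.nan, np.nan, np.nan)])
        assert chain.n_residues == 1
        assert chain.all_coords().shape == (4, 3)

    def test_empty_input_rejected(self):
        with pytest.raises(GeometryError):
            torsions_to_backbone([])

    def test_nonfinite_defined_angle_rejected(self):
        with pytest.raises(GeometryError):
            torsions_to_backbone([(np.nan, np.inf, 180.0), (-60.0, np.nan, np.nan)])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(
        st.floats(-179.9, 180.0), st.floats(-179.9, 180.0),
        st.floats(-179.9, 180.0).filter(lambda w: abs(w) > 20.0)),
        min_size=2, max_size=8))
    def test_roundtrip_property(self, torsions):
        """Construction/measurement are inverse for any finite torsions."""
        chain = torsions_to_backbone(np.asarray(torsions))
        back = measure_torsions(chain)
        defined = np.isfinite(chain.torsions)
        assert np.allclose(back[defined], chain.torsions[defined], atol=1e-6)


class TestIdealHelix:
    def test_minimum_length_valid(self):
        assert build_ideal_helix(5).n_residues == 5

    def test_bad_length_rejected(self):
        with pytest.raises(GeometryError):
            build_ideal_helix(0)

    def test_abego_all_A(self):
        chain = build_ideal_helix(12)
        assert abego_string(chain.torsions).strip("-") == "A" * 10

    def test_rise_and_residues_per_turn(self):
        chain = build_ideal_helix(20)
        rise, per_turn = helix_rise_and_twist(chain, SegmentSpan("helix", 1, 20))
        assert 1.4 <= rise <= 1.6
        assert 3.5 <= per_turn <= 3.8

    def test_helix_parameters_from_distance_closed_form(self):
        """Recover rise/twist from CA-CA distances of a regular helix.

        For a regular helix with radius r, rise d and twist w,
        |CA(i+k) - CA(i)|^2 = (k d)^2 + 4 r^2 sin^2(k w / 2); solving the
        k = 1, 2, 3 system gives an axis-free estimate of d and w.
        """
        from scipy.optimize import least_squares
        chain = build_ideal_helix(25)
        cas = chain.ca
        dist = {k: np.mean([np.linalg.norm(cas[i + k] - cas[i])
                            for i in range(len(cas) - k)]) for k in (1, 2, 3)}

        def residuals(params):
            r, d, w = params
            return [np.sqrt((k * d) ** 2 + 4 * r ** 2 * np.sin(k * w / 2) ** 2)
                    - dist[k] for k in (1, 2, 3)]

        fit = least_squares(residuals, x0=[2.3, 1.5, 1.7], bounds=([0.1, 0.1, 0.5], [5, 3, 3]))
        r, d, w = fit.x
        assert abs(d - 1.5) < 0.05  # rise per residue, Å
        assert 3.5 <= 2 * np.pi / w <= 3.8  # residues per turn

    def test_every_residue_carries_ideal_torsions(self):
        chain = build_ideal_helix(8)
        defined = np.isfinite(chain.torsions)
        expect = np.tile([-60.0, -45.0, 180.0], (8, 1))
        assert np.allclose(chain.torsions[defined], expect[defined])


class TestAbego:
    @pytest.mark.parametrize("phi,psi,omega,label", [
        (-60.0, -45.0, 180.0, "A"),
        (-120.0, 135.0, 180.0, "B"),
        (61.0, 40.0, 180.0, "G"),
        (75.0, -170.0, 180.0, "E"),
        (-60.0, -45.0, 5.0, "O"),
    ])
    def test_bin_lookup(self, phi, psi, omega, label):
        assert abego_label(phi, psi, omega) == label

    def test_total_on_finite_inputs(self, rng):
        for _ in range(200):
            phi, psi = rng.uniform(-180, 180, 2)
            omega = rng.uniform(-180, 180)
            assert abego_label(phi, psi, omega) in "ABEGO"


class _StubMotif:
    loop_torsions = [(-120.0, 130.0, 180.0), (60.0, 40.0, 180.0),
                     (-90.0, 0.0, 180.0)]
    pre_psi = -40.0
    pre_omega = 178.0
    post_phi = -62.0


class TestGrowth:
    def test_length_bookkeeping(self):
        chain = append_motif_then_helix(build_ideal_helix(10), _StubMotif(), 7)
        assert chain.n_residues == 20  # 10 + 3 loop + 7

    def test_loop_reproduces_motif_torsions(self):
        chain = append_motif_then_helix(build_ideal_helix(10), _StubMotif(), 7)
        measured = measure_torsions(chain)
        assert np.allclose(measured[10:13], np.asarray(_StubMotif.loop_torsions),
                           atol=1e-6)

    def test_existing_torsions_and_coords_preserved(self):
        base = build_ideal_helix(10)
        grown = append_motif_then_helix(base, _StubMotif(), 7)
        defined = np.isfinite(base.torsions)
        assert np.allclose(grown.torsions[:10][defined], base.torsions[defined],
                           atol=1e-6)
        for name in ("n", "ca", "c"):
            assert np.allclose(getattr(grown, name)[:10], getattr(base, name))
        # carbonyl O unchanged except at the junction residue, whose psi
        # only becomes defined on growth
        assert np.allclose(grown.o[:9], base.o[:9])

    def test_n_terminal_growth_prepends(self):
        base = build_ideal_helix(10)
        grown = append_motif_then_helix(base, _StubMotif(), 7, side="N_terminal")
        assert grown.n_residues == 20
        measured = measure_torsions(grown)
        assert np.allclose(measured[7:10], np.asarray(_StubMotif.loop_torsions),
                           atol=1e-6)

    def test_unknown_side_rejected(self):
        with pytest.raises(GeometryError):
            append_motif_then_helix(build_ideal_helix(10), _StubMotif(), 7,
                                    side="sideways")


class TestHelixAxis:
    def test_unit_norm_and_z_alignment(self):
        chain = build_ideal_helix(15)
        axis = fit_helix_axis(chain, SegmentSpan("helix", 1, 15))
        assert np.linalg.norm(axis) == pytest.approx(1.0, abs=1e-9)
        # rigidly align the chain's own axis to z and re-fit
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(axis, z)
        c = float(axis @ z)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1 + c)
        rotated = chain.transformed(R, np.zeros(3))
        axis_rot = fit_helix_axis(rotated, SegmentSpan("helix", 1, 15))
        assert abs(axis_rot @ z) > 0.999

    def test_rotation_equivariance(self, rng):
        chain = build_ideal_helix(12)
        span = SegmentSpan("helix", 1, 12)
        axis = fit_helix_axis(chain, span)
        R, t = random_rigid_transform(rng)
        moved = chain.transformed(R, t)
        assert np.allclose(fit_helix_axis(moved, span), R @ axis, atol=1e-6)

    def test_reversal_flips_sign(self):
        chain = build_ideal_helix(12)
        span = SegmentSpan("helix", 1, 12)
        axis = fit_helix_axis(chain, span)
        reversed_chain = BackboneChain(
            n=chain.n[::-1].copy(), ca=chain.ca[::-1].copy(),
            c=chain.c[::-1].copy(), o=chain.o[::-1].copy())
        assert np.allclose(fit_helix_axis(reversed_chain, span), -axis, atol=1e-6)

    def test_short_span_rejected(self):
        chain = build_ideal_helix(12)
        with pytest.raises(GeometryError):
            SegmentSpan("helix", 1, 4)
        with pytest.raises(GeometryError):
            fit_helix_axis(chain, SegmentSpan("loop", 1, 4))


class TestRigidInvariance:
    def test_torsions_invariant(self, rng):
        t = random_torsions(rng, 10)
        chain = torsions_to_backbone(t)
        R, tr = random_rigid_transform(rng)
        moved = chain.transformed(R, tr)
        a, b = measure_torsions(chain), measure_torsions(moved)
        defined = np.isfinite(a)
        assert np.allclose(a[defined], b[defined], atol=1e-6)

    def test_interhelix_angle_invariant(self, rng):
        chain = append_motif_then_helix(build_ideal_helix(10), _StubMotif(), 10)
        s1, s2 = SegmentSpan("helix", 1, 10), SegmentSpan("helix", 14, 23)
        ang = np.dot(fit_helix_axis(chain, s1), fit_helix_axis(chain, s2))
        R, tr = random_rigid_transform(rng)
        moved = chain.transformed(R, tr)
        ang2 = np.dot(fit_helix_axis(moved, s1), fit_helix_axis(moved, s2))
        assert ang2 == pytest.approx(ang, abs=1e-6)


class TestPdbRoundTrip:
    def test_coordinates_survive_to_pdb_precision(self, tmp_path, rng):
        from helixweaver.pdbio import read_backbone_pdb, write_backbone_pdb
        t = random_torsions(rng, 12)
        chain = torsions_to_backbone(t)
        path = tmp_path / "chain.pdb"
        write_backbone_pdb(chain, path)
        back, seq = read_backbone_pdb(path)
        assert back.n_residues == chain.n_residues
        assert seq == "A" * 12
        for name in ("n", "ca", "c", "o"):
            assert np.allclose(getattr(back, name), getattr(chain, name), atol=1.1e-3)
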