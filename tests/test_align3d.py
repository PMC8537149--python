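import numpy as np
import pytest

from alphaq.align3d import (
    RotamerSet,
    align_pair,
    apply_alignment,
    cross_correlation_map,
    hopf_rotations,
    random_rotations,
    rotate_field,
    rotate_molecule,
    self_correlation,
)
from alphaq.chem_io import Atom, Molecule
from alphaq.espgrid import (
    ChargeModel,
    GridBox,
    ScalarField,
    build_common_box,
    density_field,
    solve_poisson,
)

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])
Q_Z90 = np.array([np.cos(np.pi / 4), 0.0, 0.0, np.sin(np.pi / 4)])


class TestHopf:
    def test_single_sample_is_identity(self):
        rs = hopf_rotations(1)
        assert np.allclose(rs.quaternions[0], IDENTITY)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            hopf_rotations(0)

    def test_deterministic(self):
        a = hopf_rotations(500)
        b = hopf_rotations(500)
        assert np.array_equal(a.quaternions, b.quaternions)
        assert np.allclose(a.quaternions[0], IDENTITY)

    def test_second_moment_uniformity(self):
        # E[q q^T] = I/4 on a uniform S3 sample
        q = hopf_rotations(2000).quaternions
        moment = np.einsum("ni,nj->ij", q, q) / len(q)
        assert np.all(np.abs(np.diag(moment) - 0.25) < 0.02)

    def test_more_even_than_random(self):
        # nearest-neighbour rotation-angle dispersion must beat 2x a random
        # sample of the same size
        def nn_angle_std(quats):
            dots = np.abs(quats @ quats.T)
            np.fill_diagonal(dots, -1.0)
            return np.std(2 * np.arccos(np.clip(dots.max(axis=1), -1, 1)))

        hopf = nn_angle_std(hopf_rotations(2000).quaternions)
        rand = nn_angle_std(random_rotations(2000, seed=11).quaternions)
        assert hopf < 2.0 * rand


class TestRotateMolecule:
    def test_identity(self, tripod):
        out = rotate_molecule(tripod, IDENTITY, tripod.centroid())
        assert np.allclose(out.positions, tripod.positions)

    def test_inverse_restores(self, tripod):
        q = hopf_rotations(50).quaternions[17]
        q_inv = q * np.array([1.0, -1.0, -1.0, -1.0])
        there = rotate_molecule(tripod, q, np.zeros(3))
        back = rotate_molecule(there, q_inv, np.zeros(3))
        assert np.allclose(back.positions, tripod.positions, atol=1e-12)

    def test_z180_flips_xy(self):
        mol = Molecule("p", [Atom("C", [1.0, 2.0, 3.0], 0.0)])
        q = np.array([0.0, 0.0, 0.0, 1.0])
        out = rotate_molecule(mol, q, np.zeros(3))
        assert np.allclose(out.positions[0], [-1.0, -2.0, 3.0])

    def test_distances_preserved(self, tripod):
        q = hopf_rotations(100).quaternions[31]
        out = rotate_molecule(tripod, q, [0.3, -0.2, 1.0])
        d0 = np.linalg.norm(
            tripod.positions[:, None] - tripod.positions[None], axis=-1)
        d1 = np.linalg.norm(
            out.positions[:, None] - out.positions[None], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)

    def test_non_unit_quaternion_rejected(self, tripod):
        with pytest.raises(ValueError):
            rotate_molecule(tripod, np.array([1.0, 1.0, 0.0, 0.0]),
                            np.zeros(3))


class TestRotateField:
    def test_identity_unchanged(self, tripod, promolecule_model):
        box = build_common_box([tripod], spacing=0.4, margin=2.7)
        rho = density_field(tripod, box, promolecule_model)
        out = rotate_field(rho, IDENTITY)
        assert np.allclose(out.values, rho.values)

    def test_integral_preserved(self, promolecule_model):
        # sigma = 4 x spacing: trilinear re-sampling keeps the quadrature
        mol = Molecule("c", [Atom("C", [0, 0, 0], 0.0)])
        model = ChargeModel(mode="promolecule", sigma=0.8)
        box = build_common_box([mol], spacing=0.2, margin=2.7)
        rho = density_field(mol, box, model)
        q = hopf_rotations(20).quaternions[7]
        out = rotate_field(rho, q)
        assert out.values.sum() == pytest.approx(rho.values.sum(), rel=0.01)

    def test_matches_analytic_rotation(self, tripod):
        model = ChargeModel(mode="promolecule", sigma=0.8)
        # cubic box centred on the centroid so rotation stays inside
        c = tripod.translated(-tripod.centroid())
        box = GridBox((-4.0, -4.0, -4.0), 0.2, (41, 41, 41))
        rho = density_field(c, box, model)
        q = Q_Z90
        interp = rotate_field(rho, q)
        exact = density_field(rotate_molecule(c, q, box.center), box, model)
        rms = np.sqrt(np.mean((interp.values - exact.values) ** 2))
        scale = np.sqrt(np.mean(exact.values**2))
        assert rms < 0.02 * scale


class TestCrossCorrelation:
    def test_delta_density_sifts_template(self):
        box = GridBox((0, 0, 0), 0.5, (6, 6, 6))
        rng = np.random.default_rng(0)
        phi = ScalarField(box, rng.normal(size=box.dims), "esp")
        rho_vals = np.zeros(box.dims)
        rho_vals[2, 3, 1] = 4.0
        rho = ScalarField(box, rho_vals, "density")
        score = cross_correlation_map(phi, rho)
        # score(t) = w * dV * phi(hot + t)
        n = np.array(box.dims)
        for t in [(0, 0, 0), (1, -2, 0), (-1, 1, 2)]:
            loc = tuple(np.array(t) + n - 1)
            expect = 4.0 * box.voxel_volume * phi.values[2 + t[0], 3 + t[1],
                                                         1 + t[2]]
            assert score.values[loc] == pytest.approx(expect, abs=1e-12)

    def test_matches_bruteforce_on_8cube(self):
        box = GridBox((0, 0, 0), 0.5, (8, 8, 8))
        rng = np.random.default_rng(1)
        phi = ScalarField(box, rng.normal(size=box.dims), "esp")
        rho = ScalarField(box, rng.normal(size=box.dims), "density")
        score = cross_correlation_map(phi, rho)
        n = 8
        brute = np.zeros((2 * n - 1,) * 3)
        for ti in range(-(n - 1), n):
            for tj in range(-(n - 1), n):
                for tk in range(-(n - 1), n):
                    acc = 0.0
                    for i in range(max(0, ti), min(n, n + ti)):
                        for j in range(max(0, tj), min(n, n + tj)):
                            for k in range(max(0, tk), min(n, n + tk)):
                                acc += phi.values[i, j, k] * \
                                    rho.values[i - ti, j - tj, k - tk]
                    brute[ti + n - 1, tj + n - 1, tk + n - 1] = \
                        acc * box.voxel_volume
        scale = np.abs(brute).max()
        assert np.max(np.abs(score.values - brute)) < 1e-10 * scale

    def test_zero_density_zero_map(self):
        box = GridBox((0, 0, 0), 0.5, (5, 5, 5))
        phi = ScalarField(box, np.ones(box.dims), "esp")
        rho = ScalarField(box, np.zeros(box.dims), "density")
        assert np.all(cross_correlation_map(phi, rho).values == 0.0)

    def test_mismatched_boxes_rejected(self):
        a = GridBox((0, 0, 0), 0.5, (5, 5, 5))
        b = GridBox((0, 0, 0), 0.4, (5, 5, 5))
        with pytest.raises(ValueError):
            cross_correlation_map(
                ScalarField(a, np.zeros(a.dims), "esp"),
                ScalarField(b, np.zeros(b.dims), "density"),
            )


class TestAlignPair:
    def test_self_alignment_is_identity(self, tripod, promolecule_model):
        box = build_common_box([tripod], spacing=0.4, margin=2.7)
        centered = tripod.translated(box.center - tripod.centroid())
        rset = hopf_rotations(8)
        res = align_pair(centered, centered, box, rset, promolecule_model)
        e_ii = self_correlation(centered, box, promolecule_model)
        assert res.rotamer_index == 0
        assert np.allclose(res.translation, 0.0, atol=1e-9)
        assert res.e_ij == pytest.approx(e_ii, rel=1e-9)

    def test_self_alignment_is_optimal(self, tripod, promolecule_model):
        # Cauchy-Schwarz for the Coulomb kernel: score(t) <= E_ii everywhere
        box = build_common_box([tripod], spacing=0.4, margin=2.7)
        centered = tripod.translated(box.center - tripod.centroid())
        rho = density_field(centered, box, promolecule_model)
        phi = solve_poisson(rho)
        score = cross_correlation_map(phi, rho)
        e_ii = self_correlation(centered, box, promolecule_model)
        assert score.values.max() <= e_ii * (1 + 1e-9)

    def test_grid_displacement_recovered(self, tripod, promolecule_model):
        box = build_common_box([tripod], spacing=0.4, margin=2.7)
        centered = tripod.translated(box.center - tripod.centroid())
        d = np.array([2, -1, 1]) * box.spacing
        moved = centered.translated(d)
        res = align_pair(centered, moved, box, RotamerSet(IDENTITY),
                         promolecule_model)
        assert np.allclose(res.translation, -d, atol=1e-9)
        aligned = apply_alignment(moved, box, res)
        assert np.allclose(aligned.positions, centered.positions, atol=1e-9)

    def test_rotated_dumbbell_recovers_rotamer(self, dumbbell,
                                               promolecule_model):
        box = build_common_box([dumbbell], spacing=0.4, margin=2.7)
        template = dumbbell.translated(box.center - dumbbell.centroid())
        target = rotate_molecule(template, Q_Z90, template.centroid())
        q_back = Q_Z90 * np.array([1.0, -1.0, -1.0, -1.0])
        q_wrong = np.array([np.cos(np.pi / 4), 0.0, np.sin(np.pi / 4), 0.0])
        rset = RotamerSet(np.array([IDENTITY, q_back, q_wrong]))
        res = align_pair(template, target, box, rset, promolecule_model)
        assert res.rotamer_index == 1

    def test_scaling_template_does_not_change_argmax(self, dumbbell, tripod,
                                                     promolecule_model):
        # any positive rescaling of phi leaves the optimal placement alone
        box = build_common_box([dumbbell, tripod], spacing=0.4, margin=2.7)
        template = dumbbell.translated(box.center - dumbbell.centroid())
        rho = density_field(template, box, promolecule_model)
        phi = solve_poisson(rho)
        phi_scaled = ScalarField(box, 7.3 * phi.values, "esp")
        rset = hopf_rotations(12)
        res1 = align_pair(template, tripod, box, rset, promolecule_model,
                          template_phi=phi)
        res2 = align_pair(template, tripod, box, rset, promolecule_model,
                          template_phi=phi_scaled)
        assert res1.rotamer_index == res2.rotamer_index
        assert np.allclose(res1.translation, res2.translation)
        assert res2.e_ij == pytest.approx(7.3 * res1.e_ij, rel=1e-9)

    def test_box_too_small_raises(self, promolecule_model):
        # a box smaller than the vdW envelope leaves no valid shift
        mol = Molecule("big", [Atom("C", [0, 0, 0], 0.0)])
        small = GridBox((-1.0, -1.0, -1.0), 0.5, (5, 5, 5))
        rho = density_field(mol, small, promolecule_model)
        phi = solve_poisson(rho)
        with pytest.raises(ValueError, match="box too small"):
            align_pair(mol, mol, small, RotamerSet(IDENTITY),
                       promolecule_model, template_phi=phi)


class TestSelfCorrelation:
    def test_positive_for_promolecule(self, tripod, promolecule_model):
        box = build_common_box([tripod], spacing=0.4, margin=2.7)
        assert self_correlation(tripod, box, promolecule_model) > 0.0

    def test_bilinear_in_weights(self, promolecule_model):
        base = Molecule("b", [Atom("C", [0, 0, 0], 0.5),
                              Atom("O", [1.2, 0, 0], -0.5)])
        double = Molecule("d", [Atom("C", [0, 0, 0], 1.0),
                                Atom("O", [1.2, 0, 0], -1.0)])
        model = ChargeModel(mode="partial_charge", sigma=0.4)
        box = build_common_box([base], spacing=0.3, margin=2.7)
        e1 = self_correlation(base, box, model)
        e2 = self_correlation(double, box, model)
        assert e2 == pytest.approx(4.0 * e1, rel=1e-9)

    def test_matches_correlation_map_at_zero_shift(self, tripod,
                                                   promolecule_model):
        box = build_common_box([tripod], spacing=0.4, margin=2.7)
        rho = density_field(tripod, box, promolecule_model)
        phi = solve_poisson(rho)
        score = cross_correlation_map(phi, rho)
        n = np.array(box.dims)
        center = tuple(n - 1)
        e_ii = self_correlation(tripod, box, promolecule_model)
        assert score.values[center] == pytest.approx(e_ii, rel=1e-12)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1.0, 1.0), min_size=4, max_size=4))
    def test_rotation_is_an_isometry_property(raw_q):
        # any unit quaternion rotation preserves interatomic distances
        q = np.asarray(raw_q)
        norm = np.linalg.norm(q)
        if norm < 1e-3:
            return
        q = q / norm
        mol = Molecule("m", [Atom("C", [0.0, 0, 0], 0.0),
                             Atom("O", [1.3, 0, 0], 0.0),
                             Atom("N", [0.0, 1.1, 0.4], 0.0)])
        out = rotate_molecule(mol, q, np.array([0.2, -0.1, 0.5]))
        d0 = np.linalg.norm(mol.positions[:, None] - mol.positions[None],
                            axis=-1)
        d1 = np.linalg.norm(out.positions[:, None] - out.positions[None],
                            axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


def test_approximate_symmetry(dumbbell, tripod, promolecule_model):
    # E_ij vs E_ji agree within 2% (equal in the continuum; the grid breaks
    # the symmetry slightly)
    box = build_common_box([dumbbell, tripod], spacing=0.3, margin=2.7)
    rset = hopf_rotations(16)
    a = dumbbell.translated(box.center - dumbbell.centroid())
    b = tripod.translated(box.center - tripod.centroid())
    e_ab = align_pair(a, b, box, rset, promolecule_model).e_ij
    e_ba = align_pair(b, a, box, rset, promolecule_model).e_ij
    assert abs(e_ab - e_ba) / e_ab < 0.02
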