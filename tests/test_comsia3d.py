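"""Alignment, similarity-index fields, grids, PLS, and contour analysis."""

import math

import numpy as np
import pytest

from nmqsar import comsia3d, synthetic_data, validation
from nmqsar.comsia3d import GridSpec, Molecule3D
from nmqsar.mlr_heuristic import fit_ols


def _mol(coords, **props):
    coords = np.atleast_2d(np.asarray(coords, float))
    return Molecule3D(
        molecule_id="m",
        elements=tuple("X" * len(coords)),
        coords=coords,
        **props,
    )


def _rotation(axis, angle):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


TRIANGLE = np.array([[0.0, 0, 0], [1.5, 0, 0], [0.7, 1.2, 0], [0.4, 0.3, 1.1]])


class TestKabschAlign:
    def test_identity(self):
        t = _mol(TRIANGLE)
        aligned, rmsd, R, tr = comsia3d.kabsch_align(t, _mol(TRIANGLE), [(i, i) for i in range(4)])
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_translation_removed(self):
        t = _mol(TRIANGLE)
        moved = _mol(TRIANGLE + np.array([5.0, 0, 0]))
        aligned, rmsd, _, _ = comsia3d.kabsch_align(t, moved, [(i, i) for i in range(4)])
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(aligned.coords, TRIANGLE, atol=1e-10)

    def test_rotation_recovered(self):
        R90 = _rotation([0, 0, 1], math.pi / 2)
        rotated = _mol(TRIANGLE @ R90.T)
        aligned, rmsd, R, _ = comsia3d.kabsch_align(
            _mol(TRIANGLE), rotated, [(i, i) for i in range(4)]
        )
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(R, R90.T, atol=1e-9)  # inverse of the applied rotation
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_agrees_with_scipy(self, rng):
        from scipy.spatial.transform import Rotation

        pts = rng.standard_normal((6, 3))
        R_true = _rotation([1, 2, 3], 0.7)
        target = _mol(pts @ R_true.T + [1.0, -2.0, 0.5])
        aligned, rmsd, R, _ = comsia3d.kabsch_align(_mol(pts), target, [(i, i) for i in range(6)])
        est, _ = Rotation.align_vectors(pts - pts.mean(0), target.coords - target.coords.mean(0))
        np.testing.assert_allclose(R, est.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_too_few_or_collinear_pairs_rejected(self):
        t = _mol(TRIANGLE)
        with pytest.raises(ValueError, match="3 atom pairs"):
            comsia3d.kabsch_align(t, t, [(0, 0), (1, 1)])
        line = _mol([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            comsia3d.kabsch_align(line, line, [(0, 0), (1, 1), (2, 2)])


class TestBuildGrid:
    def test_single_atom_125_points(self):
        grid = comsia3d.build_grid([_mol([[0, 0, 0]])], spacing=2, margin=4)
        assert grid.counts == (5, 5, 5)
        assert grid.n_points == 125
        pts = grid.points()
        assert pts.min() == -4.0 and pts.max() == 4.0

    def test_two_atoms_150_points(self):
        grid = comsia3d.build_grid([_mol([[0, 0, 0], [2, 0, 0]])], spacing=2, margin=4)
        assert grid.counts == (6, 5, 5)
        assert grid.n_points == 150

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            comsia3d.build_grid([_mol([[0, 0, 0]])], spacing=0)


class TestComsiaField:
    def test_probe_on_atom(self):
        m = _mol([[0, 0, 0]], charge=np.array([1.0]))
        v = comsia3d.field_values(m, [[0, 0, 0]], "E", alpha=0.3)
        assert v[0] == pytest.approx(-1.0, abs=1e-15)

    def test_probe_at_one_angstrom(self):
        m = _mol([[0, 0, 0]], charge=np.array([1.0]))
        v = comsia3d.field_values(m, [[1, 0, 0]], "E", alpha=0.3)
        assert v[0] == pytest.approx(-math.exp(-0.3), abs=1e-12)

    def test_linearity_in_atoms(self, rng):
        pts = rng.uniform(-3, 3, size=(40, 3))
        a = _mol([[0, 0, 0]], steric=np.array([2.0]))
        b = _mol([[1.5, 0.5, 0]], steric=np.array([0.7]))
        both = _mol(
            np.vstack([a.coords, b.coords]), steric=np.array([2.0, 0.7])
        )
        np.testing.assert_allclose(
            comsia3d.field_values(both, pts, "S"),
            comsia3d.field_values(a, pts, "S") + comsia3d.field_values(b, pts, "S"),
            atol=1e-12,
        )

    def test_missing_property_names_field(self):
        m = _mol([[0, 0, 0]])  # no properties at all
        with pytest.raises(ValueError, match="'H'"):
            comsia3d.field_values(m, [[0, 0, 0]], "H")

    def test_rigid_motion_invariance(self, rng):
        """Transforming molecule AND probe points together leaves fields unchanged."""
        m = _mol(rng.uniform(-2, 2, (5, 3)), charge=rng.uniform(-0.5, 0.5, 5))
        pts = rng.uniform(-4, 4, size=(30, 3))
        R = _rotation([1, 1, 0], 1.1)
        t = np.array([2.0, -1.0, 3.0])
        before = comsia3d.field_values(m, pts, "E")
        after = comsia3d.field_values(m.transformed(R, t), pts @ R.T + t, "E")
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_grid_refinement_shares_values(self):
        """Halving the spacing reproduces identical values at shared points."""
        m = _mol([[0.0, 0, 0]], charge=np.array([0.8]))
        coarse = comsia3d.build_grid([m], spacing=2, margin=4)
        fine = comsia3d.build_grid([m], spacing=1, margin=4)
        vc = comsia3d.field_values(m, coarse.points(), "E")
        vf = comsia3d.field_values(m, fine.points(), "E")
        pc, pf = coarse.points(), fine.points()
        lookup = {tuple(p): v for p, v in zip(map(tuple, pf), vf)}
        for p, v in zip(map(tuple, pc), vc):
            assert lookup[p] == pytest.approx(v, abs=1e-15)


class TestPLS:
    def test_univariate_matches_ols(self, rng):
        x = rng.standard_normal((12, 1))
        y = 2.0 * x[:, 0] + 0.1 * rng.standard_normal(12)
        m = comsia3d.pls_fit(x, y, 1)
        ols = fit_ols(x, y)
        np.testing.assert_allclose(m.predict(x), ols.predict(x), atol=1e-10)

    def test_constant_y_predicts_constant(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.full(10, 4.2)
        m = comsia3d.pls_fit(X, y, 1)
        np.testing.assert_allclose(m.predict(X), 4.2, atol=1e-10)

    def test_full_rank_matches_multicolumn_ols(self, rng):
        X = rng.standard_normal((15, 4))
        y = X @ [1.0, -2.0, 0.5, 3.0] + 0.2 * rng.standard_normal(15)
        m = comsia3d.pls_fit(X, y, 4)
        ols = fit_ols(X, y)
        np.testing.assert_allclose(m.predict(X), ols.predict(X), atol=1e-8)

    def test_matches_sklearn_nipals(self, rng):
        """Independent cross-check against scikit-learn's PLS."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((20, 6))
        y = X @ [1, 0, -1, 0.5, 0, 2.0] + 0.3 * rng.standard_normal(20)
        for c in (1, 2, 3):
            mine = comsia3d.pls_fit(X, y, c, pretreat=False)
            ref = PLSRegression(n_components=c, scale=False).fit(X, y)
            np.testing.assert_allclose(
                mine.predict(X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_out_of_range_components_rejected(self, rng):
        X = rng.standard_normal((8, 3))
        with pytest.raises(ValueError, match="n_components"):
            comsia3d.pls_fit(X, rng.standard_normal(8), 9)

    def test_prediction_invariant_to_column_shift(self, rng):
        """Centring metadata makes predictions affine-equivariant."""
        X = rng.standard_normal((14, 5))
        y = X @ [1, 2, 0, -1, 0.5] + 0.1 * rng.standard_normal(14)
        shift = rng.uniform(-10, 10, 5)
        m1 = comsia3d.pls_fit(X, y, 2)
        m2 = comsia3d.pls_fit(X + shift, y, 2)
        np.testing.assert_allclose(m1.predict(X), m2.predict(X + shift), atol=1e-9)


class TestPLSLooOnc:
    def test_single_latent_direction(self, rng):
        w = rng.standard_normal(6)
        T = rng.standard_normal((16, 1))
        X = T @ w.reshape(1, -1)  # rank one: a single latent direction
        y = T[:, 0]
        m = comsia3d.pls_loo_onc(X, y, max_components=4)
        assert m.q2 >= 0.99
        assert m.n_components == 1

    def test_permuted_response_has_low_q2(self, rng):
        X = rng.standard_normal((20, 8))
        y = X @ np.arange(1.0, 9.0)
        hits = 0
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(20)
            m = comsia3d.pls_loo_onc(X, y[perm], max_components=3)
            if m.q2 <= 0.2:
                hits += 1
        assert hits >= 9

    def test_q2_matches_generic_loo_oracle(self, rng):
        X = rng.standard_normal((12, 5))
        y = X @ [1, -1, 0.5, 0, 2] + 0.2 * rng.standard_normal(12)
        m = comsia3d.pls_loo_onc(X, y, max_components=3)
        onc = m.n_components

        def fitter(Xtr, ytr):
            return comsia3d.pls_fit(Xtr, ytr, onc).predict

        oracle = validation.loo_cv(fitter, X, y)
        assert m.q2 == pytest.approx(oracle, abs=1e-10)


class TestContoursAndContributions:
    def test_fractions_sum_to_one(self, aligned_set):
        molecules, y, _ = aligned_set
        grid = comsia3d.build_grid(molecules)
        X, labels = comsia3d.stack_fields(molecules, grid)
        m = comsia3d.pls_loo_onc(X, y, max_components=5, field_labels=labels)
        _, fractions = comsia3d.contour_and_contrib(m, grid)
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_field_model_gets_full_fraction(self):
        m = comsia3d.PLSModel(
            n_components=1,
            kept_columns=np.arange(4),
            column_means=np.zeros(4),
            column_scales=np.ones(4),
            coefficients=np.array([1.0, -2.0, 0.0, 0.0]),
            y_mean=0.0,
            field_labels=np.array(["S", "S", "E", "H"]),
            column_stdevs=np.array([1.0, 1.0, 1.0, 1.0]),
        )
        _, fractions = comsia3d.contour_and_contrib(m)
        assert fractions["S"] == pytest.approx(1.0)
        assert all(fractions[f] == 0.0 for f in "EHDA")

    def test_favorable_level_at_least_unfavorable(self, aligned_set):
        molecules, y, _ = aligned_set
        grid = comsia3d.build_grid(molecules)
        X, labels = comsia3d.stack_fields(molecules, grid)
        m = comsia3d.pls_loo_onc(X, y, max_components=5, field_labels=labels)
        contours, _ = comsia3d.contour_and_contrib(m, grid)
        for fav, unfav in contours.levels.values():
            assert fav >= unfav

    def test_planted_electrostatic_effect_ranks_first(self, aligned_set):
        molecules, y, truth = aligned_set
        grid = comsia3d.build_grid(molecules)
        X, labels = comsia3d.stack_fields(molecules, grid)
        m = comsia3d.pls_loo_onc(X, y, max_components=5, field_labels=labels)
        _, fractions = comsia3d.contour_and_contrib(m, grid)
        assert max(fractions, key=fractions.get) == truth["effect_field"]
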