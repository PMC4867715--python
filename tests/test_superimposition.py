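import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molarmorph.superimposition import (
    ShapeError,
    centroid_size,
    center_and_scale,
    gpa,
    gpa_objective,
    optimal_superimpose,
    procrustes_distance,
    procrustes_distance_matrix,
    tangent_project,
)

from conftest import random_shape


def rotation(theta):
    return np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )


class TestCentroidSize:
    def test_unit_square(self):
        square = np.array([[0.0, 0.0], [1, 0], [1, 1], [0, 1]])
        assert centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(s=st.floats(0.01, 100), tx=st.floats(-50, 50), ty=st.floats(-50, 50))
    def test_homogeneity_and_translation_invariance(self, s, tx, ty):
        x = random_shape(np.random.default_rng(3), k=8)
        cs = centroid_size(x)
        assert centroid_size(x * s) == pytest.approx(cs * s, rel=1e-9)
        assert centroid_size(x + [tx, ty]) == pytest.approx(cs, rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ShapeError):
            centroid_size(np.zeros((15, 2)) + 3.0)


class TestOptimalSuperimpose:
    def test_exact_recovery_of_similarity_transform(self, rng):
        src = random_shape(rng)
        tgt = (src @ rotation(np.pi / 6).T) * 3.0 + [5.0, -2.0]
        _, rot, residual = optimal_superimpose(src, tgt)
        assert residual < 1e-12
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_reflection_case(self, rng):
        src = random_shape(rng)
        mirrored = src * np.array([-1.0, 1.0])
        _, _, res_no = optimal_superimpose(src, mirrored, allow_reflection=False)
        _, _, res_yes = optimal_superimpose(src, mirrored, allow_reflection=True)
        assert res_no > 1e-4
        assert res_yes < 1e-12

    def test_landmark_count_mismatch(self, rng):
        with pytest.raises(ShapeError):
            optimal_superimpose(random_shape(rng, k=15), random_shape(rng, k=14))

    def test_matches_grid_search_oracle(self, rng):
        """Analytic rotation equals a brute-force 0.1-degree rotation search."""
        grid = np.deg2rad(np.arange(0.0, 360.0, 0.1))
        for _ in range(5):
            a = center_and_scale(random_shape(rng))
            b = center_and_scale(random_shape(rng))
            brute = min(((a @ rotation(t).T - b) ** 2).sum() for t in grid)
            _, _, residual = optimal_superimpose(a, b)
            assert residual <= brute + 1e-12
            assert brute - residual < 1e-4  # grid coarseness

    def test_matches_scipy_full_procrustes(self, rng):
        """scipy's disparity is the full-Procrustes residual 1 - t^2; ours is
        the partial residual 2 - 2t (reflection allowed in both)."""
        from scipy.spatial import procrustes as scipy_procrustes

        for _ in range(5):
            a, b = random_shape(rng), random_shape(rng)
            _, _, partial = optimal_superimpose(a, b, allow_reflection=True)
            t = 1.0 - partial / 2.0
            _, _, disparity = scipy_procrustes(a, b)
            assert disparity == pytest.approx(1.0 - t**2, abs=1e-9)


class TestProcrustesDistance:
    def test_zero_for_similarity_copies(self, rng):
        a = random_shape(rng)
        b = (a @ rotation(1.2).T) * 0.2 + [3.0, 3.0]
        assert procrustes_distance(a, b) < 1e-9

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = random_shape(rng), random_shape(rng)
            assert procrustes_distance(a, b) == pytest.approx(
                procrustes_distance(b, a), abs=1e-12
            )

    def test_equals_root_superimposition_residual(self, rng):
        a, b = random_shape(rng), random_shape(rng)
        _, _, residual = optimal_superimpose(a, b)
        assert procrustes_distance(a, b) == pytest.approx(np.sqrt(residual), abs=1e-12)

    def test_matches_kendall_complex_closed_form_on_triangles(self, rng):
        """For planar shapes as centred unit complex vectors z, w the optimal
        rotation-only residual is 2 - 2|conj(z) . w| (Kendall shape sphere)."""
        for _ in range(20):
            a, b = random_shape(rng, k=3), random_shape(rng, k=3)
            za = center_and_scale(a) @ [1, 1j]
            zb = center_and_scale(b) @ [1, 1j]
            closed = np.sqrt(max(2.0 - 2.0 * abs(np.conj(za) @ zb), 0.0))
            assert procrustes_distance(a, b) == pytest.approx(closed, abs=1e-9)

    def test_distance_matrix_is_a_metric(self, rng):
        shapes = np.stack([random_shape(rng) for _ in range(8)])
        dm = procrustes_distance_matrix(shapes)
        d = dm.d
        assert np.allclose(d, d.T)
        assert np.abs(np.diag(d)).max() == 0.0
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestGPA:
    def test_two_copies_give_that_shape_as_consensus(self, rng):
        base = random_shape(rng)
        shapes = np.stack([
            (base @ rotation(0.7).T) * 2.0,
            (base @ rotation(-1.1).T) * 0.5 + [4.0, 4.0],
        ])
        res = gpa(shapes)
        assert res.converged
        assert procrustes_distance(res.consensus, base) < 1e-9
        assert gpa_objective(res.procrustes_coords, res.consensus) < 1e-12

    def test_consensus_invariants(self, small_dataset):
        ds, _ = small_dataset
        res = gpa(ds.coords())
        assert centroid_size(res.consensus) == pytest.approx(1.0, abs=1e-9)
        assert np.abs(res.procrustes_coords.mean(axis=1)).max() < 1e-9  # centred
        assert res.converged

    def test_invariance_to_order_and_similarity_transforms(self, rng):
        shapes = np.stack([random_shape(rng) + random_shape(rng) * 0.05 for _ in range(12)])
        res1 = gpa(shapes)
        perm = rng.permutation(len(shapes))
        transformed = []
        for s in shapes[perm]:
            transformed.append(
                (s @ rotation(rng.uniform(0, 2 * np.pi)).T) * rng.uniform(0.5, 2.0)
                + rng.uniform(-5, 5, 2)
            )
        res2 = gpa(np.stack(transformed))
        assert procrustes_distance(res1.consensus, res2.consensus) < 1e-6

    def test_two_distinct_shapes_equidistant_from_consensus(self, rng):
        a, b = random_shape(rng), random_shape(rng)
        res = gpa(np.stack([a, b]))
        da = procrustes_distance(res.procrustes_coords[0], res.consensus)
        db = procrustes_distance(res.procrustes_coords[1], res.consensus)
        assert da == pytest.approx(db, abs=1e-9)

    def test_objective_non_increasing(self, rng):
        shapes = np.stack([random_shape(rng) for _ in range(10)])
        res = gpa(shapes)
        hist = np.array(res.objective_history)
        assert (np.diff(hist) <= 1e-12).all()

    def test_too_few_shapes(self, rng):
        with pytest.raises(ShapeError):
            gpa(random_shape(rng)[None])


class TestTangentProjection:
    def test_orthogonal_to_consensus_and_consensus_maps_to_zero(self, small_dataset):
        ds, _ = small_dataset
        res = tangent_project(gpa(ds.coords()))
        c = res.consensus.reshape(-1)
        assert np.abs(res.tangent_coords @ c).max() < 1e-9
        cons_tangent = c - (c @ c) * c / (c @ c)
        assert np.abs(cons_tangent).max() < 1e-12

    def test_small_perturbation_limit(self, rng, template):
        """For sigma=0.001 noise, tangent coordinates agree with Procrustes
        residuals (aligned minus consensus) to 1e-5 per coordinate."""
        base = center_and_scale(template)
        shapes = np.stack(
            [base + rng.normal(scale=0.001, size=base.shape) for _ in range(10)]
        )
        res = tangent_project(gpa(shapes))
        residuals = res.procrustes_coords.reshape(res.n, -1) - res.consensus.reshape(-1)
        assert np.abs(res.tangent_coords - residuals).max() < 1e-5
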