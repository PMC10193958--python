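"""T1 lattice resampling and T2 feature reductions."""

import numpy as np
import pytest

from varimap.kernels import gaussian_cell_weight
from varimap.measures import ConditionalLaw, Features, Grid, ParticleMeasure
from varimap.renormalize import (
    Stage,
    bayes_reduce,
    cascade,
    cells_to_tissue,
    entropy,
    fisher_rao_distance,
    kmeans_fisher_rao,
    moment_features,
    pst_fourier,
    resample_to_lattice,
    rna_to_cells,
)


@pytest.fixture
def rng():
    return np.random.default_rng(13)


def scalar_measure(rng, n=50, lo=2.0, hi=8.0):
    return ParticleMeasure(
        rng.uniform(lo, hi, size=(n, 2)),
        rng.uniform(0.5, 2.0, n),
        Features("scalar", rng.uniform(1.0, 3.0, n)),
    )


class TestResample:
    def test_narrow_kernel_concentrates_in_cell(self):
        mu = ParticleMeasure([[2.5, 3.5]], [2.0], Features("scalar", [7.0]))
        grid = Grid((0, 0), (1, 1), (6, 6))
        lat = resample_to_lattice(mu, grid, sigma=0.01)
        j = np.argmax(lat.site_weights)
        np.testing.assert_allclose(grid.centers()[j], [2.5, 3.5])
        assert lat.site_weights[j] == pytest.approx(2.0, abs=1e-12)
        law = lat.site_laws[j]
        assert len(law.probs) == 1 and law.atoms[0].value[0] == 7.0

    def test_mass_conservation_with_padding(self, rng):
        mu = scalar_measure(rng)
        grid = Grid((0, 0), (1, 1), (10, 10))
        lat = resample_to_lattice(mu, grid, sigma=0.3)
        assert abs(lat.site_weights.sum() - mu.weights.sum()) <= 1e-8

    def test_brute_force_double_loop_oracle(self, rng):
        mu = scalar_measure(rng, n=50)
        grid = Grid((0, 0), (1, 1), (10, 10))
        sigma = 0.3
        lat = resample_to_lattice(mu, grid, sigma=sigma)
        centers = grid.centers()
        ref = np.zeros(grid.n_sites)
        for i in range(mu.n):
            for j in range(grid.n_sites):
                pij = gaussian_cell_weight(sigma, mu.positions[i],
                                           centers[j] - 0.5, centers[j] + 0.5)
                ref[j] += mu.weights[i] * pij
        np.testing.assert_allclose(lat.site_weights, ref, atol=1e-10)

    def test_empty_measure_gives_empty_lattice(self):
        lat = resample_to_lattice(ParticleMeasure.empty(2), Grid((0, 0), (1, 1), (3, 3)),
                                  sigma=0.5)
        assert np.all(lat.site_weights == 0)
        assert all(l is None for l in lat.site_laws)

    def test_insufficient_padding_warns(self, rng):
        mu = scalar_measure(rng, lo=0.2, hi=9.8)
        with pytest.warns(UserWarning, match="6 sigma"):
            resample_to_lattice(mu, Grid((0, 0), (1, 1), (10, 10)), sigma=1.0)

    def test_refinement_consistency(self, rng):
        """Halving the spacing and summing child weights reproduces the
        parent weights to 1e-10."""
        mu = scalar_measure(rng)
        coarse = resample_to_lattice(mu, Grid((0, 0), (1, 1), (10, 10)), sigma=0.3)
        fine = resample_to_lattice(mu, Grid((0, 0), (0.5, 0.5), (20, 20)), sigma=0.3)
        w = fine.site_weights.reshape(20, 20)
        pooled = w.reshape(10, 2, 10, 2).sum(axis=(1, 3))
        np.testing.assert_allclose(pooled.ravel(), coarse.site_weights, atol=1e-10)

    def test_nearest_mode_conserves_mass(self, rng):
        mu = scalar_measure(rng)
        lat = resample_to_lattice(mu, Grid((0, 0), (1, 1), (10, 10)), mode="nearest")
        assert lat.site_weights.sum() == pytest.approx(mu.weights.sum(), abs=1e-12)

    def test_invalid_sigma_errors(self, rng):
        with pytest.raises(ValueError, match="sigma"):
            resample_to_lattice(scalar_measure(rng), Grid((0, 0), (1, 1), (10, 10)))


class TestMomentFeatures:
    def test_point_mass(self):
        law = ConditionalLaw(Features("scalar", [4.0]), [1.0])
        mean, var = moment_features(law, "mean_var")
        assert (mean, var) == (4.0, 0.0)
        out = moment_features(law, "mean_meansq_entropy")
        np.testing.assert_allclose(out, [4.0, 16.0, 0.0])

    def test_uniform_entropy_is_log_k(self):
        k = 5
        law = ConditionalLaw(Features("scalar", np.arange(k, dtype=float)),
                             np.full(k, 1 / k))
        assert moment_features(law, "mean_meansq_entropy")[-1] == pytest.approx(np.log(k))

    def test_two_atom_moments(self):
        law = ConditionalLaw(Features("scalar", [2.0, 10.0]), [0.3, 0.7])
        mean, meansq, _ = moment_features(law, "mean_meansq_entropy")
        assert mean == pytest.approx(7.6)
        assert meansq == pytest.approx(71.2)

    def test_variance_nonnegative(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = rng.integers(1, 6)
            p = rng.dirichlet(np.ones(k))
            law = ConditionalLaw(Features("scalar", rng.normal(size=k)), p)
            assert moment_features(law, "mean_var")[1] >= 0.0
            h = moment_features(law, "mean_meansq_entropy")[-1]
            assert -1e-12 <= h <= np.log(k) + 1e-12


class TestBayesReduce:
    REGIONS = [(0, 64), (64, 128), (128, 256)]

    def test_concentrated_law(self):
        law = ConditionalLaw(Features("scalar", [100.0]), [1.0])
        np.testing.assert_allclose(bayes_reduce(law, self.REGIONS), [0, 1, 0])

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 256, size=30).astype(float)
        law = ConditionalLaw(Features("scalar", vals), rng.dirichlet(np.ones(30)))
        assert bayes_reduce(law, self.REGIONS).sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_gray_levels(self):
        law = ConditionalLaw(Features("scalar", np.arange(256.0)), np.full(256, 1 / 256))
        np.testing.assert_allclose(bayes_reduce(law, self.REGIONS), [0.25, 0.25, 0.5],
                                   atol=1e-12)

    def test_non_partition_errors(self):
        law = ConditionalLaw(Features("scalar", [10.0]), [1.0])
        with pytest.raises(ValueError, match="cover|disjoint"):
            bayes_reduce(law, [(0, 64), (70, 256)])


class TestPstFourier:
    def test_phi0_is_one_when_bins_cover(self):
        law = ConditionalLaw(Features("spike-times", [[0.1, 0.4, 0.9]]), [1.0])
        phi = pst_fourier(law, np.linspace(0, 1, 9), n_max=3)
        assert phi[0] == pytest.approx(1.0)
        assert abs(phi[0].imag) < 1e-12

    def test_single_bin_train_gives_pure_phase(self):
        b, B = 3, 8
        edges = np.linspace(0, 1, B + 1)
        times = [edges[b - 1] + 0.01, edges[b - 1] + 0.02]  # all in bin b (1-based)
        law = ConditionalLaw(Features("spike-times", [times]), [1.0])
        phi = pst_fourier(law, edges, n_max=B - 1)
        omega = 2 * np.pi / B
        for n in range(B):
            assert phi[n] == pytest.approx(np.exp(1j * omega * n * b), abs=1e-12)

    def test_equal_occupancy_kills_harmonics(self):
        B = 6
        edges = np.linspace(0, 1, B + 1)
        times = edges[:-1] + 0.05
        law = ConditionalLaw(Features("spike-times", [times]), [1.0])
        phi = pst_fourier(law, edges, n_max=B - 1)
        assert phi[0] == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(phi[1:]), 0.0, atol=1e-12)

    def test_spike_outside_range_errors(self):
        law = ConditionalLaw(Features("spike-times", [[0.5, 1.5]]), [1.0])
        with pytest.raises(ValueError, match="1.5"):
            pst_fourier(law, np.linspace(0, 1, 5), n_max=2)


class TestFisherRao:
    def test_identical_laws(self):
        p = np.array([0.2, 0.3, 0.5])
        assert fisher_rao_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_pi(self):
        assert fisher_rao_distance([1, 0], [0, 1]) == pytest.approx(np.pi)

    def test_closed_form_quarter_turn(self):
        assert fisher_rao_distance([1, 0], [0.5, 0.5]) == pytest.approx(np.pi / 2, abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            fisher_rao_distance([1, 0], [1, 0, 0])


class TestKmeansFisherRao:
    def test_k_equals_n_distinct_gives_zero_objective(self, rng):
        laws = rng.dirichlet(np.ones(4), size=6)
        labels, cents, obj = kmeans_fisher_rao(laws, 6, seed=0)
        assert obj == pytest.approx(0.0, abs=1e-12)

    def test_two_separated_clusters_recovered(self, rng):
        a = np.array([0.9, 0.05, 0.05]) + 0.02 * rng.dirichlet(np.ones(3), 20)
        b = np.array([0.05, 0.05, 0.9]) + 0.02 * rng.dirichlet(np.ones(3), 20)
        laws = np.vstack([a, b])
        laws /= laws.sum(axis=1, keepdims=True)
        labels, _, _ = kmeans_fisher_rao(laws, 2, seed=1)
        first, second = labels[:20], labels[20:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_lloyd_objective_non_increasing(self, rng):
        laws = rng.dirichlet(np.ones(5), size=40)
        trace: list = []
        kmeans_fisher_rao(laws, 3, seed=2, restarts=1, trace=trace)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_invalid_k_errors(self, rng):
        laws = rng.dirichlet(np.ones(3), size=5)
        with pytest.raises(ValueError):
            kmeans_fisher_rao(laws, 9, seed=0)


class TestRnaToCells:
    def test_single_center_single_gene(self):
        pos = np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.1]])
        onehot = np.tile([1.0, 0.0], (3, 1))
        mu = ParticleMeasure(pos, np.ones(3), Features("simplex", onehot))
        cells, info = rna_to_cells(mu, [[0.0, 0.0]], n_types=1, seed=0)
        assert cells.n == 1
        assert cells.weights[0] == 3.0
        np.testing.assert_allclose(cells.features.as_matrix(), [[1.0]])

    def test_assignment_matches_brute_force(self, rng):
        from varimap.kernels import nearest_center

        pos = rng.uniform(0, 10, size=(200, 2))
        onehot = np.zeros((200, 3))
        onehot[np.arange(200), rng.integers(3, size=200)] = 1.0
        mu = ParticleMeasure(pos, np.ones(200), Features("simplex", onehot))
        centers = rng.uniform(0, 10, size=(12, 2))
        _, info = rna_to_cells(mu, centers, n_types=2, seed=0)
        for i in range(200):
            assert info["assignment"][i] == nearest_center(pos[i], centers)

    def test_zero_rna_cells_flagged_and_dropped(self, rng):
        pos = np.array([[0.0, 0.0], [0.2, 0.1]])
        onehot = np.tile([1.0, 0.0], (2, 1))
        mu = ParticleMeasure(pos, np.ones(2), Features("simplex", onehot))
        centers = [[0.0, 0.0], [50.0, 50.0]]
        cells, info = rna_to_cells(mu, centers, n_types=1, seed=0)
        assert list(info["empty_cells"]) == [1]
        assert cells.n == 1


class TestCellsToTissue:
    @pytest.mark.filterwarnings("ignore:lattice does not pad")
    def test_single_type_maps_to_one_class_per_site(self, rng):
        pos = rng.uniform(2, 8, size=(30, 2))
        simplices = np.tile([1.0, 0.0], (30, 1))
        simplices[0] = [0.0, 1.0]  # a second distinct law so k=2 is valid
        mu = ParticleMeasure(pos, np.ones(30), Features("simplex", simplices))
        lat = cells_to_tissue(mu, Grid((0, 0), (1, 1), (10, 10)), sigma=0.5, k=2, seed=0)
        feats = lat.site_features.as_matrix()
        occ = lat.site_weights > 0
        assert np.all(np.isclose(feats[occ].sum(axis=1), 1.0, atol=1e-9))

    @pytest.mark.filterwarnings("ignore:lattice does not pad")
    def test_weight_conservation(self, rng):
        pos = rng.uniform(2, 8, size=(25, 2))
        simplices = rng.dirichlet(np.ones(3), size=25)
        mu = ParticleMeasure(pos, rng.uniform(1, 5, 25), Features("simplex", simplices))
        lat = cells_to_tissue(mu, Grid((0, 0), (1, 1), (10, 10)), sigma=0.3, k=2, seed=0)
        assert abs(lat.site_weights.sum() - mu.weights.sum()) <= 1e-8


class TestCascade:
    def test_empty_recipe_is_single_scale(self, rng):
        mu = scalar_measure(rng, n=10)
        msm = cascade(mu, [])
        assert len(msm) == 1 and msm[0] is mu

    def test_mass_preserved_through_stage(self, rng):
        mu = scalar_measure(rng)
        stage = Stage(Grid((0, 0), (1, 1), (10, 10)), 0.3)
        msm = cascade(mu, [stage])
        assert abs(msm[0].site_weights.sum() - mu.weights.sum()) <= 1e-8

    @pytest.mark.filterwarnings("ignore:lattice does not pad")
    def test_two_stage_recipe_equals_manual_composition(self, rng):
        from varimap.renormalize import resample_to_lattice

        mu = scalar_measure(rng)
        s1 = Stage(Grid((0, 0), (0.5, 0.5), (20, 20)), 0.25)
        s2 = Stage(Grid((0, 0), (2.0, 2.0), (5, 5)), 0.8)
        msm = cascade(mu, [s1, s2])
        assert len(msm) == 3
        # manual: resample mu, reduce, resample the reduced particles
        lat1 = msm[1]
        manual = resample_to_lattice(lat1.to_particles(), s2.grid, s2.sigma)
        np.testing.assert_allclose(msm[0].site_weights, manual.site_weights, atol=1e-12)

    def test_incompatible_reduction_names_stage(self, rng):
        pos = np.zeros((3, 2))
        trains = Features("spike-times", [[0.1], [0.2], [0.3]])
        mu = ParticleMeasure(pos + np.arange(3)[:, None], np.ones(3), trains)
        stage = Stage(Grid((-3, -3), (1, 1), (9, 9)), 0.3, reduce="mean_var")
        with pytest.raises(TypeError, match="stage 0"):
            cascade(mu, [stage])


def test_entropy_bounds():
    assert entropy([1.0]) == 0.0
    assert entropy([0.5, 0.5, 0.0]) == pytest.approx(np.log(2))
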