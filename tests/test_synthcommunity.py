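import numpy as np
import pytest
from scipy.special import ndtr

from biodivmap.synthcommunity import (
    ResponseTerm,
    SpeciesResponseSpec,
    extract_site_covariates,
    generate_landscape,
    generate_species,
    make_design,
    simulate_incidence,
    true_probability,
)


def lag1_correlation(layer):
    a = layer[:, :-1].ravel()
    b = layer[:, 1:].ravel()
    return np.corrcoef(a, b)[0, 1]


class TestGenerateLandscape:
    def test_white_noise_has_no_lag1_autocorrelation(self):
        land = generate_landscape((32, 32), 3, 0.0, seed=1)
        for layer in land.layers:
            assert abs(lag1_correlation(layer)) < 0.12

    def test_smoothed_layers_are_autocorrelated(self):
        land = generate_landscape((32, 32), 3, 8.0, seed=1)
        for layer in land.layers:
            assert lag1_correlation(layer) > 0.5

    def test_deterministic_given_seed(self):
        a = generate_landscape((32, 32), 3, 4.0, seed=1)
        b = generate_landscape((32, 32), 3, 4.0, seed=1)
        np.testing.assert_array_equal(a.layers, b.layers)

    def test_different_seed_differs(self):
        a = generate_landscape((16, 16), 2, 0.0, seed=1)
        b = generate_landscape((16, 16), 2, 0.0, seed=2)
        assert not np.array_equal(a.layers, b.layers)

    def test_standardization_exact(self):
        land = generate_landscape((20, 25), 5, 3.0, seed=7)
        flat = land.layers.reshape(5, -1)
        np.testing.assert_allclose(flat.mean(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(flat.std(axis=1), 1.0, atol=1e-8)

    @pytest.mark.parametrize("shape", [(0, 10), (10, 0), (-3, 4)])
    def test_invalid_grid_raises(self, shape):
        with pytest.raises(ValueError):
            generate_landscape(shape, 2, 1.0, seed=0)

    def test_invalid_args_raise(self):
        with pytest.raises(ValueError):
            generate_landscape((8, 8), 0, 1.0, seed=0)
        with pytest.raises(ValueError):
            generate_landscape((8, 8), 2, -1.0, seed=0)


class TestGenerateSpecies:
    def test_rank_zero_has_no_loadings(self):
        land = generate_landscape((16, 16), 3, 2.0, seed=1)
        spec = generate_species(land, 5, latent_rank=0, sparsity=0.5, seed=2)
        assert spec.loadings.shape == (5, 0)

    def test_sparsity_one_over_p_gives_single_covariate(self):
        land = generate_landscape((8, 8), 29, 0.0, seed=1)
        spec = generate_species(land, 6, latent_rank=0, sparsity=1 / 29, seed=2)
        for j in range(6):
            assert len(spec.active_covariates(j)) == 1

    def test_deterministic(self):
        land = generate_landscape((16, 16), 4, 2.0, seed=1)
        a = generate_species(land, 5, 2, 0.5, seed=9)
        b = generate_species(land, 5, 2, 0.5, seed=9)
        np.testing.assert_array_equal(a.intercepts, b.intercepts)
        np.testing.assert_array_equal(a.loadings, b.loadings)

    def test_rank_exceeding_species_raises(self):
        land = generate_landscape((8, 8), 3, 1.0, seed=1)
        with pytest.raises(ValueError):
            generate_species(land, 3, latent_rank=4, sparsity=0.5, seed=0)

    def test_sparsity_bounds(self):
        land = generate_landscape((8, 8), 3, 1.0, seed=1)
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                generate_species(land, 3, 0, bad, seed=0)

    def test_prevalence_calibrated_within_bounds(self):
        land = generate_landscape((24, 24), 5, 3.0, seed=3)
        spec = generate_species(land, 8, 2, 0.4, seed=4)
        probs = true_probability(spec, land)
        prevalence = probs.reshape(8, -1).mean(axis=1)
        assert np.all(prevalence > 0.05) and np.all(prevalence < 0.95)


def _flat_spec(land, n_species, coef=0.0, intercept=0.0, loadings=None):
    if loadings is None:
        loadings = np.zeros((n_species, 0))
    return SpeciesResponseSpec(
        covariate_names=list(land.covariate_names),
        terms=[[ResponseTerm(covariate=0, shape="linear", coef=coef)] for _ in range(n_species)],
        intercepts=np.full(n_species, intercept),
        loadings=loadings,
    )


class TestTrueProbability:
    def test_null_model_is_half_everywhere(self):
        land = generate_landscape((10, 10), 2, 0.0, seed=1)
        probs = true_probability(_flat_spec(land, 3), land)
        np.testing.assert_allclose(probs, 0.5)

    def test_large_intercept_saturates_to_one(self):
        land = generate_landscape((10, 10), 2, 0.0, seed=1)
        probs = true_probability(_flat_spec(land, 2, intercept=50.0), land)
        np.testing.assert_allclose(probs, 1.0)

    def test_probabilities_in_unit_interval(self):
        land = generate_landscape((12, 12), 4, 2.0, seed=5)
        spec = generate_species(land, 6, 2, 0.5, seed=6)
        probs = true_probability(spec, land)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_marginal_matches_latent_monte_carlo(self, rng):
        # closed form Phi(eta / sqrt(1 + ||lambda||^2)) vs 1e5 latent draws
        land = generate_landscape((6, 6), 2, 0.0, seed=1)
        loadings = np.array([[0.8, -0.4], [0.3, 0.9]])
        spec = _flat_spec(land, 2, coef=1.0, intercept=0.3, loadings=loadings)
        probs = true_probability(spec, land).reshape(2, -1)
        eta = spec.linear_predictor(land.pixel_matrix())
        M = 10**5
        h = rng.standard_normal((M, 2))
        mc = ndtr(0) * 0
        mc = np.stack(
            [ndtr(eta[:, j][None, :] + (h @ loadings[j])[:, None]).mean(axis=0) for j in range(2)]
        )
        se = np.sqrt(mc * (1 - mc) / M) + 1e-4
        assert np.all(np.abs(mc - probs) < 4 * se + 2e-3)

    def test_schema_mismatch_raises(self):
        land = generate_landscape((8, 8), 2, 0.0, seed=1)
        other = generate_landscape((8, 8), 3, 0.0, seed=1)
        spec = generate_species(other, 3, 0, 0.5, seed=2)
        with pytest.raises(ValueError):
            true_probability(spec, land)


class TestDesignAndIncidence:
    def test_design_counts_and_pairing(self):
        land = generate_landscape((32, 32), 2, 0.0, seed=1)
        design = make_design(land, n_points=89, paired_fraction=32 / 89, seed=2)
        assert design.n_points == 89
        assert design.n_samples == 121
        # paired samples share a point but have distinct sample ids
        counts = np.bincount(design.sample_point)
        assert set(counts.tolist()) <= {1, 2}
        assert (counts == 2).sum() == 32
        assert len(set(design.sample_ids)) == design.n_samples

    def test_certain_species_always_present(self):
        land = generate_landscape((10, 10), 2, 0.0, seed=1)
        spec = _flat_spec(land, 2, intercept=40.0)
        design = make_design(land, 30, 0.0, seed=3)
        Y = simulate_incidence(spec, land, design, seed=4)
        assert np.all(Y.values == 1)

    def test_empirical_frequency_matches_truth(self):
        land = generate_landscape((4, 4), 2, 0.0, seed=1)
        spec = generate_species(land, 4, latent_rank=1, sparsity=0.5, seed=2)
        design = make_design(land, 10, 1.0, seed=3)  # 20 samples per draw
        n_sims = 2000
        sims = [simulate_incidence(spec, land, design, seed=s) for s in range(n_sims)]
        freq = np.mean([s.values for s in sims], axis=0)  # (20, 4)
        truth = true_probability(spec, land).reshape(4, -1).T[design.sample_pixels()]
        se = np.sqrt(truth * (1 - truth) / n_sims)
        assert np.all(np.abs(freq - truth) <= 3 * se + 0.01)

    def test_seed_reproducibility(self):
        land = generate_landscape((8, 8), 2, 0.0, seed=1)
        spec = generate_species(land, 3, 1, 0.5, seed=2)
        design = make_design(land, 20, 0.5, seed=3)
        a = simulate_incidence(spec, land, design, seed=7)
        b = simulate_incidence(spec, land, design, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_extract_site_covariates_matches_pixels(self):
        land = generate_landscape((8, 8), 3, 0.0, seed=1)
        design = make_design(land, 10, 0.0, seed=2)
        X = extract_site_covariates(land, design)
        np.testing.assert_array_equal(
            X.values, land.pixel_matrix()[design.sample_pixels()]
        )

    def test_too_many_points_raises(self):
        land = generate_landscape((3, 3), 1, 0.0, seed=1)
        with pytest.raises(ValueError):
            make_design(land, 10, 0.0, seed=0)
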