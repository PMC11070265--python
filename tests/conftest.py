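import numpy as np
import pytest

from biodivmap.jsdm import Hyperparameters, fit
from biodivmap.synthcommunity import (
    extract_site_covariates,
    generate_landscape,
    generate_species,
    make_design,
    simulate_incidence,
    true_probability,
)


@pytest.fixture(scope="session")
def recovery_case():
    """Linear, rank-0 parameter-recovery setting: 400 samples, 10 species,
    one truly informative covariate per species."""
    landscape = generate_landscape((48, 48), 6, 4.0, seed=1)
    spec = generate_species(
        landscape, n_species=10, latent_rank=0, sparsity=1 / 6, seed=2,
        shapes=("linear",), coef_scale=1.8,
    )
    design = make_design(landscape, n_points=400, paired_fraction=0.0, seed=3)
    Y = simulate_incidence(spec, landscape, design, seed=4)
    X = extract_site_covariates(landscape, design)
    hyper = Hyperparameters(
        env_penalty=1e-3, env_mix=0.0, trend_penalty=1e-2, trend_mix=0.0,
        loading_penalty=1e-3, latent_rank=0, hidden=(), lr=0.05, epochs=800,
    )
    model = fit(Y, X, hyper=hyper, seed=5)
    return {
        "landscape": landscape,
        "spec": spec,
        "design": design,
        "Y": Y,
        "X": X,
        "hyper": hyper,
        "model": model,
        "truth": true_probability(spec, landscape),
    }


@pytest.fixture(scope="session")
def small_community():
    """Small joint community for tuning/evaluation tests."""
    landscape = generate_landscape((24, 24), 4, 3.0, seed=11)
    spec = generate_species(
        landscape, n_species=6, latent_rank=1, sparsity=0.25, seed=12,
        shapes=("linear",), coef_scale=1.6, prevalence_range=(0.25, 0.75),
    )
    design = make_design(landscape, n_points=120, paired_fraction=0.0, seed=13)
    Y = simulate_incidence(spec, landscape, design, seed=14)
    X = extract_site_covariates(landscape, design)
    return {"landscape": landscape, "spec": spec, "Y": Y, "X": X}


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Demo pipeline executed twice with the same config (for determinism)."""
    from biodivmap.pipeline import demo_config, run_pipeline

    base = tmp_path_factory.mktemp("pipeline")
    out1 = run_pipeline(demo_config(), base / "run1")
    out2 = run_pipeline(demo_config(), base / "run2")
    return out1, out2


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
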