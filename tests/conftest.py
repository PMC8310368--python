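import numpy as np
import pytest

from selekt import bayes, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """A 6-ligand star+ring dataset with moderate noise, fixed seed."""
    return synthetic.generate(
        synthetic.SyntheticConfig(n_ligands=6, rho_true=0.5, seed=101)
    )


@pytest.fixture(scope="session")
def fitted_small(small_dataset):
    """Posterior samples on the small dataset (reduced draws)."""
    ds = small_dataset
    spec = bayes.ModelSpec(n_draws=1500, n_tune=500, seed=7)
    model = bayes.build_model(
        ds.maps["target1"],
        ds.maps["target2"],
        ds.observations["target1"],
        ds.observations["target2"],
        spec,
    )
    return bayes.sample_posterior(model, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
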