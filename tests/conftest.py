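import numpy as np
import pandas as pd
import pytest

from invasim.simulate import SynthConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(n_communities=60, n_otus=30, n_groups=3,
                       library_size=3000, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A small synthetic study shared across read-only tests."""
    return simulate_dataset(small_config)


def make_latent_indicator_data(beta_cp, beta_pi, beta_ci, n=680, seed=0,
                               loading=0.8, n_c=3, n_p=2, n_i=6):
    """Indicator table generated directly from the latent mediation model.

    All latents are standardised; every indicator loads with ``loading``
    on its latent plus independent normal noise.  Returns (DataFrame,
    column lists) for the composition, productivity and invasion blocks.
    """
    rng = np.random.default_rng(seed)
    C = rng.standard_normal(n)
    P = beta_cp * C + np.sqrt(1 - beta_cp ** 2) * rng.standard_normal(n)
    explained = (beta_pi ** 2 + beta_ci ** 2
                 + 2 * beta_pi * beta_ci * beta_cp)
    I = (beta_pi * P + beta_ci * C
         + np.sqrt(max(0.0, 1 - explained)) * rng.standard_normal(n))
    noise_sd = np.sqrt(1 - loading ** 2)

    def block(latent, prefix, k):
        return {f"{prefix}{j}": loading * latent + noise_sd * rng.standard_normal(n)
                for j in range(k)}

    cols_c = [f"c{j}" for j in range(n_c)]
    cols_p = [f"p{j}" for j in range(n_p)]
    cols_i = [f"i{j}" for j in range(n_i)]
    data = pd.DataFrame({**block(C, "c", n_c), **block(P, "p", n_p),
                         **block(I, "i", n_i)})
    return data, cols_c, cols_p, cols_i
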