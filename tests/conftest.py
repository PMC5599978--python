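import numpy as np
import pandas as pd
import pytest

from nutriqg import (GenParams, McmcSettings, simulate_halfsib_choice,
                     simulate_nochoice, simulate_outbred_choice, z_standardize)
from nutriqg.synthetic import surface_spec


@pytest.fixture(scope="session")
def linear_surface_data():
    """No-choice data from noisy linear-only surfaces with different sex
    gradients (published life-span betas), standardized within sex."""
    specs = {
        ("female", "lifespan"): surface_spec((-0.06, 0.60), (0, 0), 0.0, 0.9),
        ("male", "lifespan"): surface_spec((0.28, 0.76), (0, 0), 0.0, 0.9),
    }
    raw = simulate_nochoice(specs, n_per_diet_per_sex=10, seed=42)
    return raw, z_standardize(raw, group_by="sex")


@pytest.fixture(scope="session")
def choice_data():
    return simulate_outbred_choice(seed=7)


@pytest.fixture(scope="session")
def tiny_halfsib():
    params = GenParams(n_sires=10, n_dams_per_sire=2,
                       n_offspring_per_dam_per_sex=4)
    data, ped = simulate_halfsib_choice(params, seed=5)
    std = z_standardize(data, columns=["p_intake", "c_intake"], group_by="sex")
    return std, ped


@pytest.fixture(scope="session")
def tiny_posterior(tiny_halfsib):
    from nutriqg import fit_animal_model

    std, ped = tiny_halfsib
    settings = McmcSettings(iterations=1200, burn_in=200, thin=5, seed=9,
                            prior_nu=1.002)
    with np.errstate(all="ignore"):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            return fit_animal_model(std, ped, settings=settings)


def make_null_table(n: int, rng: np.random.Generator,
                    trait: str = "lifespan") -> pd.DataFrame:
    """Quick intake-like table with trait independent of a shared surface."""
    z = rng.standard_normal((n, 2))
    return pd.DataFrame({
        "individual_id": [str(i) for i in range(n)],
        "sex": "female",
        "design_cell": "d01",
        "p_intake": z[:, 0],
        "c_intake": z[:, 1],
        trait: rng.standard_normal(n),
    })
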