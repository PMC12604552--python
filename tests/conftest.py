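import numpy as np
import pandas as pd
import pytest

from nutriprocure import scoring, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """A small scored synthetic cohort shared across test modules."""
    cfg = simulate.GeneratorConfig(seed=424242, n_products=600, n_schools=6,
                                   n_guided=3, products_per_school=80)
    scored, ledger, truth = simulate.simulate_study(cfg)
    return scored, ledger, truth


def random_profiles(rng: np.random.Generator, n: int, beverage: bool = False,
                    with_total_fat: bool = False):
    """Random but physically valid nutrient profiles for oracle comparisons."""
    out = []
    for _ in range(n):
        if beverage:
            energy = rng.uniform(0, 450)
            sugars = rng.uniform(0, 15)
        else:
            energy = rng.uniform(0, 3800)
            sugars = rng.uniform(0, 60)
        satfat = rng.uniform(0, 30)
        kwargs = {}
        if with_total_fat:
            total = rng.uniform(satfat, 100)
            kwargs["total_fat_g"] = total
        out.append(scoring.NutrientProfile(
            energy_kj=energy,
            sugars_g=sugars,
            saturated_fat_g=satfat,
            salt_g=rng.uniform(0, 5),
            protein_g=rng.uniform(0, 30),
            fiber_g=rng.uniform(0, 10),
            fvl_percent=rng.uniform(0, 100),
            has_nonnutritive_sweeteners=bool(rng.random() < 0.3),
            **kwargs,
        ))
    return out
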