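import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_cohort(trajectories: dict, genotype="WT", treatment="saline") -> pd.DataFrame:
    """Small hand-built cohort: {animal_id: [mass week1, mass week2, ...]}.

    NaN entries become missing weeks.  ``genotype``/``treatment`` may be a
    single label or a per-animal dict.
    """
    rows = []
    for animal, masses in trajectories.items():
        g = genotype[animal] if isinstance(genotype, dict) else genotype
        t = treatment[animal] if isinstance(treatment, dict) else treatment
        for week, mass in enumerate(masses, start=1):
            if mass is None or (isinstance(mass, float) and np.isnan(mass)):
                continue
            rows.append((animal, g, t, week, float(mass), False))
    return pd.DataFrame(
        rows, columns=["animal_id", "genotype", "treatment", "week", "mass_g", "excluded"]
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Default-design cohort with no treatment effect (seeded)."""
    from minpweight import default_spec, generate_cohort

    return generate_cohort(default_spec(effect_size=0.0, seed=11))


@pytest.fixture(scope="session")
def effect_cohort():
    """Default-design cohort with the standard 5% effect (seeded)."""
    from minpweight import default_spec, generate_cohort

    return generate_cohort(default_spec(seed=7))
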