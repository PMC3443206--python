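import numpy as np
import pandas as pd
import pytest

from comorbid_aaf import (
    PopulationSpec,
    apply_nonresponse,
    draw_sample,
    generate_population,
    recovery_spec,
)


@pytest.fixture(scope="session")
def recovery_population():
    """Generated population of the documented 5-condition recovery scenario."""
    spec = recovery_spec(seed=11, population_size=60_000)
    return spec, generate_population(spec)


@pytest.fixture(scope="session")
def recovery_survey(recovery_population):
    """Respondent table (sampled, with response flags) of the same scenario."""
    spec, pop = recovery_population
    return spec, pop, apply_nonresponse(draw_sample(pop, spec), spec)


@pytest.fixture(scope="session")
def default_survey():
    """Small 12-condition synthetic survey for pipeline-level tests."""
    spec = PopulationSpec(population_size=60_000, seed=5)
    pop = generate_population(spec)
    return spec, pop, apply_nonresponse(draw_sample(pop, spec), spec)


def balanced_population(conditions: dict[str, np.ndarray], n_rep: int = 1) -> pd.DataFrame:
    """Tiny population table with constant covariates, for oracle tests."""
    n = len(next(iter(conditions.values())))
    df = pd.DataFrame(
        {
            "age": np.full(n, 50.0),
            "sex": ["female"] * n,
            "marital_status": ["married"] * n,
            "living_alone": [False] * n,
            "education_level": ["primary"] * n,
            "residence": ["rural"] * n,
            "age_class": ["40-65"] * n,
        }
    )
    for k, v in conditions.items():
        df[k] = np.asarray(v, dtype=bool)
    if n_rep > 1:
        df = pd.concat([df] * n_rep, ignore_index=True)
    return df
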