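import numpy as np
import pytest

from dielrhythm import (
    ActivitySimSpec,
    ExpressionSimSpec,
    aggregate_cohort,
    bin_hourly,
    normalize_to_max,
    simulate_activity_cohort,
    simulate_expression_timecourse,
)


@pytest.fixture(scope="session")
def ld_cohort():
    """35-animal LD cohort at generator defaults (72 h, 12:12)."""
    spec = ActivitySimSpec(n_animals=35, seed=101)
    traces, truth = simulate_activity_cohort(spec)
    return spec, traces, truth


@pytest.fixture(scope="session")
def ld_cohort_mean(ld_cohort):
    _, traces, _ = ld_cohort
    norm = [normalize_to_max(bin_hourly(t), t.animal_id) for t in traces]
    return aggregate_cohort(norm)


@pytest.fixture(scope="session")
def planted_expression():
    """5000-gene matrix with 180 planted rhythmic genes in 5 phase groups."""
    spec = ExpressionSimSpec(
        n_genes=5000,
        frac_rhythmic=0.036,
        phases_zt=(1.0, 5.0, 9.0, 13.0, 17.0),
        seed=202,
    )
    counts, truth = simulate_expression_timecourse(spec)
    return spec, counts, truth


@pytest.fixture
def hourly_zt():
    return np.arange(72.0)
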