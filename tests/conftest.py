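import numpy as np
import pandas as pd
import pytest

from cohortmeta.simulate import SimulationSpec, simulate_cohorts
from cohortmeta.types import ExpressionCohort


def make_cohort(
    matrix: dict[str, list[float]],
    groups: list[str],
    cohort_id: str = "C1",
    platform_id: str = "P1",
    is_log_scale: bool = True,
) -> ExpressionCohort:
    """Build a tiny cohort from {gene: values} and per-sample group labels."""
    frame = pd.DataFrame(matrix).T
    samples = [f"{cohort_id}_S{i}" for i in range(frame.shape[1])]
    frame.columns = samples
    return ExpressionCohort(
        cohort_id=cohort_id,
        platform_id=platform_id,
        matrix=frame,
        group=pd.Series(groups, index=samples),
        is_log_scale=is_log_scale,
    )


def small_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """Default study conditions with a reduced gene count for speed."""
    kwargs = dict(n_genes=8, n_up=2, n_down=2, coexpr_block=2)
    kwargs.update(overrides)
    return SimulationSpec(seed=seed, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_small_cohorts():
    cohorts, truth = simulate_cohorts(small_spec(seed=7))
    return cohorts, truth
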