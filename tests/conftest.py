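import numpy as np
import pandas as pd
import pytest

from metaexpr.core import ExpressionCohort
from metaexpr.synthetic import SyntheticConfig, generate


def make_cohort(values, genes, case_ids, control_ids, cohort_id="C1",
                **meta) -> ExpressionCohort:
    """Build a small in-memory cohort from a plain nested list."""
    samples = list(case_ids) + list(control_ids)
    group = pd.Series(["case"] * len(case_ids) + ["control"] * len(control_ids),
                      index=samples)
    return ExpressionCohort(
        cohort_id=cohort_id,
        values=pd.DataFrame(np.asarray(values, dtype=float), index=genes,
                            columns=samples),
        group=group,
        **meta,
    )


@pytest.fixture(scope="session")
def demo_study():
    """One default synthetic study shared across read-only tests."""
    cohorts, surv, truth = generate(SyntheticConfig(seed=1))
    return cohorts, surv, truth


@pytest.fixture()
def tiny_cohort():
    rng = np.random.default_rng(7)
    return make_cohort(rng.normal(8, 1, size=(4, 8)),
                       ["MAOA", "G1", "G2", "G3"],
                       [f"case{i}" for i in range(4)],
                       [f"ctrl{i}" for i in range(4)])
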