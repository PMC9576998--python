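import numpy as np
import pandas as pd
import pytest

from subshift import FeatureTable, SyntheticSpec, generate_multidomain


def make_table(rows: list[dict], feature_columns: list[str]) -> FeatureTable:
    return FeatureTable(pd.DataFrame(rows), feature_columns)


@pytest.fixture
def small_table() -> FeatureTable:
    """Two subjects x two sessions with task rows plus both baselines."""
    rng = np.random.default_rng(0)
    rows = []
    for subject in ("S0", "S1"):
        for session, label in (("low", 0.0), ("high", 1.0)):
            for _ in range(12):
                f1, f2 = rng.normal(size=2)
                rows.append(
                    dict(subject=subject, session=session, phase="task",
                         label=label, f1=f1, f2=f2 + label)
                )
        for phase in ("baseline1", "baseline2"):
            for _ in range(6):
                f1, f2 = rng.normal(size=2)
                rows.append(
                    dict(subject=subject, session="rest", phase=phase,
                         label=np.nan, f1=f1, f2=f2)
                )
    return make_table(rows, ["f1", "f2"])


@pytest.fixture(scope="session")
def cohort() -> FeatureTable:
    """Small well-separated synthetic cohort (3 subjects, no injected shift)."""
    return generate_multidomain(
        SyntheticSpec(M=3, n_per_domain=80, F=4, class_separation=2.0,
                      n_baseline=24, seed=5)
    )
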