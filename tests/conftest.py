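import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from acceptmap.codebook import DEFAULT_CODEBOOK
from acceptmap.framework import ReferenceFramework
from acceptmap.schema import EvaluationSet
from acceptmap.simulate import CorpusConfig, default_profiles, generate_reference

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=list(HealthCheck)
)
settings.load_profile("ci")


def make_evalset(categories: list[dict], meta: pd.DataFrame | None = None) -> EvaluationSet:
    """Small hand-built EvaluationSet from per-row dicts of variable values."""
    rows = []
    for i, cats in enumerate(categories):
        row = {"patient_id": cats.get("patient_id", f"P{i + 1:02d}"),
               "timepoint": cats.get("timepoint", 1)}
        for var in DEFAULT_CODEBOOK.variable_names:
            row[var] = cats.get(var, DEFAULT_CODEBOOK.categories(var)[0])
        rows.append(row)
    ev = pd.DataFrame(rows)
    if meta is None:
        pids = ev["patient_id"].unique()
        meta = pd.DataFrame(
            {
                "age_years": 5.0,
                "sex": "M",
                "first_exposure": True,
                "dosing_frequency": 3,
                "treatment_duration": 5,
            },
            index=pd.Index(pids, name="patient_id"),
        )
    return EvaluationSet(evaluations=ev, meta=meta)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def reference_corpus():
    """Mid-sized two-profile synthetic reference corpus (complete data)."""
    return generate_reference(CorpusConfig(n_evaluations=600, seed=11))


@pytest.fixture(scope="session")
def framework(reference_corpus):
    return ReferenceFramework().fit(reference_corpus)


@pytest.fixture()
def rng():
    return np.random.default_rng(1729)
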