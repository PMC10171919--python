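"""Shared fixtures: small synthetic cohorts and one full pipeline run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oncocea import pipeline as pl
from oncocea.synthetic_cohort import CohortGenConfig, generate_ipd


def make_cohort(times, events, endpoint="os", arm="toy") -> pd.DataFrame:
    """Hand-built single-endpoint cohort frame for small worked examples."""
    n = len(times)
    df = pd.DataFrame(
        {
            "id": [f"T-{i}" for i in range(n)],
            "arm": arm,
            f"{endpoint}_time": np.asarray(times, dtype=float),
            f"{endpoint}_event": np.asarray(events, dtype=int),
        }
    )
    return df


@pytest.fixture(scope="session")
def intervention_cohort() -> pd.DataFrame:
    """Default 74-subject intervention arm (cure mixture, 36-month follow-up)."""
    cfg = CohortGenConfig(n=74, seed=20230426, cure_fraction=0.45)
    return generate_ipd(cfg)


@pytest.fixture(scope="session")
def pipeline_result() -> pl.PipelineResult:
    """One full base-case pipeline run (no uncertainty suite) shared by tests."""
    cfg = pl.load_config()
    return pl.run_pipeline(cfg, run_uncertainty=False, run_scenarios=True)


@pytest.fixture(scope="session")
def ce_model(pipeline_result):
    return pipeline_result.model
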