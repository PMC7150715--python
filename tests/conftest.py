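"""Shared fixtures: synthetic cohorts with their scored derivatives.

The large cohort (n=1000) with its index panel, internally derived
loadings and projected scores is expensive enough to build once per
session; several structural and direction tests share it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from glucopcs.indices import panel_table
from glucopcs.pcs import build_feature_matrix, derive_loadings, project_scores
from glucopcs.simulate import GeneratorConfig, generate_cohort


@dataclass
class ScoredCohort:
    cohort: pd.DataFrame
    latents: pd.DataFrame
    features: object
    loadings: object
    scores: object
    panels: pd.DataFrame

    @property
    def v1(self):
        return (self.cohort["visit"] == "V1").to_numpy()


def _scored(n: int, seed: int) -> ScoredCohort:
    cohort, latents = generate_cohort(
        GeneratorConfig(n_subjects=n, seed=seed), return_latents=True
    )
    features = build_feature_matrix(cohort)
    loadings = derive_loadings(features)
    scores = project_scores(features, loadings)
    panels = panel_table(cohort)
    return ScoredCohort(cohort, latents, features, loadings, scores, panels)


@pytest.fixture(scope="session")
def scored_large() -> ScoredCohort:
    """n=1000 cohort, self-standardized, internally derived loadings."""
    return _scored(1000, seed=1)


@pytest.fixture(scope="session")
def cohort_small() -> pd.DataFrame:
    """Study-sized cohort (67 subjects)."""
    return generate_cohort(GeneratorConfig(n_subjects=67, seed=42))


@pytest.fixture()
def ogtt_row(cohort_small):
    """One complete subject-visit row."""
    return cohort_small.iloc[0]
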