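"""Shared fixtures: small synthetic panels and a study-scale panel.

Everything is generated programmatically at test time; the study-scale
panel (191 countries x 12 vaccines x 2015-2022) is session-scoped because
several suites reuse it.
"""

import pandas as pd
import pytest

from ghsdid import SyntheticTruth, assign_treatment, generate_panel


@pytest.fixture(scope="session")
def study_panel():
    """Default study-scale panel with planted effects (0.74, 1.23, 0.76)."""
    truth = SyntheticTruth(seed=0)
    panel, hierarchy = generate_panel(truth)
    return truth, panel, hierarchy


@pytest.fixture(scope="session")
def study_fit(study_panel):
    from ghsdid import estimate_did

    truth, panel, hierarchy = study_panel
    assignment = assign_treatment(hierarchy.score("overall"), truth.score_threshold)
    return assignment, estimate_did(panel, assignment)


@pytest.fixture
def small_panel():
    """40 countries x 3 vaccines, quick to refit."""
    truth = SyntheticTruth(seed=7, score_threshold=45.0)
    panel, hierarchy = generate_panel(truth, n_countries=40, n_vaccines=3)
    return truth, panel, hierarchy


def make_coverage_frame(countries, vaccines, years, value=85.0):
    """Dense coverage table as a plain DataFrame (helper, not a fixture)."""
    rows = [
        {"iso3": c, "vaccine": v, "year": y, "coverage": value, "is_missing": False}
        for c in countries
        for v in vaccines
        for y in years
    ]
    return pd.DataFrame(rows)
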