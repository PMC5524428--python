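"""Shared fixtures: synthetic cohorts and a tiny hand-built reference."""

import pytest

from ionaudit.synthetic_data import (
    TruthSpec,
    make_classification_fixture,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def paper_fixture():
    """Seeded 27-sample cohort realising the packaged count structure,
    with both raters' verdict tables."""
    return make_classification_fixture(seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-sample cohort with the default mechanism counts (noise-free)."""
    return simulate_cohort(TruthSpec(), n_samples=6, seed=11)


@pytest.fixture()
def tiny_reference():
    return {"chr1": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"}
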