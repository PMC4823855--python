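"""Shared fixtures: the planted study cohort and its pipeline outputs."""

import pytest

from akicode import replicate_study, study_plant_spec


@pytest.fixture(scope="session")
def study_spec():
    """Joint (stage, code-pattern) counts reconstructed from the published rows."""
    return study_plant_spec()


@pytest.fixture(scope="session")
def study_bundle():
    """Full pipeline output on the planted study cohort, paper-rounded LR+."""
    return replicate_study(seed=20160407)


@pytest.fixture(scope="session")
def study_bundle_exact_lr():
    """Same planted cohort, LR+ computed from unrounded proportions."""
    return replicate_study(seed=20160407, lr_mode="exact")
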