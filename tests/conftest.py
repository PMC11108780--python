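from dataclasses import replace

import pytest

from hierwin import (
    BUILTIN_CONFIGS,
    DAPA_HF_LIKE,
    MAIN_TIERS,
    build_tier_table,
    generate_cohort,
)
from hierwin.slope import attach_slopes, individual_slopes
from hierwin.trial import cohort_to_frames


@pytest.fixture(scope="session")
def small_cohort():
    """A 60/arm cohort under the 720-day design defaults."""
    cfg = replace(BUILTIN_CONFIGS["dapa_hf_like"], n_per_arm=60, seed=42)
    return generate_cohort(DAPA_HF_LIKE, cfg)


@pytest.fixture(scope="session")
def small_tier_table(small_cohort):
    """Tier table for the small cohort, slopes fitted by the mixed model."""
    table = build_tier_table(small_cohort, MAIN_TIERS, DAPA_HF_LIKE)
    participants, visits = cohort_to_frames(small_cohort)
    slopes = individual_slopes(participants, visits, design=DAPA_HF_LIKE)
    return attach_slopes(table, slopes)


@pytest.fixture(scope="session")
def medium_tier_table():
    """A 250/arm cohort with fitted slopes, for engine-level checks."""
    cfg = replace(BUILTIN_CONFIGS["dapa_hf_like"], n_per_arm=250, seed=7)
    cohort = generate_cohort(DAPA_HF_LIKE, cfg)
    table = build_tier_table(cohort, MAIN_TIERS, DAPA_HF_LIKE)
    participants, visits = cohort_to_frames(cohort)
    slopes = individual_slopes(participants, visits, design=DAPA_HF_LIKE)
    return attach_slopes(table, slopes)
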