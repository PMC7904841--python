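import pytest

from ptacal.cohort import cohort_to_frame, default_config, generate_cohort


@pytest.fixture(scope="session")
def study_cohort_df():
    """Synthetic cohort at the published group sizes (179 subjects), seed 1."""
    return cohort_to_frame(generate_cohort(default_config(seed=1)))


@pytest.fixture(scope="session")
def large_cohort_df():
    """Large synthetic cohort (1000 per group) for calibration-recovery checks."""
    cfg = default_config(seed=1)
    cfg.group_sizes = {g: 1000 for g in cfg.group_sizes}
    return cohort_to_frame(generate_cohort(cfg))
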