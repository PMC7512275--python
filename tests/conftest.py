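import pytest

from gaitpe import pe_feature_table
from gaitpe.synthetic import SyntheticConfig, generate_cohort


def small_config(**overrides) -> SyntheticConfig:
    """A fast miniature cohort: 4 controls, 6 patients, 2-4 cycles each."""
    defaults = dict(
        n_control=4,
        n_cp=6,
        gmfcs_counts={"I": 2, "II": 2, "III": 1, "IV": 1},
        cycles_per_subject=(2, 4),
        seed=42,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def strong_cohort():
    """The full-size strong-effect cohort used by the heavier analyses."""
    return generate_cohort(SyntheticConfig.strong_effect(seed=1))


@pytest.fixture(scope="session")
def strong_pe_table(strong_cohort):
    return pe_feature_table(strong_cohort)
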