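import pytest

import confact
from confact.simulate import permute_survival, split_cohort  # noqa: F401  (re-exported for tests)


@pytest.fixture(scope="session")
def small_cohort():
    """60 patients, 3 subtypes, 2 omics of 120 features — fast end-to-end."""
    return confact.generate_cohort(
        n_patients=60,
        omics_specs=[confact.OmicsSpec(120, 30, "mRNA"), confact.OmicsSpec(120, 30, "meth")],
        seed=11,
    )


@pytest.fixture(scope="session")
def study_cohort():
    """The default study conditions: 150 patients, 3 omics × 500 features."""
    return confact.generate_cohort(n_patients=150, seed=7)
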