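import numpy as np
import pytest

import retestkit as rk


@pytest.fixture(scope="session")
def full_dataset() -> rk.TestRetestDataset:
    """The packaged 10-subject, 5-region reference dataset, no exclusion."""
    return rk.load_fe_pe2i_pd()


@pytest.fixture(scope="session")
def main_dataset(full_dataset) -> rk.TestRetestDataset:
    """The main-analysis dataset: subject 8 excluded, n = 9."""
    return full_dataset.apply_exclusion(
        rk.EXCLUDED_SUBJECT, "single transmission scan shared by both sessions"
    )


@pytest.fixture(scope="session")
def striatum9(main_dataset) -> rk.PairedMeasurements:
    return main_dataset.region("striatum")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


def random_pairs(rng: np.random.Generator, n: int) -> rk.PairedMeasurements:
    """Small random paired dataset for property tests."""
    truth = rng.normal(1.5, 0.4, size=n)
    return rk.PairedMeasurements(
        region_name="random",
        subject_ids=tuple(str(i) for i in range(n)),
        test_values=truth + rng.normal(0, 0.1, size=n),
        retest_values=truth + rng.normal(0, 0.1, size=n),
    )
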