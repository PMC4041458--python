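from pathlib import Path

import pytest

from tryclip.simulate import SimulationConfig, make_toy_reference_set, make_truth_profile

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_refset():
    return make_toy_reference_set(seed=1)


@pytest.fixture(scope="session")
def mixed_truth(toy_refset):
    """The standard study mixture: U1 5' terminus, SL 5'ss, U6 box, decoys."""
    return make_truth_profile(
        toy_refset,
        peak_spec=[
            ("U1", (1, 9), 0.40),
            ("SL", (36, 43), 0.20),
            ("U6", (30, 45), 0.10),
        ],
        background_fraction=0.05,
    )


@pytest.fixture
def small_config():
    return SimulationConfig(n_reads=2000, seed=11)


@pytest.fixture(scope="session")
def fixture_fastq() -> Path:
    return DATA_DIR / "filter_fixture.fastq"
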