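import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sarna_design import DesignConfig, PromoterRecord, default_spec, generate_promoter
from sarna_design.thermo import load_nn_table

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg():
    return DesignConfig()


@pytest.fixture(scope="session")
def rna_table():
    return load_nn_table("rna_xia_turner_1998")


@pytest.fixture(scope="session")
def synthetic_promoter():
    """One representative seeded 2.5-kb promoter with ground truth."""
    return generate_promoter(default_spec(11))


def random_record(rng: np.random.Generator, length: int, rec_id: str = "R") -> PromoterRecord:
    """Uniform-composition random promoter with the TSS 100 bp from the end."""
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return PromoterRecord(id=rec_id, sequence=seq, tss_index=max(1, length - 100))
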