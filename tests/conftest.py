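import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import allelescan as a

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def anchor_pwm() -> a.PWM:
    """A GATA-family anchor motif (WGATAR consensus)."""
    return a.PWM.from_consensus("GATA1", "AGATAA", tf_name="GATA1", family="GATA")


@pytest.fixture(scope="session")
def context_pwm() -> a.PWM:
    """An E-box contextual motif."""
    return a.PWM.from_consensus("EBOX", "CAGCTG", tf_name="TAL1", family="EBOX")


@pytest.fixture(scope="session")
def small_truth(anchor_pwm) -> a.SimulationTruth:
    """A small two-line genome: 20 peaks, SNPs at motif offsets 2 and 4."""
    return a.simulate_genome_pair(
        length=600_000,
        n_peaks=20,
        n_snps=20,
        pwms=[anchor_pwm],
        seed=11,
        effect_by_offset={2: 0.5, 4: 0.2},
    )


def make_uniform_pwm(motif_id: str = "uniform", length: int = 6) -> a.PWM:
    return a.PWM(motif_id, matrix=np.full((length, 4), 0.25))
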