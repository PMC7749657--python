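import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_plate_config():
    from ic50screen import PlateSimConfig

    return PlateSimConfig(noise_sd=0.0, seed=7)


@pytest.fixture
def small_expression(rng):
    """Tiny planted expression matrix: 40 transcripts, 5 lines, 6 pos, 4 neg."""
    from ic50screen import ExpressionMatrix, ExpressionSimConfig, simulate_expression

    cfg = ExpressionSimConfig(
        n_transcripts=40,
        n_cell_lines=5,
        n_planted_positive=6,
        n_planted_negative=4,
        pattern_noise_sd=0.0,
        frac_absent_calls=0.0,
        seed=11,
    )
    values, calls, truth = simulate_expression(cfg)
    return ExpressionMatrix(values=values, calls=calls), truth, cfg
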