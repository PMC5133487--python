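import numpy as np
import pytest

from stagetrends import ExpressionMatrix, StageDesign


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def six_stage_design():
    """18 samples in 6 ordered stages of 3 replicates."""
    levels = [f"S{k}" for k in range(1, 7)]
    mapping = {f"smp{j:02d}": levels[(j - 1) // 3] for j in range(1, 19)}
    return StageDesign(levels, mapping)


@pytest.fixture
def small_matrix(rng, six_stage_design):
    """10 noise genes x 18 samples aligned to the six-stage design."""
    sample_ids = six_stage_design.sample_ids
    values = rng.normal(5.0, 1.0, size=(10, len(sample_ids)))
    return ExpressionMatrix(
        [f"G{i}" for i in range(10)], sample_ids, values, "log_signal"
    )
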