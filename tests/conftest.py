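import numpy as np
import pandas as pd
import pytest

from nutnet import simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.GeneratorConfig(n_subjects=300, n_clusters=10, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_intakes(small_config, small_cohort):
    cohort, truth = small_cohort
    return simulate.generate_ffq_intakes(cohort, small_config, truth)


@pytest.fixture
def rng():
    return np.random.default_rng(20200604)


@pytest.fixture(scope="session")
def table1_cohort():
    """Cohort reconstructed from the printed counts of the worked example:
    DMPW 1022/294/180 with sex splits 562F/460M, 153F/141M, 139F/41M and
    pubertal-stage counts 126/325/1040 (+5 unknown)."""
    rows = []
    for dmpw, f, m in [
        ("Agreed", 562, 460),
        ("Underestimated", 153, 141),
        ("Overestimated", 139, 41),
    ]:
        rows += [{"dmpw": dmpw, "sex": "female"}] * f
        rows += [{"dmpw": dmpw, "sex": "male"}] * m
    frame = pd.DataFrame(rows)
    stages = (
        ["pre-pubertal"] * 126 + ["pubertal"] * 325 + ["post-pubertal"] * 1040
        + ["unknown"] * 5
    )
    frame["pubertal_stage"] = stages
    return frame
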