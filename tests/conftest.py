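import datetime

import numpy as np
import pytest

from routinemine import PipelineConfig, run_pipeline, split_days
from routinemine.clustering import TimespanVector
from routinemine.synthetic import default_template, generate_log


@pytest.fixture(scope="session")
def clean_log():
    """30-day noise-free synthetic log plus ground truth."""
    template = default_template(n_days=30, noise_day_probability=0.0, seed=11)
    days, truth = generate_log(template)
    return template, days, truth


@pytest.fixture(scope="session")
def noisy_log():
    """30-day log with exactly 3 anomalous days."""
    template = default_template(n_days=30, noise_day_probability=0.1, seed=11)
    days, truth = generate_log(template)
    return template, days, truth


@pytest.fixture(scope="session")
def clean_result(clean_log):
    _, days, _ = clean_log
    return run_pipeline(days, PipelineConfig(seed=11))


@pytest.fixture(scope="session")
def noisy_result(noisy_log):
    _, days, _ = noisy_log
    return run_pipeline(days, PipelineConfig(seed=11))


def planted_vectors(
    regime_means, per_regime, jitter_sd=2.0, seed=0, period="night", n_features=None
):
    """Timespan vectors drawn from well-separated duration regimes.

    Returns (vectors, true regime labels). Inter-regime gaps must dwarf the
    jitter for recovery tests.
    """
    rng = np.random.default_rng(seed)
    vectors, labels = [], []
    day = datetime.date(2021, 3, 1)
    i = 0
    for r, mean in enumerate(regime_means):
        mean = np.asarray(mean, dtype=float)
        for _ in range(per_regime):
            values = np.clip(mean + rng.normal(0, jitter_sd, size=mean.shape), 1, None)
            vectors.append(
                TimespanVector(
                    day + datetime.timedelta(days=i),
                    period,
                    tuple(f"act{j}" for j in range(len(mean))),
                    values,
                )
            )
            labels.append(r)
            i += 1
    return vectors, np.array(labels)
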