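import numpy as np
import pytest

from stresslink.simulate import SimConfig, generate_cohort
from stresslink.survival import SurvivalRecord


def records(times, events, strain="s", assay="a", replicate="r1"):
    """Toy survival records from parallel time/event lists."""
    return [SurvivalRecord(strain, assay, replicate, float(t), int(e))
            for t, e in zip(times, events)]


def deaths(*times, **kw):
    return records(times, [1] * len(times), **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted signal, shared by read-only tests."""
    cfg = SimConfig(seed=11, n_genes=600, n_shared_driver=40,
                    n_lifespan_only=20, n_stress_specific=10,
                    n_worms_per_assay_arm=45)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
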