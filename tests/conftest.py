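import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from silkcnv import simdata
from silkcnv.config import PipelineConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """Two 300 kb scaffolds with smooth GC and ~1.4% SD coverage."""
    return simdata.simulate_genome(2, (300_000, 300_000), seed=1)


@pytest.fixture(scope="session")
def small_truths(small_genome):
    return simdata.implant_cnvs(
        small_genome,
        random_params=simdata.RandomCnvParams(n_individual=3, n_group=2, n_all=1),
        seed=2,
    )


@pytest.fixture(scope="session")
def small_reads(small_genome, small_truths):
    return {
        t.sample_id: simdata.simulate_reads(small_genome, t, 10.0, seed=100 + k)
        for k, t in enumerate(small_truths)
    }


@pytest.fixture(scope="session")
def control_reads(small_genome):
    diploid = simdata.SyntheticTruth("control", "control")
    return simdata.simulate_reads(small_genome, diploid, 10.0, seed=999)


@pytest.fixture()
def config():
    return PipelineConfig()


def overlap_bp(a, b):
    return max(0, min(a[2], b[2]) - max(a[1], b[1])) if a[0] == b[0] else 0


def reciprocal_match(a, b, frac=0.5):
    ov = overlap_bp(a, b)
    return ov >= frac * (a[2] - a[1]) and ov >= frac * (b[2] - b[1])


def precision_recall(predicted, truth, frac=0.5):
    """Interval-set precision/recall at reciprocal-overlap ``frac``.

    ``predicted`` and ``truth`` are (scaffold, start, end, state) tuples.
    """
    tp = sum(
        any(reciprocal_match(p[:3], q[:3], frac) and p[3] == q[3] for q in truth)
        for p in predicted
    )
    found = sum(
        any(reciprocal_match(p[:3], q[:3], frac) and p[3] == q[3] for p in predicted)
        for q in truth
    )
    prec = tp / len(predicted) if predicted else float("nan")
    rec = found / len(truth) if truth else float("nan")
    return prec, rec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240331)
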