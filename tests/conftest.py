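import time

import numpy as np
import pytest

from octaseg.phantom import PhantomConfig, generate_phantom

PROTOCOL_SEEDS = tuple(range(5))


@pytest.fixture(scope="session")
def phantom64():
    """One deterministic 64x64 phantom with both annotation levels."""
    return generate_phantom(PhantomConfig(size=64, seed=7), 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def seg_runs():
    """Five seeded tiny-preset trainings per contrastive-weight arm.

    The expensive shared protocol: 40 phantoms, 30 epochs, with the
    contrastive term on (lambda=0.1) and off (lambda=0).  Returns the
    per-seed results plus the wall time of the lambda=0.1 arm.
    """
    from octaseg.experiments import segmentation_experiment

    out = {}
    t0 = time.time()
    out[0.1] = [segmentation_experiment(s, lambda_nce=0.1)
                for s in PROTOCOL_SEEDS]
    out["elapsed_nce"] = time.time() - t0
    out[0.0] = [segmentation_experiment(s, lambda_nce=0.0)
                for s in PROTOCOL_SEEDS]
    return out


@pytest.fixture(scope="session")
def gap_runs():
    """Five seeded gap-corruption refinement experiments."""
    from octaseg.experiments import gap_refinement_experiment

    return [gap_refinement_experiment(s) for s in PROTOCOL_SEEDS]
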