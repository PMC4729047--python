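import numpy as np
import pytest

import charmkit as ck
from charmkit.synthetic import ClassSpec, SyntheticSpec


def extract(spec):
    """Generate a synthetic dataset and extract its feature matrix."""
    samples, records = ck.make_dataset(spec)
    return ck.feature_matrix(
        samples,
        labels={r.sample_id: r.class_label for r in records},
        batches={r.sample_id: r.batch_id for r in records},
    )


@pytest.fixture(scope="session")
def separable_fm():
    """32-image balanced two-class set with well-separated textures."""
    return extract(ck.separable_spec(seed=7))


@pytest.fixture(scope="session")
def confounded_fm():
    """Batch-leakage fixture: class signal = per-batch brightness only."""
    return extract(ck.confounded_spec(seed=11))


@pytest.fixture(scope="session")
def hard_fm():
    """Partially separable fixture (accuracy well below 1) so that
    run-to-run variability of validation schemes is visible."""
    spec = SyntheticSpec(
        classes=[
            ClassSpec("fine", kind="filtered_noise", scale=3, contrast=0.35),
            ClassSpec("coarse", kind="filtered_noise", scale=5, contrast=0.35),
        ],
        n_per_class=14,
        image_size=64,
        noise_sd=0.15,
        n_batches=14,
        seed=5,
    )
    return extract(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
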