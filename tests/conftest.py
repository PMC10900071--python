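import numpy as np
import pytest

from ltm_ood import PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid_shape=(16, 16, 16), lesion_count_range=(1, 2), seed=11)


@pytest.fixture(scope="session")
def small_volume(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, 6, base_seed=5)


def numgrad(f, x, eps=1e-4):
    """Central-difference gradient of scalar f() with respect to array x in place."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
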