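import numpy as np
import pytest

from adaunet import PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast phantom dataset config shared across tests."""
    return PhantomConfig(
        image_size=32,
        n_cases=4,
        slices_per_case=2,
        contrast=0.8,
        noise_sd=0.02,
        n_distractors=1,
        area_bounds=(0.01, 0.15),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


def gradcheck(f, arrays, eps=1e-6, tol=1e-4):
    """Central finite-difference check of ``f``'s gradients (float64)."""
    from adaunet._nn import Tensor

    tensors = [Tensor(np.asarray(a, dtype=np.float64), requires_grad=True)
               for a in arrays]
    f(*tensors).backward()
    for t in tensors:
        numeric = np.zeros_like(t.data)
        for idx in np.ndindex(t.data.shape):
            orig = t.data[idx]
            t.data[idx] = orig + eps
            hi = float(f(*tensors).data)
            t.data[idx] = orig - eps
            lo = float(f(*tensors).data)
            t.data[idx] = orig
            numeric[idx] = (hi - lo) / (2 * eps)
        assert t.grad is not None, "missing gradient"
        np.testing.assert_allclose(t.grad, numeric, atol=tol, rtol=tol)
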