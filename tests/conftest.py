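import dataclasses

import numpy as np
import pytest

from mdwcnet.phantom import PhantomParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_phantom_params(image_size: int = 64) -> PhantomParams:
    """Default anatomy proportions rescaled to a small raster."""
    return PhantomParams().scaled(image_size)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """16 phantom pairs at 64x64 with a 7:1:2 manifest, shared per session."""
    root = tmp_path_factory.mktemp("phantoms")
    generate_dataset(16, small_phantom_params(64), root, seed=7)
    return root


def finite_diff_input_grad(layer, x, proj, eps=1e-3, train=True):
    """Central finite differences of sum(forward(x) * proj) w.r.t. x."""
    g = np.zeros_like(x, dtype=np.float64)
    xd = x.astype(np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = xd.copy(); xp[i] += eps
        xm = xd.copy(); xm[i] -= eps
        lp = float((layer.forward(xp.astype(np.float32), train) * proj).sum())
        lm = float((layer.forward(xm.astype(np.float32), train) * proj).sum())
        g[i] = (lp - lm) / (2 * eps)
    return g


def finite_diff_param_grad(layer, x, proj, param, eps=1e-3, train=True):
    """Central finite differences w.r.t. one parameter tensor."""
    g = np.zeros_like(param.data, dtype=np.float64)
    orig = param.data.copy()
    it = np.nditer(orig, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        param.data = orig.copy(); param.data[i] += eps
        lp = float((layer.forward(x, train) * proj).sum())
        param.data = orig.copy(); param.data[i] -= eps
        lm = float((layer.forward(x, train) * proj).sum())
        g[i] = (lp - lm) / (2 * eps)
    param.data = orig
    return g
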