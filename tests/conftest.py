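import numpy as np
import pytest

from monetseg.phantoms import PhantomConfig, phantom_slices
from monetseg.training import fit_fixed_batch


def numeric_gradcheck(layer, shape, rng, eps=1e-5, n_input=6, n_param=3):
    """Compare backward() against central finite differences.

    Returns (max input-grad rel. error, max param-grad rel. error) for a
    random projection of the layer output; the layer must be float64.
    """
    x = rng.normal(size=shape).astype(np.float64)
    for _, lay, attr in layer.named_param_layers():
        a = getattr(lay, attr)
        setattr(lay, attr,
                rng.normal(scale=0.5, size=a.shape).astype(np.float64))

    def run(xv):
        return layer.forward(xv, training=True, rng=np.random.default_rng(7))

    w = rng.normal(size=run(x).shape)

    def objective(xv):
        return float((run(xv) * w).sum())

    layer.zero_grad()
    run(x)
    dx = layer.backward(w.astype(np.float64))

    in_err = 0.0
    for _ in range(n_input):
        i = tuple(rng.integers(0, s) for s in x.shape)
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        num = (objective(xp) - objective(xm)) / (2 * eps)
        in_err = max(in_err, abs(num - dx[i]) / max(1.0, abs(num)))

    par_err = 0.0
    for _, lay, attr in layer.named_param_layers():
        a = getattr(lay, attr)
        g = lay.grads.get(attr)
        if g is None:
            continue
        for _ in range(n_param):
            i = tuple(rng.integers(0, s) for s in a.shape)
            ap, am = a.copy(), a.copy()
            ap[i] += eps
            am[i] -= eps
            setattr(lay, attr, ap)
            fp = objective(x)
            setattr(lay, attr, am)
            fm = objective(x)
            setattr(lay, attr, a)
            num = (fp - fm) / (2 * eps)
            par_err = max(par_err, abs(num - g[i]) / max(1.0, abs(num)))
    return in_err, par_err


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def overfit_phantoms():
    """The 8 fixed 128x128 phantom slices used by the overfit harness."""
    cfg = PhantomConfig(image_size=(128, 128), seed=1)
    return phantom_slices(cfg, 8)


@pytest.fixture(scope="session")
def overfit_run(overfit_phantoms):
    """One shared overfit-harness run (the expensive convergence check)."""
    net, scores = fit_fixed_batch(overfit_phantoms, steps=300, seed=0,
                                  check_every=10, target_score=0.95)
    return net, scores
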