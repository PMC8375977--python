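"""Efficiency and interpretability analyses.

* Activation capture at tagged layers (early/middle/late), with per-layer
  histograms and the near-zero fraction |a| < tau — the collapse statistic
  that distinguishes well-utilized filters from effectively dead ones.
* CPU inference timing over a fixed slice budget (absolute times are
  hardware-dependent and only meaningful within one environment).
* The parameter-count / serialized-size table across the registry.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architectures import build_architecture, count_parameters
from .training import serialized_size_bytes

#: Which module plays the early / middle / late role in each family.
DEFAULT_STAGE_TAGS = {
    "monet": {"early": "enc1", "middle": "bottleneck", "late": "dec2"},
    "unet": {"early": "enc0", "middle": "mid", "late": "dec0"},
}


@dataclass
class ActivationSummary:
    layer_id: str
    stage_tag: str
    bin_edges: np.ndarray
    counts: np.ndarray
    near_zero_fraction: float
    channel_count: int
    shape: tuple


@dataclass
class BenchmarkReport:
    architecture: str
    parameter_count: int
    serialized_bytes: int | None
    times: list = field(default_factory=list)
    environment: str = ""

    @property
    def mean_seconds(self):
        return float(np.mean(self.times)) if self.times else float("nan")

    @property
    def sd_seconds(self):
        return (float(np.std(self.times, ddof=1)) if len(self.times) > 1
                else 0.0)

    @property
    def n_repetitions(self):
        return len(self.times)


def near_zero_fraction(activations, tau: float = 1e-3) -> float:
    """Fraction of activation elements with |a| < tau."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    a = np.asarray(activations)
    return float((np.abs(a) < tau).mean())


def activation_histogram(activations, bins: int = 64):
    """Uniform-bin histogram over the observed activation range."""
    a = np.asarray(activations).ravel()
    lo, hi = float(a.min()), float(a.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(a, bins=bins, range=(lo, hi))
    return edges, counts


def _resolve_tags(net, stage_tags):
    if isinstance(stage_tags, dict):
        return stage_tags
    family = "monet" if type(net).__name__ == "MoNet" else "unet"
    return {tag: DEFAULT_STAGE_TAGS[family][tag] for tag in stage_tags}


def extract_activations(net, input_batch, stage_tags=("early", "middle",
                                                      "late"),
                        tau: float = 1e-3, bins: int = 64):
    """Capture post-activation tensors at tagged layers during one forward.

    ``stage_tags`` is either a list of the default tags or a mapping
    tag -> module name. Capture copies the tensors on the side and does not
    alter the forward result.
    """
    tag_map = _resolve_tags(net, stage_tags)
    modules = dict(net.modules())
    hooks = []
    for tag, name in tag_map.items():
        if name not in modules:
            raise KeyError(f"no module named {name!r} for tag {tag!r}")
        hooks.append((tag, name, modules[name]))
    try:
        for _, _, m in hooks:
            m.capture = True
        net.forward(input_batch, training=False)
        summaries = []
        for tag, name, m in hooks:
            a = m.last_output
            edges, counts = activation_histogram(a, bins=bins)
            summaries.append(ActivationSummary(
                layer_id=name, stage_tag=tag, bin_edges=edges, counts=counts,
                near_zero_fraction=near_zero_fraction(a, tau),
                channel_count=int(a.shape[1]), shape=tuple(a.shape)))
    finally:
        for _, _, m in hooks:
            m.capture = False
            m.last_output = None
    return summaries


def environment_descriptor() -> str:
    return (f"{platform.platform()} | {platform.processor() or 'unknown-cpu'}"
            f" | python {platform.python_version()} | numpy {np.__version__}")


def cpu_inference_benchmark(net, n_images: int = 150, image_size: int = 256,
                            repetitions: int = 5, batch_size: int = 10,
                            name: str = "", rng=None) -> BenchmarkReport:
    """Time forward passes over ``n_images`` slices, ``repetitions`` times.

    A warm-up pass is excluded; a monotonic clock is used. Absolute values
    are environment-bound and are reported with a descriptor, never compared
    across machines.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    x = rng.normal(size=(n_images, 1, image_size, image_size)).astype(
        np.float32)
    net.forward(x[:min(batch_size, n_images)], training=False)  # warm-up
    times = []
    for _ in range(repetitions):
        t0 = time.perf_counter()
        for i in range(0, n_images, batch_size):
            net.forward(x[i:i + batch_size], training=False)
        times.append(time.perf_counter() - t0)
    return BenchmarkReport(
        architecture=name or type(net).__name__,
        parameter_count=count_parameters(net), serialized_bytes=None,
        times=times, environment=environment_descriptor())


def size_table(architectures=("monet", "unet16", "unet64"),
               to_megabytes: float = 2 ** 20) -> pd.DataFrame:
    """Parameter count and serialized container size per architecture."""
    rows = []
    for name in architectures:
        net = build_architecture(name)
        n = count_parameters(net)
        size = serialized_size_bytes(net)
        rows.append({"architecture": name, "parameter_count": n,
                     "serialized_bytes": size,
                     "size_mb": size / to_megabytes})
    return pd.DataFrame(rows)
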