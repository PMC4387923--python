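"""Deterministic synthetic traces with analytically known features.

These are pressure-*like* test signals for exercising the feature
operators: a sine with exactly known period and extrema, a two-Gaussian
"bump pair" whose valley depth is set in closed form, and a decaying pulse
train whose peak heights shrink geometrically.  They contain no noise and no
randomness; an optional jitter takes an explicit seed.  They emulate trace
*shapes* only, not the dynamics of the circuit model.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .io import SampledTrace

__all__ = ["generate_fixture"]


def _sine(n: int, dt: float, period: float, amplitude: float, offset: float) -> np.ndarray:
    t = dt * np.arange(n)
    return offset + amplitude * np.sin(2.0 * math.pi * t / period)


def _bump_pair(
    n: int, dt: float, separation: float, valley: float, height: float
) -> np.ndarray:
    # Two unit-height Gaussians at +/- separation/2 around the trace centre.
    # The midpoint value of the sum is 2*exp(-(separation/2)^2 / (2 sigma^2));
    # solving for sigma pins the valley depth exactly (up to the negligible
    # overlap at the peaks).
    if not (0 < valley < 2 * height):
        raise ValueError("bump_pair: valley must lie in (0, 2*height)")
    sigma = (separation / 2.0) / math.sqrt(2.0 * math.log(2.0 * height / valley))
    t = dt * np.arange(n)
    mid = t[-1] / 2.0
    c1, c2 = mid - separation / 2.0, mid + separation / 2.0
    return height * (
        np.exp(-((t - c1) ** 2) / (2 * sigma**2))
        + np.exp(-((t - c2) ** 2) / (2 * sigma**2))
    )


def _decaying_train(
    n: int, dt: float, period: float, decay_per_cycle: float, amplitude: float
) -> np.ndarray:
    t = dt * np.arange(n)
    envelope = amplitude * decay_per_cycle ** (t / period)
    return envelope * 0.5 * (1.0 - np.cos(2.0 * math.pi * t / period))


def generate_fixture(
    kind: str,
    n: int = 1000,
    dt: float = 0.5,
    *,
    period: float = 20.0,
    amplitude: float = 1.0,
    offset: float = 0.0,
    separation: float = 40.0,
    valley: float = 0.3,
    height: float = 1.0,
    decay_per_cycle: float = 0.7,
    jitter: float = 0.0,
    seed: Optional[int] = None,
) -> SampledTrace:
    """Generate a deterministic analytic test trace.

    Parameters
    ----------
    kind : {"sine", "bump_pair", "decaying_train"}
        ``sine``: ``offset + amplitude*sin(2*pi*t/period)``.
        ``bump_pair``: two Gaussian bumps of the given ``height`` whose sum
        dips to exactly ``valley`` at the midpoint between them.
        ``decaying_train``: raised-cosine pulses whose peak heights decay by
        the factor ``decay_per_cycle`` each period.
    n : int
        Number of samples (>= 3).
    dt : float
        Sample step in ms.
    jitter : float
        Optional additive uniform noise half-width; requires ``seed``.
    """
    if n < 3:
        raise ValueError("generate_fixture: n must be >= 3")
    if dt <= 0:
        raise ValueError("generate_fixture: dt must be > 0")
    if kind == "sine":
        y = _sine(n, dt, period, amplitude, offset)
    elif kind == "bump_pair":
        y = _bump_pair(n, dt, separation, valley, height)
    elif kind == "decaying_train":
        y = _decaying_train(n, dt, period, decay_per_cycle, amplitude)
    else:
        raise ValueError(f"generate_fixture: unknown kind {kind!r}")
    if jitter:
        if seed is None:
            raise ValueError("generate_fixture: jitter requires an explicit seed")
        rng = np.random.default_rng(seed)
        y = y + rng.uniform(-jitter, jitter, size=n)
    return SampledTrace(times=dt * np.arange(n, dtype=float), values=y)
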