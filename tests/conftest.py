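"""Shared fixtures and independent naive oracles.

The oracle functions here deliberately avoid the package's vectorised code
paths: band sums, running averages and statistics are computed with plain
Python loops so that pipeline results can be checked against a genuinely
independent evaluation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


def naive_pipeline_psi(
    centers,
    sigmas,
    amps,
    offset=0.0,
    start=650.0,
    stop=800.0,
    step=0.5,
    window_nm=4.0,
) -> float:
    """Loop-based re-implementation of the 77 K pipeline on a pure band sum.

    Evaluates the Gaussian band mixture pointwise, applies the truncated
    inclusive running average, subtracts the 798-802 nm mean, normalizes to
    the 680-690 nm maximum and returns the 710-730 nm maximum.
    """
    n = int(math.floor((stop - start) / step + 1e-9)) + 1
    wl = [start + step * i for i in range(n)]
    y = []
    for w in wl:
        v = offset
        for c, s, a in zip(centers, sigmas, amps):
            v += a * math.exp(-0.5 * ((w - c) / s) ** 2)
        y.append(v)
    half = int(math.floor(window_nm / 2.0 / step + 1e-9))
    sm = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sm.append(sum(y[lo:hi]) / (hi - lo))
    base = [v for w, v in zip(wl, sm) if 798.0 - 1e-9 <= w <= 802.0 + 1e-9]
    b = sum(base) / len(base)
    z = [v - b for v in sm]
    psii = max(v for w, v in zip(wl, z) if 680.0 - 1e-9 <= w <= 690.0 + 1e-9)
    return max(v / psii for w, v in zip(wl, z) if 710.0 - 1e-9 <= w <= 730.0 + 1e-9)


def rasterize_disk(radius_px: int, pad: int = 10) -> np.ndarray:
    n = 2 * radius_px + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius_px + pad
    return ((yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2).astype(np.int32)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
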