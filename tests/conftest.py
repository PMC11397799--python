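"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (double loops, brute-force
searches, normal equations written out by hand) so they stay independent
of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from canopyspec.synthetic import Ellipse, SyntheticSceneSpec, generate_scene


@pytest.fixture
def disk_scene():
    """Noiseless, unshifted radius-40 disk scene plus its ground truth."""
    spec = SyntheticSceneSpec(
        height=128,
        width=128,
        canopy=[Ellipse(64.0, 64.0, 40.0, 40.0)],
        noise_sd=0.0,
        nir_shift=(0.0, 0.0),
        seed=7,
    )
    return generate_scene(spec)


@pytest.fixture
def shifted_scene():
    """Scene whose NIR channel is displaced by (3, -5) pixels."""
    spec = SyntheticSceneSpec(
        height=128,
        width=128,
        canopy=[Ellipse(64.0, 64.0, 40.0, 40.0)],
        noise_sd=0.01,
        nir_shift=(3.0, -5.0),
        seed=11,
    )
    return generate_scene(spec)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def brute_force_integer_shift(
    reference: np.ndarray, moving: np.ndarray, max_shift: int = 12
) -> tuple[int, int]:
    """Argmax of mean-subtracted cross-correlation over all integer shifts.

    Returns the displacement (dy, dx) of the moving content relative to
    the reference: the moving image translated back by (-dy, -dx) best
    matches the reference on the overlap.
    """
    ref = reference - reference.mean()
    mov = moving - moving.mean()
    h, w = ref.shape
    best, best_score = (0, 0), -np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            # overlap of ref[r, c] with mov[r + dy, c + dx]
            r0, r1 = max(0, -dy), min(h, h - dy)
            c0, c1 = max(0, -dx), min(w, w - dx)
            if r1 <= r0 or c1 <= c0:
                continue
            a = ref[r0:r1, c0:c1]
            b = mov[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
            denom = np.sqrt((a**2).sum() * (b**2).sum())
            if denom == 0:
                continue
            score = float((a * b).sum() / denom)
            if score > best_score:
                best_score, best = score, (dy, dx)
    return best


def naive_quadratic_ols(x: np.ndarray, y: np.ndarray):
    """Quadratic OLS via hand-written normal equations; returns
    (b0, b1, b2, r_squared, sse, sst)."""
    X = np.column_stack([np.ones_like(x), x, x**2])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sse = float((resid**2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    return (*(float(b) for b in beta), 1.0 - sse / sst, sse, sst)
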