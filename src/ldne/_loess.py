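"""Tricube-weighted local polynomial regression.

A small loess-style smoother used both for interpolating genetic maps and
for fitting LD-decay curves. The neighbourhood of each evaluation point is
the ``ceil(span * n)`` training points nearest in x (a contiguous window
once x is sorted), weighted by the tricube kernel on scaled distance.
Degree 1 uses the closed-form weighted least-squares solution, vectorised
over evaluation points; degree 2 solves a small normal system per point.
"""

from __future__ import annotations

import numpy as np

__all__ = ["local_polynomial"]


def _windows(x_sorted: np.ndarray, x_eval: np.ndarray, k: int) -> np.ndarray:
    """Start index of the k-nearest contiguous window for each eval point.

    Greedy monotone sweep: moving the window [s, s+k) one step right trades
    its left end for x_sorted[s+k]; do so while that brings the window
    closer to the evaluation point.
    """
    n = x_sorted.size
    starts = np.empty(x_eval.size, dtype=np.intp)
    if k >= n:
        starts[:] = 0
        return starts
    s = 0
    for i in np.argsort(x_eval, kind="stable"):
        x0 = x_eval[i]
        while s + k < n and (x_sorted[s + k] - x0) < (x0 - x_sorted[s]):
            s += 1
        starts[i] = s
    return starts


def local_polynomial(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    *,
    span: float = 0.3,
    degree: int = 1,
    sample_weight: np.ndarray | None = None,
    chunk: int = 256,
) -> np.ndarray:
    """Evaluate a loess fit of ``y`` on ``x`` at ``x_eval``.

    Parameters
    ----------
    span
        Fraction of the training points in each local neighbourhood.
    degree
        1 (local linear) or 2 (local quadratic).
    sample_weight
        Optional per-point weights multiplied into the tricube kernel
        (used when points are pre-aggregated bins).
    chunk
        Evaluation points processed per vectorised block (memory control).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    if x.size == 0:
        raise ValueError("no training points")
    if x.size == 1:
        return np.full(x_eval.shape, y[0])
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    ws = (np.ones_like(xs) if sample_weight is None
          else np.asarray(sample_weight, dtype=float)[order])
    n = xs.size
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)

    starts = _windows(xs, x_eval, k)
    out = np.empty(x_eval.size, dtype=float)
    idx = starts[:, None] + np.arange(k)[None, :]
    for a in range(0, x_eval.size, chunk):
        b = min(a + chunk, x_eval.size)
        xi = xs[idx[a:b]]                      # (m, k)
        yi = ys[idx[a:b]]
        wi = ws[idx[a:b]]
        x0 = x_eval[a:b, None]
        d = np.abs(xi - x0)
        h = d.max(axis=1, keepdims=True)
        h[h == 0] = 1.0
        w = (1 - (d / h) ** 3) ** 3
        w = np.clip(w, 0.0, None) * wi
        # guard: all-zero weights (duplicated x) -> uniform
        wsum = w.sum(axis=1, keepdims=True)
        bad = wsum[:, 0] == 0
        if bad.any():
            w[bad] = 1.0
            wsum = w.sum(axis=1, keepdims=True)
        if degree == 1:
            xc = xi - x0
            sw = wsum[:, 0]
            swx = (w * xc).sum(axis=1)
            swy = (w * yi).sum(axis=1)
            swxx = (w * xc * xc).sum(axis=1)
            swxy = (w * xc * yi).sum(axis=1)
            det = sw * swxx - swx * swx
            with np.errstate(divide="ignore", invalid="ignore"):
                beta0 = (swxx * swy - swx * swxy) / det
            # degenerate (constant x in window): weighted mean
            fallback = swy / sw
            out[a:b] = np.where(np.isfinite(beta0) & (det > 0), beta0, fallback)
        elif degree == 2:
            for j in range(b - a):
                xc = xi[j] - x0[j, 0]
                X = np.column_stack([np.ones_like(xc), xc, xc * xc])
                Wh = np.sqrt(w[j])
                beta, *_ = np.linalg.lstsq(X * Wh[:, None], yi[j] * Wh, rcond=None)
                out[a + j] = beta[0]
        else:
            raise ValueError("degree must be 1 or 2")
    return out
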