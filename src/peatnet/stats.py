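"""Shared correlation statistics.

Every module that reports a Pearson correlation (module-trait screens,
GS/MM taxon scores, trait-trait tests) goes through :func:`pearson_with_p`
or its vectorised counterpart so that the r and two-sided p values are
computed identically everywhere: p comes from the exact t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees of freedom.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats as _sps

__all__ = ["PearsonResult", "pearson_with_p", "pearson_matrix", "star_band"]


class PearsonResult(NamedTuple):
    """A single correlation test: coefficient, two-sided p, pairs used."""

    r: float
    p: float
    n: int

    @property
    def computable(self) -> bool:
        return np.isfinite(self.r)


def pearson_with_p(x, y) -> PearsonResult:
    """Pearson correlation with a two-sided p-value.

    Non-finite pairs are dropped pairwise. Fewer than 3 complete pairs, or
    a constant vector, yields a not-computable result (``r`` and ``p`` are
    NaN) rather than an exception, so batch screens over many taxa never
    abort on a degenerate profile.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        return PearsonResult(np.nan, np.nan, n)
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd * xd).sum())
    sy = np.sqrt((yd * yd).sum())
    if sx == 0.0 or sy == 0.0:
        return PearsonResult(np.nan, np.nan, n)
    r = float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))
    p = _p_from_r(np.array([r]), n)[0]
    return PearsonResult(r, float(p), n)


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t transform with n-2 df; |r|=1 maps to p=0."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * _sps.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def pearson_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and p between rows of ``X`` and rows of ``Y``.

    Both matrices must share the sample axis (columns). Rows with zero
    variance produce NaN r/p. No pairwise missing-data handling here —
    callers align and drop incomplete samples first.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if Y.ndim == 1:
        Y = Y[None, :]
    if X.shape[1] != Y.shape[1]:
        raise ValueError("sample axes differ")
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc * Xc).sum(axis=1))
    sy = np.sqrt((Yc * Yc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Yc.T) / np.outer(sx, sy)
    r = np.clip(r, -1.0, 1.0)
    r[~np.isfinite(r)] = np.nan
    p = np.full_like(r, np.nan)
    ok = np.isfinite(r)
    p[ok] = _p_from_r(r[ok], n)
    return r, p


def star_band(p: float) -> str:
    """Reporting stars: * p<0.05, ** p<0.01, *** p<0.001, '' otherwise."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
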