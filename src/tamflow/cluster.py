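"""Streamline-geometry exclusion filter.

Each streamline is summarized by five critical points at arc-length
fractions 0, 1/4, 1/2, 3/4, 1 (origin, first quartile, midpoint, third
quartile, termination).  For every pair of streamlines the RMS of the
five corresponding point distances and the midpoint distance are
computed; a streamline whose geometry is far from *every* other
streamline — RMS above 10 mm or midpoint distance above 5 mm against
all others — is considered unique and excluded.  Equivalently, a
streamline survives iff at least one neighbour is close under BOTH
measures.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CriticalPoints", "ClusterParams", "critical_points",
           "rms_pair_distance", "filter_unique"]

_FRACTIONS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])


@dataclass(frozen=True)
class ClusterParams:
    rms_threshold_mm: float = 10.0
    midpoint_threshold_mm: float = 5.0

    def __post_init__(self):
        if self.rms_threshold_mm <= 0 or self.midpoint_threshold_mm <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass(frozen=True)
class CriticalPoints:
    points: np.ndarray  # (5, 3)

    @property
    def midpoint(self) -> np.ndarray:
        return self.points[2]


def _polyline_points(streamline) -> np.ndarray:
    pts = getattr(streamline, "points", streamline)
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("streamline needs >= 2 points")
    return pts


def critical_points(streamline) -> CriticalPoints:
    """Five points at exact arc-length fractions, linearly interpolated
    along the polyline segments."""
    pts = _polyline_points(streamline)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("zero-length streamline")
    s = _FRACTIONS * total
    out = np.empty((5, 3))
    for d in range(3):
        out[:, d] = np.interp(s, cum, pts[:, d])
    return CriticalPoints(out)


def rms_pair_distance(a: CriticalPoints, b: CriticalPoints):
    """(RMS over the 5 corresponding point distances, midpoint distance)."""
    d = np.linalg.norm(a.points - b.points, axis=1)
    return float(np.sqrt(np.mean(d**2))), float(d[2])


def unique_mask_bruteforce(cps: list, params: ClusterParams) -> np.ndarray:
    """Direct evaluation of the exclusion predicate (reference oracle):
    s is unique iff for every other t, rms(s,t) > R or midpoint(s,t) > M."""
    n = len(cps)
    unique = np.zeros(n, dtype=bool)
    for i in range(n):
        unique[i] = all(
            (lambda rm: rm[0] > params.rms_threshold_mm
             or rm[1] > params.midpoint_threshold_mm)(rms_pair_distance(cps[i], cps[j]))
            for j in range(n) if j != i
        )
    return unique


def _unique_mask_vectorized(P: np.ndarray, params: ClusterParams) -> np.ndarray:
    """P: (n, 5, 3) critical points.  Vectorized pairwise evaluation."""
    diff = P[:, None, :, :] - P[None, :, :, :]
    d2 = (diff**2).sum(axis=-1)  # (n, n, 5)
    rms = np.sqrt(d2.mean(axis=-1))
    mid = np.sqrt(d2[..., 2])
    close = (rms <= params.rms_threshold_mm) & (mid <= params.midpoint_threshold_mm)
    np.fill_diagonal(close, False)
    return ~close.any(axis=1)


def filter_unique(streamlines: list, params: ClusterParams = ClusterParams()):
    """Split a bundle into (kept, excluded) by the uniqueness predicate.

    Bundles with fewer than 2 streamlines are kept unchanged (the
    universal quantifier over "all other streamlines" is vacuous).
    Returns (kept, excluded, kept_mask).
    """
    if len(streamlines) == 0:
        raise ValueError("bundle is empty")
    if len(streamlines) < 2:
        return list(streamlines), [], np.ones(len(streamlines), dtype=bool)
    P = np.stack([critical_points(s).points for s in streamlines])
    n = len(streamlines)
    if n <= 2000:
        unique = _unique_mask_vectorized(P, params)
    else:  # block the O(n^2) pairwise pass to bound memory
        unique = np.ones(n, dtype=bool)
        for start in range(0, n, 1000):
            blk = P[start:start + 1000]
            diff = blk[:, None, :, :] - P[None, :, :, :]
            d2 = (diff**2).sum(axis=-1)
            rms = np.sqrt(d2.mean(axis=-1))
            mid = np.sqrt(d2[..., 2])
            close = (rms <= params.rms_threshold_mm) & (mid <= params.midpoint_threshold_mm)
            for i in range(len(blk)):
                close[i, start + i] = False
            unique[start:start + 1000] = ~close.any(axis=1)
    kept = [s for s, u in zip(streamlines, unique) if not u]
    excluded = [s for s, u in zip(streamlines, unique) if u]
    return kept, excluded, ~unique
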