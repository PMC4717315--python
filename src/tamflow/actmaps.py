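"""Active-fiber density maps and responder/non-responder comparison.

Heat maps count, on a 1 mm isotropic grid, the number of active fibers
whose trajectory passes through each voxel (exact segment-voxel
traversal, each fiber counted at most once per voxel).  Region counts
tally fibers entering each labeled gray-matter structure; a fiber may
count for several regions.  The responder comparison marks, for every
(responder, non-responder) pairing, the voxels where the responder's
active-fiber density exceeds the non-responder's by at least a
threshold (20 fibers per voxel), and correlates each responder's total
advantage-voxel count with their clinical improvement.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import AffineTransform, LabelVolume, world_to_voxel

__all__ = ["HeatMap", "RegionCounts", "ComparisonResult", "heat_map",
           "region_counts", "combine_maps", "compare_responders",
           "traversed_voxels", "make_grid", "render_heat_map"]


@dataclass
class HeatMap:
    counts: np.ndarray  # non-negative ints
    affine: AffineTransform
    n_total_fibers: int = 0
    n_active_fibers: int = 0

    def __post_init__(self):
        if not isinstance(self.affine, AffineTransform):
            self.affine = AffineTransform(self.affine)
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("heat-map counts must be >= 0")
        if self.n_active_fibers > self.n_total_fibers:
            raise ValueError("active fibers cannot exceed total fibers")

    def percentage(self) -> np.ndarray:
        if self.n_total_fibers == 0:
            return np.zeros_like(self.counts, dtype=float)
        return 100.0 * self.counts / self.n_total_fibers


@dataclass
class RegionCounts:
    active: dict  # label -> active-fiber count
    total: dict  # label -> total-fiber count
    label_names: dict = field(default_factory=dict)

    def __post_init__(self):
        for l, a in self.active.items():
            if a > self.total.get(l, 0):
                raise ValueError(f"active > total for label {l}")

    def as_frame(self):
        import pandas as pd

        labels = sorted(self.total)
        return pd.DataFrame({
            "label": labels,
            "name": [self.label_names.get(l, str(l)) for l in labels],
            "active_fibers": [self.active.get(l, 0) for l in labels],
            "total_fibers": [self.total[l] for l in labels],
        })


@dataclass
class ComparisonResult:
    marked_voxels: dict  # (responder_id, nonresponder_id) -> voxel index set
    advantage_sum: dict  # responder_id -> total marked voxels over pairings
    correlation: float | None
    correlation_method: str = "pearson"
    n_pairings: int = 0


def make_grid(extent_min_mm, extent_max_mm, voxel_mm: float = 1.0) -> tuple:
    """(affine, shape) of a voxel grid covering the world-mm box."""
    lo = np.asarray(extent_min_mm, dtype=float)
    hi = np.asarray(extent_max_mm, dtype=float)
    shape = tuple(int(np.ceil((h - l) / voxel_mm)) + 1 for l, h in zip(lo, hi))
    aff = np.eye(4)
    aff[:3, :3] *= voxel_mm
    aff[:3, 3] = lo
    return AffineTransform(aff), shape


def traversed_voxels(points_mm: np.ndarray, affine: AffineTransform,
                     shape: tuple) -> set:
    """All voxels a polyline passes through (Amanatides-Woo traversal of
    every segment against the voxel-boundary planes; voxel-center
    convention means boundaries sit at half-integer voxel coordinates)."""
    vox = np.atleast_2d(world_to_voxel(points_mm, affine))
    shape = np.asarray(shape)
    out: set = set()
    if len(vox) == 0:
        return out

    def clamp_ok(iv):
        return np.all(iv >= 0) and np.all(iv < shape)

    iv = np.round(vox[0]).astype(int)
    if clamp_ok(iv):
        out.add(tuple(int(x) for x in iv))
    for a, b in zip(vox[:-1], vox[1:]):
        d = b - a
        ia = np.round(a).astype(int)
        ib = np.round(b).astype(int)
        if np.all(ia == ib):
            if clamp_ok(ib):
                out.add(tuple(int(x) for x in ib))
            continue
        # boundary crossings per axis between the two endpoints
        ts = [0.0, 1.0]
        for ax in range(3):
            if d[ax] == 0:
                continue
            lo_b, hi_b = sorted((a[ax], b[ax]))
            first = np.floor(lo_b - 0.5) + 1.5  # first half-integer above lo
            for bd in np.arange(first, hi_b, 1.0):
                ts.append((bd - a[ax]) / d[ax])
        ts = np.unique(np.clip(ts, 0.0, 1.0))
        mids = (ts[:-1] + ts[1:]) / 2.0
        for t in mids:
            p = a + t * d
            ip = np.round(p).astype(int)
            if clamp_ok(ip):
                out.add(tuple(int(x) for x in ip))
    return out


def heat_map(active_streamlines, affine: AffineTransform, shape: tuple,
             n_total_fibers: int | None = None) -> HeatMap:
    """Count active fibers per voxel; a fiber increments each traversed
    voxel at most once."""
    counts = np.zeros(shape, dtype=np.int32)
    n_active = 0
    for s in active_streamlines:
        pts = getattr(s, "points", s)
        for v in traversed_voxels(np.asarray(pts, dtype=float), affine, shape):
            counts[v] += 1
        n_active += 1
    total = n_active if n_total_fibers is None else n_total_fibers
    return HeatMap(counts, affine, n_total_fibers=total, n_active_fibers=n_active)


def region_counts(streamlines, labels: LabelVolume,
                  active_flags=None) -> RegionCounts:
    """Per-label fiber tallies by trajectory traversal.

    ``active_flags``: optional boolean per streamline; when omitted all
    streamlines count as active.  A fiber counts for region r iff any
    traversed voxel carries label r (it may count for several regions).
    """
    streamlines = list(streamlines)
    if active_flags is None:
        active_flags = [True] * len(streamlines)
    present = sorted(set(np.unique(labels.data)) - {0})
    active = {l: 0 for l in present}
    total = {l: 0 for l in present}
    for s, is_active in zip(streamlines, active_flags):
        pts = getattr(s, "points", s)
        vox = traversed_voxels(np.asarray(pts, dtype=float), labels.affine,
                               labels.shape)
        hit = {int(labels.data[v]) for v in vox} - {0}
        for l in hit:
            total[l] += 1
            if is_active:
                active[l] += 1
    return RegionCounts(active, total, dict(labels.label_names))


def combine_maps(maps: list) -> HeatMap:
    """Voxelwise sum of heat maps on one grid; totals are summed."""
    if not maps:
        raise ValueError("no maps to combine")
    ref = maps[0]
    for m in maps[1:]:
        if m.counts.shape != ref.counts.shape or not np.allclose(
                m.affine.matrix, ref.affine.matrix):
            raise ValueError("heat-map grid/affine mismatch")
    return HeatMap(sum(np.asarray(m.counts, dtype=np.int64) for m in maps),
                   ref.affine,
                   n_total_fibers=sum(m.n_total_fibers for m in maps),
                   n_active_fibers=sum(m.n_active_fibers for m in maps))


def compare_responders(responder_maps: dict, nonresponder_maps: dict,
                       improvements_pct: dict, diff_threshold: float = 20.0,
                       method: str = "pearson") -> ComparisonResult:
    """Voxelwise responder-advantage analysis.

    For each (responder, non-responder) pairing, voxels where
    responder - non-responder >= diff_threshold are marked.  Each
    responder's advantage_sum (marked voxels summed over its pairings)
    is correlated with their percent improvement (Pearson by default,
    Spearman by config); with fewer than 2 responders the correlation
    is undefined and reported as None.
    """
    from scipy import stats as sps

    marked = {}
    advantage = {r: 0 for r in responder_maps}
    for r_id, rmap in responder_maps.items():
        for n_id, nmap in nonresponder_maps.items():
            if rmap.counts.shape != nmap.counts.shape:
                raise ValueError("maps must share one grid")
            diff = rmap.counts.astype(np.int64) - nmap.counts.astype(np.int64)
            vox = np.argwhere(diff >= diff_threshold)
            marked[(r_id, n_id)] = {tuple(int(x) for x in v) for v in vox}
            advantage[r_id] += len(vox)

    corr = None
    if len(responder_maps) >= 2:
        r_ids = sorted(responder_maps)
        x = np.array([advantage[r] for r in r_ids], dtype=float)
        y = np.array([improvements_pct[r] for r in r_ids], dtype=float)
        if np.std(x) > 0 and np.std(y) > 0:
            if method == "pearson":
                corr = float(sps.pearsonr(x, y).statistic)
            elif method == "spearman":
                corr = float(sps.spearmanr(x, y).statistic)
            else:
                raise ValueError(f"unknown correlation method {method}")
    return ComparisonResult(marked, advantage, corr, method,
                            n_pairings=len(responder_maps) * len(nonresponder_maps))


def render_heat_map(hmap: HeatMap, axis: int = 2, index: int | None = None,
                    ax=None, cmap: str = "hot"):
    """Figure-style brightness rendering of one slice (opacity ~ count)."""
    import matplotlib.pyplot as plt

    if index is None:
        index = hmap.counts.shape[axis] // 2
    sl = [slice(None)] * 3
    sl[axis] = index
    img = hmap.counts[tuple(sl)]
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(img.T, origin="lower", cmap=cmap,
                   alpha=np.clip(img.T / max(img.max(), 1), 0.15, 1.0))
    ax.set_title(f"active fibers, slice {index} (n={hmap.n_active_fibers})")
    return ax
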