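"""Probabilistic streamline tractography from seed regions.

Orientation estimation is a declared, simplified stand-in for full
Bayesian fiber fitting: direction 1 is the tensor's principal
eigenvector, a second direction (the second eigenvector) is emitted
where the tensor's planarity coefficient indicates a crossing, and the
angular dispersion of the sampling cone is a monotone decreasing
function of fractional anisotropy.  Externally computed orientation
fields can be supplied through the same container.

Propagation uses Euler steps of 0.5 mm along a direction sampled in a
cone (Gaussian tangent-plane perturbation of the voxel direction best
aligned with the incoming heading).  A pathway terminates on CSF entry,
a step-to-step turn above the +/-80 degree curvature threshold, a loop
(re-entering a visited voxel with a similar heading), grid exit, an
isotropic voxel, or after 2000 steps.  Tracking is bidirectional from
the seed and the two halves are concatenated into one polyline with the
seed recorded as an interior index.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import AffineTransform, TensorVolume, world_to_voxel, voxel_to_world

__all__ = [
    "TrackingParams",
    "OrientationField",
    "Streamline",
    "StreamlineBundle",
    "estimate_orientations",
    "propagate_streamline",
    "track_seed_region",
    "classify_seed_voxels",
]

TERMINATION_REASONS = {"csf", "loop", "max_steps", "curvature", "boundary", "isotropic"}


@dataclass(frozen=True)
class TrackingParams:
    n_streamlines_per_voxel: int = 1000
    step_mm: float = 0.5
    curvature_threshold_deg: float = 80.0
    max_steps: int = 2000

    def __post_init__(self):
        if min(self.n_streamlines_per_voxel, self.step_mm, self.max_steps) <= 0:
            raise ValueError("tracking parameters must be positive")
        if not (0 < self.curvature_threshold_deg < 180):
            raise ValueError("curvature threshold must be in (0, 180) degrees")


@dataclass
class OrientationField:
    """Up to two unit fiber directions per voxel with weights and a
    per-voxel angular dispersion (degrees)."""

    directions: np.ndarray  # (nx, ny, nz, 2, 3)
    weights: np.ndarray  # (nx, ny, nz, 2), >= 0, sum <= 1
    dispersion_deg: np.ndarray  # (nx, ny, nz)
    isotropic: np.ndarray  # (nx, ny, nz) bool: no usable direction
    affine: AffineTransform

    def __post_init__(self):
        if not isinstance(self.affine, AffineTransform):
            self.affine = AffineTransform(self.affine)
        norms = np.linalg.norm(self.directions, axis=-1)
        usable = self.weights > 0
        if not np.allclose(norms[usable], 1.0, atol=1e-6):
            raise ValueError("weighted directions must be unit-norm")
        if (self.weights < 0).any() or (self.weights.sum(-1) > 1 + 1e-9).any():
            raise ValueError("weights must be >= 0 and sum to <= 1")

    @property
    def shape(self):
        return self.isotropic.shape


def estimate_orientations(tensors: TensorVolume, dispersion_max_deg: float = 30.0,
                          dispersion_min_deg: float = 2.0,
                          planarity_threshold: float = 0.2,
                          fa_isotropic_threshold: float = 0.05) -> OrientationField:
    """Simplified per-voxel fiber orientation estimator.

    Direction 1 is the principal eigenvector.  A second direction (the
    second eigenvector) is emitted where the planarity coefficient
    CP = 2 (l2 - l3) / (l1 + l2 + l3) exceeds ``planarity_threshold``,
    i.e. where a tensor blend of two crossing bundles flattens the
    ellipsoid.  Dispersion decreases linearly with FA from
    ``dispersion_max_deg`` (FA 0) to ``dispersion_min_deg``; voxels
    with FA below ``fa_isotropic_threshold`` or a degenerate tensor are
    flagged isotropic and terminate tracking.
    """
    evals, evecs = tensors.principal_directions()
    fa = tensors.fractional_anisotropy()
    tr = evals.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cp = np.where(tr > 0, 2.0 * (evals[..., 1] - evals[..., 2]) / tr, 0.0)
    iso = (fa < fa_isotropic_threshold) | (tr <= 0)

    dirs = np.zeros(tensors.shape + (2, 3))
    weights = np.zeros(tensors.shape + (2,))
    dirs[..., 0, :] = evecs[..., :, 0]
    weights[..., 0] = np.where(iso, 0.0, 1.0)
    second = (~iso) & (cp > planarity_threshold)
    dirs[..., 1, :] = np.where(second[..., None], evecs[..., :, 1], 0.0)
    weights[..., 1] = np.where(second, 0.4, 0.0)
    weights[..., 0] = np.where(second, 0.6, weights[..., 0])

    disp = np.clip(dispersion_max_deg * (1.0 - fa),
                   dispersion_min_deg, dispersion_max_deg)
    # renormalize stored second directions to unit norm (zeros stay zero)
    n2 = np.linalg.norm(dirs[..., 1, :], axis=-1, keepdims=True)
    dirs[..., 1, :] = np.where(n2 > 0, dirs[..., 1, :] / np.where(n2 > 0, n2, 1.0), 0.0)
    return OrientationField(dirs, weights, disp, iso, tensors.affine)


@dataclass
class Streamline:
    points: np.ndarray  # (n, 3) world mm, consecutive spacing = step_mm
    seed_voxel: tuple
    termination_reason: str  # forward-side reason
    termination_reason_backward: str = "boundary"
    seed_index: int = 0  # index of the seed-side point within ``points``

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.termination_reason not in TERMINATION_REASONS:
            raise ValueError(f"unknown termination reason {self.termination_reason}")

    def __len__(self):
        return len(self.points)

    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class StreamlineBundle:
    streamlines: list
    hemisphere: str = ""
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def save_trk(self, path, reference_affine: np.ndarray, shape: tuple) -> None:
        import nibabel.streamlines as nibs

        trac = nibs.Tractogram([s.points for s in self.streamlines],
                               affine_to_rasmm=np.eye(4))
        header = {"voxel_to_rasmm": np.asarray(reference_affine, dtype=np.float32),
                  "dimensions": np.asarray(shape, dtype=np.int16),
                  "voxel_sizes": np.linalg.norm(np.asarray(reference_affine)[:3, :3],
                                                axis=0).astype(np.float32)}
        nibs.save(nibs.trk.TrkFile(trac, header), str(path))

    def save_tck(self, path) -> None:
        import nibabel.streamlines as nibs

        trac = nibs.Tractogram([s.points for s in self.streamlines],
                               affine_to_rasmm=np.eye(4))
        nibs.save(nibs.tck.TckFile(trac), str(path))

    def sidecar_table(self, kept_mask=None, active_flags=None):
        """Per-streamline metadata as a DataFrame (CSV/Parquet-ready)."""
        import pandas as pd

        rows = []
        for i, s in enumerate(self.streamlines):
            rows.append({
                "index": i,
                "seed_i": s.seed_voxel[0], "seed_j": s.seed_voxel[1],
                "seed_k": s.seed_voxel[2],
                "n_points": len(s.points),
                "arc_length_mm": s.arc_length(),
                "termination_forward": s.termination_reason,
                "termination_backward": s.termination_reason_backward,
            })
        df = pd.DataFrame(rows)
        if kept_mask is not None:
            df["kept"] = np.asarray(kept_mask, dtype=bool)
        if active_flags is not None:
            df["active"] = np.asarray(active_flags, dtype=bool)
        return df


class _BatchTracker:
    """Lock-step Euler propagation of a batch of streamline halves."""

    def __init__(self, field: OrientationField, params: TrackingParams,
                 csf_mask: np.ndarray | None, rng: np.random.Generator):
        self.field = field
        self.params = params
        self.csf = csf_mask
        self.rng = rng
        self.inv = field.affine.inverse().matrix
        self.shape = np.asarray(field.shape)
        self.cos_thresh = np.cos(np.deg2rad(params.curvature_threshold_deg))

    def _voxel_of(self, pos: np.ndarray) -> np.ndarray:
        vox = pos @ self.inv[:3, :3].T + self.inv[:3, 3]
        return np.round(vox).astype(int)

    def run(self, seeds: np.ndarray, headings: np.ndarray):
        """Returns (list of point arrays excluding the seed, reasons)."""
        n = len(seeds)
        pos = seeds.astype(float).copy()
        heading = headings.astype(float).copy()
        active = np.ones(n, dtype=bool)
        reasons = np.array(["max_steps"] * n, dtype=object)
        paths = [[] for _ in range(n)]
        visited = [dict() for _ in range(n)]
        cur_voxel = np.full((n, 3), -(10**6), dtype=int)
        disp_rad_all = np.deg2rad(self.field.dispersion_deg)

        for _ in range(self.params.max_steps):
            if not active.any():
                break
            idx = np.flatnonzero(active)
            vox = self._voxel_of(pos[idx])
            inb = np.all((vox >= 0) & (vox < self.shape), axis=1)
            for i, ok in zip(idx[~inb], [None] * int((~inb).sum())):
                reasons[i] = "boundary"
                active[i] = False
            idx = idx[inb]
            vox = vox[inb]
            if len(idx) == 0:
                continue
            vt = tuple(vox.T)
            if self.csf is not None:
                in_csf = self.csf[vt].astype(bool)
                for i in idx[in_csf]:
                    reasons[i] = "csf"
                    active[i] = False
                keep = ~in_csf
                idx, vox = idx[keep], vox[keep]
                vt = tuple(vox.T)
                if len(idx) == 0:
                    continue
            iso = self.field.isotropic[vt]
            for i in idx[iso]:
                reasons[i] = "isotropic"
                active[i] = False
            keep = ~iso
            idx, vox = idx[keep], vox[keep]
            vt = tuple(vox.T)
            if len(idx) == 0:
                continue

            # loop detection on voxel change
            changed = np.any(vox != cur_voxel[idx], axis=1)
            drop = []
            for j, i in enumerate(idx):
                if not changed[j]:
                    continue
                key = (int(vox[j, 0]), int(vox[j, 1]), int(vox[j, 2]))
                prev = visited[i].get(key)
                h = heading[i]
                if prev is not None and float(prev @ h) > 0.0:  # within 90 deg
                    reasons[i] = "loop"
                    active[i] = False
                    drop.append(j)
                else:
                    visited[i][key] = h.copy()
                    cur_voxel[i] = vox[j]
            if drop:
                keep = np.ones(len(idx), dtype=bool)
                keep[drop] = False
                idx, vox = idx[keep], vox[keep]
                vt = tuple(vox.T)
                if len(idx) == 0:
                    continue

            dirs = self.field.directions[vt]  # (m, 2, 3)
            wts = self.field.weights[vt]
            h = heading[idx]
            cosines = np.einsum("mkd,md->mk", dirs, h)
            cosines = np.where(wts > 0, np.abs(cosines), -np.inf)
            best = np.argmax(cosines, axis=1)
            d = dirs[np.arange(len(idx)), best]
            sign = np.sign(np.einsum("md,md->m", d, h))
            sign[sign == 0] = 1.0
            d = d * sign[:, None]

            disp = disp_rad_all[vt]
            if (disp > 0).any():
                noise = self.rng.normal(0.0, 1.0, (len(idx), 3)) * disp[:, None]
                noise -= d * np.einsum("md,md->m", noise, d)[:, None]
                d = d + noise
                d /= np.linalg.norm(d, axis=1, keepdims=True)

            turn = np.einsum("md,md->m", d, h)
            too_sharp = turn < self.cos_thresh
            for i in idx[too_sharp]:
                reasons[i] = "curvature"
                active[i] = False
            keep = ~too_sharp
            idx, d = idx[keep], d[keep]
            if len(idx) == 0:
                continue

            pos[idx] = pos[idx] + self.params.step_mm * d
            heading[idx] = d
            for j, i in enumerate(idx):
                paths[i].append(pos[i].copy())

        return [np.asarray(p).reshape(-1, 3) for p in paths], reasons


def _initial_direction(field: OrientationField, seed_voxel: tuple,
                       rng: np.random.Generator) -> np.ndarray | None:
    w = field.weights[seed_voxel]
    if w.sum() <= 0:
        return None
    k = int(rng.uniform() < (w[1] / w.sum())) if w[1] > 0 else 0
    return field.directions[seed_voxel][k]


def propagate_streamline(field: OrientationField, seed_point_mm: np.ndarray,
                         params: TrackingParams = TrackingParams(),
                         csf_mask: np.ndarray | None = None,
                         rng: np.random.Generator | None = None) -> Streamline:
    """Bidirectional Euler propagation of one streamline from a seed point."""
    rng = rng or np.random.default_rng(0)
    seed_point_mm = np.asarray(seed_point_mm, dtype=float)
    vox = np.round(world_to_voxel(seed_point_mm, field.affine)).astype(int)
    shape = np.asarray(field.shape)
    if ((vox < 0) | (vox >= shape)).any():
        raise ValueError("seed outside grid")
    voxt = tuple(int(v) for v in vox)
    if csf_mask is not None and bool(csf_mask[voxt]):
        return Streamline(seed_point_mm[None, :], voxt, "csf", "csf")
    d0 = _initial_direction(field, voxt, rng)
    if d0 is None:
        return Streamline(seed_point_mm[None, :], voxt, "isotropic", "isotropic")
    tracker = _BatchTracker(field, params, csf_mask, rng)
    halves, reasons = tracker.run(np.stack([seed_point_mm, seed_point_mm]),
                                  np.stack([d0, -d0]))
    fwd, bwd = halves
    pts = np.vstack([bwd[::-1], seed_point_mm[None, :], fwd])
    return Streamline(pts, voxt, str(reasons[0]), str(reasons[1]),
                      seed_index=len(bwd))


def track_seed_region(field: OrientationField, seed_region,
                      params: TrackingParams = TrackingParams(),
                      csf_mask: np.ndarray | None = None,
                      rng_seed: int = 0, hemisphere: str = "") -> StreamlineBundle:
    """n_streamlines_per_voxel streamlines per seed voxel, reproducibly."""
    seed_voxels = sorted(tuple(int(x) for x in v) for v in seed_region)
    if not seed_voxels:
        raise ValueError("seed region is empty")
    rng = np.random.default_rng(rng_seed)
    n_per = params.n_streamlines_per_voxel
    seeds, d0s, metas = [], [], []
    degenerate = []
    for v in seed_voxels:
        center = voxel_to_world(np.asarray(v, dtype=float), field.affine)
        for _ in range(n_per):
            if csf_mask is not None and bool(csf_mask[v]):
                degenerate.append(Streamline(center[None, :], v, "csf", "csf"))
                continue
            d0 = _initial_direction(field, v, rng)
            if d0 is None:
                degenerate.append(Streamline(center[None, :], v, "isotropic", "isotropic"))
                continue
            seeds.append(center)
            d0s.append(d0)
            metas.append(v)
    streamlines = list(degenerate)
    if seeds:
        tracker = _BatchTracker(field, params, csf_mask, rng)
        n = len(seeds)
        both_seeds = np.vstack([np.asarray(seeds), np.asarray(seeds)])
        both_dirs = np.vstack([np.asarray(d0s), -np.asarray(d0s)])
        halves, reasons = tracker.run(both_seeds, both_dirs)
        for i in range(n):
            fwd, bwd = halves[i], halves[n + i]
            pts = np.vstack([bwd[::-1], np.asarray(seeds[i])[None, :], fwd])
            streamlines.append(Streamline(pts, metas[i], str(reasons[i]),
                                          str(reasons[n + i]), seed_index=len(bwd)))
    return StreamlineBundle(streamlines, hemisphere=hemisphere,
                            provenance={"params": params, "rng_seed": rng_seed,
                                        "n_seed_voxels": len(seed_voxels)})


def classify_seed_voxels(field: OrientationField, seed_region,
                         target_masks: dict,
                         params: TrackingParams = TrackingParams(),
                         csf_mask: np.ndarray | None = None, rng_seed: int = 0):
    """Connectivity-based parcellation of the seed region.

    ``target_masks``: label -> boolean voxel mask.  For each seed voxel,
    counts streamlines whose trajectory enters each target; predominant
    target is the argmax, ties broken by the lowest label id and flagged.
    Returns dict voxel -> {"counts": {label: n}, "predominant": label,
    "tie": bool}.
    """
    if not target_masks:
        raise ValueError("need at least one target mask")
    bundle = track_seed_region(field, seed_region, params, csf_mask, rng_seed)
    inv = field.affine.inverse().matrix
    shape = np.asarray(field.shape)
    labels = sorted(target_masks)
    result = {}
    for v in sorted(tuple(int(x) for x in w) for w in seed_region):
        result[v] = {"counts": {l: 0 for l in labels}, "predominant": None,
                     "tie": False}
    for s in bundle:
        vox = np.round(s.points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        vox = vox[ok]
        vt = tuple(vox.T)
        rec = result[s.seed_voxel]
        for l in labels:
            if target_masks[l][vt].any():
                rec["counts"][l] += 1
    for v, rec in result.items():
        counts = rec["counts"]
        top = max(counts.values())
        if top > 0:
            winners = [l for l in labels if counts[l] == top]
            rec["predominant"] = winners[0]
            rec["tie"] = len(winners) > 1
    return result
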