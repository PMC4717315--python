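"""Model 3391 DBS lead geometry, contact placement and seed regions.

The 3391 lead carries four 3 mm contacts separated by 4 mm edge-to-edge
gaps on a 1.27 mm shaft, so consecutive contact centers are 7 mm apart.
Tractography seed regions are built as 4 mm spheres of voxels around the
active cathode contact centers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import AffineTransform, world_to_voxel

__all__ = [
    "ElectrodeSpec",
    "ElectrodePlacement",
    "StimulationSetting",
    "contact_centers",
    "build_seed_region",
]


@dataclass(frozen=True)
class ElectrodeSpec:
    lead_diameter_mm: float = 1.27
    contact_length_mm: float = 3.0
    intercontact_gap_mm: float = 4.0  # edge-to-edge
    n_contacts: int = 4
    tip_to_first_contact_mm: float = 1.5

    def __post_init__(self):
        for name in ("lead_diameter_mm", "contact_length_mm",
                     "intercontact_gap_mm", "tip_to_first_contact_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def center_spacing_mm(self) -> float:
        return self.contact_length_mm + self.intercontact_gap_mm

    def contact_span_mm(self, k: int) -> tuple:
        """Axial (start, end) of contact k, measured from the tip."""
        start = self.tip_to_first_contact_mm + k * self.center_spacing_mm
        return start, start + self.contact_length_mm


@dataclass(frozen=True)
class ElectrodePlacement:
    tip_mm: np.ndarray
    direction: np.ndarray  # unit vector, tip -> proximal
    patient_id: str = ""
    hemisphere: str = "right"

    def __post_init__(self):
        tip = np.asarray(self.tip_mm, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit-norm, |d| = {n}")
        object.__setattr__(self, "tip_mm", tip)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class StimulationSetting:
    cathodes: frozenset
    anodes: object  # frozenset of contact indices, or "CASE" (monopolar)
    amplitude_V: float
    frequency_Hz: float
    pulse_width_us: float
    impedance_ohm: float

    def __post_init__(self):
        object.__setattr__(self, "cathodes", frozenset(self.cathodes))
        if not self.cathodes:
            raise ValueError("cathodes must be nonempty")
        if self.anodes != "CASE":
            object.__setattr__(self, "anodes", frozenset(self.anodes))
            if self.cathodes & self.anodes:
                raise ValueError("cathodes and anodes must be disjoint")
        if self.amplitude_V <= 0:
            raise ValueError("amplitude_V must be > 0")
        if not (100.0 <= self.impedance_ohm <= 4000.0):
            raise ValueError(f"impedance {self.impedance_ohm} outside 100-4000 ohm")

    @property
    def is_bipolar(self) -> bool:
        return self.anodes != "CASE" and len(self.anodes) > 0


def contact_centers(placement: ElectrodePlacement, spec: ElectrodeSpec = ElectrodeSpec()) -> np.ndarray:
    """Ordered world-mm centers of all contacts (index 0 = most distal)."""
    k = np.arange(spec.n_contacts)
    offsets = (spec.tip_to_first_contact_mm + spec.contact_length_mm / 2.0
               + k * spec.center_spacing_mm)
    return placement.tip_mm[None, :] + offsets[:, None] * placement.direction[None, :]


def build_seed_region(active_centers: np.ndarray, affine: AffineTransform | np.ndarray,
                      grid_shape: tuple, radius_mm: float = 4.0) -> set:
    """Voxel indices whose centers lie within ``radius_mm`` of any center.

    Membership uses the voxel-center Euclidean distance with a <=
    comparison.  A center outside the grid bounding box is an error.
    """
    centers = np.atleast_2d(np.asarray(active_centers, dtype=float))
    if len(centers) == 0:
        raise ValueError("need at least one active contact center")
    if not isinstance(affine, AffineTransform):
        affine = AffineTransform(affine)
    shape = np.asarray(grid_shape)
    vox = np.atleast_2d(world_to_voxel(centers, affine))
    if ((vox < -0.5) | (vox > shape - 0.5)).any():
        raise ValueError("active contact center outside the grid bounding box")

    voxels: set = set()
    inv_scale = np.linalg.norm(affine.matrix[:3, :3], axis=0)
    for c, v in zip(centers, vox):
        # candidate index window around the center
        halo = np.ceil(radius_mm / inv_scale).astype(int) + 1
        lo = np.maximum(np.round(v).astype(int) - halo, 0)
        hi = np.minimum(np.round(v).astype(int) + halo, shape - 1)
        ii, jj, kk = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)],
                                 indexing="ij")
        idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        world = affine.apply(idx.astype(float))
        d = np.linalg.norm(world - c, axis=1)
        for t in idx[d <= radius_mm]:
            voxels.add(tuple(int(x) for x in t))
    return voxels
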