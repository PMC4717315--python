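"""Synthetic phantoms and patient cohorts with known ground truth.

A phantom is a voxel grid carrying diffusion tensors, gray-matter target
labels and a CSF mask, built from a small number of fiber *bundles*:
tubes around polyline centerlines whose in-tube tensors point along the
local tangent.  A synthetic cohort places DBS electrodes near the bundle
hub with per-patient jitter and draws a clinical outcome (percent YBOCS
reduction) from a linear model in the ground-truth bundle-activation
fractions, so every downstream stage of the pipeline can be tested
against a generating truth that is known exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .volumes import AffineTransform, LabelVolume, ScalarVolume, TensorVolume

__all__ = [
    "SphereSpec",
    "BoxSpec",
    "BundleSpec",
    "PhantomConfig",
    "PatientRecord",
    "SyntheticCohort",
    "OutcomeParams",
    "generate_phantom",
    "generate_cohort",
    "ground_truth_fractions",
    "activation_matrix",
    "default_phantom_config",
]


@dataclass(frozen=True)
class SphereSpec:
    center_mm: tuple
    radius_mm: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(points - np.asarray(self.center_mm), axis=-1)
        return d <= self.radius_mm


@dataclass(frozen=True)
class BoxSpec:
    min_mm: tuple
    max_mm: tuple

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo = np.all(points >= np.asarray(self.min_mm), axis=-1)
        hi = np.all(points <= np.asarray(self.max_mm), axis=-1)
        return lo & hi


@dataclass(frozen=True)
class BundleSpec:
    """A fiber bundle: a tube of given radius around a polyline centerline."""

    centerline_mm: np.ndarray
    radius_mm: float
    target_label: int

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.centerline_mm, dtype=float))
        if pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValueError("centerline needs >= 2 control points of 3 coordinates")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        object.__setattr__(self, "centerline_mm", pts)

    def resample(self, step_mm: float):
        """Dense arc-length resampling; returns (points, unit tangents)."""
        pts = self.centerline_mm
        seg = np.diff(pts, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        total = cum[-1]
        if total <= 0:
            raise ValueError("degenerate centerline")
        s = np.linspace(0.0, total, max(int(np.ceil(total / step_mm)) + 1, 2))
        dense = np.empty((len(s), 3))
        for d in range(3):
            dense[:, d] = np.interp(s, cum, pts[:, d])
        tang = np.gradient(dense, s, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        return dense, tang


@dataclass
class PhantomConfig:
    grid_shape: tuple = (64, 64, 64)
    voxel_size_mm: float = 2.0
    bundles: list = field(default_factory=list)
    csf_regions: list = field(default_factory=list)
    target_labels: dict = field(default_factory=dict)
    target_radius_mm: float = 7.0
    background_fa: float = 0.10
    bundle_fa: float = 0.75
    mean_diffusivity: float = 0.7e-3  # mm^2/s, typical white matter
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.background_fa < 1):
            raise ValueError("background_fa must be in [0, 1)")
        if not (self.background_fa < self.bundle_fa < 1):
            raise ValueError("bundle_fa must be in (background_fa, 1)")
        labels = [b.target_label for b in self.bundles]
        if any(l <= 0 for l in labels):
            raise ValueError("label ids must be positive")
        missing = set(labels) - set(self.target_labels)
        if missing:
            raise ValueError(f"bundle target labels without names: {sorted(missing)}")

    @property
    def affine(self) -> AffineTransform:
        return AffineTransform.scaling(self.voxel_size_mm)

    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) * self.voxel_size_mm

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["bundles"] = [
            {
                "centerline_mm": b.centerline_mm.tolist(),
                "radius_mm": b.radius_mm,
                "target_label": b.target_label,
            }
            for b in self.bundles
        ]
        d["csf_regions"] = [
            {"kind": type(r).__name__, **{k: list(v) if isinstance(v, tuple) else v
                                          for k, v in asdict(r).items()}}
            for r in self.csf_regions
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["bundles"] = [BundleSpec(np.asarray(b["centerline_mm"]), b["radius_mm"],
                                   b["target_label"]) for b in d["bundles"]]
        regions = []
        for r in d.get("csf_regions", []):
            kind = r.pop("kind")
            regions.append(SphereSpec(**{k: tuple(v) if isinstance(v, list) else v
                                         for k, v in r.items()})
                           if kind == "SphereSpec" else BoxSpec(**r))
        d["csf_regions"] = regions
        d["grid_shape"] = tuple(d["grid_shape"])
        d["target_labels"] = {int(k): v for k, v in d["target_labels"].items()}
        return cls(**d)


def _axial_tensor(direction: np.ndarray, fa: float, md: float) -> np.ndarray:
    """Axially symmetric tensor with given FA, mean diffusivity and axis.

    For eigenvalues m(1+2*delta), m(1-delta), m(1-delta) one has
    FA = 3*delta / sqrt(3 + 6*delta^2), inverted in closed form.
    """
    if fa == 0:
        return md * np.eye(3)
    delta = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    lam_par = md * (1 + 2 * delta)
    lam_perp = md * (1 - delta)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    outer = d[..., :, None] * d[..., None, :]
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * outer


def generate_phantom(config: PhantomConfig):
    """Build (TensorVolume, LabelVolume, csf_mask) from a phantom config.

    In-tube voxels carry an axially symmetric tensor whose principal
    eigenvector is the local centerline tangent at the phantom's
    ``bundle_fa``; background voxels carry ``background_fa`` about
    seeded random axes (exactly isotropic when background_fa = 0).
    Overlapping tubes are blended by an FA-weighted tensor sum,
    renormalized to the configured mean diffusivity, which keeps the
    blend positive definite and produces genuine two-direction voxels.
    """
    rng = np.random.default_rng(config.rng_seed)
    affine = config.affine
    shape = tuple(config.grid_shape)
    centers = ScalarVolume(np.zeros(shape), affine).voxel_centers().reshape(-1, 3)
    md = config.mean_diffusivity

    # Background: mildly anisotropic about random axes (FA=0 -> isotropic).
    if config.background_fa > 0:
        axes = rng.normal(size=(len(centers), 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        tensors = _axial_tensor(axes, config.background_fa, md)
    else:
        tensors = np.broadcast_to(md * np.eye(3), (len(centers), 3, 3)).copy()

    labels = np.zeros(shape, dtype=np.int32)
    extent = config.extent_mm()
    accum = np.zeros_like(tensors)
    weight = np.zeros(len(centers))

    for bundle in config.bundles:
        if (bundle.centerline_mm < -1e-9).any() or (bundle.centerline_mm > extent + 1e-9).any():
            raise ValueError("bundle centerline exits the phantom grid")
        dense, tang = bundle.resample(step_mm=config.voxel_size_mm / 2.0)
        tree = cKDTree(dense)
        dist, idx = tree.query(centers)
        inside = dist <= bundle.radius_mm
        t = tang[idx[inside]]
        accum[inside] += config.bundle_fa * _axial_tensor(t, config.bundle_fa, md)
        weight[inside] += config.bundle_fa
        # distal target region: sphere at the far end of the centerline
        target = SphereSpec(tuple(dense[-1]), config.target_radius_mm)
        labels.reshape(-1)[target.contains(centers)] = bundle.target_label

    in_any = weight > 0
    if in_any.any():
        blended = accum[in_any] / weight[in_any, None, None]
        tr = np.trace(blended, axis1=-2, axis2=-1)
        blended *= (3.0 * md / tr)[:, None, None]
        tensors[in_any] = blended

    csf = np.zeros(len(centers), dtype=bool)
    for region in config.csf_regions:
        csf |= region.contains(centers)

    tensor_vol = TensorVolume(tensors.reshape(*shape, 3, 3), affine)
    label_vol = LabelVolume(labels, affine, dict(config.target_labels))
    csf_vol = ScalarVolume(csf.reshape(shape).astype(np.uint8), affine)
    return tensor_vol, label_vol, csf_vol


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class OutcomeParams:
    """Linear outcome model: improvement rises with target-bundle activation
    and falls with off-target activation."""

    beta0: float = 10.0
    beta_target: float = 40.0
    beta_offtarget: float = 40.0
    noise_sd: float = 6.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PatientRecord:
    patient_id: str
    placements: dict  # hemisphere -> ElectrodePlacement
    settings: dict  # hemisphere -> StimulationSetting
    ybocs_change_pct: float
    true_fractions: dict  # bundle label -> ground-truth activated fraction


@dataclass
class SyntheticCohort:
    patients: list
    outcome_params: OutcomeParams
    target_label: int = 1
    offtarget_label: int = 2

    def to_json(self, path) -> None:
        from dataclasses import asdict as dc_asdict

        def enc(p: PatientRecord):
            d = dc_asdict(p)
            for hemi, pl in d["placements"].items():
                pl["tip_mm"] = list(map(float, pl["tip_mm"]))
                pl["direction"] = list(map(float, pl["direction"]))
            for hemi, st in d["settings"].items():
                st["cathodes"] = sorted(st["cathodes"])
                st["anodes"] = sorted(st["anodes"]) if st["anodes"] != "CASE" else "CASE"
            d["true_fractions"] = {str(k): float(v) for k, v in d["true_fractions"].items()}
            return d

        payload = {
            "outcome_params": dc_asdict(self.outcome_params),
            "target_label": self.target_label,
            "offtarget_label": self.offtarget_label,
            "patients": [enc(p) for p in self.patients],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticCohort":
        from .electrode import ElectrodePlacement, StimulationSetting

        with open(path) as fh:
            d = json.load(fh)
        patients = []
        for p in d["patients"]:
            placements = {h: ElectrodePlacement(np.asarray(pl["tip_mm"]),
                                                np.asarray(pl["direction"]),
                                                pl["patient_id"], h)
                          for h, pl in p["placements"].items()}
            settings = {h: StimulationSetting(frozenset(st["cathodes"]),
                                              "CASE" if st["anodes"] == "CASE"
                                              else frozenset(st["anodes"]),
                                              st["amplitude_V"], st["frequency_Hz"],
                                              st["pulse_width_us"], st["impedance_ohm"])
                        for h, st in p["settings"].items()}
            patients.append(PatientRecord(p["patient_id"], placements, settings,
                                          p["ybocs_change_pct"],
                                          {int(k): v for k, v in p["true_fractions"].items()}))
        return cls(patients, OutcomeParams(**d["outcome_params"]),
                   d["target_label"], d["offtarget_label"])


def ground_truth_fractions(config: PhantomConfig, cathode_centers_mm: np.ndarray,
                           capture_radius_mm: float = 4.0,
                           n_fibers: int = 64, rng_seed: int = 0) -> dict:
    """Ground-truth activated fraction per bundle label.

    Each bundle is represented by ``n_fibers`` parallel offset copies of
    its centerline (offsets uniform in the tube cross-section, seeded);
    a fiber counts as activated when any of its points lies within
    ``capture_radius_mm`` of any active cathode center.
    """
    cath = np.atleast_2d(np.asarray(cathode_centers_mm, dtype=float))
    out = {}
    for b_i, bundle in enumerate(config.bundles):
        rng = np.random.default_rng(rng_seed + 7919 * b_i)
        dense, tang = bundle.resample(step_mm=1.0)
        mean_dir = dense[-1] - dense[0]
        mean_dir /= np.linalg.norm(mean_dir)
        hit = 0
        for _ in range(n_fibers):
            v = rng.normal(size=3)
            v -= mean_dir * (v @ mean_dir)
            n = np.linalg.norm(v)
            v = v / n if n > 0 else np.zeros(3)
            r = bundle.radius_mm * np.sqrt(rng.uniform())
            fiber = dense + r * v
            d = np.linalg.norm(fiber[:, None, :] - cath[None, :, :], axis=-1)
            if (d <= capture_radius_mm).any():
                hit += 1
        out[bundle.target_label] = hit / n_fibers
    return out


def generate_cohort(config: PhantomConfig, n_patients: int,
                    outcome_params: OutcomeParams = OutcomeParams(),
                    rng_seed: int = 0, hub_mm: np.ndarray | None = None,
                    placement_jitter_mm: float = 3.0) -> SyntheticCohort:
    """Draw a cohort of patients with jittered electrode placements.

    ybocs_change_pct = beta0 + beta_target*f_target
                       - beta_offtarget*f_offtarget + N(0, noise_sd)
    where f_* are the ground-truth fractions of each bundle's fibers
    within 4 mm of the patient's active cathode center(s).
    """
    from .electrode import ElectrodePlacement, ElectrodeSpec, StimulationSetting, contact_centers

    if n_patients < 2:
        raise ValueError("need n_patients >= 2")
    rng = np.random.default_rng(rng_seed)
    spec = ElectrodeSpec()
    if hub_mm is None:
        hub_mm = np.concatenate([[b.centerline_mm[0] for b in config.bundles]]).mean(axis=0) \
            if config.bundles else config.extent_mm() / 2.0
    hub_mm = np.asarray(hub_mm, dtype=float)
    extent = config.extent_mm()

    patients = []
    cathode_options = [frozenset({0}), frozenset({1}), frozenset({2}),
                       frozenset({0, 1}), frozenset({1, 2})]
    jitter_scale = np.array([0.6, 0.6, 1.0])  # depth matters most
    for i in range(n_patients):
        placements, settings, cath_centers = {}, {}, []
        for hemi, xoff in (("left", -5.0), ("right", 5.0)):
            # lead rises through the corridor; contact 0 ventral, 3 dorsal
            tip = (hub_mm + np.array([xoff, 0.0, -12.0])
                   + rng.normal(0, placement_jitter_mm, 3) * jitter_scale)
            tip = np.clip(tip, 2.0, extent - 2.0)
            direction = np.array([0.0, 0.0, 1.0]) + rng.normal(0, 0.08, 3)
            direction /= np.linalg.norm(direction)
            pl = ElectrodePlacement(tip, direction, f"P{i+1:02d}", hemi)
            st = StimulationSetting(
                cathodes=cathode_options[rng.integers(len(cathode_options))],
                anodes="CASE",
                amplitude_V=float(np.round(rng.uniform(2.0, 6.0), 1)),
                frequency_Hz=135.0,
                pulse_width_us=float(rng.choice([90.0, 150.0, 210.0])),
                impedance_ohm=float(np.round(rng.uniform(750.0, 1250.0))),
            )
            placements[hemi], settings[hemi] = pl, st
            centers = contact_centers(pl, spec)
            cath_centers.extend(centers[k] for k in sorted(st.cathodes))
        fracs = ground_truth_fractions(config, np.asarray(cath_centers),
                                       rng_seed=rng_seed + 104729 * i)
        p = outcome_params
        f_t = fracs.get(1, 0.0)
        f_o = fracs.get(2, 0.0)
        eps = rng.normal(0.0, p.noise_sd) if p.noise_sd > 0 else 0.0
        ybocs = p.beta0 + p.beta_target * f_t - p.beta_offtarget * f_o + eps
        patients.append(PatientRecord(f"P{i+1:02d}", placements, settings,
                                      float(ybocs), fracs))
    return SyntheticCohort(patients, outcome_params)


def activation_matrix(cohort: SyntheticCohort, n_cols_per_bundle: int = 4,
                      scale: float = 400.0, noise_frac: float = 0.05,
                      rng_seed: int = 0):
    """Region-activation count matrix (patients x regions) from ground truth.

    Emulates the per-region active-fiber tallies the full pipeline
    produces: each bundle contributes ``n_cols_per_bundle`` correlated
    region columns proportional to its activated fraction, plus
    multiplicative measurement noise.  Returns (matrix, column_names,
    column_label) with column_label giving the generating bundle label.
    """
    import pandas as pd

    rng = np.random.default_rng(rng_seed)
    labels = sorted({l for p in cohort.patients for l in p.true_fractions})
    cols, names, col_label = [], [], []
    for lab in labels:
        f = np.array([p.true_fractions[lab] for p in cohort.patients])
        for j in range(n_cols_per_bundle):
            gain = scale * rng.uniform(0.5, 1.5)
            noise = rng.normal(1.0, noise_frac, len(f))
            cols.append(np.maximum(gain * f * noise, 0.0))
            names.append(f"region_L{lab}_{j}")
            col_label.append(lab)
    mat = pd.DataFrame(np.column_stack(cols), columns=names,
                       index=[p.patient_id for p in cohort.patients])
    return mat, names, col_label


def default_phantom_config(rng_seed: int = 0) -> PhantomConfig:
    """The standard study phantom: 64^3 voxels at 2 mm, three bundles
    passing an electrode corridor at distinct depths on their way to
    three labeled gray-matter targets (a therapeutic 'dlPFC-like'
    target, an 'lOFC-like' off-target and a 'thalamus-like' region),
    with one CSF sphere off to the side.  The depth separation mirrors
    the anatomical situation in which ventral vs dorsal contacts of one
    lead recruit different pathways, and keeps the ground-truth bundle
    activation fractions from collapsing onto a single 'distance to
    lead' factor across a cohort."""
    bundles = [
        BundleSpec(np.array([[64.0, 52.0, 46.0], [50.0, 70.0, 58.0],
                             [38.0, 92.0, 76.0], [34.0, 102.0, 86.0]]),
                   radius_mm=4.0, target_label=1),
        BundleSpec(np.array([[64.0, 52.0, 60.0], [78.0, 68.0, 64.0],
                             [94.0, 88.0, 70.0], [102.0, 98.0, 72.0]]),
                   radius_mm=4.0, target_label=2),
        BundleSpec(np.array([[64.0, 52.0, 54.0], [64.0, 36.0, 60.0],
                             [64.0, 24.0, 66.0]]),
                   radius_mm=4.0, target_label=3),
    ]
    return PhantomConfig(
        grid_shape=(64, 64, 64),
        voxel_size_mm=2.0,
        bundles=bundles,
        csf_regions=[SphereSpec((24.0, 24.0, 24.0), 9.0)],
        target_labels={1: "dlPFC-like", 2: "lOFC-like", 3: "thalamus-like"},
        background_fa=0.10,
        bundle_fa=0.75,
        rng_seed=rng_seed,
    )
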