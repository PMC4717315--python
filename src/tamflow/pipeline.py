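"""End-to-end orchestration: phantom/cohort -> fields -> tracking ->
clustering -> axon simulation -> maps -> statistics.

Each hemisphere is processed independently (seed region around its
active cathode contacts, unit-stimulus field solve, probabilistic
tracking, geometry filtering, cable simulation of every kept fiber at
the clinical amplitude) and the two hemispheres' heat maps are then
combined per patient.  The cohort stage compares responder and
non-responder maps voxelwise, builds the region-activation matrix and
runs the factor-analysis / stepwise-regression chain.  Every stage's
parameters and seeds are recorded so a run is bit-reproducible.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import actmaps, axonsim, cluster, efield, electrode, stats, tracking
from .synthdata import PhantomConfig, SyntheticCohort, generate_phantom
from .volumes import LabelVolume, TensorVolume

__all__ = ["RunConfig", "HemisphereResult", "PatientResult", "run_patient",
           "run_cohort"]


@dataclass
class RunConfig:
    tracking: tracking.TrackingParams = field(default_factory=tracking.TrackingParams)
    clustering: cluster.ClusterParams = field(default_factory=cluster.ClusterParams)
    circuit: efield.CircuitModel = field(default_factory=efield.CircuitModel)
    membrane: axonsim.MembraneModel = field(default_factory=axonsim.MembraneModel)
    conductivity: efield.ConductivityModel = field(default_factory=efield.ConductivityModel)
    electrode_spec: electrode.ElectrodeSpec = field(default_factory=electrode.ElectrodeSpec)
    sheath: efield.EncapsulationSheath = field(default_factory=efield.EncapsulationSheath)
    calibrate_impedance: bool = False
    seed_radius_mm: float = 4.0
    heatmap_voxel_mm: float = 1.0
    solver_h_core_mm: float = 0.75
    solver_pad_mm: float = 140.0
    sim_dt_ms: float = 0.005
    sim_duration_ms: float = 5.0
    min_axon_length_mm: float = 1.0
    rng_seed: int = 0

    def provenance(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, default=str))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["tracking"] = tracking.TrackingParams(**d["tracking"])
        d["clustering"] = cluster.ClusterParams(**d["clustering"])
        d["circuit"] = efield.CircuitModel(**d["circuit"])
        d["membrane"] = axonsim.MembraneModel(**d["membrane"])
        d["conductivity"] = efield.ConductivityModel(**d["conductivity"])
        d["electrode_spec"] = electrode.ElectrodeSpec(**d["electrode_spec"])
        d["sheath"] = efield.EncapsulationSheath(**d["sheath"])
        return cls(**d)


@dataclass
class HemisphereResult:
    hemisphere: str
    seed_region: set
    n_tracked: int
    n_kept: int
    n_excluded: int
    n_active: int
    active_flags: list
    streamlines: object
    heat: actmaps.HeatMap
    regions: actmaps.RegionCounts


@dataclass
class PatientResult:
    patient_id: str
    hemispheres: dict
    combined: actmaps.HeatMap
    response_class: str
    ybocs_change_pct: float


def _heat_grid(label_vol: LabelVolume, voxel_mm: float):
    lo = label_vol.affine.apply(np.zeros(3)) - voxel_mm
    hi = label_vol.affine.apply(np.asarray(label_vol.shape, dtype=float) - 1) + voxel_mm
    return actmaps.make_grid(np.minimum(lo, hi), np.maximum(lo, hi), voxel_mm)


def run_hemisphere(config: RunConfig, placement, setting, tensors: TensorVolume,
                   labels: LabelVolume, csf_mask, orientation_field,
                   rng_seed: int) -> HemisphereResult:
    spec = config.electrode_spec
    centers = electrode.contact_centers(placement, spec)
    active_centers = centers[sorted(setting.cathodes)]
    seed_region = electrode.build_seed_region(active_centers, tensors.affine,
                                              tensors.shape,
                                              config.seed_radius_mm)

    # unit-stimulus field (1 V cathodic) and tissue waveform
    cond = efield.diffusion_to_conductivity(tensors, config.conductivity)
    sheath = config.sheath
    if config.calibrate_impedance:
        sheath = efield.calibrate_encapsulation(cond, placement, spec, setting,
                                                setting.impedance_ohm,
                                                h_core=config.solver_h_core_mm)
    grid = efield.SolverGrid.around_lead(placement, spec,
                                         h_core=config.solver_h_core_mm,
                                         pad_mm=config.solver_pad_mm)
    potential = efield.solve_potential(cond, placement, spec, setting, sheath,
                                       grid=grid)
    waveform = efield.tissue_waveform(setting, config.circuit)

    bundle = tracking.track_seed_region(orientation_field, seed_region,
                                        config.tracking, csf_mask,
                                        rng_seed=rng_seed,
                                        hemisphere=placement.hemisphere)
    trackable = [s for s in bundle if len(s) >= 2]
    kept, excluded, _ = cluster.filter_unique(trackable, config.clustering)

    active_flags = []
    active_streamlines = []
    for s in kept:
        if s.arc_length() < max(config.min_axon_length_mm, 1.0):
            active_flags.append(False)
            continue
        axon = axonsim.build_axon(s)
        stim = axonsim.sample_extracellular(potential, axon, waveform,
                                            setting.amplitude_V,
                                            dt_ms=config.sim_dt_ms,
                                            duration_ms=config.sim_duration_ms)
        out = axonsim.simulate_activation(axon, stim, config.membrane)
        active_flags.append(out.activated)
        if out.activated:
            active_streamlines.append(s)

    aff, shape = _heat_grid(labels, config.heatmap_voxel_mm)
    heat = actmaps.heat_map(active_streamlines, aff, shape,
                            n_total_fibers=len(kept))
    regions = actmaps.region_counts(kept, labels, active_flags)
    return HemisphereResult(placement.hemisphere, seed_region,
                            n_tracked=len(trackable), n_kept=len(kept),
                            n_excluded=len(excluded),
                            n_active=len(active_streamlines),
                            active_flags=active_flags, streamlines=kept,
                            heat=heat, regions=regions)


def run_patient(config: RunConfig, patient, tensors: TensorVolume,
                labels: LabelVolume, csf_mask, orientation_field=None) -> PatientResult:
    """Run the full per-patient chain (both hemispheres, combined map)."""
    if orientation_field is None:
        orientation_field = tracking.estimate_orientations(tensors)
    hemis = {}
    for i, hemi in enumerate(sorted(patient.placements)):
        try:
            hemis[hemi] = run_hemisphere(
                config, patient.placements[hemi], patient.settings[hemi],
                tensors, labels, csf_mask, orientation_field,
                rng_seed=config.rng_seed + 31 * i + 1000 * _stable_id(patient.patient_id))
        except Exception as exc:
            raise RuntimeError(f"patient {patient.patient_id}, hemisphere "
                               f"{hemi}: {type(exc).__name__}: {exc}") from exc
    combined = actmaps.combine_maps([h.heat for h in hemis.values()])
    return PatientResult(patient.patient_id, hemis, combined,
                         stats.classify_response(patient.ybocs_change_pct),
                         patient.ybocs_change_pct)


def _stable_id(patient_id: str) -> int:
    return sum((i + 1) * ord(c) for i, c in enumerate(str(patient_id))) % 1009


def run_cohort(config: RunConfig, phantom_config: PhantomConfig,
               cohort: SyntheticCohort, eigen_threshold: float = 2.0) -> dict:
    """Per-patient runs plus the group analysis.

    Returns a report dict with per-patient results, the responder
    comparison (skipped with a notice when all patients fall in one
    class), the region-activation matrix, and (when admissible) the
    factor-analysis / stepwise chain.
    """
    import pandas as pd

    if len(cohort.patients) < 2:
        raise ValueError("need >= 2 patients")
    tensors, labels, csf = generate_phantom(phantom_config)
    ofield = tracking.estimate_orientations(tensors)
    results = {}
    for patient in cohort.patients:
        results[patient.patient_id] = run_patient(config, patient, tensors,
                                                  labels, csf.data, ofield)

    # region-activation matrix: active counts per hemisphere and label
    labels_present = sorted(labels.label_names)
    rows = {}
    for pid, res in results.items():
        row = {}
        for hemi, h in res.hemispheres.items():
            for l in labels_present:
                row[f"{hemi}_L{l}"] = h.regions.active.get(l, 0)
        rows[pid] = row
    act_matrix = pd.DataFrame(rows).T

    classes = {pid: r.response_class for pid, r in results.items()}
    responders = {pid: r.combined for pid, r in results.items()
                  if classes[pid] in ("best", "moderate")}
    nonresponders = {pid: r.combined for pid, r in results.items()
                     if classes[pid] == "none"}
    improvements = {pid: r.ybocs_change_pct for pid, r in results.items()}
    comparison = None
    notice = None
    if responders and nonresponders:
        comparison = actmaps.compare_responders(responders, nonresponders,
                                                improvements)
    else:
        notice = "responder comparison skipped: all patients in one class"

    factors = stepwise = None
    try:
        factors = stats.factor_analysis(act_matrix, eigen_threshold=eigen_threshold)
        stepwise = stats.stepwise_regression(
            factors.scores, [improvements[p] for p in act_matrix.index])
    except ValueError as exc:
        notice = (notice + "; " if notice else "") + f"factor analysis skipped: {exc}"

    return {
        "patients": results,
        "activation_matrix": act_matrix,
        "comparison": comparison,
        "factors": factors,
        "stepwise": stepwise,
        "notice": notice,
        "provenance": {"config": config.provenance(),
                       "phantom_seed": phantom_config.rng_seed,
                       "n_patients": len(cohort.patients)},
    }
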