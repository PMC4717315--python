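import numpy as np
import pytest

from tamflow.efield import (CircuitModel, ConductivityField, ConductivityModel,
                            EncapsulationSheath, SolverGrid,
                            calibrate_encapsulation, diffusion_to_conductivity,
                            graded_axis, model_impedance, monopole_benchmark,
                            solve_on_grid, solve_potential, tissue_waveform)
from tamflow.electrode import ElectrodePlacement, ElectrodeSpec, StimulationSetting
from tamflow.volumes import TensorVolume


def uniform_tensor_volume(value=1e-3, shape=(16, 16, 16), voxel=2.0):
    data = np.broadcast_to(np.eye(3) * value, shape + (3, 3)).copy()
    aff = np.diag([voxel, voxel, voxel, 1.0])
    return TensorVolume(data, aff)


class TestConductivityTransform:
    def test_zero_tensor_maps_to_zero(self):
        tv = uniform_tensor_volume(0.0)
        cf = diffusion_to_conductivity(tv, ConductivityModel(0.2, 0.7e-3))
        assert np.allclose(cf.data, 0.0)

    def test_isotropic_scalar_scaling(self):
        tv = uniform_tensor_volume(0.7e-3)
        cf = diffusion_to_conductivity(tv, ConductivityModel(0.2, 0.7e-3))
        assert np.allclose(cf.data[0, 0, 0], 0.2 * np.eye(3))

    def test_diagonal_example_by_hand(self):
        # D = diag(1.0, 0.5, 0.5) 1e-3 mm^2/s, ratio 200 -> diag(0.2, 0.1, 0.1)
        data = np.zeros((1, 1, 1, 3, 3))
        data[0, 0, 0] = np.diag([1.0e-3, 0.5e-3, 0.5e-3])
        tv = TensorVolume(data, np.eye(4))
        cf = diffusion_to_conductivity(tv, ConductivityModel(sigma_e=0.2, d_e=1e-3))
        assert np.allclose(cf.data[0, 0, 0], np.diag([0.20, 0.10, 0.10]))

    def test_zero_diffusivity_rejected(self):
        with pytest.raises(ValueError):
            ConductivityModel(0.2, 0.0)


class TestTissueWaveform:
    def setting(self, **kw):
        d = dict(cathodes={1}, anodes="CASE", amplitude_V=5.0,
                 frequency_Hz=135.0, pulse_width_us=90.0, impedance_ohm=1000.0)
        d.update(kw)
        return StimulationSetting(**d)

    def test_interface_drop_at_pulse_onset(self):
        wf = tissue_waveform(self.setting(), CircuitModel())
        assert wf.values[0] == pytest.approx(0.58, abs=1e-12)

    def test_rc_droop_closed_form(self):
        # tau = 1000 ohm * 6.6 uF = 6.6 ms; droop over 90 us = 1 - e^(-0.09/6.6)
        wf = tissue_waveform(self.setting(), CircuitModel(), dt_ms=0.0005)
        in_pulse = wf.times_ms < 0.09
        start, end = wf.values[in_pulse][0], wf.values[in_pulse][-1]
        droop = 1.0 - end / start
        t_end = wf.times_ms[in_pulse][-1]
        assert droop == pytest.approx(1.0 - np.exp(-t_end / 6.6), rel=1e-9)
        assert droop == pytest.approx(0.0135, abs=2e-3)

    def test_infinite_capacitance_limit_is_flat(self):
        wf = tissue_waveform(self.setting(), CircuitModel(capacitance_F=1.0))
        in_pulse = wf.times_ms < 0.09
        assert np.allclose(wf.values[in_pulse], 0.58, atol=1e-5)

    def test_zero_outside_pulse_and_bounded(self):
        wf = tissue_waveform(self.setting())
        assert np.all(np.abs(wf.values) <= 1.0)
        assert np.allclose(wf.values[wf.times_ms > 0.09], 0.0)

    def test_invalid_frequency_and_width(self):
        with pytest.raises(ValueError, match="frequency"):
            tissue_waveform(self.setting(frequency_Hz=-1.0))
        with pytest.raises(ValueError, match="shorter"):
            tissue_waveform(self.setting(pulse_width_us=1e6))


def small_grid(n=17, h=1.0, **bc):
    edges = np.arange(n + 1) * h - (n * h) / 2
    return SolverGrid((edges, edges, edges), **bc)


class TestSolver:
    def solve_center_cathode(self, sigma_diag, n=17, value=-1.0):
        grid = small_grid(n)
        dmask = np.zeros(grid.shape, dtype=bool)
        dmask[n // 2, n // 2, n // 2] = True
        dvals = np.where(dmask, value, 0.0)
        phi, res, _ = solve_on_grid(grid, sigma_diag, dmask, dvals)
        return grid, phi, res

    def test_boundary_is_grounded_and_maximum_principle(self):
        n = 17
        sigma = np.full((n, n, n, 3), 0.2)
        _, phi, res = self.solve_center_cathode(sigma, n)
        assert res < 1e-8
        # all values between the two Dirichlet levels
        assert phi.min() >= -1.0 - 1e-12
        assert phi.max() <= 0.0 + 1e-12
        # near-boundary cells pulled close to the ground level
        assert abs(phi[0, :, :]).max() < 0.1

    def test_linearity_in_dirichlet_amplitude(self):
        n = 13
        sigma = np.full((n, n, n, 3), 0.2)
        _, phi1, _ = self.solve_center_cathode(sigma, n, value=-1.0)
        _, phi3, _ = self.solve_center_cathode(sigma, n, value=-3.0)
        assert np.allclose(phi3, 3.0 * phi1, rtol=1e-8, atol=1e-10)

    def test_anisotropy_elongates_equipotentials(self):
        n = 17
        sigma = np.full((n, n, n, 3), 0.05)
        sigma[..., 0] = 0.5  # strong conduction along x
        grid, phi, _ = self.solve_center_cathode(sigma, n)
        c = n // 2
        d = 5
        assert abs(phi[c + d, c, c]) > abs(phi[c, c, c + d])

    def test_no_dirichlet_rejected(self):
        grid = small_grid(5, bc_low=("neumann",) * 3, bc_high=("neumann",) * 3)
        sigma = np.full(grid.shape + (3,), 0.2)
        with pytest.raises(ValueError, match="Dirichlet"):
            solve_on_grid(grid, sigma, np.zeros(grid.shape, bool),
                          np.zeros(grid.shape))

    def test_monopole_analytic_agreement_quick(self):
        """Coarse version of the spherical-contact benchmark."""
        res = monopole_benchmark(h_core=0.6, pad_mm=600.0)
        assert res["max_rel_err"] < 0.05
        assert res["residual"] < 1e-8

    def test_grid_refinement_stability(self):
        """Halving the core spacing moves probe potentials by < 3%."""
        coarse = monopole_benchmark(h_core=0.8, pad_mm=600.0)
        fine = monopole_benchmark(h_core=0.4, pad_mm=600.0)
        rel = np.abs(fine["phi_numeric"] - coarse["phi_numeric"]) / np.abs(
            fine["phi_numeric"])
        assert rel.max() < 0.03


@pytest.fixture(scope="module")
def lead_setup():
    tv = uniform_tensor_volume(0.7e-3, shape=(24, 24, 24))
    cond = diffusion_to_conductivity(tv, ConductivityModel())
    placement = ElectrodePlacement(np.array([23.0, 23.0, 10.0]),
                                   np.array([0.0, 0.0, 1.0]))
    spec = ElectrodeSpec()
    setting = StimulationSetting({0, 1}, "CASE", 4.0, 135.0, 90.0, 1000.0)
    grid = SolverGrid.around_lead(placement, spec, h_core=1.2,
                                  core_margin_mm=6.0, pad_mm=80.0, ratio=1.5)
    return cond, placement, spec, setting, grid


class TestLeadSolve:
    def test_unit_solution_properties(self, lead_setup):
        cond, placement, spec, setting, grid = lead_setup
        fld = solve_potential(cond, placement, spec, setting,
                              EncapsulationSheath(), grid=grid)
        assert fld.residual < 1e-8
        assert fld.phi.min() >= -1.0 - 1e-12 and fld.phi.max() <= 1e-12
        z = model_impedance(fld)
        assert 100.0 < z < 10000.0

    def test_sheath_conductivity_monotone_in_impedance(self, lead_setup):
        cond, placement, spec, setting, grid = lead_setup
        z = {}
        for s in (0.05, 0.1, 0.2):
            fld = solve_potential(cond, placement, spec, setting,
                                  EncapsulationSheath(sigma_S_per_m=s), grid=grid)
            z[s] = model_impedance(fld)
        assert z[0.05] > z[0.1] > z[0.2]

    def test_calibration_reproduces_target(self, lead_setup):
        cond, placement, spec, setting, grid = lead_setup
        mid = model_impedance(solve_potential(
            cond, placement, spec, setting,
            EncapsulationSheath(sigma_S_per_m=0.08), grid=grid))
        with pytest.warns(UserWarning) if not 750 <= mid <= 1250 else _nullcontext():
            sheath = calibrate_encapsulation(cond, placement, spec, setting,
                                             mid, grid=grid)
        z = model_impedance(solve_potential(cond, placement, spec, setting,
                                            sheath, grid=grid))
        assert abs(z - mid) / mid < 0.01

    def test_unattainable_target_rejected(self, lead_setup):
        cond, placement, spec, setting, grid = lead_setup
        with pytest.raises(ValueError, match="unattainable"):
            with pytest.warns(UserWarning, match="outside"):
                calibrate_encapsulation(cond, placement, spec, setting,
                                        1e7, grid=grid)


from contextlib import nullcontext as _nullcontext  # noqa: E402


class TestGradedAxis:
    def test_uniform_core_and_monotone_padding(self):
        edges = graded_axis(0.0, 10.0, 1.0, 30.0, ratio=1.4)
        d = np.diff(edges)
        assert np.all(d > 0)
        assert edges[0] <= -30.0 and edges[-1] >= 40.0
        core = d[(edges[:-1] >= -1e-9) & (edges[1:] <= 10.0 + 1e-9)]
        assert np.allclose(core, 1.0)
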