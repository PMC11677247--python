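import numpy as np
import pytest

from osseowave.engine import (
    ElementMaterials,
    PairReference,
    Simulator,
    damping,
    pair_kinematics,
    plastic_return,
    stable_dt,
    von_mises,
)
from osseowave.geometry import ModelSpec, Model, Region
from osseowave.materials import Material, default_materials
from osseowave.verify import make_block_model


def _two_element_model(d=250e-6, material="Cancellous"):
    spec = ModelSpec(d=d, include_applicator=False)
    return Model(
        spec=spec,
        positions=np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
        regions=np.full(2, int(Region.CANCELLOUS), dtype=np.int64),
        material_names=[material],
        material_id=np.zeros(2, dtype=np.int64),
        pairs=np.array([[0, 1]]),
        r0=np.array([d]),
    )


def _identity_rotations(n):
    return np.tile(np.eye(3), (n, 1, 1))


class TestPairKinematics:
    def test_undeformed_lattice_has_zero_strain(self, benchmark_model):
        m = benchmark_model
        ref = PairReference.from_model(m)
        st = pair_kinematics(m.positions, _identity_rotations(m.n_elements), ref)
        assert np.abs(st.eps_n).max() == 0.0
        assert np.abs(st.gamma).max() == 0.0

    def test_stretch_gives_engineering_normal_strain(self):
        m = _two_element_model(d=250e-6)
        ref = PairReference.from_model(m)
        pos = m.positions.copy()
        pos[1, 0] = 252.5e-6
        st = pair_kinematics(pos, _identity_rotations(2), ref)
        assert st.eps_n[0] == pytest.approx(0.01, rel=1e-12)
        assert np.linalg.norm(st.gamma[0]) == pytest.approx(0.0, abs=1e-15)

    def test_rigid_rotation_produces_no_strain(self, benchmark_model, rng):
        """Objectivity: rotating the whole model rigidly leaves every pair
        strain at zero to machine precision."""
        from scipy.spatial.transform import Rotation

        m = benchmark_model
        ref = PairReference.from_model(m)
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        center = m.positions.mean(axis=0)
        pos = (m.positions - center) @ R.T + center
        rot = np.tile(R, (m.n_elements, 1, 1))
        st = pair_kinematics(pos, rot, ref)
        assert np.abs(st.eps_n).max() < 1e-10
        assert np.abs(st.gamma).max() < 1e-10

    def test_relative_rotation_produces_shear(self):
        from scipy.spatial.transform import Rotation

        m = _two_element_model()
        ref = PairReference.from_model(m)
        rot = _identity_rotations(2)
        phi = 1e-3
        rot[0] = Rotation.from_rotvec([0, 0, phi]).as_matrix()
        rot[1] = Rotation.from_rotvec([0, 0, phi]).as_matrix()
        st = pair_kinematics(m.positions, rot, ref)
        assert np.linalg.norm(st.gamma[0]) == pytest.approx(phi, rel=1e-5)


class TestStableDt:
    def test_reference_value_with_titanium(self):
        model = make_block_model((3, 3, 3), 250e-6, "Ti-6Al-4V")
        emat = ElementMaterials.from_model(model, default_materials())
        assert stable_dt(model, emat) == pytest.approx(8.7e-9, rel=0.01)

    def test_doubling_diameter_doubles_dt(self):
        reg = default_materials()
        m1 = make_block_model((3, 3, 3), 250e-6, "Cortical")
        m2 = make_block_model((3, 3, 3), 500e-6, "Cortical")
        e1 = ElementMaterials.from_model(m1, reg)
        e2 = ElementMaterials.from_model(m2, reg)
        assert stable_dt(m2, e2) == pytest.approx(2 * stable_dt(m1, e1), rel=1e-12)

    def test_degenerate_courant_factor_rejected(self, benchmark_model):
        emat = ElementMaterials.from_model(benchmark_model, default_materials())
        with pytest.raises(ValueError):
            stable_dt(benchmark_model, emat, C=0.0)


class TestPlasticReturn:
    def test_radial_return_scales_to_yield(self):
        # uniaxial 120 MPa -> von Mises 120 MPa; Cu yields at 80 MPa
        sigma = np.array([120e6, 0, 0, 0, 0, 0.0])
        out = plastic_return(sigma, 80e6)
        assert von_mises(out[None, :])[0] == pytest.approx(80e6, rel=1e-12)
        # mean stress unchanged
        assert out[:3].sum() / 3 == pytest.approx(40e6, rel=1e-12)

    def test_below_yield_unchanged(self):
        sigma = np.array([50e6, 0, 0, 0, 0, 0.0])
        np.testing.assert_array_equal(plastic_return(sigma, 80e6), sigma)

    def test_tissues_never_rescaled(self):
        sigma = np.array([5e9, 0, 0, 1e9, 0, 0.0])
        np.testing.assert_array_equal(plastic_return(sigma, np.inf), sigma)


class TestDamping:
    def test_zero_coefficient_is_identity(self, rng):
        F = rng.normal(size=(5, 3))
        v = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(damping(F, v, 0.0), F)

    def test_opposes_velocity_sign(self):
        F = np.array([[1.0, -1.0, 0.0]])
        v = np.array([[1.0, 1.0, 1.0]])
        out = damping(F, v, 0.1)
        assert out[0, 0] == pytest.approx(0.9)
        assert out[0, 1] == pytest.approx(-1.1)

    def test_coefficient_bounds(self):
        with pytest.raises(ValueError):
            damping(np.zeros((1, 3)), np.zeros((1, 3)), 1.0)


class TestDynamics:
    def test_two_body_oscillator_frequency_and_momentum(self, oscillator_result):
        """Free vibration of a bonded pair matches the analytic spring
        frequency; total linear momentum is conserved."""
        assert oscillator_result.rel_error < 0.01
        assert oscillator_result.momentum_drift < 1e-12

    def test_newtons_third_law(self, rng):
        model = make_block_model((3, 3, 4), 500e-6, "Cancellous")
        emat = ElementMaterials.from_model(model, default_materials())
        sim = Simulator(model=model, emat=emat, poro_enabled=False,
                        fixed_mask=np.zeros(model.n_elements, bool))
        sim.pos += 1e-6 * rng.normal(size=sim.pos.shape)
        sim._compute_forces()
        total = sim._force_raw.sum(axis=0)
        scale = np.abs(sim._force_raw).sum()
        assert np.abs(total).max() < 1e-12 * scale

    def test_rigid_rotation_produces_no_stress(self, rng):
        from scipy.spatial.transform import Rotation

        model = make_block_model((3, 3, 3), 500e-6, "Cortical")
        emat = ElementMaterials.from_model(model, default_materials())
        sim = Simulator(model=model, emat=emat, poro_enabled=False,
                        fixed_mask=np.zeros(model.n_elements, bool))
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        center = sim.pos.mean(axis=0)
        sim.pos = (sim.pos - center) @ R.T + center
        sim.rot = np.tile(R, (model.n_elements, 1, 1))
        sim._compute_forces()
        assert np.abs(sim.sigma).max() < 1.0  # Pa, on GPa-scale moduli

    def test_affine_isotropic_strain_recovers_bulk_response(self):
        """Interior mean stress under uniform volumetric strain equals
        K tr(eps): the many-body closure reproduces isotropic elasticity."""
        model = make_block_model((5, 5, 5), 500e-6, "Cortical")
        reg = default_materials()
        emat = ElementMaterials.from_model(model, reg)
        sim = Simulator(model=model, emat=emat, poro_enabled=False,
                        fixed_mask=np.zeros(model.n_elements, bool))
        eps = -1e-4
        center = sim.pos.mean(axis=0)
        sim.pos = center + (sim.pos - center) * (1 + eps)
        sim._compute_forces()
        pos = model.positions
        margin = 1.2 * model.spec.a
        core = np.all((pos >= pos.min(0) + margin) & (pos <= pos.max(0) - margin), axis=1)
        K = reg["Cortical"].K
        assert sim.sigma_mean[core].mean() == pytest.approx(3 * eps * K, rel=1e-3)

    def test_uniform_boundary_stress_reaches_interior(self, modulus_results):
        """Uniaxial strain-controlled compression recovers the input E and
        nu within 3% (simulation vs tabulated values)."""
        for res in modulus_results.values():
            assert res.E_rel_error < 0.03
            assert abs(res.nu_measured - res.nu_input) < 0.03 * res.nu_input

    def test_energy_drift_bounded(self, energy_drift_value):
        assert energy_drift_value < 0.01

    def test_wave_speed_matches_analytic(self, wave_result):
        assert wave_result.rel_error < 0.05


def test_von_mises_invariants():
    hydro = np.array([[5e6, 5e6, 5e6, 0, 0, 0.0]])
    uni = np.array([[3e6, 0, 0, 0, 0, 0.0]])
    assert von_mises(hydro)[0] == pytest.approx(0.0, abs=1e-6)
    assert von_mises(uni)[0] == pytest.approx(3e6, rel=1e-12)
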