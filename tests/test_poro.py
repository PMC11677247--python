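import numpy as np
import pytest

from osseowave.engine import ElementMaterials, Simulator
from osseowave.materials import default_materials
from osseowave.poro import (
    consolidation_coefficient,
    effective_mean_stress,
    harmonic_permeability,
    pair_transmissibility,
    pore_pressure_rate,
    terzaghi_pressure,
)
from osseowave.verify import SOFT_PORO_FLUID, SOFT_PORO_MATERIAL, make_block_model


class TestTransmissibility:
    def test_equal_permeabilities_unchanged(self):
        assert harmonic_permeability(3e-16, 3e-16) == pytest.approx(3e-16)

    def test_cortical_cancellous_harmonic_mean(self):
        # series flow through 1e-20 and 3.7e-16 m^2 is throttled by the
        # tighter material
        assert harmonic_permeability(1e-20, 3.7e-16) == pytest.approx(2.0e-20, rel=1e-3)

    def test_metal_pairs_are_impermeable(self):
        T = pair_transmissibility(
            np.array([1e-16]), np.array([0.0]), np.array([False]),
            1e-7, np.array([5e-4]), 1e-10, 1e-3,
        )
        assert T[0] == 0.0


def test_effective_mean_stress_sign_convention():
    # tension-positive stress, compression-positive pressure
    assert effective_mean_stress(-1e6, 0.78, 0.5e6) == pytest.approx(-0.61e6)
    assert effective_mean_stress(2.0, 0.0, 5e6) == pytest.approx(2.0)
    assert effective_mean_stress(3.0, 0.5, 0.0) == pytest.approx(3.0)


def test_uniform_pressure_no_strain_is_stationary():
    P = np.full(4, 7e4)
    pairs = np.array([[0, 1], [1, 2], [2, 3]])
    rate = pore_pressure_rate(P, np.zeros(4), pairs, np.full(3, 1e-4),
                              np.full(4, 0.8), np.full(4, 3e9))
    np.testing.assert_allclose(rate, 0.0, atol=1e-20)


def test_undrained_skempton_response(undrained_result):
    """Sealed compression: dP = -alpha M d(eps_vol) on every element."""
    assert undrained_result.rel_error < 1e-5


def _quiet_sim(model, fluid=None):
    emat = ElementMaterials.from_model(
        model, {SOFT_PORO_MATERIAL.name: SOFT_PORO_MATERIAL}, fluid or SOFT_PORO_FLUID
    )
    sim = Simulator(model=model, emat=emat, fluid=fluid or SOFT_PORO_FLUID,
                    fixed_mask=np.ones(model.n_elements, bool), poro_enabled=True)
    return sim


def test_sealed_fluid_mass_conserved(rng):
    """With no strain and sealed boundaries, sum(V P / M) is invariant."""
    model = make_block_model((3, 3, 3), 1e-3, SOFT_PORO_MATERIAL.name)
    sim = _quiet_sim(model)
    sim.P[:] = rng.uniform(0, 1e4, model.n_elements)
    inv0 = np.sum(sim.P / sim.emat.M)
    sim.step(1000)
    inv1 = np.sum(sim.P / sim.emat.M)
    assert inv1 == pytest.approx(inv0, rel=1e-8)
    # and the field actually diffused
    assert sim.P.std() < 0.5 * 1e4


def test_drained_boundary_drives_pressure_to_zero():
    model = make_block_model((3, 3, 3), 1e-3, SOFT_PORO_MATERIAL.name)
    sim = _quiet_sim(model)
    sim.P[:] = 1e4
    top = model.positions[:, 2] >= model.positions[:, 2].max() - model.spec.a / 4
    sim.drained_mask = top
    sim.step(4000)
    assert np.abs(sim.P).max() < 0.02 * 1e4


def test_terzaghi_consolidation_profile(terzaghi_result):
    """1-D consolidation matches the analytic series within 5% RMS."""
    assert terzaghi_result.rms_rel < 0.05
    # the profile is monotone in depth at fixed time
    order = np.argsort(terzaghi_result.depth)
    P = terzaghi_result.P_sim[order]
    assert P[-1] > P[0]


def test_consolidation_coefficient_formula():
    c = consolidation_coefficient(K=1e6, G=0.75e6, alpha=1.0, M=2e6,
                                  k_perm=1e-12, eta_f=1e-3)
    Ku = 1e6 + 1e6  # K + 4G/3
    assert c == pytest.approx(1e-9 * Ku * 2e6 / (Ku + 2e6))


def test_terzaghi_series_limits():
    z = np.linspace(0, 1.0, 5)
    early = terzaghi_pressure(z, t=1e-9, H=1.0, c_v=1.0, p0=100.0)
    late = terzaghi_pressure(z, t=100.0, H=1.0, c_v=1.0, p0=100.0)
    assert early[0] == pytest.approx(0.0, abs=1e-6)       # drained face
    assert early[-1] == pytest.approx(100.0, rel=5e-3)    # still undrained
    assert np.abs(late).max() < 1e-3                      # fully consolidated
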