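import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osseowave.materials import (
    Fluid,
    Material,
    MaterialError,
    biot_constants,
    default_materials,
    derived_moduli,
    load_material_table,
    phase_material_map,
)

GPA = 1e9


@pytest.mark.parametrize(
    "name, field, value",
    [
        ("Cortical", "E", 14.7 * GPA),
        ("Cortical", "nu", 0.32),
        ("Cortical", "Ks", 17.0 * GPA),
        ("Cortical", "theta", 0.04),
        ("Cortical", "k_perm", 1.0e-20),
        ("Woven bone", "E", 1.2 * GPA),
        ("Woven bone", "nu", 0.30),
        ("Woven bone", "k_perm", 1.0e-16),
        ("Cancellous", "rho", 700.0),
        ("Ti-6Al-4V", "E", 107.1 * GPA),
        ("Ti-6Al-4V", "nu", 0.31),
        ("Ti-6Al-4V", "sigma_y", 800e6),
        ("Cu", "sigma_y", 80e6),
        ("Cu", "rho", 8950.0),
    ],
)
def test_table_round_trip(registry, name, field, value):
    """The registry reproduces the tabulated tissue/metal values exactly."""
    assert getattr(registry[name], field) == pytest.approx(value, rel=1e-12)


def test_derived_moduli_reference_values(registry):
    cort = derived_moduli(registry["Cortical"])
    assert cort.K == pytest.approx(13.611 * GPA, rel=1e-3)
    assert cort.G == pytest.approx(5.568 * GPA, rel=1e-3)
    cu = derived_moduli(registry["Cu"])
    assert cu.K == pytest.approx(116.04 * GPA, rel=1e-3)
    assert cu.G == pytest.approx(41.57 * GPA, rel=1e-3)
    assert cu.cp == pytest.approx(4377.0, rel=1e-3)


def test_zero_poisson_limit():
    m = Material(name="x", rho=1000, E=1e9, nu=1e-9)
    assert m.K == pytest.approx(m.E / 3.0, rel=1e-6)
    assert m.G == pytest.approx(m.E / 2.0, rel=1e-6)


@settings(derandomize=True, max_examples=50)
@given(
    E=st.floats(1e6, 1e12),
    nu=st.floats(0.01, 0.49),
)
def test_modulus_identity_closure(E, nu):
    """E = 9KG/(3K+G) holds for the derived moduli (isotropy closure)."""
    m = Material(name="h", rho=1000, E=E, nu=nu)
    dm = derived_moduli(m)
    assert E == pytest.approx(9 * dm.K * dm.G / (3 * dm.K + dm.G), rel=1e-12)


def test_biot_constants_reference_values(registry, fluid):
    alpha, M = biot_constants(registry["Cancellous"], fluid)
    assert alpha == pytest.approx(0.7840, abs=1e-4)
    assert M == pytest.approx(3.364 * GPA, rel=1e-3)
    alpha_c, _ = biot_constants(registry["Cortical"], fluid)
    assert alpha_c == pytest.approx(0.1994, abs=1e-4)


def test_biot_soft_skeleton_limit(fluid):
    soft = Material(name="s", rho=1000, E=1e3, nu=0.3, Ks=1e9, theta=0.5)
    alpha, _ = biot_constants(soft, fluid)
    assert alpha == pytest.approx(1.0, abs=1e-5)


def test_all_tissues_have_physical_biot_constants(registry, fluid):
    for name, mat in registry.items():
        if not mat.porous:
            continue
        alpha, M = biot_constants(mat, fluid)
        assert 0.0 < alpha <= 1.0
        assert M > 0.0
    # micro-homogeneity (alpha >= porosity) holds for the mineralized
    # tissues and granulation; the soft-tissue rows sit slightly below it
    for name in ("Dentin", "Cortical", "Cancellous", "Granulation"):
        alpha, _ = biot_constants(registry[name], fluid)
        assert alpha >= registry[name].theta


@pytest.mark.parametrize(
    "row, match",
    [
        (dict(rho=1000, E=1.0, nu=0.6, Ks=2.0, theta=0.5, k_perm=0.0), "Poisson"),
        (dict(rho=1000, E=30.0, nu=0.3, Ks=2.0, theta=0.5, k_perm=0.0), "exceeds grain"),
        (dict(rho=1000, E=1.0, nu=0.3, theta=0.5, k_perm=0.0), "missing field"),
        (dict(rho=-5, E=1.0, nu=0.3, Ks=2.0, theta=0.5, k_perm=0.0), "density"),
    ],
)
def test_invalid_rows_name_the_material(row, match):
    with pytest.raises(MaterialError, match="bad-row"):
        load_material_table({"bad-row": row})
    with pytest.raises(MaterialError, match=match):
        load_material_table({"bad-row": row})


def test_material_table_from_yaml(tmp_path):
    path = tmp_path / "mats.yaml"
    path.write_text(
        "Cortical: {rho: 1850, E: 14.7, nu: 0.32, Ks: 17.0, theta: 0.04, k_perm: 1.0e-20}\n"
        "Ti: {rho: 4500, E: 107.1, nu: 0.31, sigma_y: 800.0}\n"
    )
    table = load_material_table(path)
    assert table["Cortical"].E == pytest.approx(14.7e9)
    assert table["Ti"].sigma_y == pytest.approx(800e6)
    assert not table["Ti"].porous


class TestPhaseMaterialMap:
    def test_phase1_shell_is_primary_matrix(self):
        assert phase_material_map(1)["shell"] == "Primary matrix"
        assert "fibrous_interface" not in phase_material_map(1)

    def test_phase2_has_fibrous_interface(self):
        m = phase_material_map(2)
        assert m["shell"] == "Granulation"
        assert m["fibrous_interface"] == "Fibrous"

    def test_phase3_woven_bone_with_optional_interface(self):
        assert phase_material_map(3)["shell"] == "Woven bone"
        assert phase_material_map(3)["fibrous_interface"] == "Fibrous"
        assert phase_material_map(3, fibrous_interface=False)["fibrous_interface"] == "Woven bone"

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            phase_material_map(4)


def test_fluid_defaults_are_salt_water(fluid):
    assert fluid.Kf == pytest.approx(2.4e9)
    assert fluid.rho_f == pytest.approx(1000.0)
    assert fluid.eta_f == pytest.approx(1e-3)
    with pytest.raises(MaterialError):
        Fluid(Kf=-1.0)
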