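import dataclasses

import numpy as np
import pytest

from osseowave.geometry import (
    GeometryError,
    ModelSpec,
    Region,
    applicator_plate_size,
    build_model,
    build_packing,
    classify_tissue_points,
    fcc_lattice,
    shell_zone_mask,
)


def test_fcc_site_count_two_cells():
    """An FCC lattice has 4 sites per conventional cell (half-open box)."""
    d = 500e-6
    a = d * np.sqrt(2)
    sites = fcc_lattice((2 * a, 2 * a, 2 * a), d)
    assert len(sites) == 32


def test_interior_coordination_and_minimum_distance(benchmark_model):
    m = benchmark_model
    counts = np.bincount(m.pairs.ravel(), minlength=m.n_elements)
    assert counts.max() == 12
    assert (counts == 12).mean() > 0.5
    assert m.r0.min() >= 0.95 * m.spec.d


def test_region_labels_partition(benchmark_model):
    m = benchmark_model
    _, counts = np.unique(m.regions, return_counts=True)
    assert counts.sum() == m.n_elements
    for expected in (Region.GINGIVA, Region.CORTICAL, Region.CANCELLOUS,
                     Region.IMPLANT, Region.SHELL, Region.APPLICATOR, Region.BASE):
        assert np.any(m.regions == int(expected))


def test_layer_classification_by_depth():
    spec = ModelSpec()
    z_top = spec.Lz - 1e-4
    pts = np.array([
        [0.3e-3, 0.3e-3, z_top - 0.2e-3],    # 0.2 mm below the surface
        [0.3e-3, 0.3e-3, z_top - 0.7e-3],    # inside the cortical slab
        [0.3e-3, 0.3e-3, z_top - 2.0e-3],    # cancellous
    ])
    labels = classify_tissue_points(pts, spec, z_top)
    assert labels.tolist() == [Region.GINGIVA, Region.CORTICAL, Region.CANCELLOUS]


def test_peri_implant_gap_spans_declared_radii():
    spec = ModelSpec()
    z_top = spec.Lz - 1e-4
    xc, yc = spec.Lx / 2, spec.Ly / 2
    pts = np.array([
        [xc + 2.2e-3, yc, z_top - 2e-3],   # inside the 2.0-2.5 mm gap
        [xc + 1.5e-3, yc, z_top - 2e-3],   # implant body
        [xc + 2.8e-3, yc, z_top - 2e-3],   # outside the shell
    ])
    labels = classify_tissue_points(pts, spec, z_top)
    assert labels[0] == Region.SHELL
    assert labels[1] == Region.IMPLANT
    assert labels[2] != Region.SHELL


class TestShellZone:
    def test_phase1_zone_equals_shell(self, benchmark_model):
        zone = shell_zone_mask(benchmark_model)
        assert set(benchmark_model.regions[zone]) == {int(Region.SHELL)}

    def test_phase2_zone_includes_fibrous_interface(self):
        model = build_model(ModelSpec(phase=2))
        zone = shell_zone_mask(model)
        present = set(model.regions[zone].tolist())
        assert int(Region.FIBROUS_INTERFACE) in present
        assert int(Region.SHELL) in present

    def test_zone_disjoint_from_implant(self, benchmark_model):
        zone = shell_zone_mask(benchmark_model)
        assert not np.any(benchmark_model.regions[zone] == int(Region.IMPLANT))


def test_build_is_deterministic():
    a = build_model(ModelSpec())
    b = build_model(ModelSpec())
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.pairs, b.pairs)
    assert np.array_equal(a.material_id, b.material_id)
    assert np.array_equal(a.material_weights, b.material_weights)


def test_refinement_scales_element_count():
    """Halving the diameter multiplies the element count by roughly 8."""
    spec = ModelSpec(Lx=4e-3, Ly=4e-3, Lz=4e-3, include_applicator=False)
    coarse, _, _ = build_packing(spec)
    fine, _, _ = build_packing(dataclasses.replace(spec, d=spec.d / 2))
    ratio = len(fine) / len(coarse)
    assert 6.0 < ratio < 10.0


def test_volume_bookkeeping(benchmark_model):
    m = benchmark_model
    tissue = ~m.region_mask(Region.APPLICATOR)
    vol = tissue.sum() * m.element_volume
    block = m.spec.Lx * m.spec.Ly * m.spec.Lz
    assert vol == pytest.approx(block, rel=0.03)


class TestApplicator:
    def test_scaled_plate_half_block_face(self):
        spec = ModelSpec()
        size, scaled = applicator_plate_size(spec)
        assert scaled
        assert size == pytest.approx(3e-3)

    def test_full_scale_plate_when_it_fits(self):
        spec = ModelSpec(Lx=10e-3, Ly=10e-3, Lz=10e-3)
        size, scaled = applicator_plate_size(spec)
        assert not scaled
        assert size == pytest.approx(7e-3)

    def test_offset_plate_has_no_bonded_contact(self):
        spec = ModelSpec(applicator_offset=ModelSpec().d)
        model = build_model(spec)
        app = model.region_mask(Region.APPLICATOR)
        i, j = model.pairs[:, 0], model.pairs[:, 1]
        crossing = app[i] != app[j]
        assert not crossing.any()

    def test_bonded_plate_starts_strain_free(self, benchmark_model):
        m = benchmark_model
        app = m.region_mask(Region.APPLICATOR)
        i, j = m.pairs[:, 0], m.pairs[:, 1]
        crossing = (app[i] != app[j])
        assert crossing.any()
        assert np.all(m.r0[crossing] <= 1.05 * m.spec.d)


def test_partial_volume_weights_are_normalized(benchmark_model):
    W = benchmark_model.material_weights
    np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(W >= 0)


def test_block_too_small_rejected():
    with pytest.raises(GeometryError, match="smaller than"):
        build_packing(ModelSpec(Lx=1e-3, Ly=6e-3, Lz=8e-3))


def test_invalid_spec_rejected():
    with pytest.raises(GeometryError):
        ModelSpec(shell_outer_radius=1e-3)  # smaller than the implant radius
    with pytest.raises(GeometryError):
        ModelSpec(gingiva_thickness=5e-3, cortical_thickness=4e-3)


def test_teeth_must_fit_in_block():
    with pytest.raises(GeometryError, match="teeth"):
        build_model(ModelSpec(include_teeth=True))
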