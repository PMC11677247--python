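"""Synthetic model geometry: FCC particle packing and region labels.

The study geometry is a layered tissue block (gingiva on top, then cortical
bone, then cancellous bone) penetrated by a cylindrical titanium implant.
The implant sits inside a peri-implant shell — the healing gap whose tissue
follows the osseointegration phase — and a copper applicator plate is bonded
to the +X face of the block to deliver shock wave pulses.  The lowest layer
of elements is the fixed base.

Elements are packed on a face-centred-cubic lattice with nearest-neighbour
distance equal to the element diameter ``d`` (conventional cell edge
``a = d*sqrt(2)``, 4 sites per cell, coordination number 12).  The packing
is deterministic for a fixed spec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Region",
    "ModelSpec",
    "Model",
    "GeometryError",
    "fcc_lattice",
    "build_packing",
    "label_regions",
    "make_applicator",
    "shell_zone_mask",
    "build_model",
]

NEIGHBOR_TOL = 1.05  # neighbour cut-off in units of d


class GeometryError(ValueError):
    """Raised for infeasible geometry specifications."""


class Region(IntEnum):
    GINGIVA = 0
    CORTICAL = 1
    CANCELLOUS = 2
    IMPLANT = 3
    SHELL = 4
    FIBROUS_INTERFACE = 5
    APPLICATOR = 6
    DENTIN = 7
    PDL = 8
    BASE = 9

    @property
    def label(self) -> str:
        return _REGION_LABELS[self]


_REGION_LABELS = {
    Region.GINGIVA: "gingiva",
    Region.CORTICAL: "cortical",
    Region.CANCELLOUS: "cancellous",
    Region.IMPLANT: "implant",
    Region.SHELL: "shell",
    Region.FIBROUS_INTERFACE: "fibrous_interface",
    Region.APPLICATOR: "applicator",
    Region.DENTIN: "dentin",
    Region.PDL: "pdl",
    Region.BASE: "base",
}


@dataclass(frozen=True)
class ModelSpec:
    """Geometry parameters of the scaled benchmark model (SI meters).

    Defaults give the 6 x 6 x 8 mm desk-scale benchmark: full-scale layer
    thicknesses (gingiva 0.4 mm, cortical 0.6 mm), full-scale implant radius
    (2 mm) and peri-implant shell (outer radius 2.5 mm, i.e. a 0.5 mm gap),
    and an applicator plate scaled proportionally to the block.
    """

    Lx: float = 6e-3
    Ly: float = 6e-3
    Lz: float = 8e-3
    d: float = 500e-6
    gingiva_thickness: float = 400e-6
    cortical_thickness: float = 600e-6
    implant_radius: float = 2.0e-3
    implant_length: float = 6.0e-3
    shell_outer_radius: float = 2.5e-3
    fibrous_thickness: float = 250e-6
    applicator_size: float = 7e-3
    applicator_thickness: float = 300e-6
    applicator_offset: float = 0.0    # extra gap between plate and tissue face
    include_applicator: bool = True
    include_teeth: bool = False
    phase: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise GeometryError("element diameter must be positive")
        if self.shell_outer_radius <= self.implant_radius:
            raise GeometryError("shell outer radius must exceed implant radius")
        if self.gingiva_thickness + self.cortical_thickness >= self.Lz:
            raise GeometryError("tissue layers do not fit inside the block height")
        if self.phase not in (1, 2, 3):
            raise GeometryError(f"unknown phase {self.phase}")

    @property
    def a(self) -> float:
        """Conventional FCC cell edge."""
        return self.d * np.sqrt(2.0)

    @property
    def element_volume(self) -> float:
        """Lattice volume per element, a^3 / 4 = d^3 / sqrt(2)."""
        return self.a**3 / 4.0


@dataclass
class Model:
    """Particle packing with region labels, material names and pair topology."""

    spec: ModelSpec
    positions: np.ndarray        # (N, 3) m
    regions: np.ndarray          # (N,) Region codes
    material_names: list[str]    # unique material names, indexed by material_id
    material_id: np.ndarray      # (N,) int
    pairs: np.ndarray            # (M, 2) int, i < j
    r0: np.ndarray               # (M,) reference pair distance
    applicator_scaled: bool = False
    material_weights: np.ndarray | None = None  # (N, n_mat) partial volumes

    @property
    def n_elements(self) -> int:
        return len(self.positions)

    @property
    def d(self) -> float:
        return self.spec.d

    @property
    def element_volume(self) -> float:
        return self.spec.element_volume

    @property
    def contact_area(self) -> float:
        # A_pair = V_el / (2 d): with branch length r/2 and coordination 12
        # this makes the contact homogenization exactly consistent
        # (q * A * Z / 3 = V_el), so a uniform pair stress maps to the same
        # uniform element stress.
        return self.element_volume / (2.0 * self.spec.d)

    def region_mask(self, *regions: Region) -> np.ndarray:
        return np.isin(self.regions, [int(r) for r in regions])


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

_FCC_OFFSETS = np.array(
    [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
)


def fcc_lattice(box: tuple[float, float, float], d: float) -> np.ndarray:
    """All FCC sites with coordinates in the half-open box [0, L) per axis."""
    a = d * np.sqrt(2.0)
    nx, ny, nz = (int(np.ceil(L / a)) + 1 for L in box)
    cells = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    sites = (cells[:, None, :] + _FCC_OFFSETS[None, :, :]).reshape(-1, 3) * a
    eps = 1e-9 * a
    inside = np.all(sites < np.asarray(box) - eps, axis=1) & np.all(sites > -eps, axis=1)
    sites = sites[inside]
    order = np.lexsort((sites[:, 0], sites[:, 1], sites[:, 2]))
    return np.ascontiguousarray(sites[order])


def _neighbor_pairs(positions: np.ndarray, d: float) -> tuple[np.ndarray, np.ndarray]:
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r=NEIGHBOR_TOL * d, output_type="ndarray")
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    r0 = np.linalg.norm(positions[pairs[:, 1]] - positions[pairs[:, 0]], axis=1)
    return pairs, r0


def build_packing(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FCC packing of the tissue block (+ applicator slab space).

    Returns ``(positions, pairs, r0)``.  Deterministic for a fixed spec.
    """
    if min(spec.Lx, spec.Ly, spec.Lz) < 3 * spec.d:
        raise GeometryError(
            f"block {spec.Lx:g} x {spec.Ly:g} x {spec.Lz:g} m is smaller than "
            f"3 diameters ({3 * spec.d:g} m) in at least one axis"
        )
    positions = fcc_lattice((spec.Lx, spec.Ly, spec.Lz), spec.d)
    if spec.include_applicator:
        positions = np.vstack([positions, make_applicator(spec)[0]])
    pairs, r0 = _neighbor_pairs(positions, spec.d)
    return positions, pairs, r0


# ---------------------------------------------------------------------------
# applicator
# ---------------------------------------------------------------------------

def applicator_plate_size(spec: ModelSpec) -> tuple[float, bool]:
    """Plate edge length; scaled runs shrink the plate to half the block face."""
    full = spec.applicator_size
    if full <= min(spec.Ly, spec.Lz):
        return full, False
    return min(spec.Ly, spec.Lz) / 2.0, True


def make_applicator(spec: ModelSpec) -> tuple[np.ndarray, bool]:
    """Element positions of the Cu applicator plate on the +X side.

    The plate continues the tissue FCC lattice beyond the +X face so that
    bonded pairs across the interface carry zero strain initially; an
    ``applicator_offset`` > 0 shifts the plate away (a gap of one diameter
    leaves no bonded contact at all).  Returns ``(positions, scaled_flag)``.
    """
    size, scaled = applicator_plate_size(spec)
    a = spec.a
    n_planes = max(1, int(round(spec.applicator_thickness / (a / 2.0))))
    if spec.applicator_thickness < spec.d:
        warnings.warn(
            "applicator thinner than one element diameter; using a single "
            "element layer",
            stacklevel=2,
        )
        n_planes = 1
    # lattice continued past the face: generate an extended box and keep
    # the first n_planes beyond Lx
    ext = (spec.Lx + (n_planes + 1) * a, spec.Ly, spec.Lz)
    sites = fcc_lattice(ext, spec.d)
    eps = 1e-9 * a
    beyond = sites[sites[:, 0] > spec.Lx - eps]
    xs = np.unique(np.round(beyond[:, 0] / (a / 4)).astype(int))
    keep_x = set(xs[:n_planes].tolist())
    sel = np.isin(np.round(beyond[:, 0] / (a / 4)).astype(int), list(keep_x))
    plate = beyond[sel]
    # trim to the plate footprint, centred on the implant axis depth-wise
    yc = spec.Ly / 2.0
    zc = spec.Lz - spec.implant_length / 2.0
    half = size / 2.0
    inside = (np.abs(plate[:, 1] - yc) <= half + eps) & (
        np.abs(plate[:, 2] - zc) <= half + eps
    )
    plate = plate[inside]
    if len(plate) == 0:
        raise GeometryError("applicator plate contains no lattice sites")
    plate = plate.copy()
    plate[:, 0] += spec.applicator_offset
    return plate, scaled


# ---------------------------------------------------------------------------
# region labels
# ---------------------------------------------------------------------------

def classify_tissue_points(
    points: np.ndarray, spec: ModelSpec, z_top: float
) -> np.ndarray:
    """Continuum-geometry region of arbitrary points inside the tissue block.

    Top-down along Z: gingiva slab, cortical slab, cancellous below; the
    implant cylinder and its peri-implant shell (plus, for phases 2 and 3,
    the innermost fibrous interface) override the layer labels.  Structural
    labels (base, applicator) are not assigned here.
    """
    pts = np.asarray(points)
    regions = np.empty(len(pts), dtype=np.int64)
    eps = 1e-9 * spec.a
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    depth = z_top - z

    regions[:] = Region.CANCELLOUS
    regions[depth <= spec.gingiva_thickness + eps] = Region.GINGIVA
    cortical = (depth > spec.gingiva_thickness + eps) & (
        depth <= spec.gingiva_thickness + spec.cortical_thickness + eps
    )
    regions[cortical] = Region.CORTICAL

    # implant + shell: radial distance to the implant axis (block centre)
    xc, yc = spec.Lx / 2.0, spec.Ly / 2.0
    rad = np.hypot(x - xc, y - yc)
    # distance to the implant cylindrical volume (side + below-tip cap)
    dz_tip = depth - spec.implant_length
    side = np.maximum(rad - spec.implant_radius, 0.0)
    below = np.maximum(dz_tip, 0.0)
    dist_implant = np.hypot(side, below)
    in_implant = (rad <= spec.implant_radius + eps) & (dz_tip <= eps)
    gap = spec.shell_outer_radius - spec.implant_radius
    in_shell = ~in_implant & (dist_implant <= gap + eps)
    regions[in_shell] = Region.SHELL
    if spec.phase in (2, 3):
        in_fib = ~in_implant & (dist_implant <= spec.fibrous_thickness + eps)
        regions[in_fib] = Region.FIBROUS_INTERFACE
    regions[in_implant] = Region.IMPLANT

    if spec.include_teeth:
        _label_teeth(pts, spec, regions, depth, eps)
    return regions


def tissue_top(positions: np.ndarray, spec: ModelSpec) -> float:
    """Height of the top tissue lattice plane (depth reference)."""
    eps = 1e-9 * spec.a
    x, z = positions[:, 0], positions[:, 2]
    tissue = x <= spec.Lx - eps
    return float(z[tissue].max() if np.any(tissue) else z.max())


def label_regions(positions: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Assign one Region code per element (by element centre).

    The lowest element layer is the fixed base; sites beyond the +X face
    are the applicator.
    """
    pos = np.asarray(positions)
    eps = 1e-9 * spec.a
    regions = classify_tissue_points(pos, spec, tissue_top(pos, spec))
    # base: lowest element layer, fixed throughout the simulation
    z = pos[:, 2]
    regions[z <= z.min() + spec.a / 4.0] = Region.BASE
    # applicator plate: sites beyond the tissue +X face
    regions[pos[:, 0] > spec.Lx - eps] = Region.APPLICATOR
    return regions


def material_volume_weights(
    positions: np.ndarray,
    regions: np.ndarray,
    spec: ModelSpec,
    material_map: dict[str, str],
    name_to_id: dict[str, int],
    n_samples: int = 3,
) -> np.ndarray:
    """Partial-volume material weights per element, (N, n_materials).

    Each element's cubic volume cell is supersampled on an
    ``n_samples^3`` grid and every sample point is classified against the
    continuum geometry; the weights are the sample fractions.  This
    anti-aliases sub-element tissue boundaries (thin layers, the implant
    tip cap), so the realized geometry no longer depends on how the
    lattice planes happen to straddle them.  Applicator elements stay
    pure.
    """
    pos = np.asarray(positions)
    n = len(pos)
    h = spec.element_volume ** (1.0 / 3.0)
    grid = (np.arange(n_samples) + 0.5) / n_samples - 0.5
    offsets = np.stack(
        np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1
    ).reshape(-1, 3) * h
    z_top = tissue_top(pos, spec)
    eps = 1e-9 * spec.a
    weights = np.zeros((n, len(name_to_id)))
    structural = (regions == int(Region.APPLICATOR))
    lut = np.full(max(int(r) for r in Region) + 1, -1, dtype=np.int64)
    for r in Region:
        name = material_map.get(r.label)
        if name is not None:
            lut[int(r)] = name_to_id[name]
    region_mat_id = lut[regions]
    lo = pos[~structural].min(axis=0)
    hi = pos[~structural].max(axis=0)
    rows = np.arange(n)
    for off in offsets:
        pts = np.clip(pos + off, lo, hi)  # keep samples inside the tissue box
        mid = lut[classify_tissue_points(pts, spec, z_top)]
        np.add.at(weights, (rows, mid), 1.0)
    weights /= len(offsets)
    # structural elements keep their centre material exactly
    weights[structural] = 0.0
    weights[structural, region_mat_id[structural]] = 1.0
    _sharpen_radial_metal(weights, pos, regions, spec, material_map, name_to_id)
    return weights


def _sharpen_radial_metal(
    weights: np.ndarray,
    pos: np.ndarray,
    regions: np.ndarray,
    spec: ModelSpec,
    material_map: dict[str, str],
    name_to_id: dict[str, int],
) -> None:
    """Sharpen the implant side wall by per-plane equal-area dithering.

    A metal/tissue volume blend misrepresents a 100-GPa-vs-sub-GPa
    interface in both the Voigt and the Reuss direction, so elements that
    straddle the *side wall* of the implant cylinder are snapped to pure
    metal or pure tissue.  The snap is dithered per lattice plane: exactly
    enough sites become metal to match the true partial metal area (to
    half a cell), which removes the O(d) bias and most of the plane-
    alignment jitter of a fixed 50% threshold.  Elements under the implant
    footprint (the tip cap, an interface normal to the axis) keep their
    blend: the Reuss average is the correct series response there.
    Modifies ``weights`` in place.
    """
    metal_names = {"Ti-6Al-4V", "Cu"} & set(name_to_id)
    metal_ids = [name_to_id[n] for n in metal_names if n in name_to_id]
    implant_id = name_to_id.get(material_map.get("implant", ""), None)
    if implant_id is None:
        return
    w_metal = weights[:, metal_ids].sum(axis=1) if metal_ids else None
    if w_metal is None:
        return
    mixed = (w_metal > 1e-9) & (w_metal < 1.0 - 1e-9)
    mixed &= regions != int(Region.APPLICATOR)
    if not mixed.any():
        return
    xc, yc = spec.Lx / 2.0, spec.Ly / 2.0
    rad = np.hypot(pos[:, 0] - xc, pos[:, 1] - yc)
    h = spec.element_volume ** (1.0 / 3.0)
    radial = mixed & (rad > spec.implant_radius - h / 2.0)  # side-wall straddlers
    if not radial.any():
        return
    plane = np.round(pos[:, 2] / (spec.a / 4.0)).astype(np.int64)
    idx = np.flatnonzero(radial)
    for p in np.unique(plane[idx]):
        sel = idx[plane[idx] == p]
        target = w_metal[sel].sum()
        k = int(round(target))
        order = sel[np.argsort(-w_metal[sel], kind="stable")]
        to_metal, to_tissue = order[:k], order[k:]
        weights[to_metal] = 0.0
        weights[to_metal, implant_id] = 1.0
        if len(to_tissue):
            weights[np.ix_(to_tissue, np.array(metal_ids))] = 0.0
            norm = weights[to_tissue].sum(axis=1, keepdims=True)
            small = norm[:, 0] <= 1e-12
            if small.any():
                # fully-metal-sampled tissue element: fall back to its label
                fall = to_tissue[small]
                lut_ids = np.array(
                    [name_to_id[material_map[Region(int(r)).label]] for r in regions[fall]]
                )
                weights[fall] = 0.0
                weights[fall, lut_ids] = 1.0
                norm = weights[to_tissue].sum(axis=1, keepdims=True)
            weights[to_tissue] /= norm


def _label_teeth(pos, spec, regions, depth, eps) -> None:
    """Optional simplified teeth: dentin cylinders with a thin PDL shell."""
    tooth_r = 1.5e-3
    pdl_t = 0.2e-3
    xc = spec.Lx / 2.0
    span = spec.shell_outer_radius + pdl_t + tooth_r + 2 * spec.d
    for yc in (spec.Ly / 2.0 - span, spec.Ly / 2.0 + span):
        if yc - tooth_r - pdl_t < 0 or yc + tooth_r + pdl_t > spec.Ly:
            raise GeometryError("teeth do not fit inside the block")
        rad = np.hypot(pos[:, 0] - xc, pos[:, 1] - yc)
        in_root = (rad <= tooth_r + pdl_t + eps) & (depth <= spec.implant_length + eps)
        in_dentin = (rad <= tooth_r + eps) & (depth <= spec.implant_length + eps)
        regions[in_root] = Region.PDL
        regions[in_dentin] = Region.DENTIN


def shell_zone_mask(model: Model) -> np.ndarray:
    """Indices of the peri-implant zone (shell + fibrous interface).

    This is the zone over which all tissue-fate volume fractions are
    computed.
    """
    mask = model.region_mask(Region.SHELL, Region.FIBROUS_INTERFACE)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise GeometryError("peri-implant zone is empty")
    return idx


# ---------------------------------------------------------------------------
# full model assembly
# ---------------------------------------------------------------------------

def build_model(
    spec: ModelSpec,
    material_map: dict[str, str] | None = None,
    partial_volumes: bool = True,
) -> Model:
    """Build packing, labels and material assignment for one phase.

    With ``partial_volumes`` (default) boundary-straddling elements carry
    volume-fraction material weights so that sub-element tissue layers are
    represented without lattice aliasing; region labels remain discrete.
    """
    from .materials import phase_material_map

    positions, pairs, r0 = build_packing(spec)
    regions = label_regions(positions, spec)
    if material_map is None:
        material_map = phase_material_map(spec.phase)

    present = sorted({Region(int(r)).label for r in np.unique(regions)})
    missing = [lab for lab in present if lab not in material_map]
    if missing:
        raise GeometryError(f"no material assigned for region(s) {missing}")
    names = sorted(set(material_map.values()))
    name_to_id = {n: i for i, n in enumerate(names)}
    material_id = np.array(
        [name_to_id[material_map[Region(int(r)).label]] for r in regions],
        dtype=np.int64,
    )
    weights = None
    if partial_volumes:
        weights = material_volume_weights(
            positions, regions, spec, material_map, name_to_id
        )
    _, scaled = applicator_plate_size(spec)
    return Model(
        spec=spec,
        positions=positions,
        regions=regions,
        material_names=names,
        material_id=material_id,
        pairs=pairs,
        r0=r0,
        applicator_scaled=scaled and spec.include_applicator,
        material_weights=weights,
    )
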