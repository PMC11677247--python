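"""Explicit-dynamics particle mechanics core.

Elements are bonded spheres on an FCC lattice.  Pair kinematics are
total-Lagrangian: the normal strain is the relative change of the centre
distance, and the shear strain is the relative tangential displacement of
the two material points that initially coincided at the contact, divided by
the reference distance.  Because the contact material points are convected
with the element rotations, rigid-body motion of the whole model produces
exactly zero pair strains.

The pair response is a many-body closure: each element's side of a pair
responds with

    sigma_n(i) = 2 G_i eps_n + (1 - 2 G_i / (3 K_i)) sigma_eff_i

where ``sigma_eff_i`` is the element's effective mean stress, evaluated as
K_i tr(eps_i) from the current geometry-corrected strain homogenization,
and the pair value couples the two sides in series (harmonic mixing).  In
the uniform affine limit this closure reproduces isotropic linear
elasticity exactly (sigma_mean = K tr eps is also the fixed point of the
equivalent stress-feedback form).
The transmitted (total) normal stress subtracts the pair pore-fluid stress
alpha*P, so the homogenized element stress is the total stress of Biot
theory.

Motion is integrated with velocity Verlet (translations) and an explicit
update of angular velocity and accumulated rotation with sphere inertia.
Sign conventions: stress tension-positive, pore pressure positive in
compression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .geometry import Model, Region
from .materials import Fluid, Material, derived_moduli

__all__ = [
    "ElementMaterials",
    "PairReference",
    "PairStrains",
    "pair_kinematics",
    "pair_response",
    "pair_forces",
    "accumulate",
    "element_stress",
    "element_strain",
    "mean_stress",
    "von_mises",
    "plastic_return",
    "stable_dt",
    "damping",
    "Simulator",
]

# symmetric tensor storage order
_VOIGT = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


# ---------------------------------------------------------------------------
# per-element material arrays
# ---------------------------------------------------------------------------

@dataclass
class ElementMaterials:
    """Material constants gathered per element."""

    rho: np.ndarray
    G: np.ndarray
    K: np.ndarray
    alpha: np.ndarray
    M: np.ndarray
    k_perm: np.ndarray
    sigma_y: np.ndarray   # inf where no yield stress (tissues)
    porous: np.ndarray    # bool
    cp: np.ndarray

    @classmethod
    def from_model(
        cls,
        model: Model,
        registry: dict[str, Material],
        fluid: Fluid | None = None,
    ) -> "ElementMaterials":
        """Gather (and, when the model carries partial-volume weights,
        blend) material constants per element.

        Blending rules for boundary-straddling elements: Reuss (harmonic)
        averages for the elastic moduli K and G (sub-element interfaces act
        in series), volume averages for density, Biot coefficient,
        permeability and the storage compliance 1/M (extensive per unit
        volume); the yield stress follows the majority material.
        """
        fluid = fluid or Fluid()
        n_mat = len(model.material_names)
        cols = {k: np.zeros(n_mat) for k in ("rho", "G", "K", "alpha", "M", "k_perm", "cp")}
        sigma_y = np.full(n_mat, np.inf)
        porous = np.zeros(n_mat, dtype=bool)
        for i, name in enumerate(model.material_names):
            try:
                mat = registry[name]
            except KeyError:
                raise KeyError(f"material {name!r} missing from registry") from None
            dm = derived_moduli(mat, fluid)
            cols["rho"][i] = mat.rho
            cols["G"][i] = dm.G
            cols["K"][i] = dm.K
            cols["alpha"][i] = dm.alpha
            cols["M"][i] = dm.M
            cols["k_perm"][i] = mat.k_perm
            cols["cp"][i] = dm.cp
            porous[i] = mat.porous
            if mat.sigma_y is not None:
                sigma_y[i] = mat.sigma_y
        W = model.material_weights
        if W is None:
            mid = model.material_id
            return cls(
                rho=cols["rho"][mid],
                G=cols["G"][mid],
                K=cols["K"][mid],
                alpha=cols["alpha"][mid],
                M=cols["M"][mid],
                k_perm=cols["k_perm"][mid],
                sigma_y=sigma_y[mid],
                porous=porous[mid],
                cp=cols["cp"][mid],
            )
        # Reuss (series) averages for the tissue-tissue blends: the thin
        # layer boundaries these resolve lie normal to the occlusal load
        K = 1.0 / (W @ (1.0 / cols["K"]))
        G = 1.0 / (W @ (1.0 / cols["G"]))
        rho = W @ cols["rho"]
        alpha = W @ cols["alpha"]
        inv_M = np.where(porous, 1.0 / np.where(cols["M"] > 0, cols["M"], 1.0), 0.0)
        inv_M_eff = W @ inv_M
        M = np.where(inv_M_eff > 0, 1.0 / np.maximum(inv_M_eff, 1e-300), 0.0)
        k_perm = W @ cols["k_perm"]
        majority = np.argmax(W, axis=1)
        return cls(
            rho=rho,
            G=G,
            K=K,
            alpha=np.where(inv_M_eff > 0, alpha, 0.0),
            M=M,
            k_perm=k_perm,
            sigma_y=sigma_y[majority],
            porous=inv_M_eff > 0,
            cp=np.sqrt((K + 4.0 * G / 3.0) / rho),
        )


# ---------------------------------------------------------------------------
# pair kinematics
# ---------------------------------------------------------------------------

@dataclass
class PairReference:
    """Reference (build-time) pair data."""

    pairs: np.ndarray   # (M, 2)
    r0: np.ndarray      # (M,)
    b: np.ndarray       # (M, 3) vector from element i to the reference contact

    @classmethod
    def from_model(cls, model: Model) -> "PairReference":
        i, j = model.pairs[:, 0], model.pairs[:, 1]
        b = 0.5 * (model.positions[j] - model.positions[i])
        return cls(pairs=model.pairs, r0=model.r0.copy(), b=b)


@dataclass
class PairStrains:
    eps_n: np.ndarray   # (M,) normal strain, tension positive
    gamma: np.ndarray   # (M, 3) shear strain vector (tangent plane)
    n: np.ndarray       # (M, 3) current unit normal i -> j
    r: np.ndarray       # (M,) current centre distance
    u_rel: np.ndarray   # (M, 3) relative displacement of contact material points


def pair_kinematics(
    positions: np.ndarray,
    rotations: np.ndarray,
    ref: PairReference,
) -> PairStrains:
    """Normal and shear pair strains from positions and accumulated rotations.

    ``rotations`` is an (N, 3, 3) array of per-element rotation matrices
    (identity when elements have not rotated).
    """
    i, j = ref.pairs[:, 0], ref.pairs[:, 1]
    dx = positions[j] - positions[i]
    r = np.linalg.norm(dx, axis=1)
    if np.any(r == 0.0):
        raise FloatingPointError("coincident elements (pair distance zero)")
    n = dx / r[:, None]
    eps_n = (r - ref.r0) / ref.r0
    # contact material points convected with each element
    p_i = positions[i] + np.einsum("mab,mb->ma", rotations[i], ref.b)
    p_j = positions[j] - np.einsum("mab,mb->ma", rotations[j], ref.b)
    u_rel = p_j - p_i
    u_t = u_rel - np.einsum("ma,ma->m", u_rel, n)[:, None] * n
    gamma = u_t / ref.r0[:, None]
    return PairStrains(eps_n=eps_n, gamma=gamma, n=n, r=r, u_rel=u_rel)


# ---------------------------------------------------------------------------
# pair response (many-body MCA closure)
# ---------------------------------------------------------------------------

def pair_response(
    strains: PairStrains,
    pairs: np.ndarray,
    emat: ElementMaterials,
    sigma_eff_mean: np.ndarray,
    alpha_P: np.ndarray,
    plastic_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair normal (total) stress and shear stress vector.

    ``sigma_eff_mean`` is the per-element effective mean stress (tension
    positive); ``alpha_P`` is alpha*P per element (pore stress, positive
    in compression).  Returns ``(sigma_n, tau)`` where ``sigma_n`` is the
    transmitted total normal stress.
    """
    i, j = pairs[:, 0], pairs[:, 1]
    a_i, a_j = 2.0 * emat.G[i], 2.0 * emat.G[j]
    H = 2.0 * a_i * a_j / (a_i + a_j)  # harmonic (series) normal stiffness
    c_i = 1.0 - a_i / (3.0 * emat.K[i])
    c_j = 1.0 - a_j / (3.0 * emat.K[j])
    coupling = 0.5 * H * (
        c_i * sigma_eff_mean[i] / a_i + c_j * sigma_eff_mean[j] / a_j
    )
    sigma_n_eff = H * strains.eps_n + coupling
    tau = H[:, None] * strains.gamma
    if plastic_scale is not None:
        s_pair = np.minimum(plastic_scale[i], plastic_scale[j])
        tau = tau * s_pair[:, None]
    sigma_n = sigma_n_eff - 0.5 * (alpha_P[i] + alpha_P[j])
    return sigma_n, tau


def pair_forces(
    strains: PairStrains,
    sigma_n: np.ndarray,
    tau: np.ndarray,
    area: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Force on element i from each pair, and the (shared) contact torque.

    Tension (sigma_n > 0) pulls i toward j.  The tangential force acts at
    the contact point, a lever of r/2 from each centre; both elements
    receive the same torque.  ``area`` may be scalar or per pair.
    """
    A = np.asarray(area)
    if A.ndim == 1:
        A = A[:, None]
    F = A * (sigma_n[:, None] * strains.n + tau)
    F_t = A * tau
    lever = 0.5 * strains.r
    torque = lever[:, None] * np.cross(strains.n, F_t)
    return F, torque


def pair_area_weights(
    pairs: np.ndarray,
    positions: np.ndarray,
    r0: np.ndarray,
    d: float,
    n_elements: int,
    w_min: float = 0.5,
    w_max: float = 3.0,
) -> np.ndarray:
    """Directional surface quadrature weights for the pair contact areas.

    An element with the full FCC coordination transmits a uniform stress
    exactly with A = V/(2d); surface elements with missing bonds
    under-transmit in the missing directions.  Per element a symmetric
    weight tensor S is fitted so that

        sum_j r^2 (n . S n) n (x) n  =  4 d^2 I

    (the full-coordination value; the interior solution is S = I), and the
    pair area weight is the mean of its two sides' n.S.n, clipped to
    [w_min, w_max].  This restores the transmitted traction at free
    surfaces direction by direction, rather than uniformly inflating all
    bonds of a deficient element.
    """
    i, j = pairs[:, 0], pairs[:, 1]
    n_vec = (positions[j] - positions[i]) / r0[:, None]
    phi = np.stack(
        [n_vec[:, 0] ** 2, n_vec[:, 1] ** 2, n_vec[:, 2] ** 2,
         n_vec[:, 0] * n_vec[:, 1], n_vec[:, 0] * n_vec[:, 2],
         n_vec[:, 1] * n_vec[:, 2]],
        axis=1,
    )
    D = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
    outer = (r0**2)[:, None, None] * np.einsum("mc,me->mce", phi, phi * D[None, :])
    A_mat = np.zeros((n_elements, 6, 6))
    np.add.at(A_mat, i, outer)
    np.add.at(A_mat, j, outer)
    b = np.zeros(6)
    b[:3] = 4.0 * d**2
    s = np.einsum("nce,e->nc", np.linalg.pinv(A_mat, rcond=1e-8), b)
    side_i = (phi * D[None, :] * s[i]).sum(axis=1)
    side_j = (phi * D[None, :] * s[j]).sum(axis=1)
    return np.clip(0.5 * (side_i + side_j), w_min, w_max)


def accumulate(values: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Sum per-pair values onto elements (vectorized scatter-add)."""
    if values.ndim == 1:
        return np.bincount(idx, weights=values, minlength=n)
    ncol = values.shape[1]
    flat_idx = (np.arange(ncol)[:, None] * n + idx[None, :]).ravel()
    out = np.bincount(flat_idx, weights=values.T.ravel(), minlength=n * ncol)
    return out.reshape(ncol, n).T


def _sym_outer(n_vec: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Symmetrized outer product n (x) w in Voigt order, per pair."""
    out = np.empty((len(n_vec), 6))
    for c, (a, b) in enumerate(_VOIGT):
        out[:, c] = 0.5 * (n_vec[:, a] * w[:, b] + n_vec[:, b] * w[:, a])
    return out


def element_stress(
    pairs: np.ndarray,
    strains: PairStrains,
    F_pair: np.ndarray,
    volume: float,
    n_elements: int,
) -> np.ndarray:
    """Homogenized symmetric stress tensor per element, Voigt (N, 6).

    sigma_ab = (1/V) sum_j (r/2) sym(n_a F_b); both pair endpoints receive
    the same contribution ((-n) (x) (-F) = n (x) F).
    """
    w = (0.5 * strains.r / volume)[:, None] * F_pair
    contrib = _sym_outer(strains.n, w)
    i, j = pairs[:, 0], pairs[:, 1]
    return accumulate(contrib, i, n_elements) + accumulate(contrib, j, n_elements)


def element_strain(
    pairs: np.ndarray,
    strains: PairStrains,
    r0: np.ndarray,
    area: float,
    volume: float,
    n_elements: int,
) -> np.ndarray:
    """Homogenized small-strain tensor per element, Voigt (N, 6).

    Uses the same contact homogenization as the stress, applied to the
    relative displacements of the contact material points; recovers the
    affine strain exactly in the uniform limit.
    """
    w = (0.5 * area * strains.r / (volume * r0))[:, None] * strains.u_rel
    contrib = _sym_outer(strains.n, w)
    i, j = pairs[:, 0], pairs[:, 1]
    return accumulate(contrib, i, n_elements) + accumulate(contrib, j, n_elements)


def mean_stress(sigma6: np.ndarray) -> np.ndarray:
    """Mean (hydrostatic) stress, tension positive."""
    return sigma6[..., :3].sum(axis=-1) / 3.0


def von_mises(sigma6: np.ndarray) -> np.ndarray:
    sxx, syy, szz, sxy, sxz, syz = (sigma6[..., c] for c in range(6))
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + sxz**2 + syz**2)
    )


def equivalent_strain(eps6: np.ndarray) -> np.ndarray:
    """Von Mises equivalent (distortional) strain of the deviator."""
    tr = eps6[..., :3].sum(axis=-1) / 3.0
    e = eps6.copy()
    e[..., :3] -= tr[..., None]
    exx, eyy, ezz, exy, exz, eyz = (e[..., c] for c in range(6))
    return np.sqrt(
        (2.0 / 3.0) * (exx**2 + eyy**2 + ezz**2 + 2.0 * (exy**2 + exz**2 + eyz**2))
    )


def plastic_return(sigma6: np.ndarray, sigma_y: np.ndarray) -> np.ndarray:
    """Radial return: scale the stress deviator to the yield surface.

    Elements whose von Mises stress exceeds their yield stress get their
    deviatoric stress scaled by sigma_y / vonMises; the mean stress is
    unchanged.  Elements without a yield stress (sigma_y = inf) are never
    rescaled.
    """
    arr = np.asarray(sigma6, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    vm = von_mises(arr)
    sy = np.broadcast_to(np.asarray(sigma_y, dtype=float), vm.shape)
    scale = np.where(vm > sy, sy / np.maximum(vm, 1e-300), 1.0)
    sm = mean_stress(arr)
    out = arr * scale[:, None]
    out[:, :3] += (sm * (1.0 - scale))[:, None]
    return out[0] if single else out


def plastic_scale_factors(sigma6: np.ndarray, sigma_y: np.ndarray) -> np.ndarray:
    vm = von_mises(sigma6)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        s = np.where(vm > sigma_y, sigma_y / np.maximum(vm, 1e-300), 1.0)
    return s


# ---------------------------------------------------------------------------
# timestep, damping
# ---------------------------------------------------------------------------

def stable_dt(model: Model, emat: ElementMaterials, C: float = 0.2) -> float:
    """Explicit timestep dt = C d / max(cp) over materials present."""
    if C <= 0:
        raise ValueError("Courant factor C must be positive")
    return C * model.spec.d / float(emat.cp.max())


def damping(forces: np.ndarray, velocities: np.ndarray, c: float) -> np.ndarray:
    """Non-viscous local (Cundall) damping.

    Each force component is reduced by the fraction ``c`` of its magnitude
    in the direction opposing the velocity:  F -> F - c |F| sign(v).
    """
    if c < 0 or c >= 1:
        raise ValueError("damping coefficient must lie in [0, 1)")
    if c == 0.0:
        return forces
    return forces - c * np.abs(forces) * np.sign(velocities)


def _rodrigues(omega_dt: np.ndarray) -> np.ndarray:
    """Rotation matrices for per-element rotation vectors (N, 3)."""
    theta = np.linalg.norm(omega_dt, axis=1)
    out = np.tile(np.eye(3), (len(omega_dt), 1, 1))
    nz = theta > 0
    if not np.any(nz):
        return out
    axis = omega_dt[nz] / theta[nz, None]
    s, c = np.sin(theta[nz]), np.cos(theta[nz])
    K = np.zeros((nz.sum(), 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axis[:, 2], axis[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axis[:, 2], -axis[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axis[:, 1], axis[:, 0]
    out[nz] = (
        c[:, None, None] * np.eye(3)
        + s[:, None, None] * K
        + (1 - c)[:, None, None] * np.einsum("ma,mb->mab", axis, axis)
    )
    return out


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

@dataclass
class Simulator:
    """Time-stepping state machine over a bonded Model.

    Boundary conditions: ``fixed_mask`` elements never move; a
    ``prescribed_velocity`` callback ``f(t) -> (mask, (3,) or (n,3) velocity)``
    overrides the velocities of a moving set each step (rigid applicator or
    loaded top plane).  Pore-fluid coupling is explicit with automatic
    diffusion sub-cycling; ``drained_mask`` elements are held at P = 0.
    """

    model: Model
    emat: ElementMaterials
    fluid: Fluid = field(default_factory=Fluid)
    damping_coeff: float = 0.0
    dt_factor: float = 0.2
    fixed_mask: np.ndarray | None = None
    prescribed_velocity: Callable[[float], tuple[np.ndarray, np.ndarray]] | None = None
    drained_mask: np.ndarray | None = None
    poro_enabled: bool = True
    external_force: np.ndarray | None = None   # (N, 3) constant applied force
    component_fixed: np.ndarray | None = None  # (N, 3) bool, per-axis constraints

    def __post_init__(self) -> None:
        m = self.model
        n = m.n_elements
        self.time = 0.0
        self.dt = stable_dt(m, self.emat, self.dt_factor)
        self.pos = m.positions.copy()
        self.vel = np.zeros((n, 3))
        self.omega = np.zeros((n, 3))
        self.rot = np.tile(np.eye(3), (n, 1, 1))
        self.acc = np.zeros((n, 3))
        self.acc_rot = np.zeros((n, 3))
        self.P = np.zeros(n)
        self._sigma = np.zeros((n, 6))
        self._sigma_mean = np.zeros(n)
        self._stress_dirty = False
        self.plastic_scale = np.ones(n)
        self.ref = PairReference.from_model(m)
        self.A_pair = m.contact_area * pair_area_weights(
            m.pairs, m.positions, m.r0, m.spec.d, n
        )
        self.mass = self.emat.rho * m.element_volume
        self.inertia = 0.4 * self.mass * (m.spec.d / 2.0) ** 2
        if self.fixed_mask is None:
            self.fixed_mask = m.region_mask(Region.BASE)
        self._strains: PairStrains | None = None
        self._force: np.ndarray = np.zeros((n, 3))
        self._init_geo_tensor()
        if self.poro_enabled:
            self._init_poro()
        self._treps_prev: np.ndarray | None = None
        self._compute_forces()

    def _init_geo_tensor(self) -> None:
        """Inverse pair-geometry tensor Geo_i = sum_j r0^2 n0 (x) n0.

        tr(Geo^-1 sym(L Geo)) = tr(L) for any L, which makes the mean
        stress and volumetric-strain-rate estimators exact for uniform
        fields even on surface elements with incomplete neighbour sets.
        """
        m = self.model
        i, j = m.pairs[:, 0], m.pairs[:, 1]
        n0 = (m.positions[j] - m.positions[i]) / self.ref.r0[:, None]
        outer = np.einsum("ma,mb->mab", n0, n0) * (self.ref.r0**2)[:, None, None]

        def inv6(weights: np.ndarray | None) -> np.ndarray:
            w = outer if weights is None else outer * weights[:, None, None]
            geo = np.zeros((m.n_elements, 3, 3))
            np.add.at(geo, i, w)
            np.add.at(geo, j, w)
            inv = np.linalg.pinv(geo)
            # Voigt storage, off-diagonals doubled: tr(Geo^-1 E) = sum inv6_c E6_c
            return np.stack(
                [inv[:, 0, 0], inv[:, 1, 1], inv[:, 2, 2],
                 2.0 * inv[:, 0, 1], 2.0 * inv[:, 0, 2], 2.0 * inv[:, 1, 2]],
                axis=1,
            )

        # kinematic tensor (strain estimators) and area-weighted tensor
        # (mean-stress estimator; the pair areas carry surface quadrature
        # weights)
        self._geo_inv6 = inv6(None)
        self._geo_force_inv6 = inv6(self.A_pair / m.contact_area)

    # -- poro -------------------------------------------------------------

    def _init_poro(self) -> None:
        from .poro import pair_transmissibility

        m = self.model
        i, j = m.pairs[:, 0], m.pairs[:, 1]
        self.T_pair = pair_transmissibility(
            self.emat.k_perm[i],
            self.emat.k_perm[j],
            self.emat.porous[i] & self.emat.porous[j],
            self.A_pair,
            self.ref.r0,
            m.element_volume,
            self.fluid.eta_f,
        )
        n = m.n_elements
        T_row = accumulate(self.T_pair, i, n) + accumulate(self.T_pair, j, n)
        with np.errstate(over="ignore"):
            rate_max = float(np.max(self.emat.M * T_row, initial=0.0))
        self.dt_diff_limit = 0.5 / rate_max if rate_max > 0 else np.inf
        self.n_subcycles = max(1, int(np.ceil(self.dt / self.dt_diff_limit)))

    def volumetric_strain_rate(self) -> np.ndarray:
        """Per-element volumetric strain rate from centre velocities.

        Uses the pair-geometry-corrected estimator
        tr(M_i^{-1} sum_j r sym(v_rel (x) n)), exact for affine velocity
        fields on arbitrary (including surface) neighbour sets.
        """
        m = self.model
        i, j = m.pairs[:, 0], m.pairs[:, 1]
        st = self._strains
        v_rel = self.vel[j] - self.vel[i]
        contrib = st.r[:, None] * _sym_outer(st.n, v_rel)
        E6 = accumulate(contrib, i, m.n_elements) + accumulate(contrib, j, m.n_elements)
        return np.einsum("nc,nc->n", self._geo_inv6, E6)

    def _update_pore_pressure(self) -> None:
        """Darcy exchange on the step clock (storage is handled inside the
        force evaluation from the strain increment)."""
        from .poro import pore_pressure_rate

        m = self.model
        zero = np.zeros(m.n_elements)
        dt_sub = self.dt / self.n_subcycles
        for _ in range(self.n_subcycles):
            dP = pore_pressure_rate(
                self.P, zero, m.pairs, self.T_pair, self.emat.alpha, self.emat.M
            )
            self.P = self.P + dt_sub * dP
        self.P[~self.emat.porous] = 0.0
        if self.drained_mask is not None:
            self.P[self.drained_mask] = 0.0

    # -- forces -----------------------------------------------------------

    def volumetric_strain(self) -> np.ndarray:
        """Per-element volumetric strain tr(eps) from the current pair state.

        Same geometry-corrected estimator as the strain rate; exact for
        affine displacement fields on arbitrary neighbour sets.
        """
        m = self.model
        i, j = m.pairs[:, 0], m.pairs[:, 1]
        st = self._strains
        contrib = st.r[:, None] * _sym_outer(st.n, st.u_rel)
        E6 = accumulate(contrib, i, m.n_elements) + accumulate(contrib, j, m.n_elements)
        return np.einsum("nc,nc->n", self._geo_inv6, E6)

    def _compute_forces(self) -> None:
        m = self.model
        st = pair_kinematics(self.pos, self.rot, self.ref)
        self._strains = st
        # many-body coupling evaluated from the current volumetric strain:
        # the effective mean stress is K tr(eps) in the uniform limit, and
        # using the instantaneous value (rather than the homogenized stress
        # of the previous step) keeps the force a direct function of the
        # configuration -- a delayed feedback would pump the stiff modes.
        self._treps = self.volumetric_strain()
        sigma_eff_mean = self.emat.K * self._treps
        if self.poro_enabled and self._treps_prev is not None:
            # undrained storage response applied with the current strain
            # increment: the pore stiffness must not lag the configuration
            # (a one-step-delayed alpha*P term pumps the stiff modes of
            # high-alpha^2*M tissues just like a lagged stress would)
            self.P = self.P - self.emat.M * self.emat.alpha * (
                self._treps - self._treps_prev
            )
            self.P[~self.emat.porous] = 0.0
            if self.drained_mask is not None:
                self.P[self.drained_mask] = 0.0
        self._treps_prev = self._treps
        alpha_P = self.emat.alpha * self.P
        sigma_n, tau = pair_response(
            st, m.pairs, self.emat, sigma_eff_mean, alpha_P, self.plastic_scale
        )
        F_pair, torque = pair_forces(st, sigma_n, tau, self.A_pair)
        if not np.all(np.isfinite(F_pair)):
            raise FloatingPointError("non-finite pair force (unstable run?)")
        i, j = m.pairs[:, 0], m.pairs[:, 1]
        n = m.n_elements
        F = accumulate(F_pair, i, n) - accumulate(F_pair, j, n)
        T = accumulate(torque, i, n) + accumulate(torque, j, n)
        if self.external_force is not None:
            F = F + self.external_force
        self._force_raw = F
        F = damping(F, self.vel, self.damping_coeff)
        T = damping(T, self.omega, self.damping_coeff)
        self._F_pair = F_pair
        self._stress_dirty = True
        self._force = F
        self.acc = F / self.mass[:, None]
        self.acc_rot = T / self.inertia[:, None]

    def _update_stress(self) -> None:
        """Homogenize element stress (lazy: only when sigma is read).

        Also refreshes the radial-return plastic scale factors; with the
        default sampling cadence this keeps plasticity checks a few steps
        behind the force loop, which is immaterial for metals loaded far
        below yield.
        """
        m = self.model
        st = self._strains
        self._sigma = element_stress(m.pairs, st, self._F_pair, m.element_volume,
                                     m.n_elements)
        # geometry-corrected mean stress: sigma accumulates (r/2V) sym(nF),
        # and tr(Geo^-1 sum r sym(nF)) = 2V tr(Geo^-1 sigma)
        tr = np.einsum("nc,nc->n", self._geo_force_inv6, self._sigma)
        self._sigma_mean = (
            2.0 * m.element_volume * m.spec.d / (3.0 * m.contact_area)
        ) * tr
        self.plastic_scale = plastic_scale_factors(self._sigma, self.emat.sigma_y)
        self._stress_dirty = False

    @property
    def sigma(self) -> np.ndarray:
        """Per-element stress tensors, Voigt (N, 6)."""
        if self._stress_dirty:
            self._update_stress()
        return self._sigma

    @property
    def sigma_mean(self) -> np.ndarray:
        """Per-element mean stress (tension positive, geometry-corrected)."""
        if self._stress_dirty:
            self._update_stress()
        return self._sigma_mean

    # -- boundary conditions ----------------------------------------------

    def _apply_bc(self) -> None:
        self.vel[self.fixed_mask] = 0.0
        self.omega[self.fixed_mask] = 0.0
        self.acc[self.fixed_mask] = 0.0
        self.acc_rot[self.fixed_mask] = 0.0
        if self.prescribed_velocity is not None:
            mask, v = self.prescribed_velocity(self.time)
            self.vel[mask] = v
            self.omega[mask] = 0.0
            self.acc[mask] = 0.0
            self.acc_rot[mask] = 0.0
        if self.component_fixed is not None:
            self.vel[self.component_fixed] = 0.0
            self.acc[self.component_fixed] = 0.0

    # -- stepping ----------------------------------------------------------

    def step(self, n_steps: int = 1) -> None:
        """Advance by velocity-Verlet (kick-drift-kick) steps."""
        dt = self.dt
        for _ in range(n_steps):
            self._apply_bc()
            self.vel += 0.5 * dt * self.acc
            self.omega += 0.5 * dt * self.acc_rot
            self._apply_bc()
            self.pos += dt * self.vel
            moving = np.any(self.omega != 0.0, axis=1)
            if np.any(moving):
                dR = _rodrigues(self.omega[moving] * dt)
                self.rot[moving] = np.einsum("mab,mbc->mac", dR, self.rot[moving])
            self.time += dt
            self._compute_forces()
            if self.poro_enabled:
                self._update_pore_pressure()
            self.vel += 0.5 * dt * self.acc
            self.omega += 0.5 * dt * self.acc_rot
            self._apply_bc()

    # -- measurements ------------------------------------------------------

    def reaction_force(self, mask: np.ndarray) -> np.ndarray:
        """Total internal (undamped) force on an element set, N."""
        return self._force_raw[mask].sum(axis=0)

    def strain_tensors(self) -> np.ndarray:
        m = self.model
        return element_strain(
            m.pairs, self._strains, self.ref.r0, m.contact_area,
            m.element_volume, m.n_elements,
        )

    def shear_strain_intensity(self) -> np.ndarray:
        return equivalent_strain(self.strain_tensors())

    def pair_shear_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self._strains.gamma, axis=1)

    def kinetic_energy(self) -> float:
        ke = 0.5 * np.sum(self.mass * np.einsum("na,na->n", self.vel, self.vel))
        ke += 0.5 * np.sum(self.inertia * np.einsum("na,na->n", self.omega, self.omega))
        return float(ke)

    def elastic_energy(self) -> float:
        """Pair elastic energy (exact potential for nu = 0 materials)."""
        st = self._strains
        i, j = self.model.pairs[:, 0], self.model.pairs[:, 1]
        a_i, a_j = 2.0 * self.emat.G[i], 2.0 * self.emat.G[j]
        H = 2.0 * a_i * a_j / (a_i + a_j)
        A, r0 = self.A_pair, self.ref.r0
        u = 0.5 * A * r0 * H * (st.eps_n**2 + np.einsum("ma,ma->m", st.gamma, st.gamma))
        return float(u.sum())
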