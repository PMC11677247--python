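"""Biot pore-fluid coupling.

Each porous element carries one pore pressure P (Pa, positive in
compression).  P evolves with the volumetric strain rate of the skeleton
and inter-element Darcy exchange:

    dP_i/dt = M_i ( -alpha_i d(eps_vol)_i/dt + sum_j T_ij (P_j - P_i) )

with the two-point-flux transmissibility

    T_ij = (k_harm / eta_f) * A_pair / (L_ij * V_el)

where ``k_harm`` is the harmonic mean of the two intrinsic permeabilities.
Pairs touching a metal element (impermeable implant or applicator) have
T = 0.  The pressure feeds back into the skeleton through the effective
mean stress sigma_eff = sigma_total + alpha P (tension-positive stress,
compression-positive pressure).

Integration is explicit on the mechanical clock; the Simulator sub-cycles
the diffusion operator automatically when dt exceeds the explicit
diffusion stability limit 0.5 / max(M_i sum_j T_ij).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "harmonic_permeability",
    "pair_transmissibility",
    "pore_pressure_rate",
    "effective_mean_stress",
    "consolidation_coefficient",
    "terzaghi_pressure",
]


def harmonic_permeability(k_i: np.ndarray, k_j: np.ndarray) -> np.ndarray:
    """Harmonic mean permeability of a pair (series flow)."""
    k_i, k_j = np.asarray(k_i, dtype=float), np.asarray(k_j, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        kh = 2.0 * k_i * k_j / (k_i + k_j)
    return np.where(k_i + k_j > 0, kh, 0.0)


def pair_transmissibility(
    k_i: np.ndarray,
    k_j: np.ndarray,
    both_porous: np.ndarray,
    area: float,
    L: np.ndarray,
    volume: float,
    eta_f: float,
) -> np.ndarray:
    """T_ij = (k_harm/eta) A / (L V); zero unless both elements are porous."""
    kh = harmonic_permeability(k_i, k_j)
    T = (kh / eta_f) * area / (np.asarray(L) * volume)
    return np.where(np.asarray(both_porous, dtype=bool), T, 0.0)


def pore_pressure_rate(
    P: np.ndarray,
    evol_rate: np.ndarray,
    pairs: np.ndarray,
    T_pair: np.ndarray,
    alpha: np.ndarray,
    M: np.ndarray,
) -> np.ndarray:
    """dP/dt per element from storage and Darcy exchange."""
    i, j = pairs[:, 0], pairs[:, 1]
    flux = T_pair * (P[j] - P[i])  # into i, positive
    n = len(P)
    exchange = np.bincount(i, weights=flux, minlength=n) - np.bincount(
        j, weights=flux, minlength=n
    )
    return M * (-alpha * evol_rate + exchange)


def effective_mean_stress(
    sigma_mean_total: np.ndarray, alpha: np.ndarray, P: np.ndarray
) -> np.ndarray:
    """sigma_eff = sigma_total + alpha P (tension-positive sigma, compression-positive P)."""
    return sigma_mean_total + alpha * P


# ---------------------------------------------------------------------------
# analytic benchmarks
# ---------------------------------------------------------------------------

def consolidation_coefficient(
    K: float, G: float, alpha: float, M: float, k_perm: float, eta_f: float
) -> float:
    """One-dimensional consolidation coefficient c_v.

    c_v = (k/eta) (K + 4G/3) M / ((K + 4G/3) + alpha^2 M)
    """
    Ku = K + 4.0 * G / 3.0
    return (k_perm / eta_f) * Ku * M / (Ku + alpha**2 * M)


def terzaghi_pressure(
    z: np.ndarray, t: float, H: float, c_v: float, p0: float, n_terms: int = 200
) -> np.ndarray:
    """Terzaghi series solution for a column drained at z = 0, sealed at z = H.

    ``z`` is depth below the drained surface; ``p0`` the initial (undrained)
    excess pore pressure.  Returns P(z, t).
    """
    z = np.asarray(z, dtype=float)
    acc = np.zeros_like(z)
    for m in range(n_terms):
        lam = (2 * m + 1) * np.pi / (2.0 * H)
        acc += (
            (4.0 / ((2 * m + 1) * np.pi))
            * np.sin(lam * z)
            * np.exp(-(lam**2) * c_v * t)
        )
    return p0 * acc
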