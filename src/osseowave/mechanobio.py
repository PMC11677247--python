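"""Mechanobiological classification of per-element mechanical state.

Threshold rules map the local mean (hydrostatic) stress, shear strain and
pore-fluid pressure to tissue-differentiation fates:

* ``quiescent``   — |sigma| below 3 kPa: neither chondrogenesis nor
  osteogenesis occurs.
* ``osteogenic``  — stress magnitude between 3 kPa and 0.15 MPa with shear
  strain up to 5%: osteoblast differentiation, intramembranous ossification.
* ``fibrogenic``  — tensile stress above 0.15 MPa (0.7 MPa most favorable),
  or sub-threshold stress with shear above 5%: fibroblast differentiation.
* ``chondrogenic`` — compressive stress between 0.15 and 2 MPa:
  chondrocyte differentiation, endochondral ossification (high shear
  strengthens this fate).
* ``overload``    — compressive stress beyond 2 MPa.

Cell transport is driven by the interstitial fluid pressure: 20 kPa to
2 MPa is sufficient for migration, with 68 kPa the most favorable value
(the optimal band is a configurable factor, default x2, around it).
A distortional-strain band 0.05-1.1% (0.5% optimum) is reported as an
auxiliary fibro/cartilage-favoring flag, not a primary fate.

Stress is tension-positive; pore pressure positive in compression.
Boundaries are closed on the osteogenic side.  Zone statistics follow the
study procedure: count elements of each fate inside the peri-implant zone,
divide by the zone size, average over the sampling window, and floor
reported fractions below 5%.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "Fate",
    "Transport",
    "Thresholds",
    "FateReport",
    "classify_fate",
    "classify_transport",
    "distortion_flag",
    "zone_fractions",
]


class Fate(IntEnum):
    QUIESCENT = 0
    OSTEOGENIC = 1
    CHONDROGENIC = 2
    FIBROGENIC = 3
    OVERLOAD = 4

    @property
    def label(self) -> str:
        return self.name.lower()


class Transport(IntEnum):
    NONE = 0
    SUFFICIENT = 1
    OPTIMAL = 2


@dataclass(frozen=True)
class Thresholds:
    """Mechanobiological thresholds (SI: Pa, strain as fraction)."""

    osteo_min: float = 3e3            # below: quiescent
    osteo_max: float = 0.15e6         # osteogenic stress ceiling
    osteo_compress_max: float = 0.15e6  # compressive osteogenic ceiling (config: 0.2e6)
    chondro_max: float = 2e6          # compressive chondrogenic ceiling
    shear_split: float = 0.05         # 5% shear strain
    fibro_tension_min: float = 0.15e6
    fibro_tension_opt: float = 0.7e6
    transport_min: float = 20e3
    transport_max: float = 2e6
    transport_opt: float = 68e3
    transport_opt_factor: float = 2.0
    distortion_lo: float = 0.0005     # 0.05%
    distortion_hi: float = 0.011      # 1.1%
    distortion_opt: float = 0.005     # 0.5%

    def __post_init__(self) -> None:
        if not self.osteo_min < self.osteo_max < self.chondro_max:
            raise ValueError("need osteo_min < osteo_max < chondro_max")
        if not self.transport_min < self.transport_opt < self.transport_max:
            raise ValueError("need transport_min < transport_opt < transport_max")


def classify_fate(
    sigma_mean: np.ndarray,
    shear_strain: np.ndarray,
    thresholds: Thresholds | None = None,
) -> np.ndarray:
    """Tissue-differentiation fate per element.

    ``sigma_mean`` tension-positive (Pa); ``shear_strain`` as a fraction.
    Decision order: quiescent below 3 kPa in magnitude; overload beyond
    2 MPa compression; fibrogenic above 0.15 MPa tension; then shear > 5%
    gates the chondro/fibro fates while shear <= 5% gates osteogenesis up
    to the (configurable) compressive ceiling, with larger compression
    still chondrogenic.
    """
    th = thresholds or Thresholds()
    s = np.asarray(sigma_mean, dtype=float)
    g = np.asarray(shear_strain, dtype=float)
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(g))):
        raise ValueError("non-finite classifier inputs")
    out = np.full(s.shape, int(Fate.QUIESCENT), dtype=np.int64)

    active = np.abs(s) >= th.osteo_min
    overload = active & (s < -th.chondro_max)
    fibro_tension = active & (s > th.fibro_tension_min)
    high_shear = g > th.shear_split

    # shear <= 5%: osteogenic while |sigma| within the osteogenic band
    osteo = (
        active
        & ~high_shear
        & (s <= th.osteo_max)
        & (s >= -th.osteo_compress_max)
    )
    # compression beyond the osteogenic ceiling (up to 2 MPa): chondrogenic
    chondro_lo = active & ~high_shear & (s < -th.osteo_compress_max) & (s >= -th.chondro_max)
    # shear > 5%: compression -> chondrogenic, tension -> fibrogenic
    chondro_hi = active & high_shear & (s <= 0) & (s >= -th.chondro_max)
    fibro_shear = active & high_shear & (s > 0) & (s <= th.fibro_tension_min)
    # tension between osteo_max and fibro_tension_min with low shear
    # (non-empty only when the two ceilings are configured apart)
    fibro_mid = active & ~high_shear & (s > th.osteo_max) & (s <= th.fibro_tension_min)

    out[osteo] = Fate.OSTEOGENIC
    out[chondro_lo | chondro_hi] = Fate.CHONDROGENIC
    out[fibro_tension | fibro_shear | fibro_mid] = Fate.FIBROGENIC
    out[overload] = Fate.OVERLOAD
    return out


def classify_transport(
    P: np.ndarray, thresholds: Thresholds | None = None
) -> np.ndarray:
    """Cell-transport flag from pore-fluid pressure (compression-positive Pa)."""
    th = thresholds or Thresholds()
    P = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(P)):
        raise ValueError("non-finite pore pressure")
    out = np.full(P.shape, int(Transport.NONE), dtype=np.int64)
    sufficient = (P >= th.transport_min) & (P <= th.transport_max)
    out[sufficient] = Transport.SUFFICIENT
    f = th.transport_opt_factor
    optimal = sufficient & (P >= th.transport_opt / f) & (P <= th.transport_opt * f)
    out[optimal] = Transport.OPTIMAL
    return out


def distortion_flag(
    shear_strain: np.ndarray, thresholds: Thresholds | None = None
) -> np.ndarray:
    """Auxiliary fibro/cartilage-favoring flag: distortional strain in band."""
    th = thresholds or Thresholds()
    g = np.asarray(shear_strain, dtype=float)
    return (g >= th.distortion_lo) & (g <= th.distortion_hi)


def osteogenic_compressive_boundary(
    thresholds: Thresholds | None = None,
    shear_strain: float = 0.01,
    tol: float = 1.0,
) -> float:
    """Compressive mean-stress magnitude (Pa) at which an element leaves
    the osteogenic fate, located by bisection to ``tol`` Pa.

    The bracket spans the activity floor to beyond the chondrogenic
    ceiling; the classifier is evaluated as a black box.
    """
    th = thresholds or Thresholds()

    def is_osteo(mag: float) -> bool:
        return classify_fate(np.array([-mag]), np.array([shear_strain]), th)[0] == int(
            Fate.OSTEOGENIC
        )

    lo, hi = th.osteo_min, 2.0 * th.chondro_max
    if not is_osteo(lo):
        raise ValueError("lower bracket is not osteogenic")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if is_osteo(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class FateReport:
    """Time-averaged peri-implant zone statistics.

    ``fractions`` has one row per fate label plus transport/distortion
    rows; the ``reported`` column floors values under ``report_floor`` to
    the string ``"<5%"`` as in the study's reporting convention.
    """

    fractions: pd.DataFrame
    n_zone: int
    n_samples: int
    report_floor: float = 0.05

    def fraction(self, label: str) -> float:
        return float(self.fractions.loc[label, "mean_fraction"])


def zone_fractions(
    fate_samples: np.ndarray,
    transport_samples: np.ndarray,
    zone_idx: np.ndarray,
    distortion_samples: np.ndarray | None = None,
    report_floor: float = 0.05,
) -> FateReport:
    """Per-zone volume fractions averaged over the sampling window.

    ``fate_samples``/``transport_samples`` are (T, N) label arrays over T
    time samples; ``zone_idx`` indexes the peri-implant zone.  Per sample,
    fraction = count(label in zone) / |zone|; the reported value is the
    time mean, with fractions below the floor rendered ``"<5%"``.
    """
    fate_samples = np.atleast_2d(fate_samples)
    transport_samples = np.atleast_2d(transport_samples)
    if fate_samples.shape[0] < 1:
        raise ValueError("need at least one time sample")
    zone_idx = np.asarray(zone_idx)
    if zone_idx.size == 0:
        raise ValueError("empty peri-implant zone")
    nz = zone_idx.size
    zf = fate_samples[:, zone_idx]
    zt = transport_samples[:, zone_idx]

    rows: dict[str, float] = {}
    for fate in Fate:
        rows[fate.label] = float(np.mean((zf == int(fate)).sum(axis=1) / nz))
    rows["transport_sufficient"] = float(
        np.mean((zt >= int(Transport.SUFFICIENT)).sum(axis=1) / nz)
    )
    rows["transport_optimal"] = float(
        np.mean((zt == int(Transport.OPTIMAL)).sum(axis=1) / nz)
    )
    if distortion_samples is not None:
        zd = np.atleast_2d(distortion_samples)[:, zone_idx]
        rows["distortion_band"] = float(np.mean(zd.sum(axis=1) / nz))

    df = pd.DataFrame(
        {"mean_fraction": pd.Series(rows, dtype=float)}
    )
    df["reported"] = [
        "<5%" if v < report_floor else f"{100 * v:.1f}%" for v in df["mean_fraction"]
    ]
    return FateReport(
        fractions=df,
        n_zone=int(nz),
        n_samples=int(fate_samples.shape[0]),
        report_floor=report_floor,
    )
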