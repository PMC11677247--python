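"""Study orchestration: build -> load -> simulate -> classify -> report.

The drivers here are the scaled analogues of the study workflow: a
physiological benchmark (displacement ramp to a target occlusal force,
secant stiffness, convergence over discretizations) and shock wave
scenarios (pulse train at a given energy flux density, peri-implant fate
and transport statistics).  Every run is deterministic for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mechanobio
from .engine import ElementMaterials, Simulator
from .geometry import Model, ModelSpec, Region, build_model, shell_zone_mask
from .loading import ESWTProtocol, PhysioProtocol, applicator_waveform
from .materials import Fluid, Material, default_materials
from .mechanobio import Thresholds, zone_fractions

__all__ = [
    "RunConfig",
    "ScenarioResult",
    "PhysioResult",
    "make_simulator",
    "run_eswt",
    "run_physio",
    "run_scenario",
    "stiffness",
    "convergence_study",
    "write_fields",
    "read_vtk_points",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration of one scenario run."""

    spec: ModelSpec = field(default_factory=ModelSpec)
    protocol: str = "eswt"                 # "eswt" | "physio"
    efd_list: tuple[float, ...] = (0.02, 0.15, 0.26)
    target_list: tuple[float, ...] = (100.0, 200.0)
    cadence: int = 10                      # steps between field samples
    seed: int = 0
    outdir: str | None = None
    damping: float | None = None           # default: 0 for ESWT, 0.05 physio
    write_snapshots: bool = False

    def __post_init__(self) -> None:
        if self.protocol not in ("eswt", "physio"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.cadence < 1:
            raise ValueError("cadence must be >= 1")

    @property
    def damping_resolved(self) -> float:
        if self.damping is not None:
            return self.damping
        return 0.0 if self.protocol == "eswt" else 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spec = ModelSpec(**raw.pop("geometry", {}))
        kwargs = {}
        for key in ("protocol", "cadence", "seed", "outdir", "damping", "write_snapshots"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if "efd_list" in raw:
            kwargs["efd_list"] = tuple(raw.pop("efd_list"))
        if "target_list" in raw:
            kwargs["target_list"] = tuple(raw.pop("target_list"))
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(spec=spec, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spec"] = dataclasses.asdict(self.spec)
        return d


# ---------------------------------------------------------------------------
# simulator assembly
# ---------------------------------------------------------------------------

def make_simulator(
    spec: ModelSpec,
    registry: dict[str, Material] | None = None,
    fluid: Fluid | None = None,
    damping: float = 0.0,
) -> tuple[Model, Simulator]:
    registry = registry or default_materials()
    fluid = fluid or Fluid()
    model = build_model(spec)
    emat = ElementMaterials.from_model(model, registry, fluid)
    sim = Simulator(model=model, emat=emat, fluid=fluid, damping_coeff=damping)
    return model, sim


def _top_mask(model: Model) -> np.ndarray:
    """Top boundary plane of the tissue block (loaded set for physio runs)."""
    pos = model.positions
    tissue = ~model.region_mask(Region.APPLICATOR)
    z_top = pos[tissue, 2].max()
    return tissue & (pos[:, 2] >= z_top - model.spec.a / 4.0)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Artifacts of one shock-wave scenario."""

    config_label: str
    report: mechanobio.FateReport
    max_shell_pair_shear: float          # fraction
    max_compressive_stress: float        # Pa, magnitude of most-compressive mean stress
    times: np.ndarray
    samples: dict[str, np.ndarray]       # per-sample (T, N) field arrays
    model: Model


def run_eswt(
    spec: ModelSpec,
    efd: float,
    registry: dict[str, Material] | None = None,
    protocol: ESWTProtocol | None = None,
    thresholds: Thresholds | None = None,
    cadence: int = 10,
    tail_periods: float = 0.0,
) -> ScenarioResult:
    """Shock wave pulse train on the model; classify the peri-implant zone.

    Records, at the sampling cadence, the per-element mean stress, shear
    strain intensity and pore pressure, classifies them, and additionally
    tracks the running maximum of the pair shear strain over pairs incident
    to the peri-implant shell (every step).
    """
    registry = registry or default_materials()
    protocol = protocol or ESWTProtocol(efd=efd)
    if protocol.efd != efd:
        raise ValueError("protocol EFD disagrees with the efd argument")
    model, sim = make_simulator(spec, registry, damping=0.0)
    cu = registry["Cu"]
    V = protocol.peak_velocity(cu)

    app_mask = model.region_mask(Region.APPLICATOR)
    if not np.any(app_mask):
        raise ValueError("ESWT scenario requires the applicator plate")

    def prescribe(t: float):
        v = applicator_waveform(t, V, protocol)
        return app_mask, np.array([-v, 0.0, 0.0])  # plate pushes toward the tissue

    sim.prescribed_velocity = prescribe

    zone = shell_zone_mask(model)
    i, j = model.pairs[:, 0], model.pairs[:, 1]
    in_zone = np.zeros(model.n_elements, dtype=bool)
    in_zone[zone] = True
    zone_pairs = in_zone[i] | in_zone[j]

    duration = protocol.duration + tail_periods * protocol.period
    n_steps = int(np.ceil(duration / sim.dt))
    times, fates, transports, distortions = [], [], [], []
    sig_samples, P_samples, shear_samples = [], [], []
    max_pair_shear = 0.0
    max_compress = 0.0
    for step in range(n_steps):
        sim.step()
        gmax = float(sim.pair_shear_magnitude()[zone_pairs].max())
        max_pair_shear = max(max_pair_shear, gmax)
        if step % cadence == 0 or step == n_steps - 1:
            shear = sim.shear_strain_intensity()
            times.append(sim.time)
            sig_samples.append(sim.sigma_mean.copy())
            P_samples.append(sim.P.copy())
            shear_samples.append(shear)
            fates.append(mechanobio.classify_fate(sim.sigma_mean, shear, thresholds))
            transports.append(mechanobio.classify_transport(sim.P, thresholds))
            distortions.append(mechanobio.distortion_flag(shear, thresholds))
            max_compress = max(max_compress, float(-sim.sigma_mean.min()))

    report = zone_fractions(
        np.array(fates), np.array(transports), zone, np.array(distortions)
    )
    return ScenarioResult(
        config_label=f"eswt_efd{efd:g}_phase{spec.phase}",
        report=report,
        max_shell_pair_shear=max_pair_shear,
        max_compressive_stress=max_compress,
        times=np.array(times),
        samples={
            "sigma_mean": np.array(sig_samples),
            "pore_pressure": np.array(P_samples),
            "shear": np.array(shear_samples),
            "fate": np.array(fates),
            "transport": np.array(transports),
        },
        model=model,
    )


@dataclass
class PhysioResult:
    """Force-displacement history of one physiological ramp."""

    config_label: str
    displacement: np.ndarray   # m, downward positive
    force: np.ndarray          # N, reaction on the moving set
    stiffness_kN_mm: float
    report: mechanobio.FateReport
    model: Model
    reached_target: bool = True


def run_physio(
    spec: ModelSpec,
    protocol: PhysioProtocol,
    registry: dict[str, Material] | None = None,
    thresholds: Thresholds | None = None,
    damping: float = 0.05,
) -> PhysioResult:
    """Displacement-controlled ramp to a target occlusal force.

    The top boundary moves down at the protocol velocity while the reaction
    force on the moving set is recorded each step; on reaching the target
    the set is held fixed.  Secant stiffness is evaluated at the target by
    linear interpolation of the crossing.
    """
    registry = registry or default_materials()
    model, sim = make_simulator(spec, registry, damping=damping)
    top = _top_mask(model)

    v = protocol.ramp_velocity
    target = protocol.target_force
    settle_damping = 0.5       # numerical relaxation while the set is held
    tol = 5e-3                 # settled force within 0.5% of the target
    check, window = 50, 250    # settling test cadence / plateau window

    vz_now = -v

    def prescribe(t: float):
        return top, np.array([0.0, 0.0, vz_now])

    sim.prescribed_velocity = prescribe
    z_top0 = float(sim.pos[top, 2].mean())

    def held_u() -> float:
        return z_top0 - float(sim.pos[top, 2].mean())

    def ramp_to(u_stop: float) -> None:
        """Move the top set at the protocol speed to the requested depth."""
        nonlocal vz_now
        sim.damping_coeff = damping
        direction = 1.0 if u_stop >= held_u() else -1.0
        vz_now = -v * direction
        while direction * (u_stop - held_u()) > 0:
            sim.step()
            u = held_u()
            disp.append(u)
            force.append(float(sim.reaction_force(top)[2]))
            if u > protocol.max_displacement:
                raise RuntimeError(
                    f"physiological ramp: target {target} N not reached within "
                    f"{protocol.max_displacement * 1e3:g} mm"
                )
        vz_now = 0.0

    def settle(plateau: float) -> float:
        """Hold the set fixed, relax the inertial transient, return the
        sustained (static) reaction force.

        ``plateau``: required force flatness over the plateau window,
        relative to the target (coarse for intermediate secant iterates,
        tight for the final state).
        """
        sim.damping_coeff = settle_damping
        hist: list[float] = []
        for _ in range(400):
            sim.step(check)
            hist.append(float(sim.reaction_force(top)[2]))
            if len(hist) >= window // check:
                recent = hist[-(window // check):]
                if max(recent) - min(recent) < plateau * target:
                    break
        disp.append(held_u())
        force.append(hist[-1])
        return hist[-1]

    disp, force = [0.0], [0.0]
    # initial ramp: protocol velocity until the instantaneous reaction
    # first crosses the target
    sim.damping_coeff = damping
    while True:
        sim.step()
        u = held_u()
        Fz = float(sim.reaction_force(top)[2])  # interior pushes the set up
        disp.append(u)
        force.append(Fz)
        if Fz >= target:
            break
        if u > protocol.max_displacement:
            raise RuntimeError(
                f"physiological ramp: target {target} N not reached within "
                f"{protocol.max_displacement * 1e3:g} mm (force {Fz:.1f} N)"
            )
    vz_now = 0.0
    # the sustained resistance at held displacement is the static reaction;
    # iterate displacement by secant steps on the (linear) F(u) relation
    coarse = 4 * tol
    u1, F1 = held_u(), settle(coarse)
    S_est = F1 / u1
    reached = False
    for _ in range(12):
        if abs(F1 - target) <= tol * target:
            F1 = settle(tol)  # confirm at the tight plateau tolerance
            u1 = held_u()
            if abs(F1 - target) <= tol * target:
                reached = True
                break
        du = (target - F1) / S_est
        ramp_to(u1 + du)
        u2, F2 = held_u(), settle(coarse)
        if abs(u2 - u1) > 1e-12:
            S_est = (F2 - F1) / (u2 - u1)
        u1, F1 = u2, F2
    if not reached:
        raise RuntimeError("physiological ramp did not converge to the target force")
    sim.damping_coeff = damping
    disp_arr, force_arr = np.array(disp), np.array(force)
    S = stiffness(np.array([F1]), np.array([u1]))

    shear = sim.shear_strain_intensity()
    fate = mechanobio.classify_fate(sim.sigma_mean, shear, thresholds)
    transport = mechanobio.classify_transport(sim.P, thresholds)
    dist = mechanobio.distortion_flag(shear, thresholds)
    report = zone_fractions(fate, transport, shell_zone_mask(model), dist)
    return PhysioResult(
        config_label=f"physio_{protocol.target_force:g}N_phase{spec.phase}",
        displacement=disp_arr,
        force=force_arr,
        stiffness_kN_mm=S,
        report=report,
        model=model,
        reached_target=reached,
    )


# ---------------------------------------------------------------------------
# stiffness + convergence
# ---------------------------------------------------------------------------

_KN_PER_MM = 1e6  # N/m in one kN/mm


def stiffness(force, displacement, target: float | None = None) -> float:
    """Secant stiffness in kN/mm.

    With scalar inputs, simply force/displacement.  With histories, the
    displacement at the target force is interpolated linearly between the
    bracketing samples of the monotone ramp segment.
    """
    f = np.atleast_1d(np.asarray(force, dtype=float))
    u = np.atleast_1d(np.asarray(displacement, dtype=float))
    if f.size == 1:
        if abs(u[0]) < 1e-15:
            raise ZeroDivisionError("displacement is zero")
        if f[0] == 0:
            raise ValueError("zero force carries no stiffness information")
        return float(f[0] / u[0]) / _KN_PER_MM
    if target is None:
        target = f[-1]
    cross = np.nonzero(f >= target)[0]
    if cross.size == 0:
        raise ValueError(f"force history never reaches the target {target} N")
    k = int(cross[0])
    if k == 0 or f[k] == f[k - 1]:
        u_t = u[k]
    else:
        w = (target - f[k - 1]) / (f[k] - f[k - 1])
        u_t = u[k - 1] + w * (u[k] - u[k - 1])
    if u_t <= 0:
        raise ZeroDivisionError("displacement at target is zero")
    return float(target / u_t) / _KN_PER_MM


def convergence_study(
    base_spec: ModelSpec,
    diameters: tuple[float, ...] = (500e-6, 400e-6, 333e-6),
    target_force: float = 100.0,
    registry: dict[str, Material] | None = None,
) -> pd.DataFrame:
    """Physiological benchmark at several discretizations of one geometry.

    Returns a table of (d, N, stiffness) with the attribute
    ``spread_percent``: the maximum pairwise relative stiffness difference.
    """
    if len(diameters) < 2:
        raise ValueError("need at least two discretizations")
    rows = []
    for d in diameters:
        spec = dataclasses.replace(base_spec, d=d)
        res = run_physio(spec, PhysioProtocol(target_force=target_force), registry)
        rows.append(
            dict(d_um=d * 1e6, n_elements=res.model.n_elements, stiffness_kN_mm=res.stiffness_kN_mm)
        )
    df = pd.DataFrame(rows)
    n_sorted = df.sort_values("d_um", ascending=False)["n_elements"].to_numpy()
    if np.any(np.diff(n_sorted) < 0):
        raise RuntimeError("element count does not grow under refinement (packing bug)")
    s = df["stiffness_kN_mm"].to_numpy()
    df.attrs["spread_percent"] = float((s.max() - s.min()) / s.min() * 100.0)
    return df


# ---------------------------------------------------------------------------
# scenario dispatch + outputs
# ---------------------------------------------------------------------------

def run_scenario(config: RunConfig) -> list[ScenarioResult | PhysioResult]:
    """Execute the configured scenario list and (optionally) write artifacts."""
    np.random.seed(config.seed % (2**31))  # the pipeline itself is deterministic
    results: list[ScenarioResult | PhysioResult] = []
    if config.protocol == "eswt":
        for efd in config.efd_list:
            results.append(
                run_eswt(config.spec, efd, cadence=config.cadence)
            )
    else:
        for target in config.target_list:
            results.append(
                run_physio(
                    config.spec,
                    PhysioProtocol(target_force=target),
                    damping=config.damping_resolved,
                )
            )
    if config.outdir is not None:
        _write_artifacts(config, results)
    return results


def summary_table(results: list[ScenarioResult | PhysioResult]) -> pd.DataFrame:
    """Tidy zone-fraction table, one row per (scenario, label)."""
    rows = []
    for res in results:
        frac = res.report.fractions
        for label, row in frac.iterrows():
            rows.append(
                dict(
                    scenario=res.config_label,
                    label=label,
                    mean_fraction=row["mean_fraction"],
                    reported=row["reported"],
                )
            )
    return pd.DataFrame(rows)


def _write_artifacts(config: RunConfig, results) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    summary_table(results).to_csv(outdir / "zone_fractions.csv", index=False)
    for res in results:
        if isinstance(res, PhysioResult):
            pd.DataFrame(
                {"displacement_m": res.displacement, "force_N": res.force}
            ).to_csv(outdir / f"{res.config_label}_history.csv", index=False)
        elif config.write_snapshots:
            fields = {
                "sigma_mean": res.samples["sigma_mean"][-1],
                "pore_pressure": res.samples["pore_pressure"][-1],
                "shear": res.samples["shear"][-1],
                "fate": res.samples["fate"][-1].astype(float),
            }
            write_fields(res.model, fields, outdir / f"{res.config_label}.vtk")


def write_fields(model: Model, fields: dict[str, np.ndarray], path: str | Path) -> Path:
    """Legacy-VTK ASCII point cloud with per-element scalars (float32)."""
    path = Path(path)
    n = model.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "osseowave element fields",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    pts = model.positions.astype(np.float32)
    lines += [" ".join(f"{v:.7g}" for v in p) for p in pts]
    lines.append(f"POINT_DATA {n}")
    base = {
        "region": model.regions.astype(float),
        "material": model.material_id.astype(float),
    }
    for name, values in {**base, **fields}.items():
        v = np.asarray(values, dtype=np.float32).reshape(n)
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{x:.7g}" for x in v]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk_points(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read back a legacy-VTK point cloud written by :func:`write_fields`."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    points = None
    scalars: dict[str, np.ndarray] = {}
    line = next(it)
    while True:
        try:
            if line.startswith("POINTS"):
                n = int(line.split()[1])
                vals = [next(it).split() for _ in range(n)]
                points = np.array(vals, dtype=float)
            elif line.startswith("SCALARS"):
                name = line.split()[1]
                next(it)  # LOOKUP_TABLE
                n = len(points)
                scalars[name] = np.array([float(next(it)) for _ in range(n)])
            line = next(it)
        except StopIteration:
            break
    if points is None:
        raise ValueError(f"{path} is not a VTK point cloud")
    return points, scalars
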