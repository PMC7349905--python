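"""Configuration, run artifacts, and end-to-end scenario presets.

Configs are plain YAML with four blocks, all optional (missing keys fall
back to the model's canonical defaults)::

    system:   {Dm, Dc, L, n_bar, boundary}
    flow:     {kind, vf | vmax, t0, t_off}
    reaction: {kon, kfb, koff, KD}
    sim:      {N, t_end, save_every, seed, noise_amplitude, scheme,
               rtol, atol}

Every simulation run can be written to disk as a kymograph TSV (long
format: t, x, m, c), a mass-ledger TSV and a YAML manifest that echoes all
parameters, the seed and the package version; the manifest alone re-executes
the run bit-identically.

The scenario presets bundle the protocols that exercise the model's
signature behaviours end to end: linear pattern growth from noise, upstream
peak propagation under uniform flow, the mesa-to-peak transition, and
flow-induced polarization by a parabolic flow with subsequent flow removal.
Reconstructed (non-printed) parameter choices are logged at INFO so the
provenance of every number is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import ReactionParams
from .stability import FlowProfile, SystemParams, dispersion, dispersion_relation
from .dynamics import DEFAULT_N, RTOL, ATOL, make_initial, simulate, SimulationResult
from .patterns import (
    classify_pattern,
    phase_trajectory,
    regional_instability,
    track_peak,
    unstable_density_range,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimSettings",
    "ScenarioPreset",
    "ScenarioReport",
    "load_config",
    "config_dict",
    "write_run",
    "read_kymograph",
    "run_from_manifest",
    "PRESETS",
    "get_preset",
    "run_scenario",
]


@dataclass(frozen=True)
class SimSettings:
    """Numerical settings of one simulation run."""

    N: int = DEFAULT_N
    t_end: float = 600.0
    save_every: float = 10.0
    seed: int = 0
    noise_amplitude: float | None = None
    scheme: str = "upwind"
    rtol: float = RTOL
    atol: float = ATOL
    initial: str = "homogeneous-noise"


# ------------------------------------------------------------------ config I/O

def _build_system(cfg: dict) -> SystemParams:
    reaction = ReactionParams(**cfg.get("reaction", {}))
    flow = FlowProfile(**cfg.get("flow", {}))
    system = cfg.get("system", {})
    return SystemParams(reaction=reaction, flow=flow, **system)


def load_config(source) -> tuple[SystemParams, SimSettings]:
    """Read a YAML config file (or ready dict) into parameter objects."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(source or {})
    return _build_system(cfg), SimSettings(**cfg.get("sim", {}))


def config_dict(sys: SystemParams, sim: SimSettings | None = None) -> dict:
    """Round-trippable dict form of a parameter set (units: um, s, 1/um)."""
    out = {
        "system": {
            "Dm": sys.Dm, "Dc": sys.Dc, "L": sys.L,
            "n_bar": sys.n_bar, "boundary": sys.boundary,
        },
        "flow": {k: v for k, v in dataclasses.asdict(sys.flow).items() if v is not None},
        "reaction": dataclasses.asdict(sys.reaction),
        "units": {"length": "um", "time": "s", "density": "1/um"},
    }
    if sim is not None:
        out["sim"] = {k: v for k, v in dataclasses.asdict(sim).items() if v is not None}
    return out


# -------------------------------------------------------------- run artifacts

def write_run(result: SimulationResult, sim: SimSettings, outdir) -> Path:
    """Write kymograph, mass ledger and manifest for one run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    T, N = result.m.shape
    frame = pd.DataFrame(
        {
            "t": np.repeat(result.times, N),
            "x": np.tile(result.x, T),
            "m": result.m.ravel(),
            "c": result.c.ravel(),
        }
    )
    frame.to_csv(outdir / "kymograph.tsv", sep="\t", index=False, float_format="%.17g")
    ledger = pd.DataFrame({"t": result.times, "n_bar": result.n_bar_series})
    ledger.to_csv(outdir / "mass_ledger.tsv", sep="\t", index=False, float_format="%.17g")
    manifest = config_dict(result.params, sim)
    manifest["version"] = __version__
    manifest["seed"] = result.seed
    manifest["mass_drift"] = float(result.mass_drift)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    logger.info("run written to %s (mass drift %.2e)", outdir, result.mass_drift)
    return outdir


def read_kymograph(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Read a kymograph TSV back into (times, x, m, c) arrays."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    times = frame["t"].unique()
    x = frame["x"].unique()
    T, N = times.size, x.size
    return times, x, frame["m"].to_numpy().reshape(T, N), frame["c"].to_numpy().reshape(T, N)


def run_from_manifest(path) -> SimulationResult:
    """Re-execute the run a manifest describes (bit-identical by construction:
    all parameters, the seed and the numerical settings are in the file)."""
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    sys_, sim = load_config(manifest)
    init = make_initial(
        sim.initial, sys_, N=sim.N, amplitude=sim.noise_amplitude, seed=manifest.get("seed", sim.seed)
    )
    return simulate(
        init, sys_, t_end=sim.t_end, save_every=sim.save_every,
        seed=manifest.get("seed", sim.seed), scheme=sim.scheme,
        rtol=sim.rtol, atol=sim.atol,
    )


# ------------------------------------------------------------------- scenarios

@dataclass(frozen=True)
class ScenarioPreset:
    """A self-contained protocol: parameters plus the checks it must satisfy."""

    name: str
    system: SystemParams
    sim: SimSettings
    expected_checks: tuple[str, ...]
    notes: str = ""


@dataclass
class ScenarioReport:
    name: str
    seed: int
    checks: dict[str, tuple[bool, str]] = field(default_factory=dict)
    artifacts: dict[str, float] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(ok for ok, _ in self.checks.values())

    def add(self, name: str, ok: bool, detail: str) -> None:
        self.checks[name] = (bool(ok), detail)
        (logger.info if ok else logger.warning)(
            "check %-38s %s  (%s)", name, "PASS" if ok else "FAIL", detail
        )


def _mass_check(report: ScenarioReport, *results: SimulationResult) -> None:
    drift = max(r.mass_drift for r in results)
    report.add("mass_conserved", drift < 1e-6, f"max relative drift {drift:.2e}")


def _preset_fig2() -> ScenarioPreset:
    return ScenarioPreset(
        name="fig2",
        system=SystemParams(),
        sim=SimSettings(N=256, t_end=8.0, save_every=0.25, noise_amplitude=5e-4),
        expected_checks=("mode_growth_matches_lsa", "mode_drifts_upstream", "mass_conserved"),
        notes="dispersion relation + early-time growth of the dominant mode from noise",
    )


def _preset_fig4() -> ScenarioPreset:
    return ScenarioPreset(
        name="fig4",
        system=SystemParams(L=10.0).with_flow(vf=20.0, t0=240.0),
        sim=SimSettings(N=256, t_end=600.0, save_every=5.0, initial="single-peak"),
        expected_checks=("peak_moves_upstream", "loop_opens", "mass_conserved"),
        notes="stationary peak, uniform flow switched on at t0",
    )


def _preset_fig5() -> ScenarioPreset:
    # slow-cytosol-diffusion operating point: the pattern amplitude pins at
    # the third FBS-nullcline intersection (a mesa); reconstructed Dc and
    # flow speeds are logged by run_scenario
    return ScenarioPreset(
        name="fig5",
        system=SystemParams(Dm=0.1, Dc=5.0, L=20.0, n_bar=7.0),
        sim=SimSettings(N=256, t_end=600.0, save_every=100.0, initial="single-peak"),
        expected_checks=(
            "no_flow_is_mesa",
            "fast_flow_is_peak",
            "fast_diffusion_is_peak",
            "mass_conserved",
        ),
        notes="mesa-to-peak transition under fast flow (vf=50) or fast diffusion (100x Dc)",
    )


FIG6_VMAX = 5.0
FIG6_NBAR_FACTOR = 0.95  # just below the laterally unstable density range
FIG6_DECAY_FACTOR = 0.3  # well below: pattern cannot outlive the flow


def _preset_fig6(decay: bool = False) -> ScenarioPreset:
    factor = FIG6_DECAY_FACTOR if decay else FIG6_NBAR_FACTOR
    base = SystemParams(boundary="no-flux", L=20.0, n_bar=1.0)  # n_bar set at run time
    n_minus, _ = unstable_density_range(base.reaction, base, vf=0.0)
    n_bar = factor * n_minus
    sysp = dataclasses.replace(base, n_bar=n_bar).with_flow(
        kind="parabolic", vmax=FIG6_VMAX, t0=0.0, t_off=400.0
    )
    checks = ["regional_trigger_precedes_pattern", "pattern_at_downstream_edge", "mass_conserved"]
    checks.insert(2, "flow_off_decays" if decay else "flow_off_persists")
    return ScenarioPreset(
        name="fig6-low" if decay else "fig6",
        system=sysp,
        sim=SimSettings(N=256, t_end=1000.0, save_every=1.0),
        expected_checks=tuple(checks),
        notes=(
            f"parabolic flow (vmax={FIG6_VMAX}) polarizes a laterally stable uniform state; "
            f"n_bar = {factor} * n_minus = {n_bar:.4f} (n_minus = {n_minus:.4f}, computed at run time)"
        ),
    )


PRESETS = ("fig2", "fig4", "fig5", "fig6", "fig6-low")


def get_preset(name: str) -> ScenarioPreset:
    if name == "fig2":
        return _preset_fig2()
    if name == "fig4":
        return _preset_fig4()
    if name == "fig5":
        return _preset_fig5()
    if name == "fig6":
        return _preset_fig6(decay=False)
    if name == "fig6-low":
        return _preset_fig6(decay=True)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")


def run_scenario(preset: ScenarioPreset | str, seed: int = 0, outdir=None) -> ScenarioReport:
    """Execute a preset protocol and evaluate its expected checks.

    Running requires nothing beyond the preset and a seed; two runs with the
    same seed produce identical reports (and identical files when ``outdir``
    is given).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    logger.info("scenario %s: %s", preset.name, preset.notes)
    report = ScenarioReport(name=preset.name, seed=seed)
    sysp, sim = preset.system, preset.sim
    runner = {
        "fig2": _run_fig2, "fig4": _run_fig4, "fig5": _run_fig5,
        "fig6": _run_fig6, "fig6-low": _run_fig6,
    }[preset.name]
    main_result = runner(preset, seed, report)
    missing = set(preset.expected_checks) - set(report.checks)
    if missing:
        raise RuntimeError(f"scenario {preset.name} did not evaluate checks {missing}")
    if outdir is not None:
        write_run(main_result, sim, Path(outdir) / preset.name)
        lines = [
            f"{name}\t{'PASS' if ok else 'FAIL'}\t{detail}"
            for name, (ok, detail) in report.checks.items()
        ]
        (Path(outdir) / preset.name / "report.tsv").write_text(
            "check\tstatus\tdetail\n" + "\n".join(lines) + "\n"
        )
    return report


def _run_fig2(preset, seed, report):
    sysp, sim = preset.system, preset.sim
    state = sysp.steady_state()
    disp = dispersion_relation(state, sysp, vf=0.0)
    vf = 20.0
    init = make_initial("homogeneous-noise", sysp, N=sim.N,
                        amplitude=sim.noise_amplitude, seed=seed)
    res = simulate(init, sysp.with_flow(vf=vf, t0=0.0), t_end=sim.t_end,
                   save_every=sim.save_every, seed=seed)
    # growth/drift of the discrete mode closest to the fastest-growing one
    k = int(round(disp.q_star * sysp.L / (2 * np.pi)))
    q_k = 2 * np.pi * k / sysp.L
    amps = np.fft.rfft(res.m, axis=1)[:, k]
    sel = res.times >= 2.0  # skip the decaying-branch transient
    growth = np.polyfit(res.times[sel], np.log(np.abs(amps[sel])), 1)[0]
    drift = np.polyfit(res.times[sel], np.unwrap(np.angle(amps[sel])), 1)[0]
    sig, _ = dispersion(q_k, state, sysp, vf)
    err_re = abs(growth - sig.real) / abs(sig.real)
    report.add("mode_growth_matches_lsa", err_re < 0.05,
               f"measured {growth:.4f} vs sigma {sig.real:.4f} (q={q_k:.3f}, err {err_re:.2%})")
    report.add("mode_drifts_upstream", np.sign(drift) == np.sign(vf) and drift != 0,
               f"Im sigma measured {drift:.4f}, predicted {sig.imag:.4f}")
    _mass_check(report, res)
    report.artifacts.update(q_star=disp.q_star, q_max=disp.q_max, growth_rate=growth)
    return res


def _run_fig4(preset, seed, report):
    sysp, sim = preset.system, preset.sim
    init = make_initial("single-peak", sysp, N=sim.N, seed=seed)
    res = simulate(init, sysp, t_end=sim.t_end, save_every=sim.save_every, seed=seed)
    t0 = sysp.flow.t0
    track = track_peak(res, window=(t0 + 120.0, sim.t_end))
    report.add("peak_moves_upstream",
               track.steady and track.v_p < 0,
               f"v_p = {track.v_p:.5f} um/s under vf = {sysp.flow.vf} um/s")
    traj = phase_trajectory(res.field(-1), sysp.reaction, sysp)
    report.add("loop_opens", traj.cL > traj.cR,
               f"cL = {traj.cL:.5f}, cR = {traj.cR:.5f}")
    _mass_check(report, res)
    report.artifacts.update(v_p=track.v_p, cL=traj.cL, cR=traj.cR, loop_area=traj.loop_area)
    return res


def _run_fig5(preset, seed, report):
    sysp, sim = preset.system, preset.sim
    results = []

    def steady_pattern(sys_v):
        init = make_initial("single-peak", sys_v, N=sim.N, seed=seed, relax_max_t=30000.0)
        if sys_v.flow.vf != 0.0 or sys_v.flow.kind != "uniform":
            res = simulate(init, sys_v, t_end=sim.t_end, save_every=sim.save_every, seed=seed)
            results.append(res)
            return res, res.field(-1)
        res = simulate(init, sys_v, t_end=60.0, save_every=30.0, seed=seed)
        results.append(res)
        return res, res.field(-1)

    res0, f0 = steady_pattern(sysp)
    cls0 = classify_pattern(f0, sysp.reaction, sysp)
    report.add("no_flow_is_mesa", cls0.label == "mesa",
               f"label {cls0.label}, plateau {cls0.plateau_width:.2f} um, "
               f"interface {cls0.interface_width:.2f} um")
    sys_fast = sysp.with_flow(vf=50.0, t0=0.0)
    _, f_flow = steady_pattern(sys_fast)
    cls_flow = classify_pattern(f_flow, sysp.reaction, sys_fast)
    report.add("fast_flow_is_peak", cls_flow.label == "peak",
               f"vf=50: label {cls_flow.label}, amplitude {cls_flow.amplitude:.2f}")
    sys_dc = dataclasses.replace(sysp, Dc=100.0 * sysp.Dc)
    _, f_dc = steady_pattern(sys_dc)
    cls_dc = classify_pattern(f_dc, sys_dc.reaction, sys_dc)
    report.add("fast_diffusion_is_peak", cls_dc.label == "peak",
               f"Dc={sys_dc.Dc}: label {cls_dc.label}, amplitude {cls_dc.amplitude:.2f}")
    _mass_check(report, *results)
    report.artifacts.update(
        mesa_amplitude=cls0.amplitude, peak_amplitude_flow=cls_flow.amplitude,
        peak_amplitude_dc=cls_dc.amplitude,
    )
    return res0


def _run_fig6(preset, seed, report):
    sysp, sim = preset.system, preset.sim
    init = make_initial("homogeneous-noise", sysp, N=sim.N,
                        amplitude=1e-3 * sysp.n_bar, seed=seed)
    res = simulate(init, sysp, t_end=sim.t_end, save_every=sim.save_every, seed=seed)
    amp = res.m.max(axis=1) - res.m.min(axis=1)
    t_off = sysp.flow.t_off
    i_off = int(np.argmin(np.abs(res.times - t_off)))
    final_on_amp = amp[i_off]
    # trigger time of the regional instability vs emergence of the pattern
    density_range = unstable_density_range(sysp.reaction, sysp, vf=0.0)
    trig_t, edge_ok = None, False
    for i, t in enumerate(res.times):
        if t > t_off:
            break
        mask, trig = regional_instability(res.field(i), sysp.reaction, sysp,
                                          density_range=density_range)
        if trig:
            trig_t = t
            # marked region must sit at the downstream (right) end
            edge_ok = bool(mask[-1]) and res.x[mask].mean() > sysp.L / 2
            break
    i10 = int(np.argmax(amp > 0.1 * final_on_amp))
    t10 = res.times[i10]
    report.add("regional_trigger_precedes_pattern",
               trig_t is not None and trig_t < t10,
               f"trigger at t={trig_t}, 10%-amplitude at t={t10:.0f}")
    report.add("pattern_at_downstream_edge",
               edge_ok and res.x[int(np.argmax(res.m[i_off]))] > sysp.L / 2,
               f"peak position {res.x[int(np.argmax(res.m[i_off]))]:.2f} of L={sysp.L}")
    # flow-off behaviour: compare amplitude 100 s after switch-off (shape
    # readjustment done) with the final amplitude >= 500 s later
    i_ref = int(np.argmin(np.abs(res.times - (t_off + 100.0))))
    change = (amp[-1] - amp[i_ref]) / max(amp[i_ref], 1e-12)
    if "flow_off_decays" in preset.expected_checks:
        report.add("flow_off_decays", amp[-1] < 1e-3 * sysp.n_bar,
                   f"final amplitude {amp[-1]:.3e} (was {final_on_amp:.2f} under flow)")
    else:
        report.add("flow_off_persists", abs(change) < 0.05 and amp[-1] > 0.5 * final_on_amp,
                   f"amplitude change {change:+.2%} over {res.times[-1]-res.times[i_ref]:.0f} s")
    _mass_check(report, res)
    report.artifacts.update(trigger_time=trig_t if trig_t is not None else float("nan"),
                            amplitude_final=float(amp[-1]))
    return res
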