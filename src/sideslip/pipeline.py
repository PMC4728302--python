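"""End-to-end orchestration: simulate -> observe -> (videogrammetry) ->
kinematics -> fit -> report.

A :class:`RunConfig` describes a whole synthetic study: several moths, each
flying several trials in which wing-pitch-split pulses command alternating
sideslip maneuvers while bilateral amplitude wobble and small left-right
amplitude asymmetries keep the other predictors informative.  Every
stochastic choice derives from the single run seed, so identical configs
produce byte-identical stroke tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinematics import build_stroke_table, write_stroke_table
from .models import (
    EQN_LATERAL,
    EQN_ROLL,
    EQN_VERTICAL,
    ManeuverModel,
    ModelSpec,
    cascade_select,
    contribution_table,
    damping_time_constants,
    fit_linear,
    fit_mixed_random_intercept,
    roll_acceleration_check,
)
from .observe import (
    Morphology,
    generate_wand,
    landmarks_from_trajectory,
    project_to_cameras,
    write_landmarks_csv,
)
from .simulate import (
    CommandSchedule,
    SimConfig,
    WingCommand,
    WingParams,
    integrate_flight,
    trim_hover,
)
from .videogrammetry import (
    calibrate_dlt,
    make_camera,
    triangulate_table,
    wand_diagnostics,
    write_dlt_csv,
)

__all__ = ["RunConfig", "run_pipeline", "make_report", "simulate_study",
           "maneuver_schedule", "sim_config_from_dict", "wing_command_from_dict"]


@dataclass
class RunConfig:
    """Configuration of one seeded end-to-end run."""

    seed: int = 1
    out_dir: str = "runs/demo"
    n_moths: int = 4
    trials_per_moth: int = 3
    wingbeats_per_trial: int = 20
    pitch_split_lo: float = 6.0      # deg, commanded |alpha_LR| range
    pitch_split_hi: float = 10.0
    keyframe_wingbeats: float = 2.5  # spacing of command updates
    amp_wobble_sd: float = 0.03      # bilateral sweep-amplitude fraction
    theta_wobble_sd: float = 0.06    # bilateral elevation-amplitude fraction
    phi_p_asym_sd: float = 2.0       # deg, per-wing sweep amplitude asymmetry
    theta_p_asym_sd: float = 1.5     # deg, per-wing elevation asymmetry
    moth_theta0_sd: float = 1.0      # deg, per-moth elevation baseline
    moth_phi_p_sd: float = 2.0       # deg, per-moth amplitude baseline
    noise_sd: float = 0.05           # cm, landmark noise
    missing_p5_rate: float = 0.02
    use_cameras: bool = False
    pixel_noise_sd: float = 0.0
    stages: tuple = ("simulate", "observe", "kinematics", "fit", "report")
    sim: dict = field(default_factory=dict)   # SimConfig field overrides

    def sim_config(self) -> SimConfig:
        return SimConfig(**self.sim)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def sim_config_from_dict(data: dict) -> SimConfig:
    return SimConfig(**(data or {}))


def wing_command_from_dict(data: dict) -> WingCommand:
    """Build a WingCommand from a mapping with optional 'left'/'right'
    sections; unsectioned keys apply to both wings."""
    data = dict(data or {})
    left = dict(data.pop("left", {}))
    right = dict(data.pop("right", {}))
    return WingCommand(left=WingParams(**{**data, **left}),
                       right=WingParams(**{**data, **right}))


def maneuver_schedule(base: WingCommand, rng: np.random.Generator,
                      cfg: SimConfig, run: RunConfig) -> CommandSchedule:
    """One trial's command schedule.

    Two opposite-signed wing-pitch-split pulses command a rightward then a
    leftward sideslip; on a faster keyframe grid the bilateral sweep and
    elevation amplitudes wobble and small per-wing amplitude asymmetries are
    redrawn, keeping those predictors informative and uncorrelated with the
    roll state."""
    T = cfg.period
    A = rng.uniform(run.pitch_split_lo, run.pitch_split_hi)

    def wobble(c: WingCommand) -> WingCommand:
        f = 1.0 + rng.normal(0.0, run.amp_wobble_sd)
        c = c.scaled_amplitude(f, f)
        dt_ = rng.normal(0.0, run.theta_wobble_sd)
        c = WingCommand(
            left=replace(c.left, theta_p=max(c.left.theta_p * (1 + dt_), 1.0)),
            right=replace(c.right, theta_p=max(c.right.theta_p * (1 + dt_), 1.0)))
        return WingCommand(
            left=replace(c.left,
                         phi_p=c.left.phi_p + rng.normal(0, run.phi_p_asym_sd),
                         theta_p=max(c.left.theta_p + rng.normal(0, run.theta_p_asym_sd), 1.0)),
            right=replace(c.right,
                          phi_p=c.right.phi_p + rng.normal(0, run.phi_p_asym_sd),
                          theta_p=max(c.right.theta_p + rng.normal(0, run.theta_p_asym_sd), 1.0)))

    n_beats = run.wingbeats_per_trial
    step = run.keyframe_wingbeats
    keys = [(0.0, base)]
    tcur = 2.0
    half = (n_beats - 2.0) / 2.0
    while tcur < n_beats - 0.5:
        # +split during the first half of the trial, -split during the second
        sgn = 1.0 if tcur < 2.0 + half - step / 2.0 else -1.0
        keys.append((tcur * T, wobble(base.with_pitch_split(sgn * A))))
        tcur += step
    return CommandSchedule(keys, blend_width=0.8 / cfg.flap_frequency,
                           flap_frequency=cfg.flap_frequency)


def simulate_study(run: RunConfig) -> list[dict]:
    """Simulate every trial of the configured study.

    Returns a list of dicts with moth_id, trial_id, the Trajectory and the
    per-trial landmark seed.
    """
    cfg = run.sim_config()
    base = trim_hover(cfg)
    rng = np.random.default_rng(run.seed)
    trials = []
    for m in range(run.n_moths):
        dth = rng.normal(0.0, run.moth_theta0_sd)
        dpp = rng.normal(0.0, run.moth_phi_p_sd)
        moth_base = WingCommand(
            left=replace(base.left, theta0=base.left.theta0 + dth,
                         phi_p=base.left.phi_p + dpp),
            right=replace(base.right, theta0=base.right.theta0 + dth,
                          phi_p=base.right.phi_p + dpp))
        for tr in range(run.trials_per_moth):
            sch = maneuver_schedule(moth_base, rng, cfg, run)
            traj = integrate_flight(cfg, sch, run.wingbeats_per_trial * cfg.period)
            trials.append({
                "moth_id": f"moth{m + 1}",
                "trial_id": f"m{m + 1}t{tr + 1}",
                "trajectory": traj,
                "landmark_seed": int(rng.integers(2 ** 31)),
            })
    return trials


def _default_rig(volume):
    (x0, x1), (y0, y1), (z0, z1) = volume
    c = np.array([(x0 + x1) / 2, (y0 + y1) / 2, (z0 + z1) / 2])
    span = max(x1 - x0, y1 - y0, z1 - z0)
    d = 6.0 * span
    return [
        make_camera(c + [d, 0.0, -0.25 * d], c, label="cam1"),
        make_camera(c + [0.35 * d, d, -0.2 * d], c, label="cam2"),
        make_camera(c + [-0.3 * d, -d, -0.3 * d], c, label="cam3"),
    ]


def _videogrammetry_stage(landmarks: pd.DataFrame, run: RunConfig,
                          out: Path, rng: np.random.Generator) -> pd.DataFrame:
    """Project landmarks through a 3-camera rig, calibrate each camera from
    synthetic control points, triangulate back, and run the wand check."""
    xyz_cols = [c for c in landmarks.columns if c[-2:] in ("_x", "_y", "_z")]
    pts = landmarks[xyz_cols].to_numpy(dtype=float)
    pts = pts.reshape(-1, 3)
    pts = pts[np.isfinite(pts).all(axis=1)]
    lo = pts.min(axis=0) - 2.0
    hi = pts.max(axis=0) + 2.0
    volume = tuple(zip(lo, hi))
    rig = _default_rig(volume)
    # calibration from a control grid filling the volume
    gx, gy, gz = np.meshgrid(*[np.linspace(a, b, 3) for a, b in volume])
    control = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    cams = []
    rmses = []
    for cam in rig:
        px = cam.project(control)
        if run.pixel_noise_sd > 0:
            px = px + rng.normal(0.0, run.pixel_noise_sd, px.shape)
        fitted, rmse = calibrate_dlt(control, px, image_size=cam.image_size,
                                     label=cam.label)
        cams.append(fitted)
        rmses.append(rmse)
    write_dlt_csv(cams, out / "dlt_coefficients.csv")
    wand = generate_wand(rig, volume, n_frames=60,
                         pixel_noise_sd=run.pixel_noise_sd,
                         seed=int(rng.integers(2 ** 31)))
    diag = wand_diagnostics(cams, wand)
    with open(out / "wand_diagnostics.json", "w") as fh:
        json.dump({k: v for k, v in diag.items() if np.isscalar(v)}, fh, indent=1)
    # project + triangulate the landmarks themselves
    pix = project_to_cameras(landmarks, rig, pixel_noise_sd=run.pixel_noise_sd,
                             seed=int(rng.integers(2 ** 31)))
    for i, tab in enumerate(pix):
        tab.to_csv(out / f"pixels_{rig[i].label}.csv", index=False)
    tri = triangulate_table(cams, pix)
    wide = landmarks.copy()
    for _, row in tri.iterrows():
        sel = wide["frame"] == row["frame"]
        for ax, val in zip("xyz", (row["x"], row["y"], row["z"])):
            wide.loc[sel, f"{row['point_name']}_{ax}"] = val
    return wide


FIT_SPECS = {"lateral": EQN_LATERAL, "vertical": EQN_VERTICAL, "roll": EQN_ROLL}


def fit_stage(table: pd.DataFrame, out: Path | None = None,
              select: bool = False) -> dict:
    """Fit the three maneuver equations (OLS and moth random intercept) and
    derived reports; optionally run cascade selection."""
    results = {}
    for name, spec in FIT_SPECS.items():
        ols = fit_linear(table, spec)
        entry = {"ols": ols}
        if table["moth_id"].nunique() >= 2:
            try:
                entry["mixed"] = fit_mixed_random_intercept(table, spec, "moth_id")
            except ValueError:
                pass
        best = min(entry.values(), key=lambda r: r.aicc)
        entry["best"] = best
        entry["contributions"] = contribution_table(best)
        if name in ("lateral", "vertical"):
            entry["time_constants"] = damping_time_constants(best)
        results[name] = entry
    results["roll_order_check"] = roll_acceleration_check(table)
    if select:
        for name, spec in FIT_SPECS.items():
            sel_spec, trace = cascade_select(
                table, spec.response, spec.terms,
                intercept=spec.response not in ("beta_dot", "beta_ddot"))
            results[name]["selected_spec"] = sel_spec
            results[name]["selection_trace"] = trace
    if out is not None:
        rows = []
        for name, entry in results.items():
            if name == "roll_order_check":
                continue
            best = entry["best"]
            for term in best.params.index:
                rows.append({
                    "model": name, "term": term, "K": best.params[term],
                    "SE": best.bse[term], "p": best.pvalues[term],
                    "aicc": best.aicc, "r_squared": best.r_squared,
                    "r2_kind": best.r2_kind,
                })
        pd.DataFrame(rows).to_csv(out / "coefficients.csv", index=False)
        contrib = {name: entry["contributions"].to_dict()
                   for name, entry in results.items() if name != "roll_order_check"}
        with open(out / "contributions.json", "w") as fh:
            json.dump(contrib, fh, indent=1)
        tc = {}
        for name in ("lateral", "vertical"):
            tc[name] = {k: {kk: (vv if np.isfinite(vv) else None)
                            if isinstance(vv, float) else vv
                            for kk, vv in v.items()}
                        for k, v in results[name]["time_constants"].items()}
        with open(out / "time_constants.json", "w") as fh:
            json.dump(tc, fh, indent=1)
    return results


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(run: RunConfig) -> dict:
    """Execute the enabled stages, writing artifacts and a manifest.

    Returns a dict with the stroke table, fit results and artifact paths.
    Identical config and seed produce byte-identical stroke tables.
    """
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    artifacts = {}
    result = {"artifacts": artifacts}
    rng = np.random.default_rng(np.random.SeedSequence([run.seed, 77]))

    if "simulate" not in run.stages:
        raise ValueError("pipeline currently requires the simulate stage")
    trials = simulate_study(run)
    for tr in trials:
        p = out / f"trajectory_{tr['trial_id']}.csv"
        tr["trajectory"].to_csv(p)
    artifacts["trajectories"] = sorted(str(p) for p in out.glob("trajectory_*.csv"))

    if "observe" in run.stages:
        frames = []
        offset = 0
        for tr in trials:
            lm = landmarks_from_trajectory(
                tr["trajectory"], noise_sd=run.noise_sd,
                missing_p5_rate=run.missing_p5_rate, seed=tr["landmark_seed"],
                moth_id=tr["moth_id"], trial_id=tr["trial_id"])
            lm["frame"] += offset
            offset = int(lm["frame"].max()) + 1
            frames.append(lm)
        landmarks = pd.concat(frames, ignore_index=True)
        if run.use_cameras:
            landmarks = _videogrammetry_stage(landmarks, run, out, rng)
        lm_path = out / "landmarks.csv"
        write_landmarks_csv(landmarks, lm_path)
        artifacts["landmarks"] = str(lm_path)
        result["landmarks"] = landmarks

    if "kinematics" in run.stages:
        if "observe" not in run.stages:
            raise ValueError("kinematics stage requires the observe stage output")
        tabs = []
        for tid, grp in result["landmarks"].groupby("trial_id", sort=True):
            grp = grp.reset_index(drop=True)
            grp["frame"] = np.arange(len(grp))
            tabs.append(build_stroke_table(grp))
        table = pd.concat(tabs, ignore_index=True)
        # re-center over the combined data set
        means = {}
        for col in ("alpha_bar", "phi_p_bar", "theta_p_bar", "psi_p_bar"):
            means[col] = float(table[col].mean())
            table[f"{col}_c"] = table[col] - means[col]
        table.attrs["centering_means"] = means
        st_path = out / "stroke_table.csv"
        write_stroke_table(table, st_path)
        artifacts["stroke_table"] = str(st_path)
        result["stroke_table"] = table

    if "fit" in run.stages:
        if "stroke_table" not in result:
            raise ValueError("fit stage requires the kinematics stage output")
        result["fits"] = fit_stage(result["stroke_table"], out=out)
        artifacts["coefficients"] = str(out / "coefficients.csv")

    manifest = {
        "version": __version__,
        "seed": run.seed,
        "config": dataclasses.asdict(run),
        "elapsed_s": round(time.time() - t_start, 2),
        "hashes": {k: _sha256(Path(v)) for k, v in artifacts.items()
                   if isinstance(v, str) and Path(v).exists()},
        "n_trials": len(trials),
    }
    manifest["config"]["stages"] = list(manifest["config"]["stages"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    result["manifest"] = manifest

    if "report" in run.stages and "fits" in result:
        make_report(result, out)
    return result


def make_report(result: dict, out: Path) -> list[str]:
    """Observed-vs-model panels, per-halfstroke contribution traces and the
    roll stair-step figure, from a completed pipeline result."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result["stroke_table"]
    fits = result["fits"]
    paths = []

    fig, axes = plt.subplots(1, 3, figsize=(13, 4.2))
    for ax, name in zip(axes, ("lateral", "vertical", "roll")):
        best = fits[name]["best"]
        obs = best.model.endog.to_numpy()
        pred = np.asarray(best.fittedvalues)
        ax.plot(pred, obs, ".", ms=4, alpha=0.6)
        lim = np.nanmax(np.abs(np.concatenate([obs, pred]))) * 1.05
        ax.plot([-lim, lim], [-lim, lim], "k-", lw=1.6, label="slope 1")
        sl = float(np.polyfit(pred, obs, 1)[0])
        ax.plot([-lim, lim], [-lim * sl, lim * sl], "r-", lw=0.9,
                label=f"fitted slope {sl:.2f}")
        ax.set_title(f"{best.spec.response}  ({best.r2_kind} r2={best.r_squared:.2f})")
        ax.set_xlabel("model")
        ax.set_ylabel("observed")
        ax.legend(fontsize=8)
    fig.tight_layout()
    p = out / "fig_observed_vs_model.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(str(p))

    trial = table["trial_id"].iloc[0]
    sub = table[table["trial_id"] == trial]
    fig, axes = plt.subplots(3, 1, figsize=(8, 8), sharex=True)
    from .models import TERM_BUILDERS
    from .simulate import GRAVITY_CM_S2
    for ax, name in zip(axes, ("lateral", "vertical", "roll")):
        best = fits[name]["best"]
        ax.plot(sub["time_s"], sub[best.spec.response], "k-", lw=2,
                label=best.spec.response)
        for term in best.spec.terms:
            x = TERM_BUILDERS[term](sub, GRAVITY_CM_S2)
            ax.plot(sub["time_s"], best.params.get(term, 0.0) * x, lw=1,
                    label=term)
        ax.legend(fontsize=7, ncol=3)
    axes[-1].set_xlabel("time (s)")
    fig.tight_layout()
    p = out / "fig_contributions.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(str(p))

    fig, ax = plt.subplots(figsize=(8, 4))
    for st, marker in (("down", "v"), ("up", "^")):
        s = sub[sub["stroke"] == st]
        ax.plot(s["time_s"], s["beta"], marker, ms=5, label=f"{st}stroke")
    ax.plot(sub["time_s"], sub["beta"], "-", color="0.6", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("roll beta (deg)")
    ax.legend()
    fig.tight_layout()
    p = out / "fig_roll_stairstep.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(str(p))
    return paths
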