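"""Synthetic digitized observations of a simulated moth.

Renders a simulated flight into the observable a videographic study yields:
3D positions of 8 body/wing landmarks (scutum, abdomen tip, left/right wing
bases, forewing tips and hindwing tips) sampled at the four visually
identifiable stroke phases -- end-downstroke, end-upstroke, mid-downstroke,
mid-upstroke -- with configurable isotropic Gaussian landmark noise and
occasional missing hindwing tips.  Optionally projects landmarks through
DLT cameras and generates a synthetic two-LED calibration wand track.

Phase times are taken from the commanded sweep waveform: end-strokes at the
sweep extrema, midstrokes where sweep crosses its mean -- the deterministic
analogue of visual phase identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SimConfig, Trajectory, _rot_x, _D2R, wing_kinematics_waveform

__all__ = [
    "Morphology",
    "WandTrack",
    "PHASES",
    "POINT_NAMES",
    "landmarks_from_trajectory",
    "project_to_cameras",
    "generate_wand",
    "read_landmarks_csv",
    "write_landmarks_csv",
]

PHASES = ("end_up", "mid_down", "end_down", "mid_up")

POINT_NAMES = (
    "p1_scutum", "p2_abdomen",
    "p3L_wingbase", "p3R_wingbase",
    "p4L_forewingtip", "p4R_forewingtip",
    "p5L_hindwingtip", "p5R_hindwingtip",
)


@dataclass(frozen=True)
class Morphology:
    """Rigid body-landmark template (cm, body frame: +x forward, +z down).

    The scutum point, wing-base line and abdomen tip are placed so that the
    body x-axis reconstructed from points 1-3 (centroid minus abdomen tip)
    is exactly the template's +x axis.
    """

    wing_length: float = 5.0
    chord_mark: float = 1.5      # |p4 - p5|, hindwing-tip to forewing-tip chord
    base_half_sep: float = 0.5   # lateral offset of each wing base
    scutum: tuple = (0.5, 0.0, -0.3)
    abdomen_length: float = 2.0  # distance from points-1-3 centroid to abdomen tip

    def body_points(self) -> dict[str, np.ndarray]:
        p1 = np.array(self.scutum, dtype=float)
        p3l = np.array([0.0, -self.base_half_sep, 0.0])
        p3r = np.array([0.0, self.base_half_sep, 0.0])
        centroid = (p1 + p3l + p3r) / 3.0
        p2 = centroid - np.array([self.abdomen_length, 0.0, 0.0])
        return {"p1_scutum": p1, "p2_abdomen": p2,
                "p3L_wingbase": p3l, "p3R_wingbase": p3r}

    @classmethod
    def from_config(cls, cfg: SimConfig, **kwargs) -> "Morphology":
        return cls(wing_length=cfg.wing_length, base_half_sep=cfg.base_half_sep,
                   **kwargs)


def _span_unit(phi_deg, theta_deg, h):
    phi, theta = phi_deg * _D2R, theta_deg * _D2R
    return np.array([math.cos(theta) * math.sin(phi),
                     h * math.cos(theta) * math.cos(phi),
                     -math.sin(theta)])


def _chord_unit(gamma_deg):
    g = gamma_deg * _D2R
    return np.array([math.cos(g), 0.0, -math.sin(g)])


def landmarks_from_trajectory(traj: Trajectory, morphology: Morphology | None = None,
                              noise_sd: float = 0.0, missing_p5_rate: float = 0.0,
                              seed: int = 0, moth_id: str = "moth1",
                              trial_id: str = "trial1") -> pd.DataFrame:
    """Sample the 8 landmarks at the four stroke phases of each wingbeat.

    Parameters
    ----------
    traj : Trajectory from :func:`sideslip.simulate.integrate_flight`
        (must carry its config and command schedule)
    morphology : rigid landmark template; defaults to one consistent with
        the trajectory's config
    noise_sd : isotropic Gaussian landmark noise, cm (GRF)
    missing_p5_rate : per-side probability of a missing hindwing tip
    seed : RNG seed; output is deterministic given the seed

    Returns a wide table with one row per digitized frame: ``frame``,
    ``time_s``, ``phase``, ``moth_id``, ``trial_id`` and x/y/z columns per
    named point (NaN for dropped hindwing tips).
    """
    if traj.config is None or traj.schedule is None:
        raise ValueError("trajectory must carry its simulation config and schedule")
    cfg = traj.config
    if morphology is None:
        morphology = Morphology.from_config(cfg)
    if abs(morphology.wing_length - cfg.wing_length) > 1e-9:
        raise ValueError("morphology wing_length inconsistent with trajectory config")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t_end = traj.time[-1]
    if t_end < 2.0 * cfg.period:
        raise ValueError("trajectory must cover at least 2 wingbeats")
    rng = np.random.default_rng(seed)

    # phase times from the sweep waveform: end-up at sweep phase pi (+2 pi k)
    phase0 = traj.schedule.commands[0].right.phase_phi * _D2R
    f = cfg.flap_frequency
    t0 = ((math.pi - phase0) / (2.0 * math.pi)) / f
    while t0 < 0:
        t0 += 1.0 / f
    times, phases = [], []
    k = 0
    while True:
        base = t0 + k / f
        done = False
        for j, ph in enumerate(PHASES):
            t = base + j / (4.0 * f)
            if t > t_end + 1e-9:
                done = True
                break
            times.append(min(t, t_end))
            phases.append(ph)
        if done:
            break
        k += 1

    body_pts = morphology.body_points()
    tt = traj.time
    y = np.interp(times, tt, traj["y_cm"])
    z = np.interp(times, tt, traj["z_cm"])
    beta = np.interp(times, tt, traj["beta_deg"])
    kin = wing_kinematics_waveform(traj.schedule, np.asarray(times),
                                   flap_frequency=f, reversal_frac=cfg.reversal_frac)
    rows = []
    for i, (t, ph) in enumerate(zip(times, phases)):
        R = _rot_x(beta[i] * _D2R)
        com = np.array([0.0, y[i], z[i]])
        pts = {}
        for name, p_b in body_pts.items():
            pts[name] = com + R @ p_b
        for side, h, tag in (("left", -1.0, "L"), ("right", 1.0, "R")):
            kw = kin[side]
            s_hat = _span_unit(kw["phi"][i], kw["theta"][i], h)
            c_hat = _chord_unit(kw["gamma"][i])
            base_b = np.array([0.0, h * morphology.base_half_sep, 0.0])
            p4_b = base_b + morphology.wing_length * s_hat
            p5_b = p4_b - morphology.chord_mark * c_hat
            pts[f"p4{tag}_forewingtip"] = com + R @ p4_b
            pts[f"p5{tag}_hindwingtip"] = com + R @ p5_b
        row = {"frame": i, "time_s": t, "phase": ph,
               "moth_id": moth_id, "trial_id": trial_id}
        for name in POINT_NAMES:
            p = pts[name]
            if noise_sd > 0:
                p = p + rng.normal(0.0, noise_sd, size=3)
            drop = (name.startswith("p5")
                    and missing_p5_rate > 0
                    and rng.random() < missing_p5_rate)
            for ax, val in zip("xyz", p):
                row[f"{name}_{ax}"] = np.nan if drop else val
        rows.append(row)
    return pd.DataFrame(rows)


def write_landmarks_csv(frames: pd.DataFrame, path) -> None:
    frames.to_csv(path, index=False)


def read_landmarks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "time_s", "phase"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV missing columns {required - set(df.columns)}")
    return df


def project_to_cameras(frames: pd.DataFrame, cameras: list,
                       pixel_noise_sd: float = 0.0, seed: int = 0
                       ) -> list[pd.DataFrame]:
    """Project landmark frames through DLT cameras.

    Returns one long table per camera with columns ``frame, point_name, u,
    v``; points behind a camera plane or missing in 3D are NaN.
    """
    if len(cameras) < 2:
        raise ValueError("need at least 2 cameras")
    rng = np.random.default_rng(seed)
    tables = []
    for cam in cameras:
        recs = []
        for _, row in frames.iterrows():
            for name in POINT_NAMES:
                p = np.array([row[f"{name}_{ax}"] for ax in "xyz"])
                if np.isnan(p).any():
                    uv = (np.nan, np.nan)
                else:
                    uv = cam.project(p[None, :])[0]
                    if pixel_noise_sd > 0 and np.isfinite(uv).all():
                        uv = uv + rng.normal(0.0, pixel_noise_sd, size=2)
                recs.append({"frame": row["frame"], "point_name": name,
                             "u": uv[0], "v": uv[1]})
        tables.append(pd.DataFrame(recs))
    return tables


@dataclass
class WandTrack:
    """Two-LED calibration wand observed by all cameras.

    ``pixels`` has shape (n_frames, n_cameras, 2 LEDs, 2) and ``points``
    holds the true 3D LED positions, shape (n_frames, 2, 3), cm.
    """

    pixels: np.ndarray
    points: np.ndarray
    separation_mm: float = 68.5

    def __post_init__(self):
        if self.separation_mm <= 0:
            raise ValueError("LED separation must be positive")
        if self.pixels.shape[0] < 40:
            raise ValueError("a wand track needs at least 40 frames")


def generate_wand(cameras: list, volume, n_frames: int = 120,
                  separation_mm: float = 68.5, pixel_noise_sd: float = 0.0,
                  seed: int = 0) -> WandTrack:
    """Wave a synthetic wand through the working volume.

    Parameters
    ----------
    cameras : calibrated/ground-truth CameraModel list
    volume : ((xmin, xmax), (ymin, ymax), (zmin, zmax)) working volume, cm
    n_frames : >= 40
    separation_mm : true LED separation (default 68.5 mm)

    The wand centre follows a smooth pseudo-random Lissajous path filling the
    volume while the wand orientation precesses; every frame's true LED
    separation is exactly ``separation_mm``.  Raises if the volume is not
    visible to the cameras.
    """
    if n_frames < 40:
        raise ValueError("n_frames must be >= 40")
    rng = np.random.default_rng(seed)
    vol = np.asarray(volume, dtype=float)
    lo, hi = vol[:, 0], vol[:, 1]
    centre = (lo + hi) / 2.0
    amp = (hi - lo) / 2.0 * 0.85
    half = separation_mm / 10.0 / 2.0  # cm
    tpar = np.linspace(0.0, 1.0, n_frames)
    freqs = rng.uniform(1.0, 2.5, size=3)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=3)
    path = centre[None, :] + amp[None, :] * np.sin(
        2.0 * math.pi * freqs[None, :] * tpar[:, None] + phases[None, :])
    # precessing orientation
    w1, w2 = rng.uniform(2.0, 5.0, size=2)
    az = 2.0 * math.pi * w1 * tpar + rng.uniform(0, 2 * math.pi)
    el = 0.9 * np.sin(2.0 * math.pi * w2 * tpar + rng.uniform(0, 2 * math.pi))
    d = np.column_stack([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az),
                         np.sin(el)])
    points = np.stack([path - half * d, path + half * d], axis=1)
    pixels = np.full((n_frames, len(cameras), 2, 2), np.nan)
    n_visible = 0
    for fidx in range(n_frames):
        frame_ok = True
        for ci, cam in enumerate(cameras):
            uv = cam.project(points[fidx])
            pixels[fidx, ci] = uv
            w, hgt = cam.image_size
            inside = (np.isfinite(uv).all()
                      and (uv[:, 0] >= 0).all() and (uv[:, 0] < w).all()
                      and (uv[:, 1] >= 0).all() and (uv[:, 1] < hgt).all())
            if not inside:
                frame_ok = False
        if frame_ok:
            n_visible += 1
    if n_visible == 0:
        raise ValueError("working volume is outside all camera frusta")
    if pixel_noise_sd > 0:
        pixels = pixels + rng.normal(0.0, pixel_noise_sd, size=pixels.shape)
    return WandTrack(pixels=pixels, points=points, separation_mm=separation_mm)
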