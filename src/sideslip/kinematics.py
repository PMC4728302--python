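"""Body and wing kinematics from digitized landmark sequences.

Turns 3D landmark tables (8 points at 4 stroke phases per wingbeat) into the
measures used by the maneuver regressions: body Euler angles, the
yaw-aligned MGRF, per-wing sweep/elevation/wing-pitch angles, halfstroke
amplitudes, left-right asymmetries, wingbeat-scale body-state derivatives,
maneuver segmentation, and a one-row-per-halfstroke stroke table.

Frames
------
GRF   global frame, +z down (parallel with gravity).
MGRF  GRF rotated about the vertical so +x matches the moth's heading;
      z-coordinates are unchanged.
BRF   body frame from the intrinsic yaw->pitch->roll (z-y-x) Euler
      decomposition of the landmark-built body axes.

Derivatives are computed from wingbeat-to-wingbeat changes between
like-phase samples only, which filters out all within-wingbeat oscillation;
the four phase-specific estimates of each wingbeat are then averaged.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .observe import PHASES, POINT_NAMES

__all__ = [
    "BodyPose",
    "body_euler",
    "wing_angles",
    "stroke_amplitudes",
    "wingbeat_derivatives",
    "segment_maneuvers",
    "stroke_plane_roll",
    "build_stroke_table",
    "write_stroke_table",
    "read_stroke_table",
]

_R2D = 180.0 / math.pi

DOWN_PHASES = {"mid_down", "end_down"}


class LandmarkDegeneracyError(ValueError):
    pass


@dataclass(frozen=True)
class BodyPose:
    """Body orientation: intrinsic z-y-x Euler angles (deg) and the
    body->GRF rotation matrix."""

    yaw: float
    pitch: float
    roll: float
    rotation: np.ndarray  # columns = BRF axes expressed in GRF

    def to_brf(self, v: np.ndarray) -> np.ndarray:
        """Express GRF vector(s) in the body frame."""
        return np.asarray(v) @ self.rotation


def _get_point(frame, name) -> np.ndarray:
    if isinstance(frame, dict):
        return np.asarray(frame[name], dtype=float)
    return np.array([frame[f"{name}_{ax}"] for ax in "xyz"], dtype=float)


def body_euler(frame) -> BodyPose:
    """Body pose from the scutum (p1), abdomen tip (p2) and wing bases (p3).

    The body x-axis runs from the abdomen tip to the centroid of points 1-3;
    the y-axis is the wing-base line (left to right) orthonormalized against
    x by Gram-Schmidt; z completes the right-handed triad (down).  Euler
    angles come from the intrinsic z-y-x (yaw, pitch, roll) decomposition,
    so roll is measured absolute to the GRF horizontal plane.

    ``frame`` may be a landmark-table row or a ``{point_name: xyz}`` dict.
    """
    p1 = _get_point(frame, "p1_scutum")
    p2 = _get_point(frame, "p2_abdomen")
    p3l = _get_point(frame, "p3L_wingbase")
    p3r = _get_point(frame, "p3R_wingbase")
    for name, p in (("p1", p1), ("p2", p2), ("p3L", p3l), ("p3R", p3r)):
        if np.isnan(p).any():
            raise LandmarkDegeneracyError(f"point {name} missing in frame")
    centroid = (p1 + p3l + p3r) / 3.0
    x = centroid - p2
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise LandmarkDegeneracyError("abdomen tip coincides with body centroid")
    x = x / nx
    y_raw = p3r - p3l
    y = y_raw - (y_raw @ x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise LandmarkDegeneracyError("wing-base line parallel to body axis")
    y = y / ny
    z = np.cross(x, y)
    R = np.column_stack([x, y, z])
    yaw, pitch, roll = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
    return BodyPose(yaw=yaw, pitch=pitch, roll=roll, rotation=R)


def wing_angles(frame, pose: BodyPose) -> dict:
    """Per-wing sweep, elevation and wing-pitch angles from one frame.

    Sweep (phi) is the angle of the base-to-forewing-tip vector projected
    onto the BRF x/y plane, measured from straight-lateral toward +x;
    elevation (theta) is its angle above the BRF horizontal.  Wing pitch
    (alpha) is the angle of the hindwing-tip to forewing-tip chord projected
    onto the BRF x/z plane, measured from the +x axis in downstroke frames
    and from the -x axis in upstroke frames.  When the hindwing tip is
    missing, alpha falls back to the wing-vector normal in the x/z plane and
    is flagged ``alpha_quality='fallback'``.
    """
    phase = frame["phase"] if not isinstance(frame, dict) else frame.get("phase")
    is_down = phase in DOWN_PHASES
    out = {}
    for tag, h in (("L", -1.0), ("R", 1.0)):
        p3 = _get_point(frame, f"p3{tag}_wingbase")
        p4 = _get_point(frame, f"p4{tag}_forewingtip")
        p5 = _get_point(frame, f"p5{tag}_hindwingtip")
        r_fw = pose.to_brf(p4 - p3)
        n_fw = np.linalg.norm(r_fw)
        if not np.isfinite(n_fw) or n_fw < 1e-9:
            raise LandmarkDegeneracyError(f"forewing tip {tag} missing or degenerate")
        phi = math.atan2(r_fw[0], h * r_fw[1]) * _R2D
        theta = math.atan2(-r_fw[2], math.hypot(r_fw[0], r_fw[1])) * _R2D
        alpha = np.nan
        quality = "chord"
        if not np.isnan(p5).any():
            r_chord = pose.to_brf(p4 - p5)
            cx, cz = r_chord[0], r_chord[2]
            if math.hypot(cx, cz) < 1e-6:
                quality = "missing"
                warnings.warn(f"chord {tag} projects to zero length in x/z plane",
                              RuntimeWarning)
            else:
                alpha = math.atan2(-cz, cx if is_down else -cx) * _R2D
        else:
            # fallback: normal of the wing vector within the sagittal plane
            fx, fz = r_fw[0], r_fw[2]
            if math.hypot(fx, fz) < 1e-9:
                quality = "missing"
            else:
                delta = math.atan2(-fz, fx if is_down else -fx)
                alpha = (delta * _R2D + 90.0) % 180.0
                quality = "fallback"
        out[tag] = {"phi": phi, "theta": theta, "alpha": alpha,
                    "alpha_quality": quality, "r_fw": r_fw}
    return out


def stroke_amplitudes(frame_a, pose_a: BodyPose, frame_b, pose_b: BodyPose) -> dict:
    """Halfstroke amplitudes from two consecutive opposite-type endstrokes.

    Psi_p is the full 3D angle swept by the base-to-forewing-tip vector in
    the BRF; phi_p and theta_p are the angles between its projections onto
    the BRF x/y and x/z planes respectively.  Raises on same-type
    consecutive endstrokes.
    """
    ph_a = frame_a["phase"] if not isinstance(frame_a, dict) else frame_a.get("phase")
    ph_b = frame_b["phase"] if not isinstance(frame_b, dict) else frame_b.get("phase")
    if {ph_a, ph_b} != {"end_up", "end_down"}:
        raise ValueError(
            f"stroke amplitudes need consecutive opposite endstrokes, got {ph_a}, {ph_b}"
        )

    def angle(u, v):
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            return 0.0
        # atan2 form is accurate near 0 and 180 deg
        return math.atan2(np.linalg.norm(np.cross(u, v)), float(np.dot(u, v))) * _R2D

    out = {}
    for tag in ("L", "R"):
        a = wing_angles(frame_a, pose_a)[tag]["r_fw"]
        b = wing_angles(frame_b, pose_b)[tag]["r_fw"]
        out[tag] = {
            "psi_p": angle(a, b),
            "phi_p": angle(a * [1, 1, 0], b * [1, 1, 0]),
            "theta_p": angle(a * [1, 0, 1], b * [1, 0, 1]),
        }
    return out


def wingbeat_derivatives(times: np.ndarray, values: np.ndarray,
                         frames_per_beat: int = 4) -> np.ndarray:
    """First derivative from like-phase (one-wingbeat-apart) differences.

    For frame i the derivative is the central difference between frames
    i - frames_per_beat and i + frames_per_beat; the first/last wingbeat
    falls back to forward/backward one-wingbeat differences.  Any signal
    with period exactly one wingbeat contributes zero.  Missing samples
    propagate as NaN.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    n = len(v)
    k = frames_per_beat
    if n < 2 * k + 1:
        raise ValueError("need at least 3 consecutive wingbeats of samples")
    d = np.full(n, np.nan)
    # central
    i = np.arange(k, n - k)
    d[i] = (v[i + k] - v[i - k]) / (t[i + k] - t[i - k])
    # ends: one-beat forward/backward
    i = np.arange(0, k)
    d[i] = (v[i + k] - v[i]) / (t[i + k] - t[i])
    i = np.arange(n - k, n)
    d[i] = (v[i] - v[i - k]) / (t[i] - t[i - k])
    return d


def segment_maneuvers(times: np.ndarray, ydd: np.ndarray,
                      min_duration: float = 0.077) -> np.ndarray:
    """Label maximal constant-sign runs of lateral acceleration as maneuvers.

    Runs whose time span is at least ``min_duration`` (s) receive maneuver
    ids 1, 2, ...; all other samples get 0.  NaN samples break runs.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(ydd, dtype=float)
    sign = np.where(np.isnan(a), 0, np.sign(a)).astype(int)
    labels = np.zeros(len(a), dtype=int)
    next_id = 1
    i = 0
    while i < len(a):
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(a) and sign[j + 1] == sign[i]:
            j += 1
        if t[j] - t[i] >= min_duration:
            labels[i:j + 1] = next_id
            next_id += 1
        i = j + 1
    return labels


def stroke_plane_roll(frame) -> float:
    """Angle of the line between the two forewing tips relative to the GRF
    horizontal (deg), positive when the right tip is lower."""
    p4l = _get_point(frame, "p4L_forewingtip")
    p4r = _get_point(frame, "p4R_forewingtip")
    if np.isnan(p4l).any() or np.isnan(p4r).any():
        raise LandmarkDegeneracyError("forewing tip missing for stroke-plane roll")
    d = p4r - p4l
    span = math.hypot(d[0], d[1])
    if span < 1e-9 and abs(d[2]) < 1e-9:
        raise LandmarkDegeneracyError("coincident forewing tips")
    return math.atan2(d[2], span) * _R2D


def _heading_reference(yaws: np.ndarray) -> float:
    """Circular mean heading (deg) used to define the trial's MGRF."""
    rad = np.deg2rad(yaws)
    return math.degrees(math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))


def _mgrf_rotation(yaw_ref_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(yaw_ref_deg)), math.sin(math.radians(yaw_ref_deg))
    # rotate GRF by -yaw about the vertical: z unchanged
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def build_stroke_table(frames: pd.DataFrame, min_maneuver_s: float = 0.077
                       ) -> pd.DataFrame:
    """One row per halfstroke: midstroke angles, amplitudes, asymmetries and
    wingbeat-scale body-state derivatives.

    Expects the wide landmark schema (``frame, time_s, phase`` plus x/y/z
    per named point) with phases cycling end_up -> mid_down -> end_down ->
    mid_up.  Body position/velocity are expressed in the trial's MGRF;
    roll is GRF-absolute.  Centered columns (suffix ``_c``) subtract the
    whole-table mean; the means used are stored in ``table.attrs``
    ['centering_means'] along with stair-step summaries in
    ``table.attrs['annotations']``.
    """
    df = frames.sort_values("frame").reset_index(drop=True)
    phases = df["phase"].to_list()
    start = phases.index("end_up")
    df = df.iloc[start:].reset_index(drop=True)
    phases = df["phase"].to_list()
    n = len(df)
    for i, ph in enumerate(phases):
        if ph != PHASES[i % 4]:
            raise ValueError(
                f"phase sequence broken at frame {i}: expected {PHASES[i % 4]}, got {ph}"
            )
    if n < 12:
        raise ValueError("need at least 3 complete wingbeats of landmark frames")

    poses = [body_euler(df.iloc[i]) for i in range(n)]
    yaw = np.array([p.yaw for p in poses])
    roll = np.unwrap(np.array([p.roll for p in poses]), period=360.0)
    yaw_ref = _heading_reference(yaw)
    M = _mgrf_rotation(yaw_ref)
    # whole-body reference point: centroid of points 1-3, in MGRF
    body_xyz = np.stack([
        (_get_point(df.iloc[i], "p1_scutum")
         + _get_point(df.iloc[i], "p3L_wingbase")
         + _get_point(df.iloc[i], "p3R_wingbase")) / 3.0
        for i in range(n)]) @ M.T
    t = df["time_s"].to_numpy()
    y_m = body_xyz[:, 1]
    z_m = body_xyz[:, 2]

    ydot = wingbeat_derivatives(t, y_m)
    zdot = wingbeat_derivatives(t, z_m)
    betadot = wingbeat_derivatives(t, roll)
    yddot = wingbeat_derivatives(t, ydot)
    zddot = wingbeat_derivatives(t, zdot)
    betaddot = wingbeat_derivatives(t, betadot)

    def beat_mean(series, k):
        lo, hi = 4 * k, min(4 * k + 4, n)
        window = series[lo:hi]
        return float(np.nanmean(window)) if np.isfinite(window).any() else np.nan

    wing = [wing_angles(df.iloc[i], poses[i]) for i in range(n)]

    rows = []
    half_id = 0
    for k in range(n // 4):
        base = 4 * k
        for stroke, mid_off, e1_off, e2_off in (("down", 1, 0, 2), ("up", 3, 2, 4)):
            mid = base + mid_off
            e1 = base + e1_off
            e2 = base + e2_off
            if e2 >= n or mid >= n:
                continue
            amp = stroke_amplitudes(df.iloc[e1], poses[e1], df.iloc[e2], poses[e2])
            wm = wing[mid]
            alpha_L, alpha_R = wm["L"]["alpha"], wm["R"]["alpha"]
            yd = beat_mean(ydot, k)
            zd = beat_mean(zdot, k)
            row = {
                "halfstroke": half_id,
                "time_s": t[mid],
                "stroke": stroke,
                "moth_id": df.iloc[mid].get("moth_id", "moth1"),
                "trial_id": df.iloc[mid].get("trial_id", "trial1"),
                "alpha_L": alpha_L, "alpha_R": alpha_R,
                "alpha_LR": alpha_L - alpha_R,
                "alpha_bar": 0.5 * (alpha_L + alpha_R),
                "alpha_quality_L": wm["L"]["alpha_quality"],
                "alpha_quality_R": wm["R"]["alpha_quality"],
                "phi_L": wm["L"]["phi"], "phi_R": wm["R"]["phi"],
                "phi_LR": wm["L"]["phi"] - wm["R"]["phi"],
                "theta_L": wm["L"]["theta"], "theta_R": wm["R"]["theta"],
                "theta_LR": wm["L"]["theta"] - wm["R"]["theta"],
                "phi_p_L": amp["L"]["phi_p"], "phi_p_R": amp["R"]["phi_p"],
                "phi_p_LR": amp["L"]["phi_p"] - amp["R"]["phi_p"],
                "phi_p_bar": 0.5 * (amp["L"]["phi_p"] + amp["R"]["phi_p"]),
                "theta_p_L": amp["L"]["theta_p"], "theta_p_R": amp["R"]["theta_p"],
                "theta_p_LR": amp["L"]["theta_p"] - amp["R"]["theta_p"],
                "theta_p_bar": 0.5 * (amp["L"]["theta_p"] + amp["R"]["theta_p"]),
                "psi_p_L": amp["L"]["psi_p"], "psi_p_R": amp["R"]["psi_p"],
                "psi_p_LR": amp["L"]["psi_p"] - amp["R"]["psi_p"],
                "psi_p_bar": 0.5 * (amp["L"]["psi_p"] + amp["R"]["psi_p"]),
                "beta": roll[mid],
                "sgn_beta": float(np.sign(roll[mid])) if roll[mid] != 0 else 0.0,
                "yaw": yaw[mid],
                "pitch": poses[mid].pitch,
                "stroke_plane_roll": stroke_plane_roll(df.iloc[mid]),
                "y_dot": yd, "z_dot": zd,
                "y_ddot": beat_mean(yddot, k), "z_ddot": beat_mean(zddot, k),
                "beta_dot": beat_mean(betadot, k),
                "beta_ddot": beat_mean(betaddot, k),
            }
            # ipsilateral-to-lateral-velocity wing: drag proxy |v| sin(theta_i)
            if np.isfinite(yd):
                theta_i = wm["R"]["theta"] if yd > 0 else wm["L"]["theta"]
                speed = math.hypot(yd, zd if np.isfinite(zd) else 0.0)
                row["theta_i"] = theta_i
                row["drag_i"] = speed * math.sin(math.radians(theta_i))
            else:
                row["theta_i"] = np.nan
                row["drag_i"] = np.nan
            rows.append(row)
            half_id += 1

    table = pd.DataFrame(rows)
    # centering over the entire data set
    means = {}
    for col in ("alpha_bar", "phi_p_bar", "theta_p_bar", "psi_p_bar"):
        means[col] = float(table[col].mean())
        table[f"{col}_c"] = table[col] - means[col]

    # maneuver labels from the halfstroke-level lateral acceleration series
    table["maneuver_id"] = segment_maneuvers(
        table["time_s"].to_numpy(), table["y_ddot"].to_numpy(),
        min_duration=min_maneuver_s)

    down = table[table["stroke"] == "down"]
    up = table[table["stroke"] == "up"]
    ann = {}
    if len(down) and len(up):
        with np.errstate(invalid="ignore"):
            ann["abs_alpha_LR_down_over_up"] = float(
                down["alpha_LR"].abs().mean() / max(up["alpha_LR"].abs().mean(), 1e-12))
            ann["alpha_bar_down_over_up"] = float(
                down["alpha_bar"].mean() / up["alpha_bar"].mean())
    x = table["alpha_LR"].to_numpy()
    x = x[np.isfinite(x)]
    if len(x) > 4:
        xc = x - x.mean()
        denom = float(np.sum(xc ** 2))
        ann["alpha_LR_autocorr"] = {
            k: float(np.sum(xc[:-k] * xc[k:]) / denom) for k in (1, 2, 4)
        }
    table.attrs["centering_means"] = means
    table.attrs["annotations"] = ann
    return table


def write_stroke_table(table: pd.DataFrame, path) -> None:
    """Write the stroke table CSV plus a JSON sidecar of centering means."""
    table.to_csv(path, index=False)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"centering_means": table.attrs.get("centering_means", {}),
                   "annotations": table.attrs.get("annotations", {})}, fh, indent=1)


def read_stroke_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        table.attrs.update(meta)
    except FileNotFoundError:
        pass
    return table
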