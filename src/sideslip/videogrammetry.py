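"""Direct linear transformation (DLT) camera calibration and triangulation.

The 11-coefficient DLT maps a 3D point (X, Y, Z) to pixels (u, v):

    u = (L1 X + L2 Y + L3 Z + L4) / (L9 X + L10 Y + L11 Z + 1)
    v = (L5 X + L6 Y + L7 Z + L8) / (L9 X + L10 Y + L11 Z + 1)

fixing the 12th projective parameter to 1, the convention used by the
coefficient files of common digitization tools (11 rows, one column per
camera).  Calibration here requires known 3D control points; a calibration
wand with two LEDs at a known separation is used as a reconstruction
diagnostic, not for self-calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CameraModel",
    "calibrate_dlt",
    "triangulate",
    "triangulate_table",
    "wand_diagnostics",
    "make_camera",
    "read_dlt_csv",
    "write_dlt_csv",
]


@dataclass
class CameraModel:
    """One camera's 11 DLT coefficients plus image metadata."""

    L: np.ndarray
    image_size: tuple[int, int] = (1024, 1024)
    label: str = "cam"

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float).ravel()
        if self.L.shape != (11,):
            raise ValueError("CameraModel needs exactly 11 DLT coefficients")

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project (n, 3) world points to (n, 2) pixels.

        Points at or behind the camera plane (denominator <= 0) yield NaN.
        """
        P = np.atleast_2d(np.asarray(points, dtype=float))
        L = self.L
        den = P @ L[8:11] + 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (P @ L[0:3] + L[3]) / den
            v = (P @ L[4:7] + L[7]) / den
        bad = den <= 1e-12
        uv = np.column_stack([u, v])
        uv[bad] = np.nan
        return uv


def make_camera(position, target, up=(0.0, 0.0, -1.0), focal_px: float = 1500.0,
                principal=(512.0, 512.0), image_size=(1024, 1024),
                label: str = "cam") -> CameraModel:
    """Build a pinhole camera looking from ``position`` toward ``target`` and
    return its exact DLT coefficients.

    The explicit projection-matrix construction doubles as an independent
    oracle for :func:`calibrate_dlt`.
    """
    pos = np.asarray(position, dtype=float)
    fwd = np.asarray(target, dtype=float) - pos
    fwd = fwd / np.linalg.norm(fwd)
    upv = np.asarray(up, dtype=float)
    right = np.cross(fwd, upv)
    nr = np.linalg.norm(right)
    if nr < 1e-9:
        raise ValueError("up vector parallel to viewing direction")
    right /= nr
    down = np.cross(fwd, right)
    Rw2c = np.vstack([right, down, fwd])          # world -> camera axes
    t = -Rw2c @ pos
    K = np.array([[focal_px, 0.0, principal[0]],
                  [0.0, focal_px, principal[1]],
                  [0.0, 0.0, 1.0]])
    P = K @ np.hstack([Rw2c, t[:, None]])          # 3x4 projection matrix
    P = P / P[2, 3]                                # DLT normalization: P[2,3] = 1
    L = np.concatenate([P[0, :], P[1, :], P[2, :3]])
    return CameraModel(L=L, image_size=tuple(image_size), label=label)


def calibrate_dlt(control_points_3d: np.ndarray, pixels: np.ndarray,
                  image_size=(1024, 1024), label: str = "cam"
                  ) -> tuple[CameraModel, float]:
    """Least-squares DLT calibration from >= 6 non-coplanar control points.

    Returns ``(CameraModel, reprojection RMSE in px)`` where the RMSE is
    computed over all control points, pooling u and v residuals.
    """
    X = np.atleast_2d(np.asarray(control_points_3d, dtype=float))
    uv = np.atleast_2d(np.asarray(pixels, dtype=float))
    if X.shape[0] != uv.shape[0]:
        raise ValueError("3D points and pixel observations must align")
    if X.shape[0] < 6:
        raise ValueError("DLT calibration needs at least 6 control points")
    # coplanarity / degenerate geometry check
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-6 * max(sv[0], 1.0):
        raise ValueError(
            "control points are coplanar (or collinear): DLT system is rank deficient"
        )
    n = X.shape[0]
    A = np.zeros((2 * n, 11))
    b = np.empty(2 * n)
    A[0::2, 0:3] = X
    A[0::2, 3] = 1.0
    A[0::2, 8:11] = -uv[:, 0:1] * X
    A[1::2, 4:7] = X
    A[1::2, 7] = 1.0
    A[1::2, 8:11] = -uv[:, 1:2] * X
    b[0::2] = uv[:, 0]
    b[1::2] = uv[:, 1]
    L, *_ = np.linalg.lstsq(A, b, rcond=None)
    cam = CameraModel(L=L, image_size=tuple(image_size), label=label)
    resid = cam.project(X) - uv
    rmse = float(np.sqrt(np.nanmean(resid ** 2)))
    return cam, rmse


def triangulate(cameras: list[CameraModel], pixels: np.ndarray
                ) -> tuple[np.ndarray, float]:
    """Linear least-squares 3D intersection of DLT rays.

    Parameters
    ----------
    cameras : list of CameraModel
    pixels : (n_cameras, 2) pixel observations; rows with NaN are treated as
        missing views

    Returns ``(xyz, reprojection_residual_px)``.  With fewer than two valid
    views the point is unreconstructable and ``(nan array, nan)`` is
    returned rather than raising, matching sparse hand digitization.
    """
    uv = np.atleast_2d(np.asarray(pixels, dtype=float))
    if uv.shape[0] != len(cameras):
        raise ValueError("one pixel row per camera required")
    valid = ~np.isnan(uv).any(axis=1)
    if valid.sum() < 2:
        return np.full(3, np.nan), np.nan
    rows = []
    rhs = []
    for cam, (u, v), ok in zip(cameras, uv, valid):
        if not ok:
            continue
        L = cam.L
        rows.append(L[0:3] - u * L[8:11])
        rhs.append(u - L[3])
        rows.append(L[4:7] - v * L[8:11])
        rhs.append(v - L[7])
    A = np.asarray(rows)
    b = np.asarray(rhs)
    xyz, *_ = np.linalg.lstsq(A, b, rcond=None)
    res = []
    for cam, (u, v), ok in zip(cameras, uv, valid):
        if not ok:
            continue
        proj = cam.project(xyz[None, :])[0]
        res.append(proj - (u, v))
    rmse = float(np.sqrt(np.mean(np.square(res))))
    return xyz, rmse


def triangulate_table(cameras: list[CameraModel],
                      pixel_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Triangulate per-camera pixel tables (columns frame, point_name, u, v)
    into a long table of 3D points (frame, point_name, x, y, z, residual_px)."""
    merged = None
    for i, tab in enumerate(pixel_tables):
        t = tab.rename(columns={"u": f"u{i}", "v": f"v{i}"})
        merged = t if merged is None else merged.merge(
            t, on=["frame", "point_name"], how="outer")
    out = []
    for _, row in merged.iterrows():
        uv = np.array([[row.get(f"u{i}", np.nan), row.get(f"v{i}", np.nan)]
                       for i in range(len(cameras))], dtype=float)
        xyz, resid = triangulate(cameras, uv)
        out.append({"frame": row["frame"], "point_name": row["point_name"],
                    "x": xyz[0], "y": xyz[1], "z": xyz[2], "residual_px": resid})
    return pd.DataFrame(out)


def wand_diagnostics(cameras: list[CameraModel], wand,
                     nominal_mm: float | None = None) -> dict:
    """Reconstruct the two wand LEDs per frame and report the separation
    statistics against the nominal length.

    ``wand`` is a :class:`~sideslip.observe.WandTrack` (or any object with
    ``pixels`` of shape (n_frames, n_cameras, 2 LEDs, 2) and
    ``separation_mm``).  Separations are reported in mm (world units cm).
    """
    nominal = float(wand.separation_mm if nominal_mm is None else nominal_mm)
    if nominal <= 0:
        raise ValueError("nominal wand length must be positive")
    px = wand.pixels
    n_frames = px.shape[0]
    seps = np.full(n_frames, np.nan)
    for f in range(n_frames):
        a, _ = triangulate(cameras, px[f, :, 0, :])
        b, _ = triangulate(cameras, px[f, :, 1, :])
        if np.isnan(a).any() or np.isnan(b).any():
            continue
        seps[f] = np.linalg.norm(a - b) * 10.0  # cm -> mm
    ok = np.isfinite(seps)
    if not ok.any():
        raise ValueError("no wand frame could be reconstructed from >= 2 views")
    err = seps[ok] - nominal
    return {
        "separation_mm": seps,
        "mean_mm": float(np.mean(seps[ok])),
        "sd_mm": float(np.std(seps[ok], ddof=1)) if ok.sum() > 1 else 0.0,
        "rmse_mm": float(np.sqrt(np.mean(err ** 2))),
        "nominal_mm": nominal,
        "n_reconstructed": int(ok.sum()),
    }


def write_dlt_csv(cameras: list[CameraModel], path) -> None:
    """Write coefficients as 11 rows x one column per camera."""
    df = pd.DataFrame({c.label: c.L for c in cameras})
    df.to_csv(path, index=False)


def read_dlt_csv(path, image_size=(1024, 1024)) -> list[CameraModel]:
    df = pd.read_csv(path)
    if df.shape[0] != 11:
        raise ValueError("DLT coefficient file must have exactly 11 rows")
    return [CameraModel(L=df[c].to_numpy(), image_size=image_size, label=str(c))
            for c in df.columns]
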