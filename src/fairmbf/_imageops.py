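"""Internal helpers: numpy <-> SimpleITK conversion and rigid resampling.

All 2-D arrays follow the (row, col) = (y, x) convention with y increasing
downward; SimpleITK images index (x, y), so conversion is handled here once.
Physical coordinates are index * spacing (origin at pixel 0's center).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import SimpleITK as sitk


@dataclass
class RigidTransform:
    """In-plane rigid motion: translation in pixels, rotation in degrees.

    Semantics follow resampling: applying the transform maps each output
    (fixed-grid) point p to the input point R(p - c) + c + t, i.e. image
    content moves by approximately (-tx, -ty) pixels and -theta degrees.
    Rotation is about the stated ROI/phantom center.
    """

    tx_px: float = 0.0
    ty_px: float = 0.0
    theta_deg: float = 0.0

    def __post_init__(self):
        if not all(np.isfinite([self.tx_px, self.ty_px, self.theta_deg])):
            raise ValueError("rigid transform parameters must be finite")

    def inverse(self) -> "RigidTransform":
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        # inverse of p -> R p + t (about the same center) is p -> R^T (p - t)
        tx, ty = self.tx_px, self.ty_px
        return RigidTransform(-(c * tx + s * ty), -(-s * tx + c * ty), -self.theta_deg)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        return RigidTransform(
            c * other.tx_px - s * other.ty_px + self.tx_px,
            s * other.tx_px + c * other.ty_px + self.ty_px,
            self.theta_deg + other.theta_deg,
        )

    def is_near_identity(self, tol_px: float = 0.1, tol_deg: float = 0.1) -> bool:
        return (abs(self.tx_px) <= tol_px and abs(self.ty_px) <= tol_px
                and abs(self.theta_deg) <= tol_deg)


def to_sitk(arr: np.ndarray, spacing_mm: Tuple[float, float]) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float64))
    img.SetSpacing((float(spacing_mm[1]), float(spacing_mm[0])))  # (x, y)
    return img


def from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img)


def euler2d(transform: RigidTransform, spacing_mm, center_px) -> sitk.Euler2DTransform:
    """Build the SimpleITK transform for pixel-unit rigid parameters."""
    sx, sy = float(spacing_mm[1]), float(spacing_mm[0])
    tx = sitk.Euler2DTransform()
    tx.SetCenter((center_px[1] * sx, center_px[0] * sy))
    tx.SetAngle(float(np.deg2rad(transform.theta_deg)))
    tx.SetTranslation((transform.tx_px * sx, transform.ty_px * sy))
    return tx


def rigid_from_euler2d(tx: sitk.Euler2DTransform, spacing_mm) -> RigidTransform:
    sx, sy = float(spacing_mm[1]), float(spacing_mm[0])
    angle = float(tx.GetParameters()[0])
    t = tx.GetTranslation()
    return RigidTransform(t[0] / sx, t[1] / sy, float(np.rad2deg(angle)))


def apply_rigid(arr: np.ndarray, transform: RigidTransform, spacing_mm,
                center_px, fill: float = 0.0, nearest: bool = False) -> np.ndarray:
    """Resample a 2-D array under a rigid transform (bilinear by default)."""
    img = to_sitk(arr, spacing_mm)
    tx = euler2d(transform, spacing_mm, center_px)
    interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear
    out = sitk.Resample(img, img, tx, interp, float(fill))
    return from_sitk(out)
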