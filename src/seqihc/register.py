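"""Rigid alignment of staining rounds to the first round's frame.

Each round is a rescan of the same physical section, so rounds differ only
by a small rigid jitter (stage placement, slide seating).  Translation is
estimated by phase correlation with subpixel refinement; rotation by a
coarse-to-fine search maximising the phase-correlation match.  Registration
runs on scalar signal maps rather than RGB because the tissue structure
shared across rounds — not the round-specific stain — is what should drive
the alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core import SignalMap, StainedSlideImage


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about the raster center followed by a translation.

    Maps a point ``p = (x, y)`` (x = column, y = row, pixels) to
    ``R(theta) @ (p - c) + c + (dx, dy)`` where ``c`` is the raster center.
    Positive ``theta_deg`` rotates x toward y (clockwise on screen with the
    origin top-left).
    """

    dx_px: float = 0.0
    dy_px: float = 0.0
    theta_deg: float = 0.0

    def _rotation(self) -> np.ndarray:
        th = math.radians(self.theta_deg)
        return np.array([[math.cos(th), -math.sin(th)],
                         [math.sin(th), math.cos(th)]])

    def apply(self, points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Apply to ``(n, 2)`` points in (x, y) order for a raster of ``shape``."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        c = np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])
        t = np.array([self.dx_px, self.dy_px])
        return (pts - c) @ self._rotation().T + c + t

    def inverse(self) -> "RigidTransform":
        th = math.radians(-self.theta_deg)
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        t = -rot @ np.array([self.dx_px, self.dy_px])
        return RigidTransform(t[0], t[1], -self.theta_deg)

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``first`` then ``self``."""
        t = self._rotation() @ np.array([first.dx_px, first.dy_px])
        return RigidTransform(t[0] + self.dx_px, t[1] + self.dy_px,
                              self.theta_deg + first.theta_deg)

    @property
    def is_identity(self) -> bool:
        return self.dx_px == 0.0 and self.dy_px == 0.0 and self.theta_deg == 0.0

    def to_dict(self) -> dict:
        return {"dx_px": float(self.dx_px), "dy_px": float(self.dy_px),
                "theta_deg": float(self.theta_deg)}


def _warp_plane(plane: np.ndarray, t: RigidTransform, fill: float) -> np.ndarray:
    """Inverse-mapped bilinear resampling of one 2-D plane."""
    if t.is_identity:
        return plane.copy()
    h, w = plane.shape
    inv = t.inverse()
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(np.float64)
    src = inv.apply(pts, (h, w))
    coords = np.stack([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])
    return ndimage.map_coordinates(plane, coords, order=1, mode="constant",
                                   cval=fill)


def warp(obj, t: RigidTransform, fill: float | None = None):
    """Warp an image, signal map, or bare 2-D array by a rigid transform.

    Pixels mapped from outside the field are filled with white for RGB
    images (the slide background) and 0 for signal maps (no signal).
    Output dimensions are unchanged.
    """
    if isinstance(obj, StainedSlideImage):
        f = 1.0 if fill is None else fill
        out = np.stack([_warp_plane(obj.pixels[..., c], t, f) for c in range(3)],
                       axis=-1)
        return obj.with_pixels(np.clip(out, 0.0, 1.0))
    if isinstance(obj, SignalMap):
        f = 0.0 if fill is None else fill
        out = _warp_plane(obj.values, t, f)
        return obj.with_values(np.clip(out, 0.0, 1.0), frame="reference")
    arr = np.asarray(obj, dtype=np.float64)
    if arr.ndim == 2:
        return _warp_plane(arr, t, 0.0 if fill is None else fill)
    return np.stack([_warp_plane(arr[..., c], t, 0.0 if fill is None else fill)
                     for c in range(arr.shape[2])], axis=-1)


def transform_points_um(points_um: np.ndarray, t: RigidTransform,
                        shape: tuple[int, int],
                        pixel_size_um: float) -> np.ndarray:
    """Map (x_um, y_um) points through a transform estimated on rasters.

    Pixel index ``i`` has its center at ``(i + 0.5) * pixel_size_um``;
    transforms operate on index coordinates.
    """
    idx = np.atleast_2d(np.asarray(points_um, dtype=np.float64)) / pixel_size_um - 0.5
    return (t.apply(idx, shape) + 0.5) * pixel_size_um


def _as_array(m) -> np.ndarray:
    return m.values if isinstance(m, SignalMap) else np.asarray(m, dtype=np.float64)


def _translation(reference: np.ndarray, moving: np.ndarray,
                 upsample: int) -> tuple[float, float, float]:
    """Subpixel shift aligning ``moving`` to ``reference`` plus the residual error."""
    shift, error, _ = phase_cross_correlation(reference, moving,
                                              upsample_factor=upsample,
                                              normalization=None)
    # shift is (row, col) to apply to `moving`
    return float(shift[1]), float(shift[0]), float(error)


def estimate_rigid(reference, moving, *, theta_range_deg: float = 3.0,
                   coarse_step_deg: float = 0.25, fine_step_deg: float = 0.05,
                   upsample: int = 100) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` to ``reference``.

    The returned ``t`` satisfies ``warp(moving, t) ≈ reference``.  Rotation
    is searched coarse-to-fine over ``±theta_range_deg`` (set 0 to estimate
    translation only); translation comes from phase correlation with
    subpixel refinement.  Fully deterministic.

    Raises
    ------
    ValueError
        If either input is constant ("no structure to register").
    """
    ref = _as_array(reference)
    mov = _as_array(moving)
    if ref.shape != mov.shape:
        raise ValueError("reference and moving must share dimensions")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise ValueError("no structure to register: constant input")

    def score(theta: float, a: np.ndarray, b: np.ndarray) -> float:
        rotated = _warp_plane(b, RigidTransform(0.0, 0.0, theta), 0.0)
        return _translation(a, rotated, upsample=10)[2]

    best_theta = 0.0
    if theta_range_deg > 0:
        # the rotation score is a global image property, so both sweeps run
        # on block-averaged rasters: ~512 px for the coarse grid, ~1024 px
        # for the fine grid around the coarse optimum
        def shrink(arr: np.ndarray, target: int) -> np.ndarray:
            factor = max(1, int(np.ceil(max(arr.shape) / target)))
            if factor == 1:
                return arr
            from skimage.transform import downscale_local_mean

            return downscale_local_mean(arr, (factor, factor))

        ref_s, mov_s = shrink(ref, 512), shrink(mov, 512)
        coarse = np.arange(-theta_range_deg, theta_range_deg + 1e-9,
                           coarse_step_deg)
        errs = [score(th, ref_s, mov_s) for th in coarse]
        best_theta = float(coarse[int(np.argmin(errs))])
        ref_f, mov_f = shrink(ref, 1024), shrink(mov, 1024)
        fine = np.arange(best_theta - coarse_step_deg,
                         best_theta + coarse_step_deg + 1e-9, fine_step_deg)
        errs = [score(th, ref_f, mov_f) for th in fine]
        best_theta = float(fine[int(np.argmin(errs))])

    rotated = _warp_plane(mov, RigidTransform(0.0, 0.0, best_theta), 0.0)
    dx, dy, _ = _translation(ref, rotated, upsample=upsample)
    # translation applied after the rotation: exactly RigidTransform(dx, dy, theta)
    return RigidTransform(dx, dy, best_theta)
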