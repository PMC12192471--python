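"""Deterministic head phantom: noiseless HU slices with GM/WM ROI masks.

The phantom is a stand-in for patient anatomy: an elliptical head with a
skull rim, brain parenchyma background, two thalamic gray-matter (GM)
ellipses and two frontal periventricular white-matter (WM) ellipses.  ROI
masks coincide with the GM/WM ellipses on the mid slice, so the noiseless
mask means equal the specified tissue values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhantomSpec", "ImageStack", "make_head_phantom"]

HU_AIR = -1000.0
HU_BONE = 900.0


@dataclass(frozen=True)
class ImageStack:
    """A stack of co-registered 2D slices in Hounsfield units."""

    values: np.ndarray  # (n_slice, H, W)
    pixel_size: float  # mm

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("image stack must be 3D (n_slice, H, W)")
        if not np.all(np.isfinite(v)):
            raise ValueError("image stack contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "values", v)

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue values of the synthetic head phantom.

    HU defaults follow typical thalamic GM (~39.9) and frontal WM (~33.5)
    attenuation; the matrix and pixel size default to the reconstruction
    grid of the emulated protocol (512 px, 0.429 mm).
    """

    matrix_size: int = 512
    pixel_size: float = 0.429  # mm
    gm_value: float = 39.916  # HU
    wm_value: float = 33.452  # HU
    background_value: float = 30.0  # HU, brain parenchyma
    n_slices: int = 1
    # parametric ellipse layout, in fractions of the matrix size:
    # (center_x, center_y, semi_x, semi_y)
    geometry: dict = field(
        default_factory=lambda: {
            "head": (0.50, 0.50, 0.42, 0.46),
            "skull_thickness": 0.035,
            "gm": [(0.435, 0.52, 0.045, 0.075), (0.565, 0.52, 0.045, 0.075)],
            "wm": [(0.42, 0.36, 0.045, 0.06), (0.58, 0.36, 0.045, 0.06)],
        }
    )

    def __post_init__(self) -> None:
        if self.matrix_size < 32:
            raise ValueError("matrix_size must be >= 32 (degenerate geometry)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not self.gm_value > self.wm_value:
            raise ValueError("gm_value must exceed wm_value")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


def _ellipse_mask(n: int, cx: float, cy: float, sx: float, sy: float) -> np.ndarray:
    x = (np.arange(n) + 0.5) / n
    xx, yy = np.meshgrid(x, x)
    return ((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2 <= 1.0


def make_head_phantom(spec: PhantomSpec) -> tuple[ImageStack, dict[str, np.ndarray]]:
    """Build the noiseless phantom stack and its GM/WM ROI masks.

    Returns
    -------
    stack : ImageStack
        (n_slices, N, N) HU values.  The head outline shrinks mildly toward
        the first and last slice to mimic the cranial vault; GM/WM regions
        are constant across slices.
    masks : dict
        Boolean ROI masks ``{"GM": ..., "WM": ...}`` for the mid slice.
    """
    n = spec.matrix_size
    geom = spec.geometry
    hx, hy, hsx, hsy = geom["head"]
    thick = geom["skull_thickness"]

    gm_mask = np.zeros((n, n), dtype=bool)
    for e in geom["gm"]:
        gm_mask |= _ellipse_mask(n, *e)
    wm_mask = np.zeros((n, n), dtype=bool)
    for e in geom["wm"]:
        wm_mask |= _ellipse_mask(n, *e)

    slices = np.empty((spec.n_slices, n, n), dtype=float)
    # parabolic through-plane scaling of the head outline, 0.88 at the ends
    if spec.n_slices > 1:
        z = np.linspace(-1.0, 1.0, spec.n_slices)
    else:
        z = np.zeros(1)
    scales = 1.0 - 0.12 * z ** 2
    for k, s in enumerate(scales):
        outer = _ellipse_mask(n, hx, hy, hsx * s, hsy * s)
        inner = _ellipse_mask(n, hx, hy, (hsx - thick) * s, (hsy - thick) * s)
        img = np.full((n, n), HU_AIR)
        img[outer] = HU_BONE
        img[inner] = spec.background_value
        img[gm_mask] = spec.gm_value
        img[wm_mask] = spec.wm_value
        slices[k] = img
    return ImageStack(slices, spec.pixel_size), {"GM": gm_mask, "WM": wm_mask}
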