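"""Focus stacking and depth-from-focus for multifocal brightfield stacks.

Compound eyes are strongly curved, so a single brightfield exposure leaves
most of the eye out of focus. Stacks are acquired at a fixed Z step (8 µm in
the reference acquisition protocol); per pixel, the plane of best focus is
found by a local sharpness score and used both to assemble an all-in-focus
2D image and to assign each pixel a physical altitude relative to the lowest
focal plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["ImageStack", "FocusedImage", "load_stack", "focus_stack", "altitude_map"]

# ITU-R 601 luma weights for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageStack:
    """An ordered stack of co-registered grayscale planes.

    Parameters
    ----------
    planes : ndarray, shape (n_planes, H, W)
        Plane intensities in [0, 1], ordered along the acquisition axis.
    z_step : float
        Physical distance between consecutive planes, in µm.
    """

    planes: np.ndarray
    z_step: float = 8.0

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValueError("stack needs >=1 plane of identical 2D shape")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


@dataclass
class FocusedImage:
    """All-in-focus composite plus the per-pixel best-focus plane index."""

    image: np.ndarray
    depth_index: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.depth_index = np.asarray(self.depth_index, dtype=int)
        if self.image.shape != self.depth_index.shape:
            raise ValueError("image and depth_index must share dimensions")
        if self.depth_index.min() < 0:
            raise ValueError("depth_index must be non-negative")


def _to_gray01(arr: np.ndarray) -> np.ndarray:
    """Convert one page to grayscale float in [0, 1]."""
    a = np.asarray(arr)
    if a.ndim == 3:
        if a.shape[-1] == 4:  # drop alpha
            a = a[..., :3]
        if a.shape[-1] != 3:
            raise ValueError(f"cannot interpret page of shape {a.shape}")
        a = a.astype(float) @ _LUMA
    else:
        a = a.astype(float)
    if np.issubdtype(np.asarray(arr).dtype, np.integer):
        a = a / np.iinfo(np.asarray(arr).dtype).max
    return np.clip(a, 0.0, 1.0)


def load_stack(path: str | Path, z_step: float = 8.0) -> ImageStack:
    """Read a single- or multi-page TIFF (or PNG/JPEG) as an ImageStack.

    RGB pages are converted to luminance; integer intensities are rescaled to
    [0, 1] by the dtype maximum. A single-page input yields a 1-plane stack.

    Raises
    ------
    ValueError
        If the file is unreadable or pages have unequal sizes.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"cannot read image file: {path}")
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        with tifffile.TiffFile(str(path)) as tif:
            pages = [p.asarray() for p in tif.pages]
    else:
        import imageio.v3 as iio

        data = iio.imread(str(path))
        # imageio may return (H, W), (H, W, C) or (N, H, W[, C])
        if data.ndim == 2 or (data.ndim == 3 and data.shape[-1] in (3, 4)):
            pages = [data]
        else:
            pages = list(data)
    if not pages:
        raise ValueError(f"no image pages found in {path}")
    gray = [_to_gray01(p) for p in pages]
    shapes = {g.shape for g in gray}
    if len(shapes) != 1:
        raise ValueError(f"pages have unequal sizes: {sorted(shapes)}")
    return ImageStack(np.stack(gray), z_step=z_step)


def sharpness_map(plane: np.ndarray, window: int) -> np.ndarray:
    """Local variance of the Laplacian within a square window.

    A standard depth-from-focus metric: in-focus regions carry high-frequency
    structure, so the Laplacian response fluctuates strongly there.
    """
    lap = ndimage.laplace(np.asarray(plane, dtype=float), mode="reflect")
    mean = ndimage.uniform_filter(lap, size=window, mode="reflect")
    mean_sq = ndimage.uniform_filter(lap * lap, size=window, mode="reflect")
    return np.maximum(mean_sq - mean * mean, 0.0)


def focus_stack(stack: ImageStack, window: int = 9) -> FocusedImage:
    """Depth-from-focus composite: per pixel, pick the sharpest plane.

    The per-pixel argmax of the sharpness score is median-filtered with the
    same window (neighborhood voting against speckle) before the composite
    image is assembled.

    Parameters
    ----------
    stack : ImageStack
    window : int
        Side of the square sharpness/median window, odd, >= 3.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    h, w = stack.shape
    if window > min(h, w):
        raise ValueError("window larger than image")
    if stack.n_planes == 1:
        return FocusedImage(stack.planes[0].copy(), np.zeros((h, w), dtype=int))
    scores = np.stack([sharpness_map(p, window) for p in stack.planes])
    depth = np.argmax(scores, axis=0)
    depth = ndimage.median_filter(depth, size=window, mode="reflect")
    image = np.take_along_axis(stack.planes, depth[None], axis=0)[0]
    return FocusedImage(image, depth)


def altitude_map(focused: FocusedImage, z_step: float = 8.0) -> np.ndarray:
    """Physical altitude (µm) per pixel, relative to the lowest focal plane.

    ``altitude = (depth_index - min(depth_index)) * z_step``; the output is
    non-negative and attains 0.
    """
    d = focused.depth_index
    return (d - d.min()) * float(z_step)
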