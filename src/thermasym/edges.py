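"""Gradient-based edge detection on thermograms.

The face (or mouth-cavity) boundary is where the skin/ambient temperature
contrast produces the largest spatial derivative, so edges are found by
thresholding the Prewitt gradient magnitude.  The threshold is relative — a
fraction of the maximum magnitude inside the region of interest — which makes
the edge map invariant to constant temperature offsets and to any uniform
rescaling of the gradient kernel.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .exceptions import NoEdgesError, ThermogramValidationError
from .io import Thermogram

__all__ = ["GradientField", "EdgeMap", "prewitt_gradient", "detect_edges", "mouth_roi_mask", "body_roi_mask"]


@dataclasses.dataclass(frozen=True)
class GradientField:
    """Prewitt derivatives of a temperature grid (°C per pixel).

    ``gx`` is the horizontal (column-direction) derivative, ``gy`` the
    vertical (row-direction) derivative, both unnormalized 3x3 Prewitt
    responses; ``magnitude = sqrt(gx**2 + gy**2)``.
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray


@dataclasses.dataclass(frozen=True)
class EdgeMap:
    """Boolean edge mask plus the (row, col) list of its true pixels."""

    mask: np.ndarray
    points: np.ndarray  # shape (n, 2), int, lexicographically sorted

    def __post_init__(self) -> None:
        expected = np.argwhere(self.mask)
        if not np.array_equal(expected, self.points):
            raise ValueError("points must enumerate exactly the true entries of mask")


def prewitt_gradient(tg: Thermogram) -> GradientField:
    """Convolve with the 3x3 Prewitt kernels (border handled by replication).

    A step of height h between two constant vertical halves yields
    |gx| = 3h on the two columns adjacent to the step away from the border,
    the classic unnormalized Prewitt response.
    """
    if tg.n_rows < 3 or tg.n_cols < 3:
        raise ThermogramValidationError("Prewitt gradient needs an image of at least 3 x 3")
    values = tg.values
    gx = ndimage.prewitt(values, axis=1, mode="nearest")
    gy = ndimage.prewitt(values, axis=0, mode="nearest")
    return GradientField(gx=gx, gy=gy, magnitude=np.hypot(gx, gy))


def detect_edges(
    tg: Thermogram,
    config: PipelineConfig | None = None,
    roi_mask: np.ndarray | None = None,
) -> EdgeMap:
    """Threshold the gradient magnitude at a fraction of its ROI maximum.

    A pixel is an edge pixel iff its gradient magnitude is at least
    ``edge_threshold_frac`` times the maximum magnitude within the region of
    interest, and it lies inside the ROI (when one is given).

    Raises
    ------
    NoEdgesError
        If the image is constant within the ROI (maximum gradient is zero)
        or the ROI is empty.
    """
    config = config or PipelineConfig()
    field = prewitt_gradient(tg)
    mag = field.magnitude
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != mag.shape:
            raise ThermogramValidationError("roi_mask shape must match the thermogram")
        if not roi_mask.any():
            raise NoEdgesError("region of interest is empty")
        max_mag = float(mag[roi_mask].max())
    else:
        max_mag = float(mag.max())
    if max_mag == 0.0:
        raise NoEdgesError("constant image: gradient magnitude is zero everywhere")
    mask = mag >= config.edge_threshold_frac * max_mag
    if roi_mask is not None:
        mask &= roi_mask
    if not mask.any():
        raise NoEdgesError("no pixel reaches the edge threshold inside the ROI")
    return EdgeMap(mask=mask, points=np.argwhere(mask))


def body_roi_mask(tg: Thermogram, config: PipelineConfig | None = None) -> np.ndarray:
    """Pixels warm enough to be body surface (face-view region of interest)."""
    config = config or PipelineConfig()
    return tg.values >= config.body_temp_floor_c


def mouth_roi_mask(tg: Thermogram, config: PipelineConfig | None = None) -> np.ndarray:
    """Pixels warm enough to be open mouth cavity (mouth-view region of interest).

    The cavity is the warmest region in an open-mouth thermogram, so a simple
    temperature floor isolates it from the surrounding skin.
    """
    config = config or PipelineConfig()
    return tg.values >= config.mouth_temp_floor_c
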