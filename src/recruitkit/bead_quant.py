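"""Bead-based protein-protein interaction quantification.

Each bead is outlined (manually in the original assay; by the simulator
here), the intensity threshold is the average of the inside and outside
mean intensities, and the reported bead value is the mean of inside pixels
at or above that threshold.  Bead values are aggregated as mean +/- sample
SD across beads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import draw, morphology

__all__ = [
    "BeadOutline",
    "BeadMeasurement",
    "quantify_bead",
    "aggregate_beads",
]


@dataclass
class BeadOutline:
    """Closed bead region as a binary mask; contour pixels count as inside."""

    bead_id: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("bead mask must be a non-empty 2-D region")

    @classmethod
    def from_polygon(
        cls, bead_id: int, vertices: np.ndarray, image_shape: tuple[int, int]
    ) -> "BeadOutline":
        """Build a mask from a closed polygon of (row, col) vertices.

        Pixels on the contour are included in the region.  Vertices outside
        the image raise an error.
        """
        vertices = np.asarray(vertices, dtype=float)
        if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
            raise ValueError("polygon needs >= 3 (row, col) vertices")
        if (
            (vertices < 0).any()
            or (vertices[:, 0] > image_shape[0] - 1).any()
            or (vertices[:, 1] > image_shape[1] - 1).any()
        ):
            raise ValueError("polygon extends beyond the image")
        mask = np.zeros(image_shape, dtype=bool)
        rr, cc = draw.polygon(vertices[:, 0], vertices[:, 1], shape=image_shape)
        mask[rr, cc] = True
        rr, cc = draw.polygon_perimeter(
            vertices[:, 0], vertices[:, 1], shape=image_shape
        )
        mask[rr, cc] = True
        return cls(bead_id, mask)


@dataclass
class BeadMeasurement:
    bead_id: int
    value: float
    threshold: float
    inside_mean: float
    outside_mean: float
    degenerate: bool


def quantify_bead(
    image: np.ndarray,
    outline: BeadOutline,
    *,
    other_beads: np.ndarray | None = None,
    annulus_width_px: int = 10,
) -> BeadMeasurement:
    """Per-bead intensity with the inside/outside average threshold.

    The outside reference is an annulus of ``annulus_width_px`` around the
    bead (excluding any pixels in ``other_beads``), which keeps the background
    local and robust to illumination gradients.  The threshold is
    ``(mean_inside + mean_outside) / 2`` and the reported value is the mean of
    inside pixels >= threshold.  When the inside mean does not exceed the
    outside mean there is no contrast to threshold on; the measurement is
    flagged degenerate and the plain inside mean is reported.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != outline.mask.shape:
        raise ValueError("outline mask shape does not match the image")
    inside = outline.mask
    annulus = ndi.binary_dilation(inside, structure=morphology.disk(annulus_width_px))
    outside = annulus & ~inside
    if other_beads is not None:
        outside &= ~np.asarray(other_beads, dtype=bool)
    if not outside.any():
        raise ValueError("no outside pixels available around the bead")
    inside_mean = float(image[inside].mean())
    outside_mean = float(image[outside].mean())
    threshold = 0.5 * (inside_mean + outside_mean)
    degenerate = inside_mean <= outside_mean
    sel = inside & (image >= threshold)
    if degenerate and not sel.any():
        value = inside_mean
    elif not sel.any():
        value = inside_mean
    else:
        value = float(image[sel].mean())
    return BeadMeasurement(
        outline.bead_id, value, threshold, inside_mean, outside_mean, degenerate
    )


def aggregate_beads(values) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) across bead values; SD is NaN for n < 2."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no bead values to aggregate")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size >= 2 else float("nan")
    return mean, sd
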