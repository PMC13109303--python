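"""Accession-region segmentation ("mask 1").

The tape patches carrying each accession's seeds are much lighter than the
scan background, so the L* channel of the CIE L*a*b* transform separates them
cleanly; the threshold is chosen by Li's minimum cross-entropy method. The
binary mask is then refined morphologically (closing, hole filling, opening)
and optionally cut along operator-supplied polylines, the file-based stand-in
for interactive splitting of fused patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage import color, draw, filters, morphology

from .errors import DegenerateInputError


@dataclass(frozen=True)
class SegmentationParams:
    """Morphological refinement settings (disk structuring elements, px)."""

    close_radius: int = 3
    open_radius: int = 2
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.close_radius < 0 or self.open_radius < 0:
            raise ValueError("radii must be >= 0")


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """CIE L*a*b* (sRGB, D65) image; L* in [0, 100]."""
    return color.rgb2lab(img)


def li_threshold(channel: np.ndarray) -> float:
    """Li's minimum cross-entropy threshold of a single channel.

    Raises :class:`DegenerateInputError` for a constant channel.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if np.ptp(channel) == 0:
        raise DegenerateInputError("constant channel has no threshold")
    return float(filters.threshold_li(channel))


def rasterize_polyline(line: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of a polyline as a 1-px 4-connected path.

    Diagonal Bresenham steps get an extra 4-neighbour pixel so the path
    blocks 8-connectivity when subtracted from a mask.
    """
    out = np.zeros(shape, bool)
    line = np.asarray(line, dtype=int)
    for (r0, c0), (r1, c1) in zip(line[:-1], line[1:]):
        rr, cc = draw.line(r0, c0, r1, c1)
        out[rr, cc] = True
        dr = np.diff(rr)
        dc = np.diff(cc)
        diag = (dr != 0) & (dc != 0)
        out[rr[:-1][diag] + dr[diag], cc[:-1][diag]] = True
    return out


def refine_mask(mask: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Closing -> hole filling -> opening, in that order."""
    params = params or SegmentationParams()
    out = np.asarray(mask, bool)
    if params.close_radius > 0:
        out = morphology.closing(out, morphology.disk(params.close_radius))
    if params.fill_holes:
        out = ndi.binary_fill_holes(out)
    if params.open_radius > 0:
        out = morphology.opening(out, morphology.disk(params.open_radius))
    return out


def apply_split_polylines(
    mask: np.ndarray, lines: Sequence[np.ndarray]
) -> np.ndarray:
    """Remove each polyline's 1-px raster from the mask (set difference)."""
    out = np.asarray(mask, bool).copy()
    for line in lines:
        out &= ~rasterize_polyline(line, out.shape)
    return out


def segment_accessions(
    img: np.ndarray,
    params: SegmentationParams | None = None,
    lines: Sequence[np.ndarray] = (),
) -> np.ndarray:
    """Full accession mask: Lab L* -> Li threshold -> refine -> polyline cuts.

    A degenerate (constant-lightness) image yields an empty mask with a
    warning instead of aborting, so batch runs survive blank frames.
    """
    lab = rgb_to_lab(img)
    lightness = lab[..., 0]
    try:
        thr = li_threshold(lightness)
    except DegenerateInputError:
        warnings.warn("constant-lightness image: emitting empty accession mask",
                      stacklevel=2)
        return np.zeros(img.shape[:2], bool)
    mask = lightness >= thr
    mask = refine_mask(mask, params)
    return apply_split_polylines(mask, lines)
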