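"""Adherent-seed splitting: watershed, median-area filters, convex-defect cuts.

The raw machine-learning seed mask merges touching seeds into single blobs.
Splitting proceeds in two stages:

1. Marker-controlled watershed on the negated Euclidean distance transform,
   with markers at distance-map local maxima separated by at least the
   splitting footprint (default 25 px). Fragments smaller than 0.75x the
   median object area are discarded as over-segmentation artifacts.
2. Objects larger than 1.25x the median area are flagged as unresolved
   multi-seed clumps. Each is wrapped in its convex hull; the hull-minus-
   region defect blobs locate the necks, Harris corner response along the
   region contour pinpoints the inflection points beside each defect, and the
   closest pair of such points (from distinct defects) is joined by a
   one-pixel cut line. The flag-and-cut loop repeats until no object exceeds
   the threshold or the iteration cap is reached, then the undersize filter
   runs once more with a freshly computed median.

A cut only removes pixels, so every output label is a subset of the input
mask, and a cut is kept only when it actually increases the number of
components, which bounds the loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import draw, feature, measure, morphology, segmentation

from .containers import compact_labels


@dataclass(frozen=True)
class SplitParams:
    """Knobs of the adherent splitter.

    ``split_footprint`` is the minimum separation (px) of distance-transform
    maxima used as watershed markers; ``under_factor``/``over_factor``
    multiply the median object area for the undersize and oversize filters.
    """

    split_footprint: int = 25
    under_factor: float = 0.75
    over_factor: float = 1.25
    harris_k: float = 0.04
    harris_quantile: float = 0.99
    min_defect_area: int = 3
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.under_factor < 1 < self.over_factor:
            raise ValueError("require 0 < under_factor < 1 < over_factor")
        if self.split_footprint < 1:
            raise ValueError("split_footprint must be >= 1")


def _object_areas(labels: np.ndarray) -> dict[int, int]:
    counts = np.bincount(labels.ravel())
    return {lab: int(counts[lab]) for lab in range(1, len(counts)) if counts[lab]}


def watershed_split(mask: np.ndarray, params: SplitParams | None = None) -> np.ndarray:
    """Marker-controlled watershed of a binary mask into a label map."""
    params = params or SplitParams()
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros(mask.shape, np.int32)
    dist = ndi.distance_transform_edt(mask)
    components = measure.label(mask, connectivity=2)
    coords = feature.peak_local_max(
        dist, min_distance=params.split_footprint, labels=components,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    labels = segmentation.watershed(-dist, markers, mask=mask).astype(np.int32)
    return compact_labels(labels)


def filter_undersized(labels: np.ndarray, under_factor: float = 0.75) -> np.ndarray:
    """Drop objects with area < under_factor x median area; compact labels.

    The median is computed over all objects before any removal, so a lone
    object (area == median) is never removed.
    """
    areas = _object_areas(labels)
    if not areas:
        return labels.copy()
    median = float(np.median(list(areas.values())))
    out = labels.copy()
    for lab, area in areas.items():
        if area < under_factor * median:
            out[out == lab] = 0
    return compact_labels(out)


def flag_oversized(labels: np.ndarray, over_factor: float = 1.25) -> list[int]:
    """Labels whose area exceeds over_factor x median area."""
    areas = _object_areas(labels)
    if not areas:
        return []
    median = float(np.median(list(areas.values())))
    return [lab for lab, area in sorted(areas.items())
            if area > over_factor * median]


def _contour_pixels(region: np.ndarray) -> np.ndarray:
    inner = morphology.erosion(region, morphology.disk(1))
    return np.argwhere(region & ~inner)


def _rep_point(
    contour: np.ndarray,
    response: np.ndarray,
    blob: np.ndarray,
) -> tuple[int, int] | None:
    """Contour point of maximal corner response adjacent to a defect blob."""
    for radius in (1, 2, 3):
        near = morphology.dilation(blob, morphology.disk(radius))
        cand = contour[near[contour[:, 0], contour[:, 1]]]
        if len(cand):
            resp = response[cand[:, 0], cand[:, 1]]
            best = resp.max()
            ties = cand[resp == best]
            ties = ties[np.lexsort((ties[:, 1], ties[:, 0]))]
            return int(ties[0, 0]), int(ties[0, 1])
    return None


def _cut_line_pixels(p0, p1, shape) -> tuple[np.ndarray, np.ndarray]:
    """1-px 4-connected straight line (extra pixel at diagonal steps)."""
    rr, cc = draw.line(p0[0], p0[1], p1[0], p1[1])
    dr, dc = np.diff(rr), np.diff(cc)
    diag = (dr != 0) & (dc != 0)
    rr = np.concatenate([rr, rr[:-1][diag] + dr[diag]])
    cc = np.concatenate([cc, cc[:-1][diag]])
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    return rr[keep], cc[keep]


def convex_defect_cut(region: np.ndarray, params: SplitParams | None = None) -> np.ndarray:
    """Cut one connected region across its deepest convex defect pair.

    Returns the region with the cut-line pixels removed; a convex region (no
    defect blob of at least ``min_defect_area`` px) is returned unchanged.
    """
    params = params or SplitParams()
    region = np.asarray(region, bool)
    if not region.any():
        return region.copy()
    hull = morphology.convex_hull_image(region)
    defects = hull & ~region
    defect_labels = measure.label(defects, connectivity=2)
    blobs = [defect_labels == lab
             for lab in range(1, defect_labels.max() + 1)
             if (defect_labels == lab).sum() >= params.min_defect_area]
    if not blobs:
        return region.copy()

    contour = _contour_pixels(region)
    response = feature.corner_harris(region.astype(np.float64), k=params.harris_k)

    reps = []
    for blob in blobs:
        p = _rep_point(contour, response, blob)
        if p is not None:
            reps.append(p)

    if len(reps) >= 2:
        # minimal-distance pair across distinct defect blobs
        best = None
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                d = (reps[i][0] - reps[j][0]) ** 2 + (reps[i][1] - reps[j][1]) ** 2
                key = (d, reps[i], reps[j])
                if best is None or key < best:
                    best = key
        _, p0, p1 = best
    elif len(reps) == 1:
        # single defect: join its two deepest adjacent contour points
        blob = blobs[0]
        depth = ndi.distance_transform_edt(hull)
        near = morphology.dilation(blob, morphology.disk(2))
        cand = contour[near[contour[:, 0], contour[:, 1]]]
        if len(cand) < 2:
            return region.copy()
        d = depth[cand[:, 0], cand[:, 1]]
        order = np.lexsort((cand[:, 1], cand[:, 0], -d))
        p0 = tuple(cand[order[0]])
        p1 = None
        for idx in order[1:]:
            q = tuple(cand[idx])
            if (q[0] - p0[0]) ** 2 + (q[1] - p0[1]) ** 2 >= 9:
                p1 = q
                break
        if p1 is None:
            return region.copy()
    else:
        return region.copy()

    rr, cc = _cut_line_pixels(p0, p1, region.shape)
    out = region.copy()
    out[rr, cc] = False
    return out


def split_seeds(
    mask: np.ndarray,
    params: SplitParams | None = None,
    return_info: bool = False,
):
    """Full mask-to-labels pipeline; see the module docstring for the stages.

    With ``return_info`` the unresolved (still-oversized) labels after the
    final pass are returned alongside the label map.
    """
    params = params or SplitParams()
    labels = watershed_split(mask, params)
    labels = filter_undersized(labels, params.under_factor)

    for _ in range(params.max_iterations):
        flagged = flag_oversized(labels, params.over_factor)
        if not flagged:
            break
        progressed = False
        next_label = int(labels.max()) + 1
        for lab in flagged:
            region = labels == lab
            cut = convex_defect_cut(region, params)
            pieces = measure.label(cut, connectivity=2)
            if pieces.max() <= 1:
                continue  # unproductive cut: keep the region intact
            progressed = True
            labels[region] = 0
            for p in range(1, pieces.max() + 1):
                labels[pieces == p] = next_label
                next_label += 1
        if not progressed:
            break

    labels = filter_undersized(labels, params.under_factor)
    unresolved = flag_oversized(labels, params.over_factor)
    if unresolved:
        warnings.warn(
            f"{len(unresolved)} oversized region(s) remain unsplit after "
            f"{params.max_iterations} iterations", stacklevel=2,
        )
    if return_info:
        return labels, unresolved
    return labels
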