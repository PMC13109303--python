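"""Morphological and elemental trait extraction for labeled seeds.

Seven morphological traits per seed: length and width (major/minor axis of
the moment-equivalent ellipse), projected area (pixel count), perimeter,
aspect ratio L/W, eccentricity E = sqrt(1 - W^2/L^2), and roundness
R = 4*pi*A/P^2 (clamped to <= 1 against discretisation noise).

The perimeter comes from the sub-pixel marching-squares contour simplified
with a 1-px Douglas-Peucker tolerance: plain contour length overestimates a
digital disk's circumference by ~5 % (staircase effect), while the simplified
polygon is within 0.5 % on disks, ellipses and squares alike, so a rasterised
disk lands at R ~ 0.99 without shape-specific calibration constants.

Elemental traits are arithmetic means of each quantitative map over the
seed's pixels, reported in the (opaque) units of the upstream maps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .containers import AccessionLayout, ElementMapStack, SeedRecord
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

_PERIMETER_TOLERANCE = 1.0  # Douglas-Peucker tolerance, px


@dataclass(frozen=True)
class Morphology:
    length: float
    width: float
    area: float
    perimeter: float
    aspect_ratio: float
    eccentricity: float
    roundness: float


def contour_perimeter(region: np.ndarray, tolerance: float = _PERIMETER_TOLERANCE) -> float:
    """Perimeter as the length of the simplified marching-squares contour."""
    padded = np.pad(np.asarray(region, float), 1)
    total = 0.0
    for c in measure.find_contours(padded, 0.5):
        poly = measure.approximate_polygon(c, tolerance=tolerance)
        total += float(np.sqrt((np.diff(poly, axis=0) ** 2).sum(axis=1)).sum())
    return total


def measure_morphology(
    region: np.ndarray,
    pixel_size: float | None = None,
    method: str = "ellipse",
) -> Morphology:
    """Seven morphological traits of one connected region.

    ``method='ellipse'`` (default) takes length/width from the moment-
    equivalent ellipse; ``method='feret'`` uses the maximum Feret diameter as
    length with the width chosen so the ellipse area matches. With
    ``pixel_size`` (length units per pixel) the dimensional traits scale
    accordingly.
    """
    region = np.asarray(region, bool)
    if not region.any():
        raise DegenerateInputError("empty region has no morphology")
    props = measure.regionprops(region.astype(np.uint8))
    rp = props[0]

    area = float(rp.area)
    perimeter = contour_perimeter(region)
    if method == "ellipse":
        length = float(rp.axis_major_length)
        width = float(rp.axis_minor_length)
    elif method == "feret":
        length = float(rp.feret_diameter_max)
        width = 4.0 * area / (math.pi * length)
    else:
        raise ValueError("method must be 'ellipse' or 'feret'")
    # guard against degenerate 1-px-thin regions
    length = max(length, 1.0)
    width = min(max(width, 1.0), length)

    eccentricity = math.sqrt(max(0.0, 1.0 - (width / length) ** 2))
    roundness = min(1.0, 4.0 * math.pi * area / perimeter**2)
    if pixel_size is not None:
        area *= pixel_size**2
        perimeter *= pixel_size
        length *= pixel_size
        width *= pixel_size
    return Morphology(
        length=length, width=width, area=area, perimeter=perimeter,
        aspect_ratio=length / width, eccentricity=eccentricity,
        roundness=roundness,
    )


def measure_elements(region: np.ndarray, stack: ElementMapStack) -> dict[str, float]:
    """Arithmetic mean of each element map over the region's pixels."""
    region = np.asarray(region, bool)
    if region.shape != stack.shape:
        raise DegenerateInputError(
            f"region grid {region.shape} does not match stack {stack.shape}"
        )
    if not region.any():
        raise DegenerateInputError("empty region has no element means")
    return {el: float(stack.maps[el][region].mean(dtype=np.float64))
            for el in stack.element_names}


def assemble_records(
    seed_labels: np.ndarray,
    layout: AccessionLayout,
    stack: ElementMapStack | None = None,
    pixel_size: float | None = None,
    method: str = "ellipse",
) -> list[SeedRecord]:
    """One :class:`SeedRecord` per seed label, keyed to accession numbering.

    Each seed belongs to the accession whose mask contains its centroid;
    orphans (centroid on background) are logged and emitted with accession
    index 0. Seed indices count in reading order (centroid row, then column)
    within each accession; records are ordered by (accession, seed index).
    """
    props = measure.regionprops(np.asarray(seed_labels))
    label_to_acc: dict[int, int] = {}
    per_seed: dict[int, tuple] = {}
    acc_ids = {e.label: e.index for e in layout.entries}
    for rp in props:
        r, c = rp.centroid
        acc_label = int(layout.labels[int(round(r)), int(round(c))])
        acc_index = acc_ids.get(acc_label, 0)
        if acc_index == 0:
            logger.warning("seed label %d centroid (%.0f, %.0f) is outside "
                           "every accession", rp.label, r, c)
        label_to_acc[rp.label] = acc_index
        per_seed[rp.label] = (r, c)

    id_of = {e.index: e.accession_id for e in layout.entries}
    records: list[SeedRecord] = []
    for acc_index in sorted(set(label_to_acc.values())):
        members = [lab for lab, a in label_to_acc.items() if a == acc_index]
        members.sort(key=lambda lab: per_seed[lab])
        for seed_index, lab in enumerate(members, start=1):
            region = seed_labels == lab
            morph = measure_morphology(region, pixel_size=pixel_size, method=method)
            elements = measure_elements(region, stack) if stack is not None else {}
            records.append(SeedRecord(
                accession_index=acc_index,
                accession_id=id_of.get(acc_index),
                seed_index=seed_index,
                length=morph.length, width=morph.width, area=morph.area,
                perimeter=morph.perimeter, aspect_ratio=morph.aspect_ratio,
                eccentricity=morph.eccentricity, roundness=morph.roundness,
                element_means=elements,
            ))
    return records
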