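"""Deterministic accession numbering in reading order.

Regions are labeled by connected components, assigned to horizontal row
bands (either from operator-supplied row delimiter polylines or by
largest-gap clustering of centroid rows), then numbered top-to-bottom,
left-to-right. Ties on centroid column break by centroid row, then label
value, so the numbering is reproducible under any relabeling.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from skimage import measure

from .containers import AccessionEntry, AccessionLayout
from .errors import XrfSeedError


def label_regions(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labeling; ``connectivity`` is 4 or 8."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    return measure.label(np.asarray(mask, bool),
                         connectivity=1 if connectivity == 4 else 2).astype(np.int32)


def detect_row_bands(
    centroids: Sequence[tuple[float, float]],
    n_rows: int | None = None,
    row_lines: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """1-based row band per centroid, bands increasing downward.

    With ``row_lines`` given, bands are the horizontal strata between
    consecutive delimiter lines (each line's band boundary is its mean row).
    Otherwise centroid rows are split at the ``n_rows - 1`` largest gaps.
    """
    centroids = np.asarray(centroids, dtype=float)
    if len(centroids) == 0:
        raise XrfSeedError("need at least one centroid")
    rows = centroids[:, 0]

    if row_lines is not None and len(row_lines) > 0:
        boundaries = np.sort([float(np.mean(np.asarray(l)[:, 0])) for l in row_lines])
        return (np.searchsorted(boundaries, rows) + 1).astype(np.int64)

    if n_rows is None:
        raise XrfSeedError("n_rows is required when no row_lines are given")
    if n_rows > len(centroids):
        raise XrfSeedError(
            f"n_rows={n_rows} exceeds number of centroids ({len(centroids)})"
        )
    order = np.argsort(rows, kind="stable")
    sorted_rows = rows[order]
    bands_sorted = np.ones(len(rows), dtype=np.int64)
    if n_rows > 1:
        gaps = np.diff(sorted_rows)
        # split after the n_rows-1 largest gaps; ties -> topmost gap first
        split_after = np.sort(np.argsort(-gaps, kind="stable")[: n_rows - 1])
        band = 1
        prev = 0
        for s in split_after:
            bands_sorted[prev:s + 1] = band
            prev = s + 1
            band += 1
        bands_sorted[prev:] = band
    out = np.empty(len(rows), dtype=np.int64)
    out[order] = bands_sorted
    return out


def order_accessions(labels: np.ndarray, bands: Sequence[int]) -> AccessionLayout:
    """Number labeled regions by (row band, centroid column) reading order."""
    props = measure.regionprops(labels)
    if len(bands) != len(props):
        raise XrfSeedError("one band per labeled region is required")
    keyed = []
    for p, band in zip(props, bands):
        r, c = p.centroid
        keyed.append((int(band), float(c), float(r), int(p.label)))
    keyed.sort()
    entries = [
        AccessionEntry(index=i, label=lab, centroid=(r, c), row_band=band)
        for i, (band, c, r, lab) in enumerate(keyed, start=1)
    ]
    return AccessionLayout(entries=entries, labels=labels)


def accession_mask(layout: AccessionLayout, index: int) -> np.ndarray:
    """Boolean mask of exactly one numbered accession's pixels."""
    entry = layout.entry(index)
    return layout.labels == entry.label


def assign_roster(layout: AccessionLayout, roster: Mapping[int, str]) -> AccessionLayout:
    """Attach accession IDs (index -> ID) from a roster mapping."""
    entries = [
        AccessionEntry(e.index, e.label, e.centroid, e.row_band,
                       roster.get(e.index, e.accession_id))
        for e in layout.entries
    ]
    return AccessionLayout(entries=entries, labels=layout.labels)


def number_accessions(
    mask: np.ndarray,
    n_rows: int | None = None,
    row_lines: Sequence[np.ndarray] | None = None,
    connectivity: int = 8,
) -> AccessionLayout:
    """Convenience: label a mask, band its centroids, and number the regions."""
    labels = label_regions(mask, connectivity)
    props = measure.regionprops(labels)
    if not props:
        return AccessionLayout(entries=[], labels=labels)
    centroids = [p.centroid for p in props]
    bands = detect_row_bands(centroids, n_rows=n_rows, row_lines=row_lines)
    return order_accessions(labels, bands)
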