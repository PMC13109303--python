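"""Shared in-memory containers and conventions.

All pixel coordinates in this package are 0-based, row-major ``(row, col)``
with the origin at the top-left corner; label maps use 0 for background and
contiguous positive integers for objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionMismatchError

#: Elements quantifiable from the K-edge fluorescence maps (18.6 keV beam).
ELEMENTS = (
    "As", "Ca", "Cl", "Cr", "Cu", "Fe", "K", "Mn",
    "Ni", "P", "Rb", "S", "Se", "Sr", "Zn",
)

#: Morphological trait columns, in canonical CSV order.
MORPHOLOGY_COLUMNS = (
    "length", "width", "area", "perimeter",
    "aspect_ratio", "eccentricity", "roundness",
)

#: Pixel-feature columns: RGB plus hexcone HSV, each normalised to [0, 1].
FEATURE_NAMES = ("R", "G", "B", "H", "S", "V")


def validate_rgb(pixels: np.ndarray) -> np.ndarray:
    """Check an H×W×3 uint8 RGB array and return it."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise DimensionMismatchError(
            f"RGB image must be H×W×3, got shape {pixels.shape}"
        )
    if pixels.dtype != np.uint8:
        raise ValueError(f"RGB image must be uint8, got {pixels.dtype}")
    return pixels


@dataclass
class ElementMapStack:
    """Aligned per-element quantitative maps plus the RGB composite.

    ``maps[el]`` is an H×W float32 array in the (opaque) concentration units
    emitted by the upstream spectral quantification; ``rgb`` shares the grid.
    """

    rgb: np.ndarray
    element_names: tuple[str, ...]
    maps: dict[str, np.ndarray]
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        validate_rgb(self.rgb)
        self.element_names = tuple(self.element_names)
        if len(set(self.element_names)) != len(self.element_names):
            raise ValueError("element names must be unique")
        unknown = [e for e in self.element_names if e not in ELEMENTS]
        if unknown:
            raise ValueError(
                f"unknown element(s) {unknown}; allowed: {list(ELEMENTS)}"
            )
        h, w = self.rgb.shape[:2]
        for el in self.element_names:
            m = np.asarray(self.maps[el], dtype=np.float32)
            if m.shape != (h, w):
                raise DimensionMismatchError(
                    f"element map '{el}' has shape {m.shape}, expected {(h, w)}"
                )
            self.maps[el] = m

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


@dataclass(frozen=True)
class AccessionEntry:
    """One numbered accession region."""

    index: int                     # 1-based reading-order index
    label: int                     # label value in the accession label map
    centroid: tuple[float, float]  # (row, col)
    row_band: int                  # 1-based, increasing downward
    accession_id: str | None = None


@dataclass
class AccessionLayout:
    """Numbered accession regions plus the label map they refer to."""

    entries: list[AccessionEntry]
    labels: np.ndarray  # H×W int label map (0 = background)

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, index: int) -> AccessionEntry:
        for e in self.entries:
            if e.index == index:
                return e
        raise IndexError(f"accession index {index} not in 1..{len(self)}")

    def to_json_dict(self) -> dict:
        return {
            "entries": [
                {
                    "index": e.index,
                    "label": int(e.label),
                    "centroid": [float(e.centroid[0]), float(e.centroid[1])],
                    "row_band": int(e.row_band),
                    "accession_id": e.accession_id,
                }
                for e in self.entries
            ]
        }


@dataclass(frozen=True)
class SeedSpec:
    """True parameters of one synthetic seed (a rotated filled ellipse)."""

    center: tuple[float, float]          # (row, col), pixels
    a: float                             # semi-major axis, px
    b: float                             # semi-minor axis, px
    theta: float                         # orientation, radians in [0, pi)
    element_means: Mapping[str, float]   # true mean concentration per element

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("require a >= b > 0")


@dataclass
class GroundTruth:
    """Exact truth for a synthetic layout (the test oracle)."""

    accession_labels: np.ndarray          # patch label map, row-major 1..N
    seed_labels: np.ndarray               # seed label map, 1..K
    seed_specs: list[SeedSpec]
    seed_accession: list[int]             # accession index owning each seed
    accession_order: list[int]            # expected numbering, reading order
    true_traits: pd.DataFrame             # analytic morphology + element means
    rng_seed: int


@dataclass
class SeedRecord:
    """All traits extracted for a single seed."""

    accession_index: int
    accession_id: str | None
    seed_index: int
    length: float
    width: float
    area: float
    perimeter: float
    aspect_ratio: float
    eccentricity: float
    roundness: float
    element_means: dict[str, float] = field(default_factory=dict)


@dataclass
class PixelSampleTable:
    """Per-pixel color features (n×6) with optional seed/background labels."""

    features: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[1] != len(FEATURE_NAMES):
            raise DimensionMismatchError(
                f"features must be n×{len(FEATURE_NAMES)}, got {self.features.shape}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool)
            if self.labels.shape != (len(self.features),):
                raise DimensionMismatchError("labels length must match features")

    def __len__(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(FEATURE_NAMES))
        if self.labels is not None:
            df["label"] = self.labels.astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PixelSampleTable":
        feats = df[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
        labels = df["label"].to_numpy(dtype=bool) if "label" in df else None
        return cls(feats, labels)


def compact_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels to 1..n (order of first appearance by value)."""
    labels = np.asarray(labels)
    vals = np.unique(labels)
    vals = vals[vals > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size and labels.max() > 0 else 1,
                   dtype=np.int32)
    for new, old in enumerate(vals, start=1):
        lut[old] = new
    return lut[labels]


def as_polylines(lines: Sequence) -> list[np.ndarray]:
    """Coerce to a list of integer (row, col) vertex arrays, each with >= 2 rows."""
    out = []
    for i, line in enumerate(lines):
        arr = np.asarray(line, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
            raise ValueError(f"polyline {i} must be an N×2 list with N >= 2")
        out.append(arr)
    return out
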