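"""Reading and writing of image and tabular artifacts.

Images are PNG or TIFF; element maps are single-channel float TIFFs (or PNG);
masks persist as 0/255 PNG; label maps as uint16 TIFF; polylines as JSON
(list of lists of ``[row, col]``); trait tables as CSV with '.' decimals.
RGB inputs deeper than 8 bits are max-normalised to the 0–255 range.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .containers import (
    ELEMENTS,
    MORPHOLOGY_COLUMNS,
    ElementMapStack,
    SeedRecord,
    as_polylines,
    validate_rgb,
)
from .errors import DimensionMismatchError, PolylineError, XrfSeedError

logger = logging.getLogger(__name__)


def _read_any(path: Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise XrfSeedError(f"file not found: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            return tifffile.imread(path)
        return iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise as package I/O error
        raise XrfSeedError(f"could not read image {path}: {exc}") from exc


def load_rgb(path: str | Path) -> np.ndarray:
    """Load an RGB composite as H×W×3 uint8.

    Grayscale inputs are broadcast to three identical channels; an alpha
    channel is dropped with a warning; >8-bit data are rescaled to 0–255 by
    max-normalisation.
    """
    img = _read_any(Path(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3:
        raise DimensionMismatchError(f"unsupported image shape {img.shape}")
    if img.shape[2] > 3:
        logger.warning("dropping alpha channel of %s", path)
        img = img[:, :, :3]
    if img.dtype != np.uint8:
        img = img.astype(np.float64)
        peak = img.max()
        if peak > 0:
            img = img / peak * 255.0
        img = np.round(img).astype(np.uint8)
    return validate_rgb(img)


def save_rgb(path: str | Path, rgb: np.ndarray) -> None:
    validate_rgb(rgb)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, rgb)
    else:
        iio.imwrite(path, rgb)


def load_element_stack(
    directory: str | Path,
    manifest: Mapping[str, str],
    rgb: np.ndarray,
) -> ElementMapStack:
    """Load per-element grayscale maps named by ``manifest`` (element -> file).

    Element order follows the manifest; every map must match the RGB grid.
    """
    directory = Path(directory)
    h, w = rgb.shape[:2]
    maps: dict[str, np.ndarray] = {}
    for el, fname in manifest.items():
        if el not in ELEMENTS:
            raise ValueError(f"unknown element '{el}'; allowed: {list(ELEMENTS)}")
        arr = _read_any(directory / fname).astype(np.float32)
        if arr.ndim != 2:
            raise DimensionMismatchError(
                f"element map '{el}' must be single-channel, got shape {arr.shape}"
            )
        if arr.shape != (h, w):
            raise DimensionMismatchError(
                f"element map '{el}' has shape {arr.shape}, expected {(h, w)}"
            )
        maps[el] = arr
    return ElementMapStack(rgb=rgb, element_names=tuple(manifest), maps=maps)


def save_element_stack(directory: str | Path, stack: ElementMapStack) -> dict[str, str]:
    """Write each element map as ``<El>.tif`` and return the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for el in stack.element_names:
        fname = f"{el}.tif"
        tifffile.imwrite(directory / fname, stack.maps[el])
        manifest[el] = fname
    return manifest


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    arr = _read_any(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label map exceeds uint16 range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return _read_any(Path(path)).astype(np.int32)


def _trait_columns(records: Sequence[SeedRecord]) -> list[str]:
    present: list[str] = []
    for el in ELEMENTS:
        if any(el in r.element_means for r in records):
            present.append(el)
    return ["accession_index", "accession_id", "seed_index",
            *MORPHOLOGY_COLUMNS, *present]


def write_traits_csv(records: Sequence[SeedRecord], path: str | Path) -> None:
    """One row per seed; stable column order; header-only file for no records."""
    cols = _trait_columns(records)
    rows = []
    for r in records:
        row = {
            "accession_index": r.accession_index,
            "accession_id": "" if r.accession_id is None else r.accession_id,
            "seed_index": r.seed_index,
        }
        for c in MORPHOLOGY_COLUMNS:
            row[c] = getattr(r, c)
        for el in cols[3 + len(MORPHOLOGY_COLUMNS):]:
            row[el] = r.element_means.get(el, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise XrfSeedError(f"cannot write traits CSV to {path}: {exc}") from exc


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps write->read exact to the last bit
    return pd.read_csv(path, float_precision="round_trip")


def read_polylines(
    path: str | Path, shape: tuple[int, int] | None = None
) -> list[np.ndarray]:
    """Read polylines from JSON; empty file -> no polylines.

    Coordinates are 0-based (row, col). With ``shape`` given, out-of-grid
    vertices raise :class:`PolylineError` naming the offending index.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        return []
    data = json.loads(text)
    try:
        lines = as_polylines(data)
    except ValueError as exc:
        raise PolylineError(str(exc)) from exc
    return validate_polylines(lines, shape)


def validate_polylines(
    lines: Sequence[np.ndarray], shape: tuple[int, int] | None
) -> list[np.ndarray]:
    lines = as_polylines(lines)
    if shape is not None:
        h, w = shape
        for i, line in enumerate(lines):
            bad = (line[:, 0] < 0) | (line[:, 0] >= h) | (line[:, 1] < 0) | (line[:, 1] >= w)
            if bad.any():
                j = int(np.flatnonzero(bad)[0])
                raise PolylineError(
                    f"polyline {i} vertex {j} {tuple(line[j])} outside grid {shape}"
                )
    return list(lines)


def write_polylines(path: str | Path, lines: Sequence[np.ndarray]) -> None:
    data = [np.asarray(l, dtype=int).tolist() for l in lines]
    Path(path).write_text(json.dumps(data))
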