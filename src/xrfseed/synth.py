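"""Synthetic seed-array generator with exact ground truth.

Emulates the geometry of a scanned seed library: bright rectangular tape
patches (one per accession) on a dark background, each carrying a handful of
seeds rendered as filled rotated ellipses, with a controllable fraction of
adherent seed pairs (boundary overlap at most 30 % of the minor axis, the
failure mode the adherent splitter exists for). Per-element maps hold the
accession's true mean concentration at every seed pixel plus optional
Gaussian noise, so that noiseless fixtures recover element means exactly.

Seeds within one accession share a single true composition: one accession is
one genotype, and the per-genotype mean is the quantity the workflow reports.
Axis lengths are drawn from a narrow range (semi-major 21-25 px, semi-minor
13.5-16.5 px), reflecting the low within-species size variance of real seed
lots; the median-area filters of the splitter assume exactly this kind of
unimodal size distribution.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import draw

from .containers import (
    FEATURE_NAMES,
    GroundTruth,
    PixelSampleTable,
    SeedSpec,
    ElementMapStack,
)
from .errors import PackingError

# Rendering palette (uint8 RGB): tape is bright and bluish-white so its
# L* channel dominates the dark background; seeds are a reddish brown.
TAPE_RGB = (205, 215, 240)
BACKGROUND_RGB = (15, 15, 18)
SEED_RGB = (150, 60, 45)

#: Plausible seed concentration ranges (map units ~ ug/g) per element.
ELEMENT_RANGES = {
    "P": (6000.0, 11000.0), "K": (7000.0, 12000.0), "S": (7000.0, 11000.0),
    "Ca": (2500.0, 6000.0), "Cl": (300.0, 900.0), "Fe": (40.0, 120.0),
    "Zn": (25.0, 90.0), "Mn": (15.0, 60.0), "Cu": (3.0, 12.0),
    "Ni": (0.5, 4.0), "Rb": (5.0, 40.0), "Sr": (5.0, 40.0),
    "As": (0.05, 0.6), "Se": (0.05, 0.8), "Cr": (0.1, 1.5),
}

DEFAULT_ELEMENTS = ("Ca", "K", "Fe", "Zn", "Mn")

_AXIS_A = (21.0, 25.0)   # semi-major range, px
_AXIS_B = (13.5, 16.5)   # semi-minor range, px


def _support_radius(a: float, b: float, theta: float, phi: float) -> float:
    """Boundary distance from the ellipse center along direction ``phi``."""
    d = phi - theta
    return math.sqrt((a * math.cos(d)) ** 2 + (b * math.sin(d)) ** 2)


def _draw_ellipse(shape, center, a, b, theta):
    return draw.ellipse(center[0], center[1], b, a, rotation=theta, shape=shape)


def _ellipse_traits(a: float, b: float) -> dict[str, float]:
    """Closed-form morphology of an ellipse (Ramanujan perimeter)."""
    h = (a - b) ** 2 / (a + b) ** 2
    perimeter = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
    area = math.pi * a * b
    return {
        "length": 2 * a,
        "width": 2 * b,
        "area": area,
        "perimeter": perimeter,
        "aspect_ratio": a / b,
        "eccentricity": math.sqrt(1 - b**2 / a**2),
        "roundness": 4 * math.pi * area / perimeter**2,
    }


def _touches(labels: np.ndarray, rr: np.ndarray, cc: np.ndarray, target: int) -> bool:
    """True when pixels (rr, cc) are 8-adjacent to (or overlap) ``target``."""
    h, w = labels.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            r2 = np.clip(rr + dr, 0, h - 1)
            c2 = np.clip(cc + dc, 0, w - 1)
            if np.any(labels[r2, c2] == target):
                return True
    return False


def _touches_any(labels: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> bool:
    """True when pixels (rr, cc) are 8-adjacent to (or overlap) any object."""
    h, w = labels.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            r2 = np.clip(rr + dr, 0, h - 1)
            c2 = np.clip(cc + dc, 0, w - 1)
            if np.any(labels[r2, c2] > 0):
                return True
    return False


def _place_adherent(rng, prev: SeedSpec, a: float, b: float,
                    overlap_range=(0.05, 0.30),
                    any_direction: bool = False) -> tuple[float, float, float]:
    """Center and orientation for a seed adherent to ``prev``.

    The new seed's major axis points along the contact direction; the
    boundary-to-boundary overlap is a fraction of the smaller minor axis.
    By default the contact direction stays near the anchor's major axis
    (the common tip-to-tip adhesion); ``any_direction`` frees it.
    """
    ov = rng.uniform(*overlap_range) * min(prev.b, b)
    if any_direction:
        phi = rng.uniform(0.0, 2.0 * math.pi)
    else:
        phi = prev.theta + rng.uniform(-0.5, 0.5)
    d = _support_radius(prev.a, prev.b, prev.theta, phi) + a - ov
    r = prev.center[0] + d * math.sin(phi)
    c = prev.center[1] + d * math.cos(phi)
    return r, c, phi % math.pi


def generate_layout(
    n_rows: int = 2,
    accessions_per_row: int = 3,
    seeds_per_accession: int | tuple[int, int] = 5,
    overlap_fraction: float = 0.2,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    elements: Sequence[str] = DEFAULT_ELEMENTS,
    patch_shape: tuple[int, int] = (180, 180),
    patch_gap: int = 30,
    margin: int = 20,
) -> tuple[np.ndarray, ElementMapStack, GroundTruth]:
    """Render a synthetic seed-array image with complete ground truth.

    ``overlap_fraction`` is the fraction of seed pairs drawn adherent: the
    number of adherent pairs is ``round(overlap_fraction * total_seeds / 2)``,
    distributed over distinct accessions. Deterministic for a fixed
    ``rng_seed``.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    ph, pw = patch_shape
    H = 2 * margin + n_rows * ph + (n_rows - 1) * patch_gap
    W = 2 * margin + accessions_per_row * pw + (accessions_per_row - 1) * patch_gap

    if isinstance(seeds_per_accession, int):
        seed_counts_range = (seeds_per_accession, seeds_per_accession)
    else:
        seed_counts_range = seeds_per_accession

    n_acc = n_rows * accessions_per_row
    seed_counts = [int(rng.integers(seed_counts_range[0], seed_counts_range[1] + 1))
                   for _ in range(n_acc)]
    total_seeds = sum(seed_counts)
    n_pairs = int(round(overlap_fraction * total_seeds / 2))
    eligible = [i for i, c in enumerate(seed_counts) if c >= 2]
    if n_pairs > len(eligible):
        raise PackingError(
            f"cannot host {n_pairs} adherent pairs in {len(eligible)} accessions "
            "with >= 2 seeds; lower overlap_fraction or add seeds"
        )
    pair_hosts = set(rng.choice(eligible, size=n_pairs, replace=False).tolist())

    rgb = np.empty((H, W, 3), np.uint8)
    rgb[:] = BACKGROUND_RGB
    accession_labels = np.zeros((H, W), np.int32)
    seed_labels = np.zeros((H, W), np.int32)
    element_names = tuple(elements)
    maps = {el: np.zeros((H, W), np.float32) for el in element_names}

    seed_specs: list[SeedSpec] = []
    seed_accession: list[int] = []
    rows: list[dict] = []

    acc_index = 0
    for row in range(n_rows):
        for col in range(accessions_per_row):
            acc_index += 1
            r0 = margin + row * (ph + patch_gap)
            c0 = margin + col * (pw + patch_gap)
            accession_labels[r0:r0 + ph, c0:c0 + pw] = acc_index
            rgb[r0:r0 + ph, c0:c0 + pw] = TAPE_RGB

            # quantise to float32 so map pixels hold the true mean exactly
            acc_means = {
                el: float(np.float32(rng.uniform(*ELEMENT_RANGES.get(el, (1.0, 50.0)))))
                for el in element_names
            }
            n_seeds = seed_counts[acc_index - 1]
            placed: list[SeedSpec] = []
            inner = (r0 + 28, r0 + ph - 28, c0 + 28, c0 + pw - 28)

            def sample_spec(adherent_to: SeedSpec | None) -> SeedSpec:
                a = float(rng.uniform(*_AXIS_A))
                b = float(rng.uniform(*_AXIS_B))
                if adherent_to is None:
                    for _ in range(300):
                        r = float(rng.uniform(inner[0], inner[1]))
                        c = float(rng.uniform(inner[2], inner[3]))
                        theta = float(rng.uniform(0, math.pi))
                        ok = True
                        for p in placed:
                            phi = math.atan2(r - p.center[0], c - p.center[1])
                            gap = (_support_radius(a, b, theta, phi)
                                   + _support_radius(p.a, p.b, p.theta, phi) + 3)
                            if (r - p.center[0]) ** 2 + (c - p.center[1]) ** 2 < gap**2:
                                ok = False
                                break
                        if ok:
                            # exact check: rendered mask must touch nothing
                            rr_c, cc_c = _draw_ellipse((H, W), (r, c), a, b, theta)
                            if not _touches_any(seed_labels, rr_c, cc_c):
                                return SeedSpec((r, c), a, b, theta, dict(acc_means))
                    raise PackingError(
                        f"could not place seed in accession {acc_index}; "
                        "use a larger patch_shape or fewer seeds"
                    )
                for attempt in range(300):
                    # after a few failures free the direction and the anchor
                    anchor = (adherent_to if attempt < 100
                              else placed[int(rng.integers(len(placed)))])
                    r, c, theta = _place_adherent(
                        rng, anchor, a, b, any_direction=attempt >= 20
                    )
                    # keep the partner on the tape patch and clear of others
                    if not (inner[0] <= r <= inner[1] and inner[2] <= c <= inner[3]):
                        continue
                    if not all(
                        p is anchor
                        or (r - p.center[0]) ** 2 + (c - p.center[1]) ** 2
                        > (a + p.a + 3) ** 2
                        for p in placed
                    ):
                        continue
                    # the rendered masks must really touch their anchor
                    anchor_k = next(i for i, s in enumerate(seed_specs, 1)
                                    if s is anchor)
                    rr_c, cc_c = _draw_ellipse((H, W), (r, c), a, b, theta)
                    if _touches(seed_labels, rr_c, cc_c, anchor_k):
                        return SeedSpec((r, c), a, b, theta, dict(acc_means))
                raise PackingError(
                    f"could not place adherent seed in accession {acc_index}; "
                    "use a larger patch_shape or fewer seeds"
                )

            adherent_slot = 1 if acc_index - 1 in pair_hosts else None
            for j in range(n_seeds):
                partner = placed[0] if (adherent_slot is not None and j == adherent_slot) else None
                spec = sample_spec(partner)
                placed.append(spec)
                seed_specs.append(spec)
                seed_accession.append(acc_index)
                k = len(seed_specs)
                rr, cc = _draw_ellipse((H, W), spec.center, spec.a, spec.b, spec.theta)
                seed_labels[rr, cc] = k
                rgb[rr, cc] = SEED_RGB
                for el in element_names:
                    maps[el][rr, cc] = spec.element_means[el]
                t = _ellipse_traits(spec.a, spec.b)
                rows.append({"seed": k, "accession_index": acc_index, **t,
                             **{el: spec.element_means[el] for el in element_names}})

    if noise_sd > 0:
        fg = seed_labels > 0
        for el in element_names:
            noise = rng.normal(0.0, noise_sd, size=int(fg.sum())).astype(np.float32)
            maps[el][fg] = np.maximum(maps[el][fg] + noise, 0.0)
        rgb_noise = rng.normal(0.0, noise_sd, size=rgb.shape)
        rgb = np.clip(rgb.astype(np.float64) + rgb_noise, 0, 255).round().astype(np.uint8)

    stack = ElementMapStack(rgb=rgb, element_names=element_names, maps=maps)
    truth = GroundTruth(
        accession_labels=accession_labels,
        seed_labels=seed_labels,
        seed_specs=seed_specs,
        seed_accession=seed_accession,
        accession_order=list(range(1, n_acc + 1)),
        true_traits=pd.DataFrame(rows),
        rng_seed=rng_seed,
    )
    return rgb, stack, truth


def generate_cluster_scene(
    n_isolated: int = 8,
    n_pairs: int = 2,
    n_triples: int = 1,
    shape: tuple[int, int] = (600, 600),
    rng_seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary mask plus seed label map: isolated ellipses and adherent clusters.

    Used to exercise the adherent splitter in isolation (no tape, no colors).
    Returns ``(mask, truth_labels)``; the mask is the union of all seeds.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    mask = np.zeros(shape, bool)
    truth = np.zeros(shape, np.int32)
    placed: list[tuple[SeedSpec, float]] = []  # (spec, clearance)
    k = 0

    def put(spec: SeedSpec, clearance: float) -> None:
        nonlocal k
        k += 1
        rr, cc = _draw_ellipse(shape, spec.center, spec.a, spec.b, spec.theta)
        mask[rr, cc] = True
        truth[rr, cc] = k
        placed.append((spec, clearance))

    def free_spot(need: float, margin: float):
        for _ in range(500):
            r = float(rng.uniform(margin, shape[0] - margin))
            c = float(rng.uniform(margin, shape[1] - margin))
            if all((r - p.center[0]) ** 2 + (c - p.center[1]) ** 2
                   > (need + pcl + 6) ** 2 for p, pcl in placed):
                return r, c
        raise PackingError("cluster scene packing failed; enlarge the grid")

    def clear_of(r, c, a, b, theta, exclude: SeedSpec | None) -> bool:
        """True when the candidate touches no placed seed except ``exclude``."""
        for p, _ in placed:
            if p is exclude:
                continue
            phi = math.atan2(r - p.center[0], c - p.center[1])
            gap = (_support_radius(a, b, theta, phi)
                   + _support_radius(p.a, p.b, p.theta, phi) + 2)
            if (r - p.center[0]) ** 2 + (c - p.center[1]) ** 2 < gap**2:
                return False
        return True

    def axes():
        return float(rng.uniform(*_AXIS_A)), float(rng.uniform(*_AXIS_B))

    # clusters first: they need the most clearance
    for size in [3] * n_triples + [2] * n_pairs:
        a, b = axes()
        r, c = free_spot(size * 28.0, margin=size * 30.0)
        prev = SeedSpec((r, c), a, b, float(rng.uniform(0, math.pi)), {})
        put(prev, size * 28.0)
        for _ in range(size - 1):
            a, b = axes()
            prev_k = k
            for attempt in range(300):
                rr_, cc_, th = _place_adherent(
                    rng, prev, a, b, any_direction=attempt >= 20
                )
                # chain members touch exactly their anchor (no folded clumps)
                if not clear_of(rr_, cc_, a, b, th, exclude=prev):
                    continue
                pr, pc = _draw_ellipse(shape, (rr_, cc_), a, b, th)
                if _touches(truth, pr, pc, prev_k):
                    break
            else:
                raise PackingError("could not grow adherent chain")
            prev = SeedSpec((rr_, cc_), a, b, th, {})
            put(prev, size * 28.0)

    for _ in range(n_isolated):
        a, b = axes()
        r, c = free_spot(a, margin=32)
        put(SeedSpec((r, c), a, b, float(rng.uniform(0, math.pi)), {}), a)

    return mask, truth


def generate_pixel_dataset(
    n_records: int = 4416,
    class_balance: float = 0.5,
    separability: float = 5.0,
    rng_seed: int = 0,
) -> PixelSampleTable:
    """Labeled six-feature pixel samples from two Gaussian class conditionals.

    Each feature (R, G, B, H, S, V) has within-class standard deviation 0.05;
    the class means are ``separability`` standard deviations apart on every
    feature, centred on 0.5 and clipped to [0, 1]. ``class_balance`` is the
    fraction of seed (positive) rows.
    """
    if n_records < 2:
        raise ValueError("n_records must be >= 2")
    if not 0.0 <= class_balance <= 1.0:
        raise ValueError("class_balance must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    sd = 0.05
    offset = separability * sd / 2.0
    n_seed = int(round(class_balance * n_records))
    n_bg = n_records - n_seed
    nf = len(FEATURE_NAMES)
    bg = rng.normal(0.5 - offset, sd, size=(n_bg, nf))
    fg = rng.normal(0.5 + offset, sd, size=(n_seed, nf))
    feats = np.clip(np.vstack([bg, fg]), 0.0, 1.0)
    labels = np.concatenate([np.zeros(n_bg, bool), np.ones(n_seed, bool)])
    perm = rng.permutation(n_records)
    return PixelSampleTable(feats[perm], labels[perm])


def pixel_table_from_layout(
    rgb: np.ndarray,
    truth: GroundTruth,
    n_per_class: int = 600,
    rng_seed: int = 0,
) -> PixelSampleTable:
    """Sample a labeled training table from a rendered layout.

    Positive rows come from true seed pixels, negative rows from tape and
    background, mimicking the hand-labeled pixel dataset a user would supply.
    """
    from .classifier import extract_features  # local import to avoid a cycle

    rng = np.random.default_rng(rng_seed)
    table = extract_features(rgb)
    flat_seed = (truth.seed_labels > 0).ravel()
    pos_idx = np.flatnonzero(flat_seed)
    neg_idx = np.flatnonzero(~flat_seed)
    pos = rng.choice(pos_idx, size=min(n_per_class, len(pos_idx)), replace=False)
    neg = rng.choice(neg_idx, size=min(n_per_class, len(neg_idx)), replace=False)
    idx = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])
    perm = rng.permutation(len(idx))
    return PixelSampleTable(table.features[idx][perm], labels[perm])
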