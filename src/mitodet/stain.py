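"""Stain separation, reference-based normalization, and dataset preparation.

H&E stains combine approximately linearly in optical-density (OD) space:
``OD = -log10(I / I0)`` for transmitted intensity ``I`` against background
``I0``. A 2x3 stain matrix (rows = hematoxylin, eosin unit OD vectors) maps
per-pixel stain concentrations to OD. Normalization estimates the source
tile's stain matrix and per-stain concentration scales, then re-renders the
concentrations through a reference profile so staining appearance is
consistent across sources.

The data-driven estimator is the robust angular-extremes method: OD pixels
above a transparency floor are projected onto their best-fit plane and the
1st/99th percentile extreme directions of the projected angle are taken as
the two stain vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .tile import HistologyTile

__all__ = [
    "RUIFROK_HE",
    "StainProfile",
    "SplitSpec",
    "DegenerateReferenceError",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_profile",
    "normalize_to_reference",
    "preprocess",
    "split_dataset",
    "pick_reference",
]

logger = logging.getLogger(__name__)

#: Published standard H&E optical-density vectors (rows: hematoxylin, eosin),
#: unit-normalized; the default stain matrix when estimation is not possible.
RUIFROK_HE = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.072, 0.990, 0.105],
    ]
)
RUIFROK_HE = RUIFROK_HE / np.linalg.norm(RUIFROK_HE, axis=1, keepdims=True)

#: Offset inside the log to avoid log(0) at intensity 0.
OD_EPS = 1.0 / 255.0


class DegenerateReferenceError(ValueError):
    """Raised when a reference tile carries no usable stain information."""


@dataclass
class StainProfile:
    """Stain OD matrix plus per-stain robust concentration maxima.

    Attributes
    ----------
    stain_matrix : (2, 3) float
        Unit-norm, non-negative OD vectors; row 0 = hematoxylin, row 1 = eosin.
    concentration_scale : (2,) float
        99th-percentile concentration per stain (dimensionless OD), > 0.
    background_intensity : float
        Per-channel background (white) level, default 255.
    """

    stain_matrix: np.ndarray
    concentration_scale: np.ndarray
    background_intensity: float = 255.0

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.concentration_scale = np.asarray(self.concentration_scale, dtype=float)
        if self.stain_matrix.shape != (2, 3):
            raise ValueError("stain_matrix must be 2x3 (rows: H, E)")
        norms = np.linalg.norm(self.stain_matrix, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("stain_matrix rows must have unit norm")
        if np.any(self.stain_matrix < -1e-12):
            raise ValueError("stain_matrix entries must be non-negative")
        if np.any(self.concentration_scale <= 0):
            raise ValueError("concentration_scale entries must be > 0")


@dataclass
class SplitSpec:
    """Train/val/test split request: fractions summing to 1, a seed, and
    whether to stratify by label."""

    fractions: Sequence[float] = (0.7, 0.15, 0.15)
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (3,):
            raise ValueError("fractions must be a 3-vector (train, val, test)")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be >= 0 and sum to 1")
        self.fractions = tuple(float(x) for x in f)


# ---------------------------------------------------------------------------
# Optical density
# ---------------------------------------------------------------------------

def rgb_to_od(pixels: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Map 8-bit RGB to optical density, elementwise.

    ``OD = -log10((pixel + eps) / background)`` with ``eps = 1/255`` so the
    transform is finite at intensity 0.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[-1] != 3:
        raise ValueError(f"expected HxWx3 RGB input, got shape {pixels.shape}")
    od = -np.log10((pixels.astype(float) + OD_EPS) / background_intensity)
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, returning uint8 RGB."""
    rgb = background_intensity * np.power(10.0, -np.asarray(od, dtype=float)) - OD_EPS
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Stain estimation
# ---------------------------------------------------------------------------

def estimate_stain_profile(
    reference: HistologyTile,
    od_floor: float = 0.15,
    angle_percentile: float = 1.0,
    min_tissue_fraction: float = 0.05,
    fallback_to_default: bool = False,
) -> StainProfile:
    """Estimate an H&E :class:`StainProfile` from a reference tile.

    Pixels with OD magnitude above ``od_floor`` (tissue, not background) are
    projected onto the top-2 principal plane of their OD distribution; the
    ``angle_percentile`` / ``100 - angle_percentile`` extreme directions of
    the projected angle are taken as the stain vectors. Concentration scales
    are 99th percentiles per stain.

    Raises
    ------
    DegenerateReferenceError
        If the tile is near-blank or has no identifiable stain plane (e.g. a
        grayscale image) and ``fallback_to_default`` is False.
    """
    od = rgb_to_od(reference.pixels).reshape(-1, 3)
    tissue = od[np.linalg.norm(od, axis=1) > od_floor]
    if tissue.shape[0] < max(30, min_tissue_fraction * od.shape[0]):
        if fallback_to_default:
            logger.warning(
                "tile %s: near-blank reference, using default H&E vectors",
                reference.id,
            )
            return StainProfile(RUIFROK_HE.copy(), np.array([1.0, 1.0]))
        raise DegenerateReferenceError(
            f"tile {reference.id!r}: tissue fraction below floor "
            f"({tissue.shape[0]}/{od.shape[0]} OD pixels above {od_floor})"
        )

    # Principal plane of the OD cloud.
    _, svals, vecs = np.linalg.svd(tissue - tissue.mean(axis=0), full_matrices=False)
    if svals[1] < 1e-4 * max(svals[0], 1e-12):
        # No second direction: gray/monochrome staining, no H-vs-E contrast.
        if fallback_to_default:
            logger.warning(
                "tile %s: no stain plane identifiable, using default vectors",
                reference.id,
            )
            return StainProfile(RUIFROK_HE.copy(), np.array([1.0, 1.0]))
        raise DegenerateReferenceError(
            f"tile {reference.id!r}: OD cloud is rank-deficient "
            "(no stain direction identifiable)"
        )
    plane = vecs[:2]  # (2, 3)
    # Orient basis so projections are positive (stains absorb, OD >= 0).
    for i in range(2):
        if plane[i] @ tissue.mean(axis=0) < 0:
            plane[i] = -plane[i]

    proj = tissue @ plane.T  # (n, 2)
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [angle_percentile, 100.0 - angle_percentile])
    v_lo = np.cos(lo) * plane[0] + np.sin(lo) * plane[1]
    v_hi = np.cos(hi) * plane[0] + np.sin(hi) * plane[1]

    vectors = []
    for v in (v_lo, v_hi):
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n < 1e-8:
            if fallback_to_default:
                return StainProfile(RUIFROK_HE.copy(), np.array([1.0, 1.0]))
            raise DegenerateReferenceError(
                f"tile {reference.id!r}: extreme stain direction degenerate"
            )
        vectors.append(v / n)
    # Hematoxylin has the larger red-channel OD (absorbs red); eosin is
    # red-transparent. Order rows accordingly.
    if vectors[0][0] >= vectors[1][0]:
        matrix = np.stack([vectors[0], vectors[1]])
    else:
        matrix = np.stack([vectors[1], vectors[0]])

    conc = _concentrations(od, matrix)
    scale = np.percentile(conc, 99.0, axis=1)
    scale = np.maximum(scale, 1e-6)
    return StainProfile(matrix, scale)


def _concentrations(od_flat: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Least-squares per-pixel stain concentrations, clipped non-negative.

    Returns a (2, n) array for flat OD input (n, 3).
    """
    conc, *_ = np.linalg.lstsq(stain_matrix.T, od_flat.T, rcond=None)
    return np.clip(conc, 0.0, None)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

#: Below this 99th-percentile source concentration a stain is considered
#: absent and its concentrations are passed through unrescaled.
_SCALE_FLOOR = 0.05


def normalize_to_reference(
    tile: HistologyTile, profile: StainProfile
) -> HistologyTile:
    """Re-render ``tile`` through the reference stain ``profile``.

    The tile's own stain matrix is estimated (falling back to the default
    H&E vectors when estimation fails), per-pixel concentrations are solved,
    rescaled per stain so their 99th percentiles match the reference's, and
    recombined through the reference stain matrix.
    """
    try:
        src = estimate_stain_profile(tile)
    except DegenerateReferenceError:
        logger.warning(
            "tile %s: source stain estimate degenerate, using default vectors",
            tile.id,
        )
        od_flat = rgb_to_od(tile.pixels).reshape(-1, 3)
        conc = _concentrations(od_flat, RUIFROK_HE)
        scale = np.maximum(np.percentile(conc, 99.0, axis=1), 1e-6)
        src = StainProfile(RUIFROK_HE.copy(), scale)

    od = rgb_to_od(tile.pixels, profile.background_intensity)
    h, w, _ = od.shape
    conc = _concentrations(od.reshape(-1, 3), src.stain_matrix)

    ratio = np.ones(2)
    for i in range(2):
        if src.concentration_scale[i] > _SCALE_FLOOR:
            ratio[i] = profile.concentration_scale[i] / src.concentration_scale[i]
    conc = conc * ratio[:, None]

    od_out = (profile.stain_matrix.T @ conc).T.reshape(h, w, 3)
    out = od_to_rgb(od_out, profile.background_intensity)
    return tile.with_pixels(out)


def pick_reference(tiles: Sequence[HistologyTile]) -> HistologyTile:
    """Convenience reference selection: the tile whose OD-chroma histogram is
    closest (L1) to the corpus median histogram."""
    if not tiles:
        raise ValueError("no tiles to pick a reference from")
    hists = []
    bins = np.linspace(-np.pi, np.pi, 37)
    for t in tiles:
        od = rgb_to_od(t.pixels).reshape(-1, 3)
        tissue = od[np.linalg.norm(od, axis=1) > 0.15]
        if tissue.shape[0] < 30:
            hists.append(np.zeros(36))
            continue
        _, _, vecs = np.linalg.svd(tissue - tissue.mean(0), full_matrices=False)
        proj = tissue @ vecs[:2].T
        phi = np.arctan2(proj[:, 1], proj[:, 0])
        hist, _ = np.histogram(phi, bins=bins)
        hists.append(hist / max(hist.sum(), 1))
    hists = np.asarray(hists)
    median = np.median(hists, axis=0)
    dists = np.abs(hists - median).sum(axis=1)
    return tiles[int(np.argmin(dists))]


# ---------------------------------------------------------------------------
# Preprocessing and splitting
# ---------------------------------------------------------------------------

def preprocess(
    tile: HistologyTile, side: int = 227, median_kernel: int = 3
) -> HistologyTile:
    """Resize to ``side x side`` and median-filter per channel.

    The mask, when present, is resized nearest-neighbor and stays binary.
    """
    if side < 32:
        raise ValueError(f"side must be >= 32, got {side}")
    if median_kernel < 1 or median_kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd >= 1, got {median_kernel}")

    pixels = tile.pixels
    if pixels.shape[:2] != (side, side):
        pixels = resize(
            pixels, (side, side), order=1, anti_aliasing=True, preserve_range=True
        )
    pixels = np.clip(np.round(pixels), 0, 255).astype(np.uint8)
    if median_kernel > 1:
        pixels = ndimage.median_filter(pixels, size=(median_kernel, median_kernel, 1))

    mask = tile.mask
    if mask is not None and mask.shape != (side, side):
        mask = resize(mask, (side, side), order=0, preserve_range=True)
        mask = (mask > 0.5).astype(np.uint8)
    return tile.with_pixels(pixels, mask=mask)


def split_dataset(ids: Sequence, labels: Optional[Sequence], spec: SplitSpec):
    """Partition ``ids`` into (train, val, test) id lists.

    Partitions are disjoint, exhaustive, and reproducible from ``spec.seed``;
    stratified splits keep per-class proportions within +-1 item per class
    (largest-remainder allocation inside each class).
    """
    ids = list(ids)
    n = len(ids)
    if n == 0:
        return [], [], []
    if spec.stratify:
        if labels is None or len(labels) != n:
            raise ValueError("stratified split requires labels aligned with ids")
        classes = {}
        for i, lab in enumerate(labels):
            classes.setdefault(lab, []).append(i)
        for lab, members in classes.items():
            if len(members) < 3:
                raise ValueError(
                    f"class {lab!r} has {len(members)} member(s), fewer than "
                    "the 3 splits; cannot stratify"
                )
        groups = [classes[k] for k in sorted(classes, key=repr)]
    else:
        groups = [list(range(n))]

    rng = np.random.default_rng(spec.seed)
    out = ([], [], [])
    for members in groups:
        members = list(members)
        rng.shuffle(members)
        counts = _largest_remainder(len(members), spec.fractions)
        start = 0
        for s, c in enumerate(counts):
            out[s].extend(ids[i] for i in members[start : start + c])
            start += c
    return tuple(list(part) for part in out)


def _largest_remainder(n: int, fractions) -> list:
    """Integer allocation of n items to fractions, exhaustive by construction."""
    ideal = [f * n for f in fractions]
    base = [int(np.floor(x)) for x in ideal]
    rem = n - sum(base)
    order = np.argsort([-(x - np.floor(x)) for x in ideal], kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return base
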