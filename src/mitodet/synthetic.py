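"""Seeded synthetic data: H&E-like tiles, labeled feature tables, benchmarks.

The tile generator renders an eosin-tinted stromal background, elliptical
hematoxylin-stained nuclei, and mitotic figures as darker star-convex
chromatin clusters, composed through the same optical-density stain model
the normalization module uses, with per-tile angular jitter of the stain
vectors and additive sensor noise. Ground truth is exact by construction:
the mask marks precisely the mitotic-figure footprints.

The table generator draws labeled feature vectors where a known subset of
columns carries a standardized between-class mean shift and the remaining
nuisance columns are equicorrelated noise — the substrate for wrapper
feature-selection experiments with a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .stain import RUIFROK_HE, od_to_rgb
from .tile import HistologyTile

__all__ = [
    "TileGenParams",
    "TableGenParams",
    "GenerationError",
    "gen_he_tile",
    "gen_stain_pair",
    "gen_feature_table",
    "benchmark_objective",
]


class GenerationError(RuntimeError):
    """Raised when requested objects cannot be placed on the canvas."""


@dataclass
class TileGenParams:
    """Parameters of the H&E tile generator.

    ``stain_perturbation`` is the angular jitter (radians, s.d.) applied to
    each stain vector per tile; ``noise_sd`` is additive Gaussian noise in
    8-bit intensity levels. ``difficulty`` switches contrast/crowding presets:
    ``easy`` = high mitotic/nuclear contrast and clear separation (smoke
    tests), ``hard`` = weaker contrast and tighter packing.
    """

    side: int = 227
    n_nuclei: int = 25
    n_mitotic: int = 3
    stain_perturbation: float = 0.05
    noise_sd: float = 3.0
    difficulty: str = "easy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mitotic > self.n_nuclei:
            raise ValueError("n_mitotic must be <= n_nuclei")
        if not (0 <= self.stain_perturbation < 0.5):
            raise ValueError("stain_perturbation must be in [0, 0.5)")
        if self.difficulty not in ("easy", "hard"):
            raise ValueError("difficulty must be 'easy' or 'hard'")


@dataclass
class TableGenParams:
    """Parameters of the labeled feature-table generator.

    ``effect_size`` is the standardized between-class mean shift of each
    informative column; ``correlation`` is the equicorrelation among
    nuisance columns.
    """

    n_samples: int = 300
    d: int = 150
    n_informative: int = 5
    effect_size: float = 2.0
    class_balance: float = 0.5
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.d:
            raise ValueError("n_informative must be <= d")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 < self.class_balance < 1):
            raise ValueError("class_balance must be in (0, 1)")
        if not (0 <= self.correlation < 1):
            raise ValueError("correlation must be in [0, 1)")


# ---------------------------------------------------------------------------
# Tile rendering
# ---------------------------------------------------------------------------

_PRESETS = {
    # (nucleus hematoxylin conc, mitotic conc, min-separation factor)
    "easy": dict(c_nuc=0.55, c_mit=1.35, sep=2.4),
    "hard": dict(c_nuc=0.65, c_mit=0.95, sep=1.3),
}


def _perturb_stain_matrix(rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Rotate each stain vector by an angle ~ N(0, sigma) within a random
    plane, keeping rows unit-norm and non-negative."""
    matrix = RUIFROK_HE.copy()
    if sigma <= 0:
        return matrix
    for i in range(2):
        v = matrix[i]
        u = rng.normal(size=3)
        u -= (u @ v) * v
        u /= np.linalg.norm(u)
        angle = rng.normal(0.0, sigma)
        w = np.cos(angle) * v + np.sin(angle) * u
        w = np.clip(w, 1e-4, None)
        matrix[i] = w / np.linalg.norm(w)
    return matrix


def _star_footprint(yy, xx, cy, cx, r0, rng) -> np.ndarray:
    """Boolean footprint of a star-convex radially perturbed ellipse."""
    stretch = rng.uniform(0.75, 1.3)
    theta0 = rng.uniform(0, 2 * np.pi)
    dy, dx = yy - cy, xx - cx
    # rotate then anisotropically scale
    ry = np.cos(theta0) * dy - np.sin(theta0) * dx
    rx = (np.sin(theta0) * dy + np.cos(theta0) * dx) / stretch
    rad = np.hypot(ry, rx)
    ang = np.arctan2(rx, ry)
    n_harm = rng.integers(3, 6)
    amps = rng.uniform(0.05, 0.12, size=n_harm)
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)
    boundary = r0 * (
        1.0
        + sum(a * np.cos((k + 2) * ang + p) for k, (a, p) in enumerate(zip(amps, phases)))
    )
    return rad <= np.maximum(boundary, 0.3 * r0)


def _ellipse_footprint(yy, xx, cy, cx, a, b, theta) -> np.ndarray:
    dy, dx = yy - cy, xx - cx
    ry = np.cos(theta) * dy - np.sin(theta) * dx
    rx = np.sin(theta) * dy + np.cos(theta) * dx
    return (ry / a) ** 2 + (rx / b) ** 2 <= 1.0


def _place_centers(rng, side, n, min_dist, margin, max_tries=4000):
    centers = []
    tries = 0
    while len(centers) < n:
        if tries > max_tries:
            raise GenerationError(
                f"could not place {n} objects on a {side}x{side} canvas "
                f"without overlap; reduce the object count"
            )
        tries += 1
        c = rng.uniform(margin, side - margin, size=2)
        if all(np.hypot(*(c - p)) >= min_dist for p in centers):
            centers.append(c)
    return centers


def _render_scene(params: TileGenParams, rng: np.random.Generator):
    """Concentration maps (hematoxylin, eosin), mask, and object records."""
    side = params.side
    preset = _PRESETS[params.difficulty]
    yy, xx = np.mgrid[0:side, 0:side].astype(float)

    # Stromal background: smooth eosin field plus a faint hematoxylin wash.
    field = ndimage.gaussian_filter(rng.normal(size=(side, side)), sigma=side / 12)
    c_e = 0.28 + 0.12 * field / max(field.std(), 1e-9)
    c_e = np.clip(c_e, 0.1, 0.5)
    c_h = np.full((side, side), 0.03)

    # Nuclear radius ~5% of the field width (a ~10 um nucleus in a 40x tile).
    r_nuc = side * 0.05
    min_dist = 2 * r_nuc * preset["sep"] / 2.0
    centers = _place_centers(rng, side, params.n_nuclei, min_dist, margin=r_nuc * 1.6)
    # The first n_mitotic placed centers become mitotic figures; placement
    # order is random, so this is an unbiased assignment.
    mask = np.zeros((side, side), dtype=np.uint8)
    objects = []
    for k, (cy, cx) in enumerate(centers):
        mitotic = k < params.n_mitotic
        if mitotic:
            r0 = r_nuc * rng.uniform(0.9, 1.15)
            foot = _star_footprint(yy, xx, cy, cx, r0, rng)
            # Keep mitotic footprints pairwise disjoint (1-px gap) so the
            # mask has exactly n_mitotic components by construction.
            grown = ndimage.binary_dilation(mask, iterations=1)
            while (foot & grown).any():
                r0 *= 0.8
                foot = _star_footprint(yy, xx, cy, cx, r0, rng)
            c_h[foot] = preset["c_mit"] * rng.uniform(0.92, 1.08)
            mask |= foot.astype(np.uint8)
        else:
            a = r_nuc * rng.uniform(0.75, 1.1)
            b = a * rng.uniform(0.55, 0.95)
            foot = _ellipse_footprint(yy, xx, cy, cx, a, b, rng.uniform(0, np.pi))
            c_h[foot] = preset["c_nuc"] * rng.uniform(0.85, 1.15)
        c_e[foot] *= 0.4
        objects.append({"center": (float(cy), float(cx)), "mitotic": bool(mitotic)})

    # Soft chromatin edges; the mask keeps the exact footprints.
    c_h = ndimage.gaussian_filter(c_h, sigma=0.8)
    c_e = ndimage.gaussian_filter(c_e, sigma=0.8)
    return c_h, c_e, mask, objects


def _compose(c_h, c_e, stain_matrix, noise_sd, rng) -> np.ndarray:
    od = c_h[..., None] * stain_matrix[0] + c_e[..., None] * stain_matrix[1]
    rgb = od_to_rgb(od).astype(float)
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def gen_he_tile(params: TileGenParams) -> HistologyTile:
    """Render one H&E-like tile with exact mitosis ground truth.

    Deterministic: identical params (including seed) give bitwise-identical
    pixels and mask. Per-object records (centers, mitotic flags) are stored
    in ``tile.meta["objects"]``.
    """
    scene_rng = np.random.default_rng([params.seed, 1])
    stain_rng = np.random.default_rng([params.seed, 2])
    c_h, c_e, mask, objects = _render_scene(params, scene_rng)
    matrix = _perturb_stain_matrix(stain_rng, params.stain_perturbation)
    pixels = _compose(c_h, c_e, matrix, params.noise_sd, stain_rng)
    return HistologyTile(
        pixels=pixels,
        mask=mask,
        id=f"synthetic-{params.seed}",
        meta={"objects": objects, "params": params},
    )


def gen_stain_pair(
    params: TileGenParams, stain_seeds: Tuple[int, int] = (0, 1)
) -> Tuple[HistologyTile, HistologyTile]:
    """Two renderings of the *same* scene under independent stain jitter.

    The pair shares geometry and concentrations exactly; only the stain
    matrices (and the noise draws) differ — the controlled setting for
    testing that normalization removes stain variation.
    """
    scene_rng = np.random.default_rng([params.seed, 1])
    c_h, c_e, mask, objects = _render_scene(params, scene_rng)
    tiles = []
    for j, s in enumerate(stain_seeds):
        rng = np.random.default_rng([params.seed, 2, s])
        matrix = _perturb_stain_matrix(rng, params.stain_perturbation)
        pixels = _compose(c_h, c_e, matrix, params.noise_sd, rng)
        tiles.append(
            HistologyTile(
                pixels=pixels,
                mask=mask.copy(),
                id=f"synthetic-{params.seed}-stain{j}",
                meta={"objects": objects},
            )
        )
    return tiles[0], tiles[1]


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def gen_feature_table(params: TableGenParams):
    """Labeled feature table with a known informative column subset.

    Returns ``(X, y, informative_indices)``. Class allocation is exact:
    ``round(class_balance * n)`` positives. Informative columns are unit-
    variance with a between-class mean shift of ``effect_size``; nuisance
    columns share pairwise correlation ``correlation`` and no shift.
    """
    rng = np.random.default_rng(params.seed)
    n, d = params.n_samples, params.d
    n_pos = int(round(params.class_balance * n))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    perm = rng.permutation(n)
    y = y[perm]

    informative = np.sort(rng.choice(d, size=params.n_informative, replace=False))
    rho = params.correlation
    X = np.empty((n, d))
    if rho > 0:
        common = rng.normal(size=(n, 1))
        X[:] = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.normal(size=(n, d))
    else:
        X[:] = rng.normal(size=(n, d))
    # Informative columns: independent noise plus the class shift.
    X[:, informative] = rng.normal(size=(n, params.n_informative))
    X[:, informative] += params.effect_size * y[:, None]
    return X, y, informative


# ---------------------------------------------------------------------------
# Benchmark objectives
# ---------------------------------------------------------------------------

def benchmark_objective(name: str, d: int):
    """Standard continuous benchmark: returns (objective, bounds_lb, bounds_ub,
    optimum_position, optimum_value)."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if name == "sphere":
        return (
            lambda x: float(np.sum(np.square(x))),
            np.full(d, -5.12), np.full(d, 5.12),
            np.zeros(d), 0.0,
        )
    if name == "rastrigin":
        return (
            lambda x: float(
                10.0 * d + np.sum(np.square(x) - 10.0 * np.cos(2 * np.pi * np.asarray(x)))
            ),
            np.full(d, -5.12), np.full(d, 5.12),
            np.zeros(d), 0.0,
        )
    if name == "rosenbrock":
        def rosen(x):
            x = np.asarray(x)
            return float(
                np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2)
            )
        return rosen, np.full(d, -5.0), np.full(d, 10.0), np.ones(d), 0.0
    raise ValueError(f"unknown benchmark objective {name!r}")
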