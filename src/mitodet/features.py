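"""The 150-slot per-tile feature bank: texture, shape, and color.

Slots are defined by a versioned :class:`FeatureRegistry` so downstream
selections can cite the exact composition. The default registry is

* texture (86): 56-bin local directional pattern (LDP) histogram — Kirsch
  compass responses, top-3 coding — plus a 30-slot local frequency pattern
  (LFP) descriptor from a 5-band x 6-orientation Gabor bank with local-mean
  exceedance coding;
* shape (42): per-component area, perimeter, eccentricity, circularity
  (4*pi*A/P^2) and solidity, each aggregated over connected components with
  eight statistics, plus component count and foreground fraction;
* color (22): RGB/HSV channel statistics (circular for hue), an 8-bin hue
  histogram, grayscale intensity entropy, and a colorfulness index.

Category shares (57.3% / 28% / 14.7%) sit inside the 50-60 / 25-30 /
10-15% bands reported for selected mitosis descriptors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats
from skimage import color as skcolor
from skimage import measure
from skimage.filters import gabor, threshold_otsu

from .stain import RUIFROK_HE, rgb_to_od, _concentrations
from .tile import HistologyTile

__all__ = [
    "FeatureRegistry",
    "FeatureVector",
    "RegistryMismatchError",
    "KIRSCH_MASKS",
    "default_feature_registry",
    "ldp_histogram",
    "lfp_histogram",
    "shape_descriptors",
    "color_features",
    "extract_feature_vector",
]

logger = logging.getLogger(__name__)


class RegistryMismatchError(ValueError):
    """Operator output length does not match the registry's slot layout."""


@dataclass
class FeatureRegistry:
    """Ordered (name, category) slots; categories are texture/shape/color."""

    slots: Sequence
    version: str = "default-1.0"

    def __post_init__(self) -> None:
        names = [s[0] for s in self.slots]
        if len(set(names)) != len(names):
            raise ValueError("slot names must be unique")
        bad = {s[1] for s in self.slots} - {"texture", "shape", "color"}
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.slots)

    @property
    def names(self) -> list:
        return [s[0] for s in self.slots]

    @property
    def categories(self) -> list:
        return [s[1] for s in self.slots]

    def category_counts(self) -> dict:
        counts = {"texture": 0, "shape": 0, "color": 0}
        for _, cat in self.slots:
            counts[cat] += 1
        return counts

    def to_dict(self) -> dict:
        return {"version": self.version,
                "slots": [[n, c] for n, c in self.slots]}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureRegistry":
        return cls(slots=[tuple(s) for s in d["slots"]], version=d["version"])


@dataclass
class FeatureVector:
    """A tile's feature values in registry order, with an optional label."""

    values: np.ndarray
    registry: FeatureRegistry
    label: Optional[int] = None
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.registry),):
            raise RegistryMismatchError(
                f"expected {len(self.registry)} values, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


# Shape-slot layout: 5 properties x 8 aggregate statistics + 2 globals.
_SHAPE_PROPS = ("area", "perimeter", "eccentricity", "circularity", "solidity")
_SHAPE_STATS = ("mean", "sd", "min", "max", "median", "iqr", "skew", "sum")
_COLOR_NAMES = (
    [f"color_{ch}_{st}" for ch in ("r", "g", "b", "h", "s", "v")
     for st in ("mean", "sd")]
    + [f"color_hue_hist_{i}" for i in range(8)]
    + ["color_entropy", "color_colorfulness"]
)


def default_feature_registry(
    ldp_k: int = 3, lfp_bands: int = 5, lfp_orientations: int = 6
) -> FeatureRegistry:
    """The default 150-slot registry (86 texture / 42 shape / 22 color)."""
    n_ldp = _n_combinations(8, ldp_k)
    slots = [(f"ldp_{i:03d}", "texture") for i in range(n_ldp)]
    slots += [
        (f"lfp_b{b}_o{o}", "texture")
        for b in range(lfp_bands)
        for o in range(lfp_orientations)
    ]
    slots += [
        (f"shape_{p}_{s}", "shape") for p in _SHAPE_PROPS for s in _SHAPE_STATS
    ]
    slots += [("shape_n_components", "shape"), ("shape_fg_fraction", "shape")]
    slots += [(name, "color") for name in _COLOR_NAMES]
    return FeatureRegistry(slots=slots)


def _n_combinations(n: int, k: int) -> int:
    import math

    return math.comb(n, k)


# ---------------------------------------------------------------------------
# Texture: local directional patterns
# ---------------------------------------------------------------------------

#: The eight Kirsch compass masks, rotating from north counter-clockwise.
KIRSCH_MASKS = np.array(
    [
        [[5, 5, 5], [-3, 0, -3], [-3, -3, -3]],   # N
        [[5, 5, -3], [5, 0, -3], [-3, -3, -3]],   # NW
        [[5, -3, -3], [5, 0, -3], [5, -3, -3]],   # W
        [[-3, -3, -3], [5, 0, -3], [5, 5, -3]],   # SW
        [[-3, -3, -3], [-3, 0, -3], [5, 5, 5]],   # S
        [[-3, -3, -3], [-3, 0, 5], [-3, 5, 5]],   # SE
        [[-3, -3, 5], [-3, 0, 5], [-3, -3, 5]],   # E
        [[-3, 5, 5], [-3, 0, 5], [-3, -3, -3]],   # NE
    ],
    dtype=float,
)


def ldp_histogram(gray: np.ndarray, k: int = 3) -> np.ndarray:
    """Local-directional-pattern code histogram.

    Per interior pixel the eight Kirsch responses are computed; the code is
    the set of the ``k`` largest absolute responses (ties broken toward the
    lowest mask index), ranked into one of C(8, k) bins. The histogram over
    interior pixels is normalized to sum 1.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2 or min(gray.shape) < 3:
        raise ValueError(f"need a 2-D image at least 3x3, got shape {gray.shape}")
    if not (1 <= k <= 7):
        raise ValueError("k must be in 1..7")

    responses = np.stack(
        [ndimage.correlate(gray, m, mode="nearest") for m in KIRSCH_MASKS]
    )[:, 1:-1, 1:-1]
    # stable argsort on -|response| -> lowest mask index wins ties
    order = np.argsort(-np.abs(responses), axis=0, kind="stable")
    top = np.sort(order[:k], axis=0)  # ascending index tuples, shape (k, h, w)

    flat = np.zeros(top.shape[1:], dtype=np.int64)
    for m in range(k):
        flat = flat * 8 + top[m]
    lookup = _combination_rank_table(k)
    codes = lookup[flat.ravel()]
    n_bins = _n_combinations(8, k)
    hist = np.bincount(codes, minlength=n_bins).astype(float)
    return hist / hist.sum()


_RANK_TABLES: dict = {}


def _combination_rank_table(k: int) -> np.ndarray:
    """Flat-index lookup mapping an ascending k-tuple of mask indices
    (base-8 encoded) to its combination rank."""
    if k not in _RANK_TABLES:
        table = np.full(8 ** k, -1, dtype=np.int64)
        for rank, combo in enumerate(itertools.combinations(range(8), k)):
            idx = 0
            for c in combo:
                idx = idx * 8 + c
            table[idx] = rank
        _RANK_TABLES[k] = table
    return _RANK_TABLES[k]


# ---------------------------------------------------------------------------
# Texture: local frequency patterns
# ---------------------------------------------------------------------------

#: Exceedance margin on unit-scaled images; a response must beat its local
#: mean by this much to count.
_LFP_MARGIN = 1e-6


def lfp_histogram(
    gray: np.ndarray,
    bands: int = 5,
    orientations: int = 6,
    window: int = 9,
) -> np.ndarray:
    """Local-frequency-pattern descriptor.

    A Gabor band-pass bank (``bands`` radial frequencies, geometrically
    spaced, x ``orientations``) is evaluated; for each filter the fraction
    of pixels whose response magnitude exceeds its own local mean (a
    ``window x window`` box average) plus a small margin is recorded. The
    result is a ``bands * orientations`` vector of rates in [0, 1].
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2 or min(gray.shape) < 8:
        raise ValueError(f"need a 2-D image at least 8x8, got shape {gray.shape}")
    if gray.max() > 1.5:  # accept 8-bit input
        gray = gray / 255.0

    freqs = np.geomspace(0.08, 0.4, bands)
    out = np.empty(bands * orientations)
    i = 0
    for f in freqs:
        for o in range(orientations):
            theta = o * np.pi / orientations
            real, imag = gabor(gray, frequency=f, theta=theta)
            mag = np.hypot(real, imag)
            local_mean = ndimage.uniform_filter(mag, size=window, mode="reflect")
            out[i] = float(np.mean(mag > local_mean + _LFP_MARGIN))
            i += 1
    return out


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

def shape_descriptors(mask: np.ndarray) -> np.ndarray:
    """42-slot shape descriptor of a binary mask.

    Area, perimeter, eccentricity, circularity and solidity per 8-connected
    component, each aggregated with mean/sd/min/max/median/IQR/skewness/sum,
    plus component count and foreground fraction. An empty mask yields the
    all-zero vector.
    """
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), [0, 1])):
        raise ValueError("mask must be binary (0/1)")
    labeled = measure.label(mask, connectivity=2)
    props = measure.regionprops(labeled)
    if not props:
        return np.zeros(len(_SHAPE_PROPS) * len(_SHAPE_STATS) + 2)

    per_prop = {p: [] for p in _SHAPE_PROPS}
    for rp in props:
        area = float(rp.area)
        perim = float(rp.perimeter)
        per_prop["area"].append(area)
        per_prop["perimeter"].append(perim)
        per_prop["eccentricity"].append(float(rp.eccentricity))
        per_prop["circularity"].append(
            4.0 * np.pi * area / perim ** 2 if perim > 0 else 0.0
        )
        per_prop["solidity"].append(float(rp.solidity))

    out = []
    for p in _SHAPE_PROPS:
        vals = np.asarray(per_prop[p])
        out.extend(_aggregate(vals))
    out.append(float(len(props)))
    out.append(float(mask.mean()))
    return np.asarray(out)


def _aggregate(vals: np.ndarray) -> list:
    q75, q25 = np.percentile(vals, [75, 25])
    skew = stats.skew(vals) if vals.size > 2 else 0.0
    return [
        float(vals.mean()),
        float(vals.std()),
        float(vals.min()),
        float(vals.max()),
        float(np.median(vals)),
        float(q75 - q25),
        float(np.nan_to_num(skew)),
        float(vals.sum()),
    ]


# ---------------------------------------------------------------------------
# Color
# ---------------------------------------------------------------------------

def color_features(tile: HistologyTile) -> np.ndarray:
    """22-slot color descriptor (RGB/HSV statistics, hue histogram,
    intensity entropy, colorfulness). Hue is circular; pixels with zero
    saturation have undefined hue and are assigned to histogram bin 0."""
    rgb = tile.pixels.astype(float) / 255.0
    hsv = skcolor.rgb2hsv(rgb)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]

    out = []
    for ch in (rgb[..., 0], rgb[..., 1], rgb[..., 2]):
        out.extend([float(ch.mean()), float(ch.std())])
    defined = s > 1e-9
    if defined.any():
        ang = h[defined] * 2.0 * np.pi
        out.extend([
            float(stats.circmean(ang, high=2 * np.pi) / (2 * np.pi)),
            float(stats.circstd(ang, high=2 * np.pi) / (2 * np.pi)),
        ])
    else:
        out.extend([0.0, 0.0])
    out.extend([float(s.mean()), float(s.std())])
    out.extend([float(v.mean()), float(v.std())])

    bins = np.clip((h * 8).astype(int), 0, 7)
    bins = np.where(defined, bins, 0)
    hist = np.bincount(bins.ravel(), minlength=8).astype(float)
    out.extend(hist / hist.sum())

    gray = np.clip(np.round(skcolor.rgb2gray(rgb) * 255), 0, 255).astype(np.uint8)
    counts = np.bincount(gray.ravel(), minlength=256).astype(float)
    p = counts[counts > 0] / counts.sum()
    out.append(float(-(p * np.log2(p)).sum()))

    rg = rgb[..., 0] - rgb[..., 1]
    yb = 0.5 * (rgb[..., 0] + rgb[..., 1]) - rgb[..., 2]
    out.append(float(
        np.hypot(rg.std(), yb.std()) + 0.3 * np.hypot(rg.mean(), yb.mean())
    ))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Full vector
# ---------------------------------------------------------------------------

def extract_feature_vector(
    tile: HistologyTile,
    registry: Optional[FeatureRegistry] = None,
    label: Optional[int] = None,
) -> FeatureVector:
    """Concatenate LDP + LFP + shape + color in registry order.

    Shape features use the tile's mask when present; otherwise foreground is
    estimated by Otsu thresholding the hematoxylin concentration channel
    (logged). Raises :class:`RegistryMismatchError` if the operator outputs
    do not tile the registry exactly.
    """
    registry = registry or default_feature_registry()
    gray = skcolor.rgb2gray(tile.pixels.astype(float) / 255.0)

    ldp = ldp_histogram(gray)
    lfp = lfp_histogram(gray)

    if tile.mask is not None:
        mask = tile.mask
    else:
        logger.info("tile %s: no mask, using Otsu hematoxylin foreground", tile.id)
        mask = _otsu_foreground(tile)
    shape = shape_descriptors(mask)
    col = color_features(tile)

    values = np.concatenate([ldp, lfp, shape, col])
    if values.shape[0] != len(registry):
        raise RegistryMismatchError(
            f"operators produced {values.shape[0]} values for a "
            f"{len(registry)}-slot registry"
        )
    counts = registry.category_counts()
    if counts["texture"] != ldp.size + lfp.size or counts["shape"] != shape.size:
        raise RegistryMismatchError(
            f"registry category layout {counts} does not match operator "
            f"outputs (texture {ldp.size + lfp.size}, shape {shape.size}, "
            f"color {col.size})"
        )
    return FeatureVector(values=values, registry=registry, label=label, id=tile.id)


def write_feature_table(path, vectors: Sequence[FeatureVector]) -> None:
    """Write feature vectors as CSV: columns id, label, then slot names."""
    import pandas as pd

    if not vectors:
        raise ValueError("no feature vectors to write")
    registry = vectors[0].registry
    rows = []
    for fv in vectors:
        row = {"id": fv.id, "label": "" if fv.label is None else int(fv.label)}
        row.update(dict(zip(registry.names, fv.values)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_table(path):
    """Read a feature-table CSV back as (ids, X, y, slot_names)."""
    import pandas as pd

    df = pd.read_csv(path)
    names = [c for c in df.columns if c not in ("id", "label")]
    y = None
    if "label" in df.columns and df["label"].notna().all():
        y = df["label"].to_numpy(dtype=int)
    return df["id"].tolist(), df[names].to_numpy(dtype=float), y, names


def write_registry(path, registry: FeatureRegistry) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(registry.to_dict(), fh, indent=2)


def read_registry(path) -> FeatureRegistry:
    import json

    with open(path) as fh:
        return FeatureRegistry.from_dict(json.load(fh))


def _otsu_foreground(tile: HistologyTile) -> np.ndarray:
    od = rgb_to_od(tile.pixels)
    h, w, _ = od.shape
    conc = _concentrations(od.reshape(-1, 3), RUIFROK_HE)
    hema = conc[0].reshape(h, w)
    if np.ptp(hema) < 1e-9:
        return np.zeros((h, w), dtype=np.uint8)
    return (hema > threshold_otsu(hema)).astype(np.uint8)
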