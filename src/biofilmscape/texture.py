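"""Spatial gray level dependence matrices (SGLDM) and textural descriptors.

Landscape-scale biofilm images carry morphological information in their
gray-level variation: on transmitted-light images dense biomass absorbs light
and appears dark, while under oblique illumination dense biomass refracts the
inclined beam and appears bright.  An SGLDM is the normalized histogram of
gray-level pairs separated by a fixed pixel offset in a fixed direction —
identical in construction to a gray-level co-occurrence matrix.  Scalar
textural descriptors (Haralick statistics) summarize each matrix; crossing
descriptors over angles, separation distances and the two illumination modes
yields one morphology feature vector per imaged location, which is averaged
over locations to describe a biofilm sample.

All descriptor formulas use 1-based gray indices (pixel value + 1), so that
the sum-average descriptor ``f6`` obeys the identity ``(f6/2) - 1 = mean gray
level`` on balanced images.  Logarithms are natural and ``0*log(0) == 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

__all__ = [
    "GrayImage",
    "OffsetSpec",
    "SGLDMatrix",
    "DescriptorSet",
    "FeatureVector",
    "DEFAULT_PIXEL_SIZE_UM",
    "DEFAULT_OFFSETS_PX",
    "DESCRIPTOR_NAMES",
    "default_offset_menu",
    "compute_sgldm",
    "compute_descriptors",
    "extract_features",
    "aggregate_locations",
    "read_gray_tiff",
    "field_of_view_mm",
]

#: Physical pixel edge length of the stereomicroscope setup, in micrometres.
DEFAULT_PIXEL_SIZE_UM = 2.92

#: Pixel separations of the default distance menu (15 distances).
DEFAULT_OFFSETS_PX = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 200, 250, 300, 350, 400)

ANGLES_DEG = (0, 45)

N_LEVELS = 256

ILLUMINATIONS = ("transmitted", "oblique")


@dataclass(frozen=True)
class GrayImage:
    """A single-channel 8-bit landscape image with acquisition metadata."""

    pixels: np.ndarray
    illumination: str
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    sample_id: str = ""
    location_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("image must be 2-D with dimensions >= 2x2")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        if self.illumination not in ILLUMINATIONS:
            raise ValueError(f"illumination must be one of {ILLUMINATIONS}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class OffsetSpec:
    """One (angle, distance) entry of the SGLDM menu.

    ``offset_px`` is the per-axis pixel separation ``d``; ``label_um`` is the
    physical distance label used in reports (pixel separation times pixel
    size, rounded to the nearest 10 um — the labelling arithmetic applies the
    per-axis pixel count also on the diagonal).
    """

    angle_deg: int
    offset_px: int
    label_um: int

    def __post_init__(self) -> None:
        if self.angle_deg not in ANGLES_DEG:
            raise ValueError(f"angle must be one of {ANGLES_DEG}")
        if self.offset_px < 1:
            raise ValueError("offset_px must be a positive integer")


@dataclass(frozen=True)
class SGLDMatrix:
    """Normalized, symmetric co-occurrence probabilities for one offset."""

    p: np.ndarray
    offset: OffsetSpec
    n_pairs: int

    def __post_init__(self) -> None:
        if self.p.shape != (N_LEVELS, N_LEVELS):
            raise ValueError("p must be 256x256")
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")


@dataclass
class DescriptorSet:
    """Values of the 15 textural descriptors for one SGLDM.

    Descriptors whose formula is undefined for a degenerate matrix (zero
    marginal variance or entropy) carry ``nan`` and are listed in
    ``undefined_flags``; they are treated as missing downstream, never as
    errors.
    """

    values: dict[str, float]
    undefined_flags: set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class FeatureVector:
    """Ordered morphology features keyed by (illumination, angle, label, descriptor)."""

    keys: list[tuple[str, int, int, str]]
    values: np.ndarray
    counts: np.ndarray | None = None  # contributing locations per key after aggregation

    def __len__(self) -> int:
        return len(self.keys)

    def to_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(
            self.keys, names=["illumination", "angle_deg", "distance_um", "descriptor"]
        )
        return pd.Series(self.values, index=idx)

    def key_strings(self) -> list[str]:
        return [f"{il}|a{a}|d{d}|{f}" for il, a, d, f in self.keys]


def _round_to_10(x: float) -> int:
    return int(math.floor(x / 10.0 + 0.5)) * 10


def default_offset_menu(pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                        offsets_px: Sequence[int] = DEFAULT_OFFSETS_PX,
                        angles_deg: Sequence[int] = ANGLES_DEG) -> list[OffsetSpec]:
    """Build the angle x distance menu with physical distance labels.

    At the default 2.92 um/pixel the 15 default pixel separations label as
    30, 60, 90, 120, 150, 180, 200, 230, 260, 290, 580, 730, 880, 1020 and
    1170 um.
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    menu = []
    for angle in angles_deg:
        for d in offsets_px:
            menu.append(OffsetSpec(angle, int(d), _round_to_10(d * pixel_size_um)))
    return menu


def compute_sgldm(img: GrayImage, offset: OffsetSpec) -> SGLDMatrix:
    """Count co-occurring gray-level pairs at one offset and normalize.

    For angle 0 a pixel at (r, c) is paired with (r, c+d); for angle 45 with
    (r-d, c+d) (up-right diagonal, per-axis separation d).  Only pairs fully
    inside the image contribute; each unordered pair is counted in both
    directions, which makes the matrix symmetric.
    """
    px = img.pixels
    n_rows, n_cols = px.shape
    d = offset.offset_px
    if offset.angle_deg == 0:
        if d >= n_cols:
            raise ValueError(
                f"offset {d}px at 0 deg exceeds image width {n_cols}px"
            )
        a = px[:, :-d]
        b = px[:, d:]
    else:  # 45 degrees
        if d >= n_rows or d >= n_cols:
            raise ValueError(
                f"offset {d}px at 45 deg exceeds image extent {n_rows}x{n_cols}px"
            )
        a = px[d:, :-d]
        b = px[:-d, d:]
    a = a.ravel().astype(np.intp)
    b = b.ravel().astype(np.intp)
    counts = np.bincount(a * N_LEVELS + b, minlength=N_LEVELS * N_LEVELS).astype(float)
    counts = counts.reshape(N_LEVELS, N_LEVELS)
    counts += counts.T  # symmetric: count each pair in both directions
    n_pairs = 2 * a.size
    return SGLDMatrix(p=counts / n_pairs, offset=offset, n_pairs=n_pairs)


# ---------------------------------------------------------------------------
# descriptors

_IDX = np.arange(1, N_LEVELS + 1, dtype=float)  # 1-based gray indices


def _marginal_stats(p: np.ndarray):
    px_m = p.sum(axis=1)
    mu = float(_IDX @ px_m)
    var = float(((_IDX - mu) ** 2) @ px_m)
    # p_{x+y}(k), k = 2..512 and p_{x-y}(k), k = 0..255
    i = np.arange(N_LEVELS)
    ksum = i[:, None] + i[None, :]  # 0..510 -> k-2
    kdiff = np.abs(i[:, None] - i[None, :])
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * N_LEVELS - 1)
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=N_LEVELS)
    return px_m, mu, var, p_sum, p_diff


def _entropy(v: np.ndarray) -> float:
    return float(-xlogy(v, v).sum())


def compute_descriptors(m: SGLDMatrix,
                        registry: Mapping[str, Callable] | None = None) -> DescriptorSet:
    """Evaluate the 15 textural descriptors of one SGLDM.

    The default registry is Haralick's f1-f14 plus the maximal probability
    (f15).  The matrix is symmetric, so the two marginal distributions
    coincide.  Degenerate matrices (a single occupied gray level) leave the
    correlation-type descriptors f3, f12, f13 and f14 undefined; these are
    flagged, not errored.
    """
    if registry is not None:
        values = {name: fn(m) for name, fn in registry.items()}
        flagged = {k for k, v in values.items() if isinstance(v, float) and math.isnan(v)}
        return DescriptorSet(values=values, undefined_flags=flagged)

    p = m.p
    px_m, mu, var, p_sum, p_diff = _marginal_stats(p)
    sigma = math.sqrt(var)
    hx = _entropy(px_m)
    hxy = _entropy(p.ravel())

    values: dict[str, float] = {}
    flags: set[str] = set()

    values["f1"] = float((p * p).sum())  # angular second moment
    kd = np.arange(N_LEVELS, dtype=float)
    values["f2"] = float((kd ** 2) @ p_diff)  # contrast

    # correlation: (E[ij] - mu_x mu_y) / (sigma_x sigma_y)
    if var > 0:
        e_ij = float(_IDX @ p @ _IDX)
        values["f3"] = (e_ij - mu * mu) / var
    else:
        values["f3"] = float("nan")
        flags.add("f3")

    values["f4"] = var  # sum of squares: variance about the marginal mean
    values["f5"] = float((p / (1.0 + (np.subtract.outer(_IDX, _IDX)) ** 2)).sum())

    ks = np.arange(2, 2 * N_LEVELS + 1, dtype=float)  # k = 2..512
    f6 = float(ks @ p_sum)
    values["f6"] = f6  # sum average; (f6/2)-1 = mean gray level
    values["f7"] = float(((ks - f6) ** 2) @ p_sum)  # sum variance (about f6)
    values["f8"] = _entropy(p_sum)  # sum entropy
    values["f9"] = hxy  # entropy

    mu_diff = float(kd @ p_diff)
    values["f10"] = float(((kd - mu_diff) ** 2) @ p_diff)  # difference variance
    values["f11"] = _entropy(p_diff)  # difference entropy

    # information measures of correlation; HX == HY by symmetry
    with np.errstate(divide="ignore", invalid="ignore"):
        pxpy = np.outer(px_m, px_m)
        hxy1 = float(-(p * np.where(pxpy > 0, np.log(np.where(pxpy > 0, pxpy, 1.0)), 0.0)).sum())
        hxy2 = _entropy(pxpy.ravel())
    if hx > 0:
        values["f12"] = (hxy - hxy1) / hx
    else:
        values["f12"] = float("nan")
        flags.add("f12")
    if var > 0:
        values["f13"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    else:
        values["f13"] = float("nan")
        flags.add("f13")

    # maximal correlation coefficient: 2nd largest singular value of
    # p(i,j)/sqrt(px(i) py(j)) restricted to occupied gray levels
    nz = px_m > 0
    if nz.sum() >= 2 and var > 0:
        sq = np.sqrt(px_m[nz])
        mat = p[np.ix_(nz, nz)] / sq[:, None] / sq[None, :]
        sv = np.linalg.svd(mat, compute_uv=False)
        values["f14"] = float(sv[1]) if len(sv) > 1 else float("nan")
    else:
        values["f14"] = float("nan")
        flags.add("f14")

    values["f15"] = float(p.max())  # maximal probability

    return DescriptorSet(values=values, undefined_flags=flags)


DESCRIPTOR_NAMES = tuple(f"f{i}" for i in range(1, 16))


def extract_features(images: Mapping[str, GrayImage],
                     menu: Sequence[OffsetSpec] | None = None,
                     descriptor_names: Sequence[str] = DESCRIPTOR_NAMES,
                     registry: Mapping[str, Callable] | None = None) -> FeatureVector:
    """Compute the fully crossed morphology feature vector for one location.

    ``images`` maps illumination mode to its image.  The key order is
    deterministic: illumination (transmitted, oblique) x angle x distance
    (menu order) x descriptor (registry order); under the defaults the vector
    has 2 x 2 x 15 x 15 = 900 entries.
    """
    for il in ILLUMINATIONS:
        if il not in images:
            raise ValueError(f"missing {il}-illumination image")
    shapes = {images[il].shape for il in ILLUMINATIONS}
    if len(shapes) != 1:
        raise ValueError(f"illumination images differ in dimensions: {shapes}")
    if menu is None:
        menu = default_offset_menu(images["transmitted"].pixel_size_um)

    keys: list[tuple[str, int, int, str]] = []
    vals: list[float] = []
    for il in ILLUMINATIONS:
        img = images[il]
        for off in menu:
            ds = compute_descriptors(compute_sgldm(img, off), registry=registry)
            for name in descriptor_names:
                keys.append((il, off.angle_deg, off.label_um, name))
                vals.append(ds.values[name])
    return FeatureVector(keys=keys, values=np.asarray(vals, dtype=float))


def aggregate_locations(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Average feature vectors over imaged locations of one sample.

    Undefined (nan) entries are excluded per key; the result records how many
    locations contributed to each mean.
    """
    if len(vectors) == 0:
        raise ValueError("need at least one feature vector")
    keys = vectors[0].keys
    for v in vectors[1:]:
        if v.keys != keys:
            raise ValueError("feature vectors have mismatched keys")
    stack = np.vstack([v.values for v in vectors])
    finite = np.isfinite(stack)
    counts = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, np.nansum(np.where(finite, stack, 0.0), axis=0)
                         / np.maximum(counts, 1), np.nan)
    return FeatureVector(keys=list(keys), values=means, counts=counts)


# ---------------------------------------------------------------------------
# I/O helpers

def read_gray_tiff(path) -> np.ndarray:
    """Read a single-channel 8-bit grayscale TIFF into a uint8 matrix."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel grayscale image")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got {arr.dtype}")
    return arr


def field_of_view_mm(n_cols: int, n_rows: int,
                     pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> tuple[float, float]:
    """Observation area edge lengths in millimetres, rounded to one decimal.

    The full-frame acquisition of 2176 x 1632 px at 2.92 um/px covers
    6.4 x 4.8 mm^2.
    """
    return (round(n_cols * pixel_size_um / 1000.0, 1),
            round(n_rows * pixel_size_um / 1000.0, 1))
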