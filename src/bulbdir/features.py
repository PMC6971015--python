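"""Shape, edge and texture features of a bulb radiograph.

Each x-ray projection image is reduced to a 105-element feature vector:

* 36 shape features — the bulb silhouette (5%-of-max threshold) is
  compared to the matched-area ellipse with the same centroid and
  principal-axis orientation; the signed silhouette/ellipse difference is
  binned into a 36-sector (10 degree) angular histogram about the
  centroid, emphasizing non-elliptical structure such as the tip.
* 36 edge features — a multiscale Hessian vesselness filter highlights
  the bulb's layered shells and central shaft; vesselness values inside
  the silhouette are accumulated into the same 36-sector histogram.
* 33 texture features — uniform local binary patterns (radius 2, six
  neighbours): 32 uniform-code bins plus one pooled non-uniform bin,
  counted over silhouette pixels.

All three histograms are z-score normalized (population std); a
degenerate-variance guard emits all zeros when a histogram is constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

__all__ = [
    "FeatureError",
    "NoObjectError",
    "DegeneratePCAError",
    "ImageSizeError",
    "Radiograph",
    "BulbSegmentation",
    "FeatureVector",
    "FEATURE_NAMES",
    "segment_bulb",
    "ellipse_mask",
    "shape_features",
    "frangi_vesselness",
    "edge_features",
    "lbp_codes",
    "uniform_code_bins",
    "texture_features",
    "extract_features",
    "zscore",
]

N_SECTORS = 36
N_SHAPE, N_EDGE, N_TEXTURE = 36, 36, 33

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"shape_{i:02d}" for i in range(N_SHAPE)]
    + [f"edge_{i:02d}" for i in range(N_EDGE)]
    + [f"lbp_{i:02d}" for i in range(N_TEXTURE)]
)


class FeatureError(ValueError):
    """Base class for feature-extraction failures."""


class NoObjectError(FeatureError):
    """Thresholding found no foreground pixels."""


class DegeneratePCAError(FeatureError):
    """Too few foreground pixels for a principal-axis fit."""


class ImageSizeError(FeatureError):
    """Image smaller than an operator's footprint."""


@dataclass(frozen=True)
class Radiograph:
    """A 2D line-integral attenuation image.

    Pixel values are integrals of linear attenuation along parallel x-ray
    paths: air is ~0 and the bulb is bright. ``pixel_size`` is mm/pixel.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise FeatureError("radiograph must be a 2D array")
        if not np.all(np.isfinite(px)):
            raise FeatureError("radiograph contains non-finite values")
        if px.min() < -1e-9:
            raise FeatureError("attenuation line integrals must be non-negative")
        object.__setattr__(self, "pixels", np.maximum(px, 0.0))


def _as_pixels(img: "Radiograph | np.ndarray") -> np.ndarray:
    if isinstance(img, Radiograph):
        return img.pixels
    return np.asarray(img, dtype=float)


@dataclass(frozen=True)
class BulbSegmentation:
    """Binary bulb silhouette with its principal-axis summary.

    ``centroid`` is (x_c, y_c) with x = column and y = row index;
    ``alpha`` is the major-axis orientation in radians (mod pi) measured
    from the image +x axis; ``semi_axes`` (a, b) are half the extents of
    the silhouette pixels projected onto the major/minor axes, a >= b.
    """

    mask: np.ndarray
    centroid: tuple[float, float]
    alpha: float
    semi_axes: tuple[float, float]


def segment_bulb(img: "Radiograph | np.ndarray", frac: float = 0.05) -> BulbSegmentation:
    """Threshold the radiograph at ``frac`` of its maximum and fit axes.

    Principal component analysis of the foreground pixel coordinates
    yields the centroid, the major-axis orientation and the semi-axes
    (half the coordinate extents along each principal direction).
    """
    px = _as_pixels(img)
    if px.size == 0 or px.max() <= 0.0:
        raise NoObjectError("image has no positive intensities")
    mask = px > frac * px.max()
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise NoObjectError("threshold produced an empty segmentation")
    if xs.size < 3:
        raise DegeneratePCAError("fewer than 3 foreground pixels")
    coords = np.stack([xs, ys], axis=1).astype(float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    major = evecs[:, 1]
    minor = evecs[:, 0]
    alpha = math.atan2(major[1], major[0]) % math.pi
    proj_major = centered @ major
    proj_minor = centered @ minor
    a = float(proj_major.max() - proj_major.min()) / 2.0
    b = float(proj_minor.max() - proj_minor.min()) / 2.0
    if b <= 0.0:
        raise DegeneratePCAError("segmentation is collinear; no minor axis extent")
    return BulbSegmentation(
        mask=mask,
        centroid=(float(centroid[0]), float(centroid[1])),
        alpha=alpha,
        semi_axes=(a, b),
    )


def ellipse_mask(seg: BulbSegmentation, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the matched ellipse for a segmentation.

    The ellipse shares the silhouette's centroid and orientation, and its
    semi-axes are the PCA semi-axes rescaled by one common factor so the
    continuous ellipse area pi*a'*b' equals the silhouette pixel count
    (same-area comparison preserving aspect ratio).
    """
    a, b = seg.semi_axes
    area = float(seg.mask.sum())
    scale = math.sqrt(area / (math.pi * a * b))
    a_s, b_s = a * scale, b * scale
    xc, yc = seg.centroid
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = xs - xc
    dy = ys - yc
    ca, sa = math.cos(seg.alpha), math.sin(seg.alpha)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / a_s) ** 2 + (v / b_s) ** 2 <= 1.0


def zscore(h: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Z-score a histogram with the population std; all-zero if constant."""
    h = np.asarray(h, dtype=float)
    std = h.std()
    if std < eps:
        return np.zeros_like(h)
    return (h - h.mean()) / std


def _sector_indices(shape: tuple[int, int], centroid: tuple[float, float]) -> np.ndarray:
    """10-degree sector index of every pixel about the centroid.

    The sector angle is measured from the image +x axis (columns) toward
    +y (rows); bin i covers [10i, 10(i+1)) degrees.
    """
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    ang = np.degrees(np.arctan2(ys - centroid[1], xs - centroid[0])) % 360.0
    return np.minimum((ang / 10.0).astype(int), N_SECTORS - 1)


def shape_features(
    img: "Radiograph | np.ndarray", frac: float = 0.05, seg: BulbSegmentation | None = None
) -> np.ndarray:
    """Signed silhouette-vs-ellipse angular histogram (36 values, z-scored).

    Pixels where the silhouette exceeds its matched ellipse contribute +1
    to their sector (protrusions such as the tip); pixels covered by the
    ellipse but not the silhouette contribute -1 (concavities).
    """
    if seg is None:
        seg = segment_bulb(img, frac)
    px = _as_pixels(img)
    ell = ellipse_mask(seg, px.shape)
    s_diff = seg.mask.astype(int) - ell.astype(int)
    sectors = _sector_indices(px.shape, seg.centroid)
    nz = s_diff != 0
    hist = np.bincount(sectors[nz], weights=s_diff[nz], minlength=N_SECTORS)[:N_SECTORS]
    return zscore(hist)


def _hessian_eigvals(smoothed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference Hessian eigenvalues ordered |l1| <= |l2|."""
    gy, gx = np.gradient(smoothed)
    hyy = np.gradient(gy, axis=0)
    hxy = np.gradient(gx, axis=0)
    hxx = np.gradient(gx, axis=1)
    half_tr = (hxx + hyy) / 2.0
    disc = np.sqrt(((hxx - hyy) / 2.0) ** 2 + hxy**2)
    e_hi = half_tr + disc
    e_lo = half_tr - disc
    swap = np.abs(e_hi) < np.abs(e_lo)
    l1 = np.where(swap, e_hi, e_lo)
    l2 = np.where(swap, e_lo, e_hi)
    return l1, l2


def frangi_vesselness(
    img: "Radiograph | np.ndarray",
    beta: float = 0.5,
    c: float = 15.0,
    sigmas: tuple[float, ...] = (3.0, 5.0, 7.0),
    classical: bool = False,
) -> np.ndarray:
    """Multiscale Hessian vesselness map in [0, 1].

    At each scale the image is Gaussian-smoothed, the per-pixel 2x2
    Hessian is formed by central finite differences, and its eigenvalues
    (|l1| <= |l2|) feed a blobness and a structure term; the per-pixel
    maximum over scales is returned.

    The default scores ``exp(-l2^2/(2 l1^2 beta^2)) *
    (1 - exp(-l1^2 l2^2 / (2 c^2)))`` gated on l1 < 0. ``classical=True``
    switches to the original Frangi 2-D form (ratio l1/l2, structure term
    l1^2 + l2^2, gated on l2 < 0) for bright structures.
    """
    px = _as_pixels(img)
    kernel_extent = int(4.0 * max(sigmas) + 0.5)
    if min(px.shape) <= 2 * kernel_extent:
        raise ImageSizeError("image smaller than the largest Gaussian kernel")
    out = np.zeros_like(px)
    for sigma in sigmas:
        sm = ndimage.gaussian_filter(px, sigma, mode="reflect")
        l1, l2 = _hessian_eigvals(sm)
        if classical:
            gate = l2 < 0.0
            with np.errstate(divide="ignore", invalid="ignore"):
                rb2 = np.where(gate, (l1 / np.where(gate, l2, 1.0)) ** 2, 0.0)
            s2 = l1**2 + l2**2
            v = np.where(
                gate,
                np.exp(-rb2 / (2.0 * beta**2)) * (1.0 - np.exp(-s2 / (2.0 * c**2))),
                0.0,
            )
        else:
            gate = l1 < 0.0
            l1_safe = np.where(gate, l1, 1.0)
            ratio2 = np.where(gate, (l2 / l1_safe) ** 2, 0.0)
            struct = l1**2 * l2**2
            v = np.where(
                gate,
                np.exp(-ratio2 / (2.0 * beta**2)) * (1.0 - np.exp(-struct / (2.0 * c**2))),
                0.0,
            )
        out = np.maximum(out, v)
    return out


def edge_features(
    img: "Radiograph | np.ndarray",
    frac: float = 0.05,
    beta: float = 0.5,
    c: float = 15.0,
    sigmas: tuple[float, ...] = (3.0, 5.0, 7.0),
    classical: bool = False,
    intensity_scale: float = 255.0,
    seg: BulbSegmentation | None = None,
) -> np.ndarray:
    """Vesselness-weighted angular histogram (36 values, z-scored).

    The radiograph is rescaled so its maximum equals ``intensity_scale``
    before filtering — the structure-term constant c is defined on a
    0-255 intensity convention and would otherwise suppress all response
    on unit-scale line integrals. Each silhouette pixel contributes its
    vesselness value to the 10-degree sector containing it.
    """
    if seg is None:
        seg = segment_bulb(img, frac)
    px = _as_pixels(img)
    scaled = px * (intensity_scale / px.max())
    v = frangi_vesselness(scaled, beta=beta, c=c, sigmas=sigmas, classical=classical)
    sectors = _sector_indices(px.shape, seg.centroid)
    inside = seg.mask
    hist = np.bincount(sectors[inside], weights=v[inside], minlength=N_SECTORS)[:N_SECTORS]
    return zscore(hist)


def lbp_codes(img: "Radiograph | np.ndarray", r: int = 2, k: int = 6) -> np.ndarray:
    """Circular local binary pattern codes, one per interior pixel.

    Samples ``k`` points uniformly on the radius-``r`` circle (bilinear
    interpolation at fractional coordinates); bit m is 1 iff the sampled
    neighbour is strictly larger than the centre. Bits are ordered
    clockwise (in the Cartesian frame with y up; row index increases
    downward) starting from the +x-axis sample, first sample most
    significant. Border pixels of width ``r`` carry the sentinel -1.
    """
    px = _as_pixels(img)
    h, w = px.shape
    if h < 2 * r + 1 or w < 2 * r + 1:
        raise ImageSizeError(f"image must exceed {2 * r + 1} pixels in both dimensions")
    codes = np.full((h, w), -1, dtype=np.int64)
    rows = np.arange(r, h - r)
    cols = np.arange(r, w - r)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    centre = px[rr, cc]
    acc = np.zeros_like(centre, dtype=np.int64)
    for m in range(k):
        ang = 2.0 * math.pi * m / k
        dc = r * math.cos(ang)
        dr = r * math.sin(ang)
        sr = rr + dr
        sc = cc + dc
        r0 = np.floor(sr).astype(int)
        c0 = np.floor(sc).astype(int)
        fr = sr - r0
        fc = sc - c0
        r1 = np.clip(r0 + 1, 0, h - 1)
        c1 = np.clip(c0 + 1, 0, w - 1)
        val = (
            (1.0 - fr) * (1.0 - fc) * px[r0, c0]
            + (1.0 - fr) * fc * px[r0, c1]
            + fr * (1.0 - fc) * px[r1, c0]
            + fr * fc * px[r1, c1]
        )
        bit = (val > centre).astype(np.int64)
        acc |= bit << (k - 1 - m)
    codes[r : h - r, r : w - r] = acc
    return codes


@lru_cache(maxsize=None)
def uniform_code_bins(k: int = 6) -> dict[int, int]:
    """Map each uniform k-bit code to its histogram bin index.

    A code is uniform when its circular bit string has at most two 0<->1
    transitions; for k=6 there are k(k-1)+2 = 32 such codes. Uniform
    codes are binned in ascending code order; all non-uniform codes share
    the final pooled bin (index = number of uniform codes).
    """
    mapping: dict[int, int] = {}
    nxt = 0
    for code in range(2**k):
        bits = [(code >> (k - 1 - i)) & 1 for i in range(k)]
        transitions = sum(bits[i] != bits[(i + 1) % k] for i in range(k))
        if transitions <= 2:
            mapping[code] = nxt
            nxt += 1
    return mapping


def texture_features(
    img: "Radiograph | np.ndarray",
    frac: float = 0.05,
    r: int = 2,
    k: int = 6,
    seg: BulbSegmentation | None = None,
) -> np.ndarray:
    """Uniform-LBP histogram over silhouette pixels (33 values, z-scored)."""
    if seg is None:
        seg = segment_bulb(img, frac)
    codes = lbp_codes(img, r=r, k=k)
    table = uniform_code_bins(k)
    n_uniform = len(table)
    lut = np.full(2**k, n_uniform, dtype=np.int64)
    for code, bin_idx in table.items():
        lut[code] = bin_idx
    valid = (codes >= 0) & seg.mask
    hist = np.bincount(lut[codes[valid]], minlength=n_uniform + 1)[: n_uniform + 1]
    return zscore(hist)


@dataclass(frozen=True)
class FeatureVector:
    """The 105 ordered features: shape (36) | edge (36) | texture (33)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_SHAPE + N_EDGE + N_TEXTURE,):
            raise FeatureError(f"feature vector must have length 105, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise FeatureError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)


def extract_features(
    img: "Radiograph | np.ndarray",
    frac: float = 0.05,
    beta: float = 0.5,
    c: float = 15.0,
    sigmas: tuple[float, ...] = (3.0, 5.0, 7.0),
    classical: bool = False,
    intensity_scale: float = 255.0,
    lbp_r: int = 2,
    lbp_k: int = 6,
) -> FeatureVector:
    """Assemble the full 105-element feature vector of one radiograph."""
    seg = segment_bulb(img, frac)
    h_shape = shape_features(img, frac, seg=seg)
    h_edge = edge_features(
        img,
        frac,
        beta=beta,
        c=c,
        sigmas=sigmas,
        classical=classical,
        intensity_scale=intensity_scale,
        seg=seg,
    )
    h_texture = texture_features(img, frac, r=lbp_r, k=lbp_k, seg=seg)
    return FeatureVector(np.concatenate([h_shape, h_edge, h_texture]))
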