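"""Spatial (GLCM texture) and temporal (adjacent-aperture Dice) features.

The spatial characteristics of a beam's integrated fluence are summarized by
five gray-level co-occurrence matrix (GLCM) statistics — correlation,
contrast, energy, entropy and homogeneity — computed at displacement d = 1
along 0°, 45°, 90° and 135° and averaged over the four directions. With
p(i, j) the co-occurrence probability of quantized levels i and j:

    contrast    = sum p(i,j) (i-j)^2
    energy      = sum p(i,j)^2
    entropy     = -sum p(i,j) log2 p(i,j)          (0 log 0 = 0)
    homogeneity = sum p(i,j) / (1 + (i-j)^2)

Two correlation variants are provided. ``correlation_paper`` is

    sum (i - Mean)(j - Mean) p(i,j)^2 / Variance

with Mean/Variance the gray-scale mean and variance of the quantized image —
an unconventional form (squared probability, image-level moments) that this
package reproduces deliberately because the pipeline it implements was
defined with it; ``correlation_standard`` is the textbook GLCM correlation
built from the marginal means and variances of p. The pipeline default is
the first, switchable via ``correlation_mode``.

Temporal variability of a beam is the mean Dice overlap of adjacent CP
apertures: Dice = 2 |A ∩ B| / (|A| + |B|). High Dice means slowly-changing
apertures; heavily modulated beams score lower.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .geometry import MlcGeometry
from .plan_fluence import (
    ApertureMask,
    Beam,
    FluenceMap,
    beam_grid,
    edge_pixels,
    rasterize_aperture,
    validate_beam,
)

#: (row, col) unit displacements for the four search directions, d = 1 pixel.
OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

DEFAULT_N_LEVELS = 16


@dataclass(frozen=True)
class Glcm:
    """Normalized co-occurrence matrix plus the quantized-image gray moments
    needed by the non-standard correlation feature."""

    matrix: np.ndarray
    n_levels: int
    offset: tuple[int, int]
    symmetric: bool
    image_mean: float
    image_variance: float


@dataclass(frozen=True)
class SpatialFeatures:
    contrast: float
    energy: float
    entropy: float
    homogeneity: float
    correlation_paper: float
    correlation_standard: float
    correlation_mode: str = "paper"
    n_levels: int = DEFAULT_N_LEVELS
    entropy_log_base: int = 2

    @property
    def correlation(self) -> float:
        return self.correlation_paper if self.correlation_mode == "paper" else self.correlation_standard


@dataclass(frozen=True)
class TemporalFeature:
    dice: float
    per_pair_dice: tuple[float, ...]


def quantize(image: FluenceMap | np.ndarray, n_levels: int = DEFAULT_N_LEVELS) -> np.ndarray:
    """Linear binning of [min, max] into ``n_levels`` integer labels.

    A constant image maps to level 0 everywhere. Invariant under positive
    affine rescaling of the intensities.
    """
    if n_levels < 2:
        raise ConfigurationError("n_levels must be >= 2")
    arr = image.grid if isinstance(image, FluenceMap) else np.asarray(image, dtype=float)
    vmin, vmax = float(arr.min()), float(arr.max())
    if vmax <= vmin:
        return np.zeros(arr.shape, dtype=np.int64)
    labels = np.floor((arr - vmin) / (vmax - vmin) * n_levels).astype(np.int64)
    return np.minimum(labels, n_levels - 1)


def glcm(
    labels: np.ndarray,
    offset: tuple[int, int],
    symmetric: bool = True,
    n_levels: int | None = None,
) -> Glcm:
    """Count label pairs co-occurring at ``offset`` (both orders if
    symmetric) and normalize to probabilities."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValidationError("labels must be a 2-D integer matrix")
    k = int(n_levels) if n_levels is not None else int(labels.max()) + 1
    if labels.min() < 0 or labels.max() >= k:
        raise ValidationError(f"labels must lie in 0..{k - 1}")
    dr, dc = offset
    nr, nc = labels.shape
    if abs(dr) >= nr or abs(dc) >= nc:
        raise ValidationError(f"image {labels.shape} smaller than offset {offset}")

    r0, r1 = max(dr, 0), nr + min(dr, 0)
    c0, c1 = max(dc, 0), nc + min(dc, 0)
    i = labels[r0 - dr : r1 - dr, c0 - dc : c1 - dc].ravel()
    j = labels[r0:r1, c0:c1].ravel()
    counts = np.bincount(i * k + j, minlength=k * k).reshape(k, k).astype(float)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValidationError("no co-occurring pairs at this offset")
    return Glcm(
        matrix=counts / total,
        n_levels=k,
        offset=(dr, dc),
        symmetric=symmetric,
        image_mean=float(labels.mean()),
        image_variance=float(labels.var()),
    )


def _features_single(g: Glcm) -> dict[str, float]:
    p = g.matrix
    k = g.n_levels
    i = np.arange(k, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff2 = (ii - jj) ** 2
    contrast = float((p * diff2).sum())
    energy = float((p * p).sum())
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    homogeneity = float((p / (1.0 + diff2)).sum())

    if g.image_variance > 0:
        corr_paper = float(
            ((ii - g.image_mean) * (jj - g.image_mean) * p**2).sum() / g.image_variance
        )
    else:
        corr_paper = 0.0

    pi, pj = p.sum(axis=1), p.sum(axis=0)
    mi, mj = float(pi @ i), float(pj @ i)
    si = float(np.sqrt(pi @ (i - mi) ** 2))
    sj = float(np.sqrt(pj @ (i - mj) ** 2))
    if si > 0 and sj > 0:
        corr_std = float(((ii - mi) * (jj - mj) * p).sum() / (si * sj))
    else:
        corr_std = 0.0
    return {
        "contrast": contrast,
        "energy": energy,
        "entropy": entropy,
        "homogeneity": homogeneity,
        "correlation_paper": corr_paper,
        "correlation_standard": corr_std,
    }


def texture_features(glcms: list[Glcm], correlation_mode: str = "paper") -> SpatialFeatures:
    """Texture features averaged over a set of GLCMs (canonically the four
    d = 1 directions)."""
    if not glcms:
        raise ValidationError("texture_features requires at least one GLCM")
    k = glcms[0].n_levels
    if any(g.n_levels != k for g in glcms):
        raise ValidationError("all GLCMs must share n_levels")
    if correlation_mode not in ("paper", "standard"):
        raise ConfigurationError("correlation_mode must be 'paper' or 'standard'")
    per = [_features_single(g) for g in glcms]
    mean = {key: float(np.mean([f[key] for f in per])) for key in per[0]}
    return SpatialFeatures(
        contrast=mean["contrast"],
        energy=mean["energy"],
        entropy=mean["entropy"],
        homogeneity=mean["homogeneity"],
        correlation_paper=mean["correlation_paper"],
        correlation_standard=mean["correlation_standard"],
        correlation_mode=correlation_mode,
        n_levels=k,
    )


def spatial_features(
    fluence: FluenceMap | np.ndarray,
    n_levels: int = DEFAULT_N_LEVELS,
    symmetric: bool = True,
    correlation_mode: str = "paper",
) -> SpatialFeatures:
    """Quantize a fluence map and compute the direction-averaged features."""
    labels = quantize(fluence, n_levels)
    glcms = [glcm(labels, off, symmetric, n_levels) for off in OFFSETS.values()]
    return texture_features(glcms, correlation_mode)


# ---------------------------------------------------------------------------
# temporal variability


def dice_pair(a: ApertureMask, b: ApertureMask) -> float:
    """Dice overlap 2|a∩b| / (|a|+|b|) of two masks on the same grid.
    Two empty masks score 1 (no shape change)."""
    if a.grid.shape != b.grid.shape or a.pixel_pitch != b.pixel_pitch:
        raise ValidationError("masks must share grid shape and pixel pitch")
    if not np.allclose(a.origin, b.origin):
        raise ValidationError("masks must share the grid origin")
    na = int(a.grid.sum())
    nb = int(b.grid.sum())
    if na + nb == 0:
        return 1.0
    overlap = int((a.grid & b.grid).sum())
    return 2.0 * overlap / (na + nb)


def dice_field(beam: Beam, geometry: MlcGeometry, pixel_pitch: float = 0.25) -> TemporalFeature:
    """Mean Dice of adjacent CP apertures, rasterized on the beam's common
    grid. Order-sensitive by construction."""
    validate_beam(beam, geometry)
    origin, shape = beam_grid(beam, geometry, pixel_pitch)
    masks = [
        rasterize_aperture(cp, geometry, pixel_pitch, origin, shape)
        for cp in beam.control_points
    ]
    pairs = tuple(dice_pair(m1, m2) for m1, m2 in zip(masks, masks[1:]))
    return TemporalFeature(dice=float(np.mean(pairs)), per_pair_dice=pairs)


def dice_pair_analytic(cp1, cp2, geometry: MlcGeometry) -> float:
    """Raster-free Dice from per-leaf interval overlap (jaws ignored); serves
    as an independent cross-check of the rasterized value."""
    widths = np.asarray(geometry.widths)
    open1 = np.maximum(cp1.bank_a - cp1.bank_b, 0.0)
    open2 = np.maximum(cp2.bank_a - cp2.bank_b, 0.0)
    a1 = float((open1 * widths).sum())
    a2 = float((open2 * widths).sum())
    lo = np.maximum(cp1.bank_b, cp2.bank_b)
    hi = np.minimum(cp1.bank_a, cp2.bank_a)
    inter = float((np.maximum(hi - lo, 0.0) * widths).sum())
    if a1 + a2 == 0:
        return 1.0
    return 2.0 * inter / (a1 + a2)


def field_features(
    beam: Beam,
    geometry: MlcGeometry,
    pixel_pitch: float = 0.25,
    n_levels: int = DEFAULT_N_LEVELS,
    edge_weight: float = 2.0,
    correlation_mode: str = "paper",
) -> dict[str, float]:
    """All per-field features in one pass: the five texture statistics of the
    edge-enhanced integrated fluence plus the field Dice. Masks are
    rasterized once and shared between the fluence sum and the Dice chain."""
    validate_beam(beam, geometry)
    origin, shape = beam_grid(beam, geometry, pixel_pitch)
    masks = [
        rasterize_aperture(cp, geometry, pixel_pitch, origin, shape)
        for cp in beam.control_points
    ]
    weights = np.asarray([cp.cumulative_meterset_weight for cp in beam.control_points])
    dmu = np.concatenate([[0.0], np.diff(weights)]) * beam.beam_mu

    grid = np.zeros(shape, dtype=float)
    for mask, mu in zip(masks, dmu):
        if mu == 0.0:
            continue
        w = mask.grid.astype(float)
        if edge_weight != 1.0:
            w[edge_pixels(mask)] *= edge_weight
        grid += mu * w
    fluence = FluenceMap(grid, pixel_pitch, beam.beam_mu, beam.collimator_angle, origin, edge_weight)

    spatial = spatial_features(fluence, n_levels, correlation_mode=correlation_mode)
    pairs = tuple(dice_pair(m1, m2) for m1, m2 in zip(masks, masks[1:]))
    return {
        "contrast": spatial.contrast,
        "correlation": spatial.correlation,
        "correlation_standard": spatial.correlation_standard,
        "energy": spatial.energy,
        "entropy": spatial.entropy,
        "homogeneity": spatial.homogeneity,
        "dice": float(np.mean(pairs)),
    }
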