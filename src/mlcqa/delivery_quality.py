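"""Gamma passing rate between 2D dose planes, and the deviation-quality
correlation analysis.

The gamma index combines a dose-difference criterion (percent of the global
reference maximum) with a distance-to-agreement (DTA, mm): for a reference
point r,

    gamma(r) = min over r' of sqrt(|r - r'|^2 / dta^2
                                   + (D_eval(r') - D_ref(r))^2 / dd^2)

with dd = dose_pct/100 * max(D_ref) (global normalization). Points below the
low-dose threshold (default 10% of the global maximum, TG-218 convention)
are excluded; the passing rate is the percentage of evaluated points with
gamma <= 1. The search covers a disk of radius 3*dta sampled at pitch/3
steps with bilinear interpolation on the evaluated plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import ConfigurationError, FormatError, ValidationError
from .stats_model import spearman_screen


@dataclass
class DosePlane:
    """2D dose grid in cGy; ``origin`` is the (x, y) mm coordinate of pixel
    [0, 0]'s center, rows along +y, columns along +x."""

    grid: np.ndarray
    pixel_pitch: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValidationError("dose grid must be 2-D")
        if self.pixel_pitch <= 0:
            raise ValidationError("pixel pitch must be positive")
        if np.any(self.grid < 0):
            raise ValidationError("doses must be non-negative")

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.grid.shape
        x = self.origin[0] + self.pixel_pitch * np.arange(nx)
        y = self.origin[1] + self.pixel_pitch * np.arange(ny)
        return x, y


@dataclass(frozen=True)
class GammaResult:
    pass_rate: float  # % of evaluated points with gamma <= 1
    dose_criterion_pct: float
    dta_mm: float
    low_dose_threshold_pct: float
    n_evaluated: int
    n_total: int
    mean_gamma: float


def write_dose_plane(plane: DosePlane, dest) -> None:
    lines = [
        "#doseplane,1",
        f"#pitch_mm,{plane.pixel_pitch:g}",
        f"#origin_mm,{plane.origin[0]:g},{plane.origin[1]:g}",
    ]
    for row in plane.grid:
        lines.append(",".join(f"{v:.4f}" for v in row))
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def read_dose_plane(source) -> DosePlane:
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    lines = [ln.strip() for ln in lines if ln.strip()]
    header: dict[str, list[str]] = {}
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        parts = lines[i][1:].split(",")
        header[parts[0]] = parts[1:]
        i += 1
    if "pitch_mm" not in header:
        raise FormatError("dose plane file missing '#pitch_mm' header")
    origin = (0.0, 0.0)
    if "origin_mm" in header:
        origin = (float(header["origin_mm"][0]), float(header["origin_mm"][1]))
    rows = [[float(v) for v in ln.split(",")] for ln in lines[i:]]
    if not rows:
        raise FormatError("dose plane file contains no data rows")
    return DosePlane(np.asarray(rows), float(header["pitch_mm"][0]), origin)


def _interpolator(plane: DosePlane) -> RegularGridInterpolator:
    x, y = plane.axes()
    return RegularGridInterpolator(
        (y, x), plane.grid, method="linear", bounds_error=False, fill_value=np.nan
    )


def resample_to(plane: DosePlane, reference: DosePlane) -> DosePlane:
    """Bilinear resampling of ``plane`` onto the reference grid."""
    interp = _interpolator(plane)
    x, y = reference.axes()
    xx, yy = np.meshgrid(x, y)
    values = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(reference.grid.shape)
    values = np.nan_to_num(values, nan=0.0)
    return DosePlane(np.maximum(values, 0.0), reference.pixel_pitch, reference.origin)


def detector_array_sample(plane: DosePlane, spacing_mm: float = 7.62) -> DosePlane:
    """Optional resampling onto a detector-array grid (default 7.62 mm
    spacing, mimicking a 32x32 ion-chamber array over a 24.4 cm plane)."""
    x, y = plane.axes()
    xs = np.arange(x[0], x[-1] + 1e-9, spacing_mm)
    ys = np.arange(y[0], y[-1] + 1e-9, spacing_mm)
    interp = _interpolator(plane)
    xx, yy = np.meshgrid(xs, ys)
    vals = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(len(ys), len(xs))
    return DosePlane(np.nan_to_num(vals, nan=0.0), spacing_mm, (float(xs[0]), float(ys[0])))


def gamma_pass_rate(
    reference: DosePlane,
    evaluated: DosePlane,
    dose_pct: float = 3.0,
    dta_mm: float = 2.0,
    low_dose_pct: float = 10.0,
    search_radius_factor: float = 3.0,
) -> GammaResult:
    """Global-normalized 2D gamma passing rate of ``evaluated`` against
    ``reference``. Planes on different pitches are commensurated by bilinear
    resampling of the evaluated plane."""
    if dose_pct <= 0 or dta_mm <= 0:
        raise ConfigurationError("dose_pct and dta_mm must be positive")
    if search_radius_factor < 1.0:
        raise ConfigurationError("search radius must be at least one DTA")
    dmax = float(reference.grid.max())
    if dmax <= 0:
        raise ValidationError("reference plane has zero maximum dose")
    if evaluated.pixel_pitch != reference.pixel_pitch or evaluated.grid.shape != reference.grid.shape:
        evaluated = resample_to(evaluated, reference)

    dd = dose_pct / 100.0 * dmax
    radius = search_radius_factor * dta_mm
    step = reference.pixel_pitch / 3.0
    n_steps = int(np.floor(radius / step))
    offs = step * np.arange(-n_steps, n_steps + 1)
    ox, oy = np.meshgrid(offs, offs)
    keep = ox**2 + oy**2 <= radius**2 + 1e-12
    offsets = np.stack([ox[keep], oy[keep]], axis=1)

    x, y = reference.axes()
    xx, yy = np.meshgrid(x, y)
    interp = _interpolator(evaluated)
    ref = reference.grid
    gamma2 = np.full(ref.shape, np.inf)
    for dx, dy in offsets:
        shifted = interp(np.stack([(yy + dy).ravel(), (xx + dx).ravel()], axis=1)).reshape(ref.shape)
        term = (shifted - ref) ** 2 / dd**2 + (dx**2 + dy**2) / dta_mm**2
        term = np.where(np.isnan(term), np.inf, term)
        np.minimum(gamma2, term, out=gamma2)

    evaluated_mask = ref >= low_dose_pct / 100.0 * dmax
    n_eval = int(evaluated_mask.sum())
    if n_eval == 0:
        raise ValidationError("low-dose threshold excludes every point")
    g2 = gamma2[evaluated_mask]
    passed = g2 <= 1.0 + 1e-9
    return GammaResult(
        pass_rate=100.0 * float(passed.mean()),
        dose_criterion_pct=dose_pct,
        dta_mm=dta_mm,
        low_dose_threshold_pct=low_dose_pct,
        n_evaluated=n_eval,
        n_total=int(ref.size),
        mean_gamma=float(np.sqrt(g2[np.isfinite(g2)]).mean()),
    )


def quality_correlation(
    treatment_deviations,
    metrics: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman r and p of each delivery-quality metric column (gamma pass
    rates, dose deviations, ...) against the per-treatment MLC deviation."""
    dev = np.asarray(treatment_deviations, dtype=float)
    if len(dev) != len(metrics):
        raise ValidationError(
            f"{len(dev)} deviations vs {len(metrics)} metric rows: length mismatch"
        )
    table = metrics.copy()
    table["deviation_mm"] = dev
    return spearman_screen(table, factors=list(metrics.columns), response="deviation_mm")
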