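"""VMAT plan control points and the edge-enhanced integrated fluence.

A VMAT beam is a sequence of control points (CPs): MLC aperture, jaw
positions and a non-decreasing cumulative meterset weight. The monitor units
delivered in CP i are ``beam_mu * (w_i - w_{i-1})``. The integrated fluence
of a beam is the sum over CPs of the delivered-MU-weighted aperture mask,
with boundary pixels of each mask counted twice ("edge enhancement") so that
a stack of small apertures does not masquerade as one large one.

Rasterization happens in collimator-fixed (MLC) coordinates: x is the leaf
travel axis, y the leaf stacking axis. The collimator angle is carried as
metadata, not resampled, because the texture features downstream are
computed over a rotation-covariant direction set.

Plans are read either from DICOM-RT Plan files (via pydicom) or from an
equivalent JSON dialect that mirrors the Beam -> ControlPoint structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, FormatError, ValidationError
from .geometry import MlcGeometry

PLAN_FORMAT = "mlcqa-plan"


@dataclass
class ControlPoint:
    """One aperture snapshot. Leaf-tip positions are mm at isocenter; for an
    open pair ``bank_b <= bank_a`` and the open interval is (b, a)."""

    index: int
    bank_a: np.ndarray
    bank_b: np.ndarray
    cumulative_meterset_weight: float
    jaw_x1: float = -200.0
    jaw_x2: float = 200.0
    jaw_y1: float = -200.0
    jaw_y2: float = 200.0
    gantry_angle: float = 0.0
    collimator_angle: float = 0.0

    def __post_init__(self) -> None:
        self.bank_a = np.asarray(self.bank_a, dtype=float)
        self.bank_b = np.asarray(self.bank_b, dtype=float)
        if self.bank_a.shape != self.bank_b.shape or self.bank_a.ndim != 1:
            raise ValidationError("bank A and B position vectors must be 1-D and equal length")
        if np.any(self.bank_b > self.bank_a + 1e-9):
            raise ValidationError(
                f"CP {self.index}: bank B tips must not exceed bank A tips"
            )

    @property
    def n_pairs(self) -> int:
        return self.bank_a.shape[0]


@dataclass
class Beam:
    beam_id: str
    beam_mu: float
    control_points: list[ControlPoint]
    collimator_angle: float = 0.0

    @property
    def n_cp(self) -> int:
        return len(self.control_points)


@dataclass
class ApertureMask:
    """Binary aperture raster. ``origin`` is the (x, y) mm coordinate of the
    center of pixel [0, 0]; rows advance along +y, columns along +x."""

    grid: np.ndarray
    pixel_pitch: float
    origin: tuple[float, float]

    @property
    def area_mm2(self) -> float:
        return float(self.grid.sum()) * self.pixel_pitch**2


@dataclass
class FluenceMap:
    """MU-weighted, optionally edge-enhanced integrated fluence."""

    grid: np.ndarray
    pixel_pitch: float
    beam_mu: float
    collimator_angle: float
    origin: tuple[float, float]
    edge_weight: float = 1.0


# ---------------------------------------------------------------------------
# plan I/O


def validate_beam(beam: Beam, geometry: MlcGeometry | None = None) -> None:
    if beam.n_cp < 2:
        raise ValidationError(f"beam {beam.beam_id}: needs >= 2 control points")
    weights = [cp.cumulative_meterset_weight for cp in beam.control_points]
    if any(b < a - 1e-12 for a, b in zip(weights, weights[1:])):
        raise ValidationError(
            f"beam {beam.beam_id}: cumulative meterset weight must be non-decreasing"
        )
    if geometry is not None:
        for cp in beam.control_points:
            if cp.n_pairs != geometry.n_pairs:
                raise ValidationError(
                    f"beam {beam.beam_id} CP {cp.index}: {cp.n_pairs} leaf pairs, "
                    f"geometry defines {geometry.n_pairs}"
                )


def cp_delivered_mu(beam: Beam) -> np.ndarray:
    """(n_cp,) monitor units delivered in each CP; the first entry is 0."""
    w = np.asarray([cp.cumulative_meterset_weight for cp in beam.control_points])
    return np.concatenate([[0.0], np.diff(w)]) * beam.beam_mu


def save_plan(beams: list[Beam], dest, plan_id: str = "plan") -> None:
    """Write the JSON plan dialect."""
    doc = {
        "format": PLAN_FORMAT,
        "version": 1,
        "plan_id": plan_id,
        "beams": [
            {
                "beam_id": b.beam_id,
                "beam_mu": b.beam_mu,
                "collimator_angle": b.collimator_angle,
                "control_points": [
                    {
                        "index": cp.index,
                        "cumulative_meterset_weight": cp.cumulative_meterset_weight,
                        "gantry_angle": cp.gantry_angle,
                        "collimator_angle": cp.collimator_angle,
                        "jaw_x1": cp.jaw_x1,
                        "jaw_x2": cp.jaw_x2,
                        "jaw_y1": cp.jaw_y1,
                        "jaw_y2": cp.jaw_y2,
                        "bank_a_positions": [round(float(v), 4) for v in cp.bank_a],
                        "bank_b_positions": [round(float(v), 4) for v in cp.bank_b],
                    }
                    for cp in b.control_points
                ],
            }
            for b in beams
        ],
    }
    text = json.dumps(doc, indent=1, sort_keys=True)
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def _load_json_plan(doc: dict, geometry: MlcGeometry | None) -> list[Beam]:
    if doc.get("format") != PLAN_FORMAT:
        raise FormatError(f"not a {PLAN_FORMAT} document")
    beams = []
    for b in doc["beams"]:
        cps = []
        for item in b["control_points"]:
            if "bank_a_positions" not in item or "bank_b_positions" not in item:
                raise FormatError(
                    f"beam {b.get('beam_id')}: control point missing leaf-position sequences"
                )
            cps.append(
                ControlPoint(
                    index=int(item["index"]),
                    bank_a=item["bank_a_positions"],
                    bank_b=item["bank_b_positions"],
                    cumulative_meterset_weight=float(item["cumulative_meterset_weight"]),
                    jaw_x1=float(item.get("jaw_x1", -200.0)),
                    jaw_x2=float(item.get("jaw_x2", 200.0)),
                    jaw_y1=float(item.get("jaw_y1", -200.0)),
                    jaw_y2=float(item.get("jaw_y2", 200.0)),
                    gantry_angle=float(item.get("gantry_angle", 0.0)),
                    collimator_angle=float(item.get("collimator_angle", 0.0)),
                )
            )
        beam = Beam(
            beam_id=str(b["beam_id"]),
            beam_mu=float(b["beam_mu"]),
            collimator_angle=float(b.get("collimator_angle", 0.0)),
            control_points=cps,
        )
        validate_beam(beam, geometry)
        beams.append(beam)
    if not beams:
        raise FormatError("plan contains no beams")
    return beams


def _load_dicom_plan(ds, geometry: MlcGeometry | None) -> list[Beam]:
    """Thin adapter for a standard RT Plan IOD (pydicom Dataset).

    Leaf positions for an MLCX device carry bank B (X1 side) in the first
    half and bank A (X2 side) in the second half; attributes absent from a
    control point are carried forward from the previous one.
    """
    mu_by_number = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(rb, "BeamMeterset"):
                mu_by_number[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    beams = []
    for beam_ds in ds.BeamSequence:
        mu = mu_by_number.get(int(getattr(beam_ds, "BeamNumber", -1)), 0.0)
        jaws = {"x1": -200.0, "x2": 200.0, "y1": -200.0, "y2": 200.0}
        mlc = None
        collimator = 0.0
        gantry = 0.0
        cps = []
        for k, cp_ds in enumerate(beam_ds.ControlPointSequence):
            gantry = float(getattr(cp_ds, "GantryAngle", gantry))
            collimator = float(getattr(cp_ds, "BeamLimitingDeviceAngle", collimator))
            for dev in getattr(cp_ds, "BeamLimitingDevicePositionSequence", []):
                kind = dev.RTBeamLimitingDeviceType
                pos = [float(v) for v in dev.LeafJawPositions]
                if kind in ("X", "ASYMX"):
                    jaws["x1"], jaws["x2"] = pos[0], pos[1]
                elif kind in ("Y", "ASYMY"):
                    jaws["y1"], jaws["y2"] = pos[0], pos[1]
                elif kind.startswith("MLC"):
                    mlc = pos
            if mlc is None:
                raise FormatError(
                    f"beam {beam_ds.BeamNumber} CP {k}: no MLC leaf-position sequence"
                )
            half = len(mlc) // 2
            cps.append(
                ControlPoint(
                    index=k,
                    bank_b=mlc[:half],
                    bank_a=mlc[half:],
                    cumulative_meterset_weight=float(cp_ds.CumulativeMetersetWeight),
                    jaw_x1=jaws["x1"],
                    jaw_x2=jaws["x2"],
                    jaw_y1=jaws["y1"],
                    jaw_y2=jaws["y2"],
                    gantry_angle=gantry,
                    collimator_angle=collimator,
                )
            )
        final_weight = float(getattr(beam_ds, "FinalCumulativeMetersetWeight", 1.0)) or 1.0
        for cp in cps:
            cp.cumulative_meterset_weight /= final_weight
        beam = Beam(
            beam_id=str(getattr(beam_ds, "BeamName", beam_ds.BeamNumber)),
            beam_mu=mu,
            collimator_angle=collimator,
            control_points=cps,
        )
        validate_beam(beam, geometry)
        beams.append(beam)
    return beams


def load_plan(source, geometry: MlcGeometry | None = None) -> list[Beam]:
    """Load a plan from the JSON dialect, a DICOM-RT Plan file, or an
    already-parsed pydicom Dataset. Returns the beams in delivery order."""
    if hasattr(source, "BeamSequence"):  # pydicom Dataset
        return _load_dicom_plan(source, geometry)
    path = Path(source)
    if path.suffix.lower() == ".dcm":
        import pydicom

        return _load_dicom_plan(pydicom.dcmread(str(path)), geometry)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: neither DICOM-RT nor valid JSON plan: {exc}") from exc
    return _load_json_plan(doc, geometry)


# ---------------------------------------------------------------------------
# rasterization


def _open_extent(cp: ControlPoint, geometry: MlcGeometry) -> tuple[float, float, float, float] | None:
    """Analytic bounding box (xmin, xmax, ymin, ymax) of the jaw-clipped open
    aperture, or None when fully closed."""
    edges = geometry.leaf_edges()
    open_pairs = cp.bank_a > cp.bank_b
    xmin = xmax = None
    ymin = ymax = None
    for i in np.nonzero(open_pairs)[0]:
        lo = max(float(cp.bank_b[i]), cp.jaw_x1)
        hi = min(float(cp.bank_a[i]), cp.jaw_x2)
        y0 = max(float(edges[i]), cp.jaw_y1)
        y1 = min(float(edges[i + 1]), cp.jaw_y2)
        if hi <= lo or y1 <= y0:
            continue
        xmin = lo if xmin is None else min(xmin, lo)
        xmax = hi if xmax is None else max(xmax, hi)
        ymin = y0 if ymin is None else min(ymin, y0)
        ymax = y1 if ymax is None else max(ymax, y1)
    if xmin is None:
        return None
    return xmin, xmax, ymin, ymax


def _grid_from_extent(extent, pixel_pitch: float, margin: int = 1):
    xmin, xmax, ymin, ymax = extent
    nx = int(np.ceil((xmax - xmin) / pixel_pitch - 1e-9)) + 2 * margin
    ny = int(np.ceil((ymax - ymin) / pixel_pitch - 1e-9)) + 2 * margin
    origin = (
        xmin + pixel_pitch / 2.0 - margin * pixel_pitch,
        ymin + pixel_pitch / 2.0 - margin * pixel_pitch,
    )
    return origin, (ny, nx)


def beam_grid(beam: Beam, geometry: MlcGeometry, pixel_pitch: float, margin: int = 1):
    """Common raster (origin, shape) covering every aperture of the beam —
    the bounding box of all jaw-clipped CP apertures plus a margin."""
    extents = [_open_extent(cp, geometry) for cp in beam.control_points]
    extents = [e for e in extents if e is not None]
    if not extents:
        return (0.0, 0.0), (1, 1)
    arr = np.asarray(extents)
    extent = (arr[:, 0].min(), arr[:, 1].max(), arr[:, 2].min(), arr[:, 3].max())
    return _grid_from_extent(extent, pixel_pitch, margin)


def rasterize_aperture(
    cp: ControlPoint,
    geometry: MlcGeometry,
    pixel_pitch: float,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
    apply_jaws: bool = True,
) -> ApertureMask:
    """Binary raster of one CP aperture.

    A pixel is open iff its center lies strictly between the two bank tips of
    its leaf row and (when ``apply_jaws``) inside the jaw rectangle. When no
    grid is given, a minimal grid covering this aperture is built.
    """
    if pixel_pitch <= 0:
        raise ConfigurationError("pixel_pitch must be positive")
    if pixel_pitch > geometry.min_width + 1e-12:
        raise ConfigurationError(
            f"pixel_pitch {pixel_pitch} mm exceeds the smallest leaf width "
            f"{geometry.min_width} mm: quarter leaves would vanish from the raster"
        )
    if cp.n_pairs != geometry.n_pairs:
        raise ValidationError("control point leaf count does not match geometry")
    if origin is None or shape is None:
        extent = _open_extent(cp, geometry)
        if extent is None:
            return ApertureMask(np.zeros((1, 1), dtype=bool), pixel_pitch, (0.0, 0.0))
        origin, shape = _grid_from_extent(extent, pixel_pitch)

    ny, nx = shape
    x = origin[0] + pixel_pitch * np.arange(nx)
    y = origin[1] + pixel_pitch * np.arange(ny)
    edges = geometry.leaf_edges()
    row_leaf = np.searchsorted(edges, y, side="right") - 1
    in_stack = (row_leaf >= 0) & (row_leaf < geometry.n_pairs) & (y < edges[-1])
    leaf = np.clip(row_leaf, 0, geometry.n_pairs - 1)

    lo = cp.bank_b[leaf][:, None]
    hi = cp.bank_a[leaf][:, None]
    grid = (x[None, :] > lo) & (x[None, :] < hi) & in_stack[:, None]
    if apply_jaws:
        grid &= (x[None, :] >= cp.jaw_x1) & (x[None, :] <= cp.jaw_x2)
        grid &= ((y >= cp.jaw_y1) & (y <= cp.jaw_y2))[:, None]
    return ApertureMask(grid, pixel_pitch, tuple(origin))


def edge_pixels(mask: ApertureMask | np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Boolean matrix of open pixels adjacent (4- or 8-connectivity) to at
    least one closed pixel or to the grid border."""
    g = mask.grid if isinstance(mask, ApertureMask) else np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ConfigurationError("connectivity must be 4 or 8")
    p = np.pad(g, 1, constant_values=False)
    interior = p[:-2, 1:-1] & p[2:, 1:-1] & p[1:-1, :-2] & p[1:-1, 2:]
    if connectivity == 8:
        interior &= p[:-2, :-2] & p[:-2, 2:] & p[2:, :-2] & p[2:, 2:]
    return g & ~interior


def integrate_fluence(
    beam: Beam,
    geometry: MlcGeometry,
    pixel_pitch: float = 0.25,
    edge_weight: float = 2.0,
    connectivity: int = 4,
    beam_mu: float | None = None,
) -> FluenceMap:
    """Integrated fluence: sum over CPs of delivered MU times the aperture
    mask, with each mask's boundary pixels multiplied by ``edge_weight``."""
    validate_beam(beam, geometry)
    if edge_weight < 1.0:
        raise ConfigurationError("edge_weight must be >= 1")
    mu_total = beam.beam_mu if beam_mu is None else beam_mu
    weights = np.asarray([cp.cumulative_meterset_weight for cp in beam.control_points])
    dmu = np.concatenate([[0.0], np.diff(weights)]) * mu_total

    origin, shape = beam_grid(beam, geometry, pixel_pitch)
    grid = np.zeros(shape, dtype=float)
    for cp, mu in zip(beam.control_points, dmu):
        if mu == 0.0:
            continue
        mask = rasterize_aperture(cp, geometry, pixel_pitch, origin, shape)
        w = mask.grid.astype(float)
        if edge_weight != 1.0:
            w[edge_pixels(mask, connectivity)] *= edge_weight
        grid += mu * w
    return FluenceMap(
        grid=grid,
        pixel_pitch=pixel_pitch,
        beam_mu=mu_total,
        collimator_angle=beam.collimator_angle,
        origin=origin,
        edge_weight=edge_weight,
    )
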