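"""Delivery-log ("dynalog") parsing and MLC positional-deviation statistics.

A dynalog records, every 0.05 s during delivery, the planned and actual tip
position of every leaf of one bank of one field. Real Varian logs are
proprietary; this module defines an equivalent plain-text CSV dialect::

    #dynalog,1
    #bank,A
    #field,t00_f1
    #unit_scale,0.01
    #n_leaves,60
    <extra "#key,value" metadata lines>
    time_s,p1,...,pN,a1,...,aN
    0.00,1050,...,...

Positions are stored as integer multiples of ``unit_scale`` mm (default
0.01 mm, i.e. centi-millimeters). A thin converter can map vendor logs onto
this dialect.

The positional deviation of a file is the mean over all samples and leaves of
|actual - planned|; deviations are analyzed as absolute values because leaves
reciprocate and signed errors would cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, ValidationError
from .geometry import BANKS, MlcGeometry

SAMPLE_INTERVAL_S = 0.05
DEFAULT_UNIT_SCALE = 0.01  # mm per stored unit
DEFAULT_THRESHOLD_MM = 1.0


@dataclass
class DynalogRecordSet:
    """Planned vs actual leaf positions for one bank of one field.

    ``planned`` and ``actual`` are (n_samples, n_leaves) arrays in mm at
    isocenter; ``sample_times`` are seconds, uniformly spaced.
    """

    bank: str
    field_id: str
    sample_times: np.ndarray
    planned: np.ndarray
    actual: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.planned = np.atleast_2d(np.asarray(self.planned, dtype=float))
        self.actual = np.atleast_2d(np.asarray(self.actual, dtype=float))
        if self.bank not in BANKS:
            raise ValidationError(f"bank must be one of {BANKS}, got {self.bank!r}")
        if self.planned.shape != self.actual.shape:
            raise ValidationError(
                f"planned {self.planned.shape} and actual {self.actual.shape} "
                "matrices must have identical shape"
            )
        if self.sample_times.shape[0] != self.planned.shape[0]:
            raise ValidationError("one timestamp per sample row required")
        if self.n_samples >= 2:
            dt = np.diff(self.sample_times)
            if np.any(dt <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], atol=1e-9):
                raise ValidationError("sample spacing must be constant")

    @property
    def n_samples(self) -> int:
        return self.planned.shape[0]

    @property
    def n_leaves(self) -> int:
        return self.planned.shape[1]


@dataclass(frozen=True)
class DeviationSummary:
    """Absolute-deviation statistics of one dynalog file."""

    mean_abs_dev: float
    max_abs_dev: float
    frac_above_threshold: float
    threshold: float
    n_samples: int
    n_leaves: int


def write_dynalog(records: DynalogRecordSet, dest, unit_scale: float = DEFAULT_UNIT_SCALE) -> None:
    """Serialize a record set into the CSV dialect (positions quantized to
    ``unit_scale`` mm)."""
    lines = [
        "#dynalog,1",
        f"#bank,{records.bank}",
        f"#field,{records.field_id}",
        f"#unit_scale,{unit_scale:g}",
        f"#n_leaves,{records.n_leaves}",
    ]
    for key in sorted(records.meta):
        lines.append(f"#{key},{records.meta[key]}")
    n = records.n_leaves
    header = ["time_s"] + [f"p{i+1}" for i in range(n)] + [f"a{i+1}" for i in range(n)]
    lines.append(",".join(header))
    stored = np.rint(
        np.concatenate([records.planned, records.actual], axis=1) / unit_scale
    ).astype(np.int64)
    for t, row in zip(records.sample_times, stored):
        lines.append(f"{t:.2f}," + ",".join(str(v) for v in row))
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def _read_lines(source) -> list[str]:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode()
        return data.splitlines()
    path = Path(source)
    return path.read_text().splitlines()


def parse_dynalog(
    source,
    geometry: MlcGeometry | None = None,
    unit_scale: float | None = None,
) -> DynalogRecordSet:
    """Parse the dynalog CSV dialect.

    ``unit_scale`` (mm per stored unit) overrides the value in the header;
    ``geometry``, if given, validates the leaf count.
    """
    lines = [ln.strip() for ln in _read_lines(source) if ln.strip()]
    header: dict[str, str] = {}
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        parts = lines[i][1:].split(",", 1)
        if len(parts) != 2 or not parts[0]:
            raise FormatError(f"malformed header line {i + 1}: {lines[i]!r}")
        header[parts[0].strip()] = parts[1].strip()
        i += 1
    for key in ("bank", "field", "n_leaves"):
        if key not in header:
            raise FormatError(f"missing required header '#{key}'")
    if i >= len(lines) or not lines[i].startswith("time_s"):
        raise FormatError("missing column header row starting with 'time_s'")
    i += 1

    n_leaves = int(header["n_leaves"])
    if geometry is not None and n_leaves != geometry.n_pairs:
        raise ValidationError(
            f"file has {n_leaves} leaves but geometry defines {geometry.n_pairs} pairs"
        )
    scale = unit_scale if unit_scale is not None else float(header.get("unit_scale", DEFAULT_UNIT_SCALE))

    expected_cols = 1 + 2 * n_leaves
    times, values = [], []
    for row_index, line in enumerate(lines[i:]):
        cols = line.split(",")
        if len(cols) != expected_cols:
            raise FormatError(
                f"data row {row_index}: expected {expected_cols} columns, got {len(cols)}"
            )
        times.append(float(cols[0]))
        values.append([float(v) for v in cols[1:]])
    if not times:
        raise FormatError("dynalog contains no sample rows")

    arr = np.asarray(values, dtype=float) * scale
    meta = {
        k: v
        for k, v in header.items()
        if k not in {"dynalog", "bank", "field", "unit_scale", "n_leaves"}
    }
    return DynalogRecordSet(
        bank=header["bank"],
        field_id=header["field"],
        sample_times=np.asarray(times),
        planned=arr[:, :n_leaves],
        actual=arr[:, n_leaves:],
        meta=meta,
    )


def deviation_summary(
    records: DynalogRecordSet, threshold: float = DEFAULT_THRESHOLD_MM
) -> DeviationSummary:
    """Absolute positional deviation pooled over all samples and leaves."""
    if records.n_samples == 0 or records.n_leaves == 0:
        raise ValidationError("cannot summarize an empty record set")
    dev = np.abs(records.actual - records.planned)
    return DeviationSummary(
        mean_abs_dev=float(dev.mean()),
        max_abs_dev=float(dev.max()),
        frac_above_threshold=float((dev > threshold).mean()),
        threshold=float(threshold),
        n_samples=records.n_samples,
        n_leaves=records.n_leaves,
    )


def signed_deviation_stats(records: DynalogRecordSet) -> tuple[float, float]:
    """(mean, max magnitude) of the signed deviation actual - planned. Not the
    default statistic — signed errors cancel under leaf reciprocation."""
    dev = records.actual - records.planned
    return float(dev.mean()), float(np.abs(dev).max())


def treatment_deviation(summaries: Sequence[DeviationSummary] | Iterable[DeviationSummary]) -> float:
    """Treatment-level deviation: unweighted mean of per-file mean absolute
    deviations (canonically 2 fields x 2 banks = 4 files)."""
    values = [s.mean_abs_dev for s in summaries]
    if not values:
        raise ValidationError("treatment_deviation requires at least one summary")
    return float(np.mean(values))
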