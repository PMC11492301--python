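"""MLC self-check ("init"-style) wear records.

Each daily self-check writes, per leaf of one bank, seven mechanical
parameters: maximum error (ME, mm), backlash (BL, mm), measured spring
compression (MSC, device units; some sources abbreviate it SC), pulse width
modulation (PWM, device units), leaf gap (LG, mm), leaf odometer (LO) and
carriage odometer (CO, distance units). Units of the device-internal
quantities are arbitrary; only ranks and ratios are used downstream.

The documented CSV dialect::

    #init,1
    #date,2020-07-01
    #bank,A
    leaf,ME,BL,MSC,PWM,LG,LO,CO
    1,0.12,...

Bank summaries average each parameter over leaves; session series are
normalized to the first session's value per parameter so drifts (and repair
resets, which appear as mutation points) are comparable across parameters.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError
from .geometry import BANKS, MlcGeometry

WEAR_PARAMS = ("ME", "BL", "MSC", "PWM", "LG", "LO", "CO")
_ALIASES = {"SC": "MSC"}


@dataclass
class WearRecord:
    """Per-leaf self-check parameters for one bank on one session date."""

    session_date: _dt.date
    bank: str
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bank not in BANKS:
            raise ValidationError(f"bank must be one of {BANKS}")
        missing = [p for p in WEAR_PARAMS if p not in self.values]
        if missing:
            raise FormatError(f"missing wear parameter(s): {', '.join(missing)}")
        self.values = {p: np.asarray(self.values[p], dtype=float) for p in WEAR_PARAMS}
        lengths = {v.shape[0] for v in self.values.values()}
        if len(lengths) != 1:
            raise ValidationError("all per-leaf parameter vectors must have equal length")

    @property
    def n_leaves(self) -> int:
        return self.values["ME"].shape[0]


@dataclass
class BankWearSummary:
    """Leaf-averaged wear parameters for one (session, bank); ``normalized``
    is filled by :func:`normalize_series` (ratio to the first session)."""

    session_date: _dt.date
    bank: str
    values: dict[str, float]
    normalized: dict[str, float] | None = None


def write_init(record: WearRecord, dest) -> None:
    lines = [
        "#init,1",
        f"#date,{record.session_date.isoformat()}",
        f"#bank,{record.bank}",
        "leaf," + ",".join(WEAR_PARAMS),
    ]
    for i in range(record.n_leaves):
        row = [str(i + 1)] + [f"{record.values[p][i]:.6g}" for p in WEAR_PARAMS]
        lines.append(",".join(row))
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def parse_init(source, geometry: MlcGeometry | None = None) -> WearRecord:
    """Parse the init CSV dialect; leaf count is validated against
    ``geometry`` when given."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    lines = [ln.strip() for ln in lines if ln.strip()]

    header: dict[str, str] = {}
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        parts = lines[i][1:].split(",", 1)
        if len(parts) != 2:
            raise FormatError(f"malformed header line {i + 1}: {lines[i]!r}")
        header[parts[0].strip()] = parts[1].strip()
        i += 1
    for key in ("date", "bank"):
        if key not in header:
            raise FormatError(f"missing required header '#{key}'")

    if i >= len(lines):
        raise FormatError("missing column header row")
    cols = [_ALIASES.get(c.strip(), c.strip()) for c in lines[i].split(",")]
    if cols[0] != "leaf":
        raise FormatError("column header must start with 'leaf'")
    missing = [p for p in WEAR_PARAMS if p not in cols]
    if missing:
        raise FormatError(f"missing wear parameter column(s): {', '.join(missing)}")
    idx = {p: cols.index(p) for p in WEAR_PARAMS}
    i += 1

    rows = []
    for line in lines[i:]:
        parts = line.split(",")
        if len(parts) != len(cols):
            raise FormatError(f"row {len(rows)}: expected {len(cols)} columns")
        rows.append([float(v) for v in parts])
    if not rows:
        raise FormatError("init file contains no leaf rows")
    arr = np.asarray(rows)
    record = WearRecord(
        session_date=_dt.date.fromisoformat(header["date"]),
        bank=header["bank"],
        values={p: arr[:, idx[p]] for p in WEAR_PARAMS},
    )
    if geometry is not None and record.n_leaves != geometry.n_pairs:
        raise ValidationError(
            f"init file has {record.n_leaves} leaves, geometry defines {geometry.n_pairs}"
        )
    return record


def bank_summary(record: WearRecord) -> BankWearSummary:
    """Reduce each parameter to its mean over leaves (permutation-invariant)."""
    return BankWearSummary(
        session_date=record.session_date,
        bank=record.bank,
        values={p: float(record.values[p].mean()) for p in WEAR_PARAMS},
    )


def normalize_series(summaries: list[BankWearSummary]) -> list[BankWearSummary]:
    """Fill ``normalized`` as the ratio to the first session's value.

    The list must be date-ordered and single-bank. A zero first-session
    value leaves that parameter's normalized series undefined (NaN) rather
    than fabricating one. Repair resets pass through as mutation points.
    """
    if not summaries:
        raise ValidationError("normalize_series requires at least one summary")
    banks = {s.bank for s in summaries}
    if len(banks) != 1:
        raise ValidationError("normalize_series expects a single bank")
    dates = [s.session_date for s in summaries]
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ValidationError("summaries must be ordered by date")
    base = summaries[0].values
    out = []
    for s in summaries:
        normalized = {
            p: (s.values[p] / base[p]) if base[p] != 0 else float("nan")
            for p in WEAR_PARAMS
        }
        out.append(
            BankWearSummary(
                session_date=s.session_date,
                bank=s.bank,
                values=dict(s.values),
                normalized=normalized,
            )
        )
    return out
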