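"""MLC bank geometry.

Leaf pairs are indexed bottom-to-top along the leaf-stacking axis (y); each
pair projects a strip of its leaf width onto the isocenter plane. Leaf-tip
coordinates run along the travel axis (x), with bank B tips on the negative
side and bank A tips on the positive side of an open pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

BANKS = ("A", "B")


@dataclass(frozen=True)
class MlcGeometry:
    """Projected leaf widths (mm at isocenter) and travel limits of one bank.

    Parameters
    ----------
    widths
        Ordered projected leaf widths, one entry per leaf pair.
    travel_min, travel_max
        Admissible leaf-tip coordinates along the travel axis, mm.
    """

    widths: tuple[float, ...]
    travel_min: float = -200.0
    travel_max: float = 200.0

    def __post_init__(self) -> None:
        if len(self.widths) == 0:
            raise ValidationError("geometry needs at least one leaf pair")
        if any(w <= 0 for w in self.widths):
            raise ValidationError("leaf widths must be strictly positive")
        if self.travel_max <= self.travel_min:
            raise ValidationError("travel_max must exceed travel_min")

    @property
    def n_pairs(self) -> int:
        return len(self.widths)

    @property
    def total_height(self) -> float:
        """Field height covered by the leaf stack, mm."""
        return float(sum(self.widths))

    @property
    def min_width(self) -> float:
        return float(min(self.widths))

    def leaf_edges(self) -> np.ndarray:
        """(n_pairs + 1,) y-coordinates of leaf-strip boundaries, centered on 0."""
        edges = np.concatenate([[0.0], np.cumsum(self.widths)])
        return edges - self.total_height / 2.0


def hd120() -> MlcGeometry:
    """HD120-style bank: 32 central quarter leaves (2.5 mm) flanked by 28 half
    leaves (5 mm projected width), 60 pairs total."""
    widths = (5.0,) * 14 + (2.5,) * 32 + (5.0,) * 14
    return MlcGeometry(widths=widths)
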