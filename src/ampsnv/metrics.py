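"""Confusion counting and the standard benchmark measures.

TPR = TP/(TP+FN), PPV = TP/(TP+FP), FDR = 1-PPV and
F1 = 2*TP/(2*TP+FP+FN). Measures with an empty denominator are None
("undefined") rather than an error. Integer-percent renderings round half
up; the fractional values are always retained because published tables
sometimes truncate instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Performance:
    """The four measures as fractions in [0, 1]; None marks an undefined value."""

    tpr: float | None
    ppv: float | None
    fdr: float | None
    f1: float | None

    def percent(self, name: str) -> int | None:
        """Integer percent, rounded half up; None stays None."""
        value = getattr(self, name)
        if value is None:
            return None
        return int(math.floor(100.0 * value + 0.5))


def confusion(
    calls: Iterable[Hashable], truth: Iterable[Hashable]
) -> ConfusionCounts:
    """TP/FP/FN from set arithmetic on call and truth identifiers."""
    calls, truth = set(calls), set(truth)
    return ConfusionCounts(
        tp=len(calls & truth), fp=len(calls - truth), fn=len(truth - calls)
    )


def performance(c: ConfusionCounts) -> Performance:
    tpr = c.tp / (c.tp + c.fn) if c.tp + c.fn else None
    ppv = c.tp / (c.tp + c.fp) if c.tp + c.fp else None
    fdr = 1.0 - ppv if ppv is not None else None
    denom = 2 * c.tp + c.fp + c.fn
    f1 = 2 * c.tp / denom if denom else None
    return Performance(tpr=tpr, ppv=ppv, fdr=fdr, f1=f1)
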