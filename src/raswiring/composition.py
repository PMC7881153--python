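"""Tissue composition from marker-protein expression.

Each of six basic tissue types (epithelial, muscle, adipose, neuronal,
connective, lymphoid) is described by a small set of marker proteins.  Per
subtype, the three markers with the highest mean expression across all
tissues are selected; a tissue's subtype score is the mean expression of
those three markers, and scores are normalized to percentages per tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

TISSUE_SUBTYPES = ("epithelial", "muscle", "adipose", "neuronal", "connective", "lymphoid")


def default_marker_sets() -> list["MarkerSet"]:
    """The shipped marker fixture (data/markers.csv), editable by users.

    The lymphoid trio (PTPRC, CD68, CD19) is a fixed reference set; the
    other subtypes carry widely used markers from vendor catalogs.
    """
    from . import io as rio
    path = Path(__file__).resolve().parent / "data" / "markers.csv"
    return rio.read_marker_sets(path)


@dataclass(frozen=True)
class MarkerSet:
    subtype: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError(f"{self.subtype}: marker set must be non-empty")


def select_top_markers(expression: pd.DataFrame, marker_set: MarkerSet,
                       n_top: int = 3, statistic: str = "mean") -> list[str]:
    """The `n_top` markers with highest mean (or max) expression across tissues.

    Ties are broken by marker name so selection is order-independent.
    """
    present = [m for m in marker_set.markers if m in expression.columns]
    if len(present) < n_top:
        raise ValueError(
            f"subtype {marker_set.subtype}: only {len(present)} of its markers "
            f"are in the expression table (need {n_top})")
    agg = expression[present].agg(statistic, axis=0)
    ranked = sorted(present, key=lambda m: (-agg[m], m))
    return ranked[:n_top]


def estimate_fractions(expression: pd.DataFrame,
                       marker_sets: Sequence[MarkerSet],
                       n_top: int = 3,
                       statistic: str = "mean") -> pd.DataFrame:
    """Tissue x subtype percentage table (rows sum to 100).

    `expression` is tissues (rows) x proteins (columns), any non-negative
    expression unit; results are invariant to a global rescaling.
    """
    seen = set()
    for ms in marker_sets:
        if ms.subtype in seen:
            raise ValueError(f"duplicate subtype: {ms.subtype}")
        seen.add(ms.subtype)
    scores = pd.DataFrame(index=expression.index)
    for ms in marker_sets:
        top = select_top_markers(expression, ms, n_top=n_top, statistic=statistic)
        scores[ms.subtype] = expression[top].mean(axis=1)
    totals = scores.sum(axis=1)
    if (totals == 0).any():
        bad = totals[totals == 0].index[0]
        raise ValueError(f"tissue {bad!r}: all subtype scores are zero")
    return scores.div(totals, axis=0) * 100.0
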