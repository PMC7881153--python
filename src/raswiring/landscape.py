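"""Determinants of complex formation: affinity vs abundance.

For effectors sharing one Kd in a solved tissue, the complex share is exactly
linear in total abundance and passes through the origin:

    C%_i = 100 * R* * E_iT / ((Kd + R*) * C_tot)

so the slope 100·R*/((Kd+R*)·C_tot) is an analytic function of the solved
state.  Fitted lines per shared-Kd group (ordinary least squares) and per
singleton (two-point through-origin) recover this slope and expose how
steeply each tissue converts effector abundance into complex share at each
affinity.  Smaller Kd gives a larger slope; low-affinity effectors
(Kd > 1 µM) stay on shallow lines regardless of abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import EffectorDef, EquilibriumState, SIGNIFICANT_COMPLEX_PCT, rank_entities

logger = logging.getLogger(__name__)

#: complex shares below this are treated as "effector effectively absent"
#: and produce no through-origin fit
MIN_FIT_PCT = 0.001

#: reporting bins for affinity ranges, µM
KD_BINS_UM = ((0.04, 0.09), (0.21, 1.0), (2.9, 50.0))


def group_by_kd(panel: Sequence[EffectorDef]) -> dict[float, list[str]]:
    """Group effectors by exact Kd value (µM).  Singleton groups have length 1."""
    groups: dict[float, list[str]] = {}
    for e in panel:
        groups.setdefault(e.kd_um, []).append(e.name)
    return {kd: sorted(names) for kd, names in sorted(groups.items())}


@dataclass(frozen=True)
class SlopeFit:
    tissue: str
    kd_um: float
    slope: float          # percent per nM
    intercept: float      # 0 for through-origin fits
    n_points: int
    through_origin: bool


def fit_abundance_complex_lines(state: EquilibriumState,
                                groups: Mapping[float, list[str]],
                                tissue: str = "",
                                min_fit_pct: float = MIN_FIT_PCT) -> list[SlopeFit]:
    """Fit C% vs E_iT per shared-Kd group on one solved tissue.

    Multi-effector groups get an ordinary least-squares line; singletons get
    the line through the origin and their single point, skipped when the
    complex share is below `min_fit_pct` (an absent effector forms no
    complex, so its line is not informative).
    """
    fits = []
    for kd, names in groups.items():
        pts = [(state.effector_total(n), state.complexes_pct.get(n, 0.0)) for n in names]
        if len(pts) == 1:
            e_tot, pct = pts[0]
            if pct < min_fit_pct or e_tot == 0:
                logger.info("%s: skipping singleton at Kd=%g µM (share %.2g%%)",
                            tissue, kd, pct)
                continue
            fits.append(SlopeFit(tissue, kd, pct / e_tot, 0.0, 1, True))
        else:
            x = np.array([p[0] for p in pts])
            y = np.array([p[1] for p in pts])
            if np.ptp(x) == 0:
                logger.info("%s: skipping degenerate group at Kd=%g µM", tissue, kd)
                continue
            slope, intercept = np.polyfit(x, y, 1)
            fits.append(SlopeFit(tissue, kd, float(slope), float(intercept),
                                 len(pts), False))
    return fits


def analytic_slope(state: EquilibriumState, kd_um: float) -> float:
    """Closed-form slope of C% vs abundance at one Kd for a solved tissue."""
    if state.total_complexes == 0:
        raise ValueError("no complexes formed; slope undefined")
    kd_nm = kd_um * 1000.0
    return 100.0 * state.free_ras / ((kd_nm + state.free_ras) * state.total_complexes)


def slope_summary(all_fits: Iterable[SlopeFit],
                  kd_range_um: tuple[float, float] = (0.04, 50.0)) -> pd.DataFrame:
    """Per-tissue average slope over the affinity range, ascending.

    Also reports per-bin averages for the standard affinity bins.
    """
    df = pd.DataFrame([f.__dict__ for f in all_fits])
    if df.empty:
        raise ValueError("no slope fits supplied")
    lo, hi = kd_range_um
    in_range = df[(df.kd_um >= lo) & (df.kd_um <= hi)]
    rows = []
    for tissue, sub in in_range.groupby("tissue"):
        row = {"tissue": tissue, "avg_slope": sub.slope.mean()}
        for blo, bhi in KD_BINS_UM:
            sel = sub[(sub.kd_um >= blo) & (sub.kd_um <= bhi)]
            row[f"avg_slope_{blo}_{bhi}"] = sel.slope.mean() if len(sel) else np.nan
        rows.append(row)
    return (pd.DataFrame(rows)
            .sort_values("avg_slope", kind="stable")
            .reset_index(drop=True))


@dataclass(frozen=True)
class KeyEffectorReport:
    effectors: frozenset[str]
    per_tissue_counts: dict[str, int]
    rankings: dict[str, list[tuple[str, float, int]]]


def key_effectors(results_by_tissue: Mapping[str, Mapping[str, float]],
                  threshold_pct: float = SIGNIFICANT_COMPLEX_PCT) -> KeyEffectorReport:
    """Effectors whose complex share reaches the threshold in at least one tissue.

    The threshold is inclusive.  Rankings cover only the key set, per tissue.
    """
    key: set[str] = set()
    counts: dict[str, int] = {}
    for tissue, pcts in results_by_tissue.items():
        hits = {e for e, p in pcts.items() if p >= threshold_pct}
        key |= hits
        counts[tissue] = len(hits)
    rankings = {
        tissue: rank_entities({e: pcts.get(e, 0.0) for e in key})
        for tissue, pcts in results_by_tissue.items()
    }
    return KeyEffectorReport(frozenset(key), counts, rankings)


def surface_grid(states_by_tissue: Mapping[str, EquilibriumState],
                 panel: Sequence[EffectorDef],
                 abundance_grid_nm: np.ndarray | None = None) -> pd.DataFrame:
    """Gridded (Kd, abundance) -> C% table for external surface plotting.

    Piecewise evaluation of the analytic per-Kd lines of each solved tissue;
    rows are (tissue, kd_um, abundance_nm, c_pct).
    """
    grid = (np.linspace(0.0, 200.0, 21) if abundance_grid_nm is None
            else np.asarray(abundance_grid_nm, dtype=float))
    kds = sorted({e.kd_um for e in panel})
    rows = []
    for tissue, state in states_by_tissue.items():
        for kd in kds:
            s = analytic_slope(state, kd)
            for a in grid:
                rows.append((tissue, kd, float(a), float(s * a)))
    return pd.DataFrame(rows, columns=["tissue", "kd_um", "abundance_nm", "c_pct"])
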