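"""One-at-a-time dissociation-constant sensitivity analyses.

Local sensitivity perturbs one effector's Kd by ±10% around its reference
value and reports the finite-difference change in that effector's complex
share; global sensitivity sweeps the Kd over the biologically observed range
0.04–39 µM while all other affinities stay at reference.  Because binding is
competitive, a complex share is monotone decreasing in its own Kd, and the
response is steepest at high affinity (small Kd).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .model import EffectorDef, GtpScenario, TissueProfile, solve_tissue

#: default global sweep: 81 points spanning 0.04–39 µM in steps of ~0.49 µM,
#: making the first (steepest) interval [0.04, 0.5275] µM
DEFAULT_GLOBAL_GRID_UM = np.linspace(0.04, 39.0, 81)


@dataclass(frozen=True)
class SensitivityRecord:
    tissue: str
    effector: str
    kd_ref_um: float
    delta_c_pct: float          # |C%(0.9 Kd) - C%(1.1 Kd)|, percentage points
    delta_c_nm: float
    delta_kd_um: float
    ratio: float                # delta_c_pct / delta_kd_um
    signed_delta_c_pct: float   # C%(0.9 Kd) - C%(1.1 Kd)


def _with_kd(panel: Sequence[EffectorDef], effector: str, kd_um: float) -> list[EffectorDef]:
    out = []
    found = False
    for e in panel:
        if e.name == effector:
            out.append(replace(e, kd_um=kd_um))
            found = True
        else:
            out.append(e)
    if not found:
        raise KeyError(f"effector {effector} not in panel")
    return out


def _share(profile, scenario, panel, effector):
    state = solve_tissue(profile, scenario, panel)
    return (state.complexes_pct.get(effector, 0.0),
            state.complexes_nm.get(effector, 0.0))


def local_sensitivity(profile: TissueProfile,
                      scenario: GtpScenario,
                      panel: Sequence[EffectorDef],
                      effector: str,
                      rel_step: float = 0.10) -> SensitivityRecord:
    """±10% perturbation of one Kd, other affinities fixed at reference."""
    ref = next(e for e in panel if e.name == effector)
    lo_pct, lo_nm = _share(profile, scenario,
                           _with_kd(panel, effector, ref.kd_um * (1 - rel_step)), effector)
    hi_pct, hi_nm = _share(profile, scenario,
                           _with_kd(panel, effector, ref.kd_um * (1 + rel_step)), effector)
    delta_kd = 2 * rel_step * ref.kd_um
    signed = lo_pct - hi_pct
    return SensitivityRecord(
        tissue=profile.tissue,
        effector=effector,
        kd_ref_um=ref.kd_um,
        delta_c_pct=abs(signed),
        delta_c_nm=abs(lo_nm - hi_nm),
        delta_kd_um=delta_kd,
        ratio=abs(signed) / delta_kd,
        signed_delta_c_pct=signed,
    )


@dataclass(frozen=True)
class GlobalSweep:
    tissue: str
    effector: str
    kd_grid_um: np.ndarray
    c_pct: np.ndarray
    c_nm: np.ndarray
    summary_delta_c_pct: float   # C%(grid[0]) - C%(grid[1]): the steepest interval

    def slope_pct_per_um(self, kd_um: float) -> float:
        """Central-difference dC%/dKd of the swept curve at a grid-interior point."""
        i = int(np.argmin(np.abs(self.kd_grid_um - kd_um)))
        i = min(max(i, 1), len(self.kd_grid_um) - 2)
        return float(
            (self.c_pct[i + 1] - self.c_pct[i - 1])
            / (self.kd_grid_um[i + 1] - self.kd_grid_um[i - 1])
        )


def global_sweep(profile: TissueProfile,
                 scenario: GtpScenario,
                 panel: Sequence[EffectorDef],
                 effector: str,
                 grid_um: np.ndarray | None = None) -> GlobalSweep:
    """Sweep one effector's Kd across the grid; other Kd's at reference."""
    grid = DEFAULT_GLOBAL_GRID_UM if grid_um is None else np.asarray(grid_um, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0) or grid[0] <= 0:
        raise ValueError("grid must be a strictly increasing positive 1-D array")
    pct = np.empty(len(grid))
    nm = np.empty(len(grid))
    for i, kd in enumerate(grid):
        pct[i], nm[i] = _share(profile, scenario, _with_kd(panel, effector, kd), effector)
    return GlobalSweep(
        tissue=profile.tissue,
        effector=effector,
        kd_grid_um=grid,
        c_pct=pct,
        c_nm=nm,
        summary_delta_c_pct=float(pct[0] - pct[1]),
    )
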