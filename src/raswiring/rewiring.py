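"""Mutant-driven network rewiring and the sweet-spot Gaussian fit.

The rewiring score of a tissue under one mutated Ras isoform is the ratio of
total Ras-effector complexes in the mutant scenario (mutated isoform fully
GTP-loaded, or scaled by a mutant level for allele/copy-number variants;
non-mutated isoforms at the 20% wild-type load) to the total in the
wild-type scenario:

    RS = tot_complexes(mutant) / tot_complexes(WT)

RS = 1 means no rewiring.  Cancer mutation frequencies per (tissue, isoform)
are then modeled as a Gaussian of RS — the "sweet spot": intermediate
rewiring is most permissive for tumor initiation, while very weak or very
strong rewiring is rarely observed in tumors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (
    BASELINE_GTP_FRACTION,
    EffectorDef,
    GtpScenario,
    TissueProfile,
    solve_tissue,
)

#: tissues rarely associated with cancer, excluded from sweet-spot fits
RARELY_CANCER_TISSUES = (
    "appendix",
    "fat",
    "heart",
    "fallopian tube",
    "placenta",
    "smooth muscle",
    "small intestine",
    "spleen",
    "tonsil",
)

DEFAULT_MUTANT_LEVELS = (0.5, 0.75, 1.0, 1.25, 1.5)


@dataclass(frozen=True)
class RewiringResult:
    tissue: str
    isoform: str
    mutant_level: float
    rs: float
    total_mutant_nm: float
    total_wt_nm: float


def rewiring_score(profile: TissueProfile,
                   isoform: str,
                   mutant_level: float,
                   panel: Sequence[EffectorDef],
                   background: float = BASELINE_GTP_FRACTION) -> RewiringResult:
    """RS for one tissue, one mutated isoform, one mutant level.

    Effector abundances are held at their reference values; only the GTP
    scenario changes between numerator and denominator.
    """
    if mutant_level <= 0:
        raise ValueError("mutant level must be positive")
    wt = solve_tissue(profile, GtpScenario.uniform(background), panel)
    if wt.total_complexes == 0:
        raise ValueError(f"{profile.tissue}: no complexes in the wild-type scenario")
    mut = solve_tissue(profile, GtpScenario.mutant(isoform, mutant_level, background), panel)
    return RewiringResult(
        tissue=profile.tissue,
        isoform=isoform,
        mutant_level=mutant_level,
        rs=mut.total_complexes / wt.total_complexes,
        total_mutant_nm=mut.total_complexes,
        total_wt_nm=wt.total_complexes,
    )


def rewiring_table(profiles: Iterable[TissueProfile],
                   panel: Sequence[EffectorDef],
                   levels: Sequence[float] = DEFAULT_MUTANT_LEVELS,
                   isoforms: Sequence[str] = ("HRAS", "KRAS", "NRAS")) -> pd.DataFrame:
    """RS for every (tissue, isoform, level), long format."""
    rows = [
        rewiring_score(p, iso, lvl, panel)
        for p in profiles for iso in isoforms for lvl in levels
    ]
    return pd.DataFrame(
        [(r.tissue, r.isoform, r.mutant_level, r.rs) for r in rows],
        columns=["tissue", "isoform", "mutant_level", "rs"],
    )


@dataclass(frozen=True)
class GaussianFit:
    amplitude: float
    mean: float
    sd: float
    residual_norm: float
    n_points: int
    excluded_tissues: tuple[str, ...]

    def predict(self, rs):
        rs = np.asarray(rs, dtype=float)
        return self.amplitude * np.exp(-((rs - self.mean) ** 2) / (2 * self.sd**2))


def fit_sweet_spot(points: pd.DataFrame | Iterable[tuple],
                   exclude: Sequence[str] = ()) -> GaussianFit:
    """Least-squares Gaussian fit of mutation frequency vs rewiring score.

    `points` is a DataFrame with columns (tissue, rs, frequency) or an
    iterable of such triples.  Tissues in `exclude` are dropped before
    fitting.  The fit is 3-parameter unweighted least squares with a
    deterministic moment-based initialization.
    """
    df = points if isinstance(points, pd.DataFrame) else pd.DataFrame(
        points, columns=["tissue", "rs", "frequency"])
    df = df[~df["tissue"].isin(set(exclude))]
    rs = df["rs"].to_numpy(dtype=float)
    freq = df["frequency"].to_numpy(dtype=float)
    if len(rs) < 4:
        raise ValueError(f"need at least 4 non-excluded points, got {len(rs)}")
    if np.ptp(rs) == 0:
        raise ValueError("degenerate input: all rewiring scores identical")

    w = np.clip(freq, 0.0, None)
    if w.sum() > 0:
        mu0 = float(np.average(rs, weights=w))
        sd0 = float(np.sqrt(np.average((rs - mu0) ** 2, weights=w)))
    else:
        mu0, sd0 = float(rs.mean()), float(rs.std())
    sd0 = max(sd0, 1e-3)
    a0 = max(float(freq.max()), 1e-6)

    def resid(theta):
        a, mu, sd = theta
        return a * np.exp(-((rs - mu) ** 2) / (2 * sd**2)) - freq

    sol = least_squares(
        resid, x0=[a0, mu0, sd0],
        bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    a, mu, sd = sol.x
    return GaussianFit(
        amplitude=float(a),
        mean=float(mu),
        sd=float(sd),
        residual_norm=float(np.linalg.norm(resid(sol.x))),
        n_points=len(rs),
        excluded_tissues=tuple(exclude),
    )
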