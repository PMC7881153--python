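"""Competitive Ras-effector binding at steady state.

Active (GTP-loaded) Ras binds the Ras-binding domains of its effectors in a
mutually exclusive fashion, so all effectors compete for one shared pool of
active Ras.  At equilibrium each pairwise reaction R + E_i <-> RE_i obeys

    RE_i = R * E_i / Kd_i

and, substituting the effector conservation E_iT = E_i + RE_i, the free-Ras
concentration R* is the unique root of the scalar conservation equation

    f(R) = R + sum_i R * E_iT / (Kd_i + R) - R_T = 0

on [0, R_T].  f is strictly increasing, so bracketed root finding is exact
and deterministic.  All internal concentrations are nanomolar; dissociation
constants enter in micromolar and are converted once at the boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

RAS_ISOFORMS = ("HRAS", "KRAS", "NRAS")

#: fraction of each isoform GTP-loaded in unstimulated, wild-type tissue
BASELINE_GTP_FRACTION = 0.20

#: complex share (percent of total complexes) above which an effector is
#: considered significantly engaged with Ras
SIGNIFICANT_COMPLEX_PCT = 5.0


@dataclass(frozen=True)
class EffectorDef:
    """Static identity of one effector: pathway class, affinity, domains."""

    name: str
    class_id: int
    kd_um: float
    domains: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (self.kd_um > 0 and math.isfinite(self.kd_um)):
            raise ValueError(f"{self.name}: kd must be positive and finite, got {self.kd_um}")
        if self.class_id not in range(1, 13):
            raise ValueError(f"{self.name}: class_id must be in 1..12, got {self.class_id}")

    @property
    def kd_nm(self) -> float:
        """Dissociation constant in nM (inputs are µM)."""
        return self.kd_um * 1000.0


def panel_by_name(panel: Iterable[EffectorDef]) -> dict[str, EffectorDef]:
    """Index a panel by effector name, enforcing uniqueness."""
    out: dict[str, EffectorDef] = {}
    for e in panel:
        if e.name in out:
            raise ValueError(f"duplicate effector name in panel: {e.name}")
        out[e.name] = e
    return out


@dataclass(frozen=True)
class TissueProfile:
    """One tissue's total protein abundances (all in nM)."""

    tissue: str
    effector_totals: Mapping[str, float]
    ras_totals: Mapping[str, float]
    receptor_totals: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group in (self.effector_totals, self.ras_totals, self.receptor_totals):
            for name, conc in group.items():
                if not (conc >= 0 and math.isfinite(conc)):
                    raise ValueError(
                        f"{self.tissue}/{name}: abundance must be finite and >= 0, got {conc}"
                    )


@dataclass(frozen=True)
class GtpScenario:
    """Per-isoform fraction of total abundance in the active GTP-bound state.

    Fractions above 1 model copy-number-gain mutants, where the active amount
    exceeds the wild-type total of that isoform.
    """

    active_fraction: Mapping[str, float]

    def __post_init__(self) -> None:
        for iso, frac in self.active_fraction.items():
            if not (frac >= 0 and math.isfinite(frac)):
                raise ValueError(f"{iso}: active fraction must be finite and >= 0, got {frac}")

    @classmethod
    def uniform(cls, fraction: float = BASELINE_GTP_FRACTION) -> "GtpScenario":
        return cls({iso: fraction for iso in RAS_ISOFORMS})

    @classmethod
    def baseline(cls) -> "GtpScenario":
        """Wild-type scenario: 20% GTP load on every isoform."""
        return cls.uniform(BASELINE_GTP_FRACTION)

    @classmethod
    def mutant(cls, isoform: str, level: float,
               background: float = BASELINE_GTP_FRACTION) -> "GtpScenario":
        """One isoform mutated to `level`, the other two at the wild-type load."""
        if isoform not in RAS_ISOFORMS:
            raise ValueError(f"unknown Ras isoform: {isoform}")
        return cls({iso: (level if iso == isoform else background) for iso in RAS_ISOFORMS})


@dataclass(frozen=True)
class EquilibriumState:
    """Solved steady state of the competitive binding system (all nM)."""

    free_ras: float
    free_effectors: dict[str, float]
    complexes_nm: dict[str, float]
    complexes_pct: dict[str, float]
    total_complexes: float
    active_ras: float
    isoform_split: dict[str, float] = field(default_factory=dict)

    def effector_total(self, name: str) -> float:
        """Reconstruct E_iT = free + bound for one effector."""
        return self.free_effectors[name] + self.complexes_nm[name]


def active_ras_by_isoform(profile: TissueProfile, scenario: GtpScenario) -> dict[str, float]:
    """Active (GTP-bound) Ras per isoform, nM."""
    out = {}
    for iso, frac in scenario.active_fraction.items():
        if iso not in profile.ras_totals:
            raise KeyError(f"{profile.tissue}: no abundance for Ras isoform {iso}")
        out[iso] = frac * profile.ras_totals[iso]
    return out


def active_ras_total(profile: TissueProfile, scenario: GtpScenario) -> float:
    """Total active Ras pooled over isoforms, nM."""
    return sum(active_ras_by_isoform(profile, scenario).values())


def isoform_split(profile: TissueProfile, scenario: GtpScenario) -> dict[str, float]:
    """Fraction of total binding attributed to each isoform.

    With one shared Kd per effector across isoforms, the three active pools are
    interchangeable, so each isoform participates in every complex in
    proportion to its share of the active pool.
    """
    active = active_ras_by_isoform(profile, scenario)
    total = sum(active.values())
    if total == 0:
        raise ValueError(f"{profile.tissue}: no active Ras; isoform split undefined")
    return {iso: amt / total for iso, amt in active.items()}


def _conservation_residual(r_free: float, active_ras: float,
                           e_totals: np.ndarray, kd_nm: np.ndarray) -> float:
    return r_free + float(np.sum(r_free * e_totals / (kd_nm + r_free))) - active_ras


def solve_equilibrium(active_ras: float,
                      effectors: Sequence[tuple[EffectorDef, float]],
                      rtol: float = 1e-12,
                      max_iter: int = 200) -> EquilibriumState:
    """Solve the competitive equilibrium for one pooled active-Ras species.

    Parameters
    ----------
    active_ras
        Total GTP-bound Ras, nM.
    effectors
        Pairs of (definition, total abundance E_iT in nM).  Zero-abundance
        effectors are retained with exactly zero complex.
    """
    if not (math.isfinite(active_ras) and active_ras >= 0):
        raise ValueError(f"active_ras must be finite and >= 0, got {active_ras}")
    names = [e.name for e, _ in effectors]
    kd_nm = np.array([e.kd_nm for e, _ in effectors], dtype=float)
    e_tot = np.array([t for _, t in effectors], dtype=float)
    if e_tot.size and (not np.all(np.isfinite(e_tot)) or np.any(e_tot < 0)):
        raise ValueError("effector totals must be finite and >= 0")

    if active_ras == 0 or e_tot.sum() == 0:
        r_free = active_ras
    else:
        f = lambda r: _conservation_residual(r, active_ras, e_tot, kd_nm)
        # f(0) = -active_ras < 0 and f(active_ras) >= 0: root is bracketed
        r_free = brentq(f, 0.0, active_ras, rtol=max(rtol, 4 * np.finfo(float).eps),
                        maxiter=max_iter)
        resid = f(r_free)
        if abs(resid) > 1e-9 * max(active_ras, 1.0):
            raise RuntimeError(
                f"equilibrium solver did not converge: residual {resid:.3e} nM"
            )

    complexes = r_free * e_tot / (kd_nm + r_free) if e_tot.size else np.array([])
    free_eff = e_tot - complexes
    total = float(complexes.sum())
    complexes_nm = dict(zip(names, complexes.tolist()))
    return EquilibriumState(
        free_ras=float(r_free),
        free_effectors=dict(zip(names, free_eff.tolist())),
        complexes_nm=complexes_nm,
        complexes_pct=complex_percentages(complexes_nm),
        total_complexes=total,
        active_ras=float(active_ras),
    )


def solve_tissue(profile: TissueProfile, scenario: GtpScenario,
                 panel: Sequence[EffectorDef]) -> EquilibriumState:
    """Solve one tissue under one GTP scenario and attach the isoform split."""
    effectors = []
    for e in panel:
        if e.name not in profile.effector_totals:
            raise KeyError(f"{profile.tissue}: missing abundance for effector {e.name}")
        effectors.append((e, profile.effector_totals[e.name]))
    state = solve_equilibrium(active_ras_total(profile, scenario), effectors)
    try:
        split = isoform_split(profile, scenario)
    except ValueError:
        split = {}
    return EquilibriumState(
        free_ras=state.free_ras,
        free_effectors=state.free_effectors,
        complexes_nm=state.complexes_nm,
        complexes_pct=state.complexes_pct,
        total_complexes=state.total_complexes,
        active_ras=state.active_ras,
        isoform_split=split,
    )


def complex_percentages(complexes_nm: Mapping[str, float]) -> dict[str, float]:
    """Share of each complex in the total, percent.  Empty if the total is 0."""
    total = sum(complexes_nm.values())
    if total == 0:
        if complexes_nm:
            logger.warning("total complexes is zero; percentages undefined")
        return {}
    return {name: 100.0 * c / total for name, c in complexes_nm.items()}


def aggregate_by_class(pcts: Mapping[str, float],
                       panel: Iterable[EffectorDef]) -> dict[int, float]:
    """Sum per-effector values into the 12 pathway classes."""
    class_of = {e.name: e.class_id for e in panel}
    out: dict[int, float] = {}
    for name, val in pcts.items():
        if name not in class_of:
            raise KeyError(f"effector {name} has no class in the panel")
        out[class_of[name]] = out.get(class_of[name], 0.0) + val
    return out


def rank_entities(pcts: Mapping[str, float]) -> list[tuple[str, float, int]]:
    """Rank descending by value; ties broken by name ascending.

    Returns (name, value, rank) with rank starting at 1.
    """
    ordered = sorted(pcts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(name, val, i + 1) for i, (name, val) in enumerate(ordered)]


def rank_changes(ref_pcts: Mapping[str, float],
                 new_pcts: Mapping[str, float]) -> dict[str, int]:
    """Rank shift per entity: rank_ref - rank_new (negative = down-ranked)."""
    ref = {name: rank for name, _, rank in rank_entities(ref_pcts)}
    new = {name: rank for name, _, rank in rank_entities(new_pcts)}
    return {name: ref[name] - new[name] for name in ref if name in new}


@dataclass(frozen=True)
class CompetitionCheck:
    sum_effectors_nm: float
    active_ras_nm: float
    competitive: bool


def competition_check(profile: TissueProfile, scenario: GtpScenario,
                      panel: Sequence[EffectorDef] | None = None) -> CompetitionCheck:
    """Is the tissue in the competition regime (sum of effectors > active Ras)?"""
    if panel is None:
        total_eff = sum(profile.effector_totals.values())
    else:
        total_eff = sum(profile.effector_totals[e.name] for e in panel)
    active = active_ras_total(profile, scenario)
    return CompetitionCheck(total_eff, active, total_eff > active)


# --------------------------------------------------------------------------
# ODE oracle: integrate the mass-action dynamics to steady state.  At
# equilibrium only the ratio k_off/k_on = Kd is observable, so a common k_on
# is used for every pair.  Retained as an independent cross-check of the
# root-finding solver; not used on the production path.

@dataclass(frozen=True)
class OdeOracleConfig:
    k_on: float = 1.0          # per nM per time unit, shared by all pairs
    horizon: float = 1e4       # initial integration window (time units)
    tol: float = 1e-10         # max relative derivative at steady state
    max_doublings: int = 12

    def __post_init__(self) -> None:
        if self.k_on <= 0:
            raise ValueError("k_on must be positive")


def ode_equilibrium(active_ras: float,
                    effectors: Sequence[tuple[EffectorDef, float]],
                    config: OdeOracleConfig = OdeOracleConfig()) -> dict[str, float]:
    """Steady-state complexes (nM) by stiff integration of dRE_i/dt.

    State vector is the complexes alone; free species follow from
    conservation.  Integration restarts with a doubled horizon until the
    largest relative derivative drops below ``config.tol``.
    """
    names = [e.name for e, _ in effectors]
    kd_nm = np.array([e.kd_nm for e, _ in effectors], dtype=float)
    e_tot = np.array([t for _, t in effectors], dtype=float)
    k = config.k_on

    def rhs(_t, y):
        r = active_ras - y.sum()
        free = e_tot - y
        return k * (r * free - kd_nm * y)

    y = np.zeros_like(e_tot)
    horizon = config.horizon
    scale = max(active_ras, float(e_tot.max(initial=0.0)), 1.0)
    for _ in range(config.max_doublings):
        sol = solve_ivp(rhs, (0.0, horizon), y, method="LSODA",
                        rtol=1e-12, atol=1e-12 * scale)
        if not sol.success:
            raise RuntimeError(f"ODE oracle integration failed: {sol.message}")
        y = sol.y[:, -1]
        dy = rhs(0.0, y)
        if np.max(np.abs(dy), initial=0.0) < config.tol * scale:
            return dict(zip(names, y.tolist()))
        horizon *= 2
    raise RuntimeError("ODE oracle did not reach steady state within the horizon cap")
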