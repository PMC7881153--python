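"""Receptor-mediated ("piggyback") effector recruitment.

A stimulated transmembrane receptor Y can bind selected effectors through a
secondary domain (SH2 against phospho-receptors, PDZ against adhesion
receptors).  Tethering the effector at the membrane, next to Ras, raises its
effective affinity for Ras by an enhancement factor alpha (~100).  For a
targeted effector j the reaction network gains

    Y + E_j  <->  YE_j        Kd = K_YE  (receptor-effector affinity)
    R + YE_j <->  RYE_j       Kd = Kd_j / alpha
    Y + RE_j <->  RYE_j       Kd = K_YE / alpha   (cycle closure)

The last constant is fixed by thermodynamic consistency of the binding
cycle, K(Y+E)·K(R+YE) = K(R+E)·K(Y+RE), so the equilibrium is fully
determined by Kd_j, K_YE and alpha.  Free R and the free receptor pool of
each stimulus are solved jointly from the conservation laws; each 1-D
conservation equation is monotone in its own free species, so the joint
solve is a damped fixed point over bracketed scalar root-finds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import (
    EffectorDef,
    EquilibriumState,
    GtpScenario,
    TissueProfile,
    active_ras_total,
    complex_percentages,
    isoform_split,
)

DEFAULT_RECEPTOR_EFFECTOR_KD_UM = 1.0
DEFAULT_ENHANCEMENT_FACTOR = 100.0
DEFAULT_STIMULATED_GTP_FRACTION = 0.90

#: effectors carrying an SH2 domain that binds activated EGFR/ErbB2
SH2_TARGETS = frozenset({"RIN1", "RIN2", "RIN3", "GRB7", "GRB10", "GRB14"})
#: effectors carrying a PDZ domain that binds nectin-family receptors
PDZ_TARGETS = frozenset(
    {"MLLT4", "SNX27", "TIAM1", "TIAM2", "RAPGEF2", "RAPGEF6", "RADIL", "RGS12"}
)


@dataclass(frozen=True)
class StimulusSpec:
    """One membrane stimulus: its receptor species and the effectors it recruits."""

    name: str
    receptor_names: tuple[str, ...]
    targeted_effectors: frozenset[str]
    receptor_effector_kd_um: float = DEFAULT_RECEPTOR_EFFECTOR_KD_UM
    enhancement_factor: float = DEFAULT_ENHANCEMENT_FACTOR
    stimulated_gtp_fraction: float = DEFAULT_STIMULATED_GTP_FRACTION

    def __post_init__(self) -> None:
        if self.enhancement_factor < 1:
            raise ValueError("enhancement factor must be >= 1")
        if self.receptor_effector_kd_um <= 0:
            raise ValueError("receptor-effector Kd must be positive")

    @property
    def receptor_effector_kd_nm(self) -> float:
        return self.receptor_effector_kd_um * 1000.0

    @classmethod
    def egf(cls) -> "StimulusSpec":
        """EGF stimulation: EGFR+ErbB2 pooled, recruiting the SH2 effectors."""
        return cls("EGF", ("EGFR", "ERBB2"), SH2_TARGETS)

    @classmethod
    def pvrl3(cls) -> "StimulusSpec":
        """Nectin-3 adhesion stimulus recruiting the PDZ effectors."""
        return cls("PVRL3", ("PVRL3",), PDZ_TARGETS)


@dataclass(frozen=True)
class PiggybackState(EquilibriumState):
    """Equilibrium with receptor species: adds YE and RYE complex pools."""

    free_receptors: dict[str, float] = field(default_factory=dict)
    ye_complexes: dict[tuple[str, str], float] = field(default_factory=dict)
    rye_complexes: dict[tuple[str, str], float] = field(default_factory=dict)

    def bound_effector(self, name: str) -> float:
        """Total Ras-engaged pool of one effector: RE + all RYE."""
        return self.complexes_nm[name] + sum(
            v for (stim, eff), v in self.rye_complexes.items() if eff == name
        )


def _receptor_total(profile: TissueProfile, stim: StimulusSpec) -> float:
    total = 0.0
    for rec in stim.receptor_names:
        if rec not in profile.receptor_totals:
            raise KeyError(f"{profile.tissue}: no abundance for receptor {rec}")
        total += profile.receptor_totals[rec]
    return total


def _effector_partition(e_tot: float, kd_nm: float, r: float,
                        stims: Sequence[tuple[StimulusSpec, float]]):
    """Partition one effector's total pool given free R and free receptor levels.

    Returns (free E, RE, {stim: YE}, {stim: RYE}).  `stims` carries only the
    stimuli targeting this effector, as (spec, free Y) pairs.
    """
    denom = 1.0 + r / kd_nm
    terms = []
    for spec, y in stims:
        kye = spec.receptor_effector_kd_nm
        t = (y / kye) * (1.0 + r * spec.enhancement_factor / kd_nm)
        terms.append((spec, y, kye, t))
        denom += t
    free = e_tot / denom
    re = free * r / kd_nm
    ye = {spec.name: free * y / kye for spec, y, kye, _ in terms}
    rye = {
        spec.name: free * (y / kye) * r * spec.enhancement_factor / kd_nm
        for spec, y, kye, _ in terms
    }
    return free, re, ye, rye


def solve_piggyback(profile: TissueProfile,
                    scenario: GtpScenario,
                    stimuli: Sequence[StimulusSpec],
                    panel: Sequence[EffectorDef],
                    rtol: float = 1e-10,
                    max_iter: int = 100_000) -> PiggybackState:
    """Joint equilibrium of Ras, receptors, and effectors for one tissue.

    Untargeted effectors behave exactly as in the receptor-free model.  A
    stimulus whose receptor abundance is zero contributes nothing.
    """
    active_ras = active_ras_total(profile, scenario)
    names = [e.name for e in panel]
    kd_nm = {e.name: e.kd_nm for e in panel}
    e_tot = {e.name: profile.effector_totals[e.name] for e in panel}
    for stim in stimuli:
        unknown = stim.targeted_effectors - set(names)
        if unknown:
            raise KeyError(f"stimulus {stim.name} targets unknown effectors: {sorted(unknown)}")
    y_tot = {stim.name: _receptor_total(profile, stim) for stim in stimuli}
    stim_by_name = {s.name: s for s in stimuli}
    targets_of = {s.name: s.targeted_effectors & set(names) for s in stimuli}

    def stims_for(eff: str, y_free: Mapping[str, float]):
        return [
            (stim_by_name[s], y_free[s]) for s in y_free if eff in targets_of[s]
        ]

    def ras_bound(r: float, y_free: Mapping[str, float]) -> float:
        total = 0.0
        for eff in names:
            _, re, _, rye = _effector_partition(
                e_tot[eff], kd_nm[eff], r, stims_for(eff, y_free))
            total += re + sum(rye.values())
        return total

    def receptor_bound(s: str, y: float, r: float, y_free: Mapping[str, float]) -> float:
        probe = dict(y_free, **{s: y})
        total = 0.0
        for eff in targets_of[s]:
            _, _, ye, rye = _effector_partition(
                e_tot[eff], kd_nm[eff], r, stims_for(eff, probe))
            total += ye[s] + rye[s]
        return total

    def solve_r(y_free: Mapping[str, float]) -> float:
        if active_ras == 0:
            return 0.0
        g = lambda r: r + ras_bound(r, y_free) - active_ras
        if g(active_ras) <= 0:
            return active_ras
        return brentq(g, 0.0, active_ras, rtol=1e-15, maxiter=200)

    def solve_y(s: str, r: float, y_free: Mapping[str, float]) -> float:
        if y_tot[s] == 0:
            return 0.0
        h = lambda y: y + receptor_bound(s, y, r, y_free) - y_tot[s]
        if h(y_tot[s]) <= 0:
            return y_tot[s]
        return brentq(h, 0.0, y_tot[s], rtol=1e-15, maxiter=200)

    y_free = {s.name: 0.0 for s in stimuli}
    r = solve_r(y_free)
    damping = 0.5
    for _ in range(max_iter):
        r_new = solve_r(y_free)
        y_new = {s: solve_y(s, r_new, y_free) for s in y_free}
        changes = [abs(r_new - r) / max(active_ras, 1e-300)]
        changes += [
            abs(y_new[s] - y_free[s]) / max(y_tot[s], 1e-300) for s in y_free
        ]
        r = r_new
        y_free = {
            s: y_free[s] + damping * (y_new[s] - y_free[s]) for s in y_free
        }
        if max(changes, default=0.0) < rtol:
            # undamped final positions satisfy their own conservation laws
            y_free = y_new
            r = solve_r(y_free)
            break
    else:
        resid_r = abs(r + ras_bound(r, y_free) - active_ras)
        raise RuntimeError(
            f"piggyback solve did not converge: Ras residual {resid_r:.3e} nM"
        )

    free_eff: dict[str, float] = {}
    complexes: dict[str, float] = {}
    ye_out: dict[tuple[str, str], float] = {}
    rye_out: dict[tuple[str, str], float] = {}
    for eff in names:
        free, re, ye, rye = _effector_partition(
            e_tot[eff], kd_nm[eff], r, stims_for(eff, y_free))
        free_eff[eff] = free
        complexes[eff] = re
        for s, v in ye.items():
            ye_out[(s, eff)] = v
        for s, v in rye.items():
            rye_out[(s, eff)] = v

    # percentages over everything Ras-engaged (RE + RYE)
    engaged = {
        eff: complexes[eff] + sum(v for (s, e2), v in rye_out.items() if e2 == eff)
        for eff in names
    }
    total = sum(engaged.values())
    try:
        split = isoform_split(profile, scenario)
    except ValueError:
        split = {}
    return PiggybackState(
        free_ras=r,
        free_effectors=free_eff,
        complexes_nm=complexes,
        complexes_pct=complex_percentages(engaged),
        total_complexes=total,
        active_ras=active_ras,
        isoform_split=split,
        free_receptors=dict(y_free),
        ye_complexes=ye_out,
        rye_complexes=rye_out,
    )


def fold_factor(stim_state: EquilibriumState,
                unstim_state: EquilibriumState,
                grouping: str = "effector",
                panel: Sequence[EffectorDef] | None = None) -> dict:
    """Ratio of stimulated to unstimulated complex concentrations (nM).

    For a piggyback state the stimulated pool counts RE + RYE.  `grouping`
    is "effector" or "class" (class ratios are sums-of-nM ratios and need a
    panel).  A zero unstimulated pool with a positive stimulated pool yields
    ``math.inf``.
    """

    def engaged(state: EquilibriumState, eff: str) -> float:
        if isinstance(state, PiggybackState):
            return state.bound_effector(eff)
        return state.complexes_nm[eff]

    effectors = sorted(unstim_state.complexes_nm)
    if set(stim_state.complexes_nm) != set(effectors):
        raise ValueError("states cover different effector panels")

    if grouping == "effector":
        out = {}
        for eff in effectors:
            lo, hi = engaged(unstim_state, eff), engaged(stim_state, eff)
            out[eff] = 1.0 if (lo == 0 and hi == 0) else (math.inf if lo == 0 else hi / lo)
        return out
    if grouping == "class":
        if panel is None:
            raise ValueError("class grouping needs the effector panel")
        class_of = {e.name: e.class_id for e in panel}
        lo_sum: dict[int, float] = {}
        hi_sum: dict[int, float] = {}
        for eff in effectors:
            c = class_of[eff]
            lo_sum[c] = lo_sum.get(c, 0.0) + engaged(unstim_state, eff)
            hi_sum[c] = hi_sum.get(c, 0.0) + engaged(stim_state, eff)
        return {
            c: (1.0 if (lo_sum[c] == 0 and hi_sum[c] == 0)
                else (math.inf if lo_sum[c] == 0 else hi_sum[c] / lo_sum[c]))
            for c in lo_sum
        }
    raise ValueError(f"unknown grouping: {grouping!r}")


def ode_piggyback(profile: TissueProfile,
                  scenario: GtpScenario,
                  stimuli: Sequence[StimulusSpec],
                  panel: Sequence[EffectorDef],
                  k_on: float = 1.0,
                  horizon: float = 1e4,
                  tol: float = 1e-10,
                  max_doublings: int = 14) -> PiggybackState:
    """Independent oracle: integrate the full mass-action network to steady state.

    All four reaction edges of each targeted effector's binding cycle are
    integrated with a shared on-rate; off-rates follow from the equilibrium
    constants, including the cycle-closure edge Y + RE <-> RYE.
    """
    active_ras = active_ras_total(profile, scenario)
    names = [e.name for e in panel]
    kd_nm = np.array([e.kd_nm for e in panel])
    e_tot = np.array([profile.effector_totals[e.name] for e in panel])
    n = len(names)
    y_tot = np.array([_receptor_total(profile, s) for s in stimuli])
    m = len(stimuli)
    targeted = np.zeros((m, n), dtype=bool)
    kye = np.array([s.receptor_effector_kd_nm for s in stimuli])
    alpha = np.array([s.enhancement_factor for s in stimuli])
    for si, s in enumerate(stimuli):
        for ei, eff in enumerate(names):
            targeted[si, ei] = eff in s.targeted_effectors

    # state: RE (n), YE (m*n), RYE (m*n)
    def unpack(v):
        re = v[:n]
        ye = v[n:n + m * n].reshape(m, n)
        rye = v[n + m * n:].reshape(m, n)
        return re, ye, rye

    def rhs(_t, v):
        re, ye, rye = unpack(v)
        r = active_ras - re.sum() - rye.sum()
        y = y_tot - ye.sum(axis=1) - rye.sum(axis=1)
        e = e_tot - re - ye.sum(axis=0) - rye.sum(axis=0)
        d_re = k_on * (r * e - kd_nm * re)
        d_ye = k_on * targeted * (y[:, None] * e[None, :] - kye[:, None] * ye)
        d_rye_a = k_on * targeted * (r * ye - (kd_nm[None, :] / alpha[:, None]) * rye)
        d_rye_b = k_on * targeted * (y[:, None] * re[None, :]
                                     - (kye[:, None] / alpha[:, None]) * rye)
        d_re = d_re - d_rye_b.sum(axis=0)
        d_ye = d_ye - d_rye_a
        d_rye = d_rye_a + d_rye_b
        return np.concatenate([d_re, d_ye.ravel(), d_rye.ravel()])

    v = np.zeros(n + 2 * m * n)
    scale = max(active_ras, float(e_tot.max(initial=0.0)),
                float(y_tot.max(initial=0.0)), 1.0)
    h = horizon
    for _ in range(max_doublings):
        sol = solve_ivp(rhs, (0.0, h), v, method="LSODA", rtol=1e-12, atol=1e-12 * scale)
        if not sol.success:
            raise RuntimeError(f"piggyback ODE oracle failed: {sol.message}")
        v = sol.y[:, -1]
        if np.max(np.abs(rhs(0.0, v)), initial=0.0) < tol * scale:
            break
        h *= 2
    else:
        raise RuntimeError("piggyback ODE oracle did not reach steady state")

    re, ye, rye = unpack(v)
    r = active_ras - re.sum() - rye.sum()
    y = y_tot - ye.sum(axis=1) - rye.sum(axis=1)
    e = e_tot - re - ye.sum(axis=0) - rye.sum(axis=0)
    engaged = {names[i]: float(re[i] + rye[:, i].sum()) for i in range(n)}
    return PiggybackState(
        free_ras=float(r),
        free_effectors={names[i]: float(e[i]) for i in range(n)},
        complexes_nm={names[i]: float(re[i]) for i in range(n)},
        complexes_pct=complex_percentages(engaged),
        total_complexes=float(sum(engaged.values())),
        active_ras=active_ras,
        free_receptors={stimuli[i].name: float(y[i]) for i in range(m)},
        ye_complexes={(stimuli[si].name, names[ei]): float(ye[si, ei])
                      for si in range(m) for ei in range(n) if targeted[si, ei]},
        rye_complexes={(stimuli[si].name, names[ei]): float(rye[si, ei])
                       for si in range(m) for ei in range(n) if targeted[si, ei]},
    )
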