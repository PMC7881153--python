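"""Three-way effector classification by binding efficiency.

Group 1: effectors whose Ras-binding domain alone yields a significant
complex share (>= 5% of total complexes) in at least one tissue under the
unstimulated reference (20% GTP, reference affinities).  Group 2: effectors
that reach the threshold only in the enhanced condition — affinity raised
100-fold (membrane recruitment) with 90% GTP load.  Group 3: everything
else; these are unlikely to be functional Ras effectors at physiological
abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .model import (
    EffectorDef,
    GtpScenario,
    SIGNIFICANT_COMPLEX_PCT,
    TissueProfile,
    solve_tissue,
)
from .piggyback import DEFAULT_ENHANCEMENT_FACTOR, DEFAULT_STIMULATED_GTP_FRACTION

#: domain tags that can mediate recruitment to the plasma membrane
RECRUITMENT_DOMAINS = frozenset({"SH2", "PDZ", "PH", "C1", "C2"})


@dataclass(frozen=True)
class EffectorGroupAssignment:
    effector: str
    group: int                     # 1, 2 or 3
    max_pct_unstim: float
    max_pct_enhanced: float
    has_recruitment_domain: bool
    domains: frozenset[str]


def enhanced_results(profiles: Iterable[TissueProfile],
                     panel: Sequence[EffectorDef],
                     factor: float = DEFAULT_ENHANCEMENT_FACTOR,
                     gtp: float = DEFAULT_STIMULATED_GTP_FRACTION
                     ) -> dict[str, dict[str, float]]:
    """Complex shares per tissue with all affinities enhanced `factor`-fold
    and a stimulated GTP load."""
    boosted = [replace(e, kd_um=e.kd_um / factor) for e in panel]
    scenario = GtpScenario.uniform(gtp)
    return {p.tissue: solve_tissue(p, scenario, boosted).complexes_pct for p in profiles}


def unstimulated_results(profiles: Iterable[TissueProfile],
                         panel: Sequence[EffectorDef]) -> dict[str, dict[str, float]]:
    """Complex shares per tissue at the 20% GTP reference."""
    scenario = GtpScenario.baseline()
    return {p.tissue: solve_tissue(p, scenario, panel).complexes_pct for p in profiles}


def classify(results_unstim: Mapping[str, Mapping[str, float]],
             results_enhanced: Mapping[str, Mapping[str, float]],
             panel: Sequence[EffectorDef],
             threshold_pct: float = SIGNIFICANT_COMPLEX_PCT,
             require_domain: bool = False) -> list[EffectorGroupAssignment]:
    """Partition the panel into the three efficiency groups.

    With `require_domain`, entry to Group 2 additionally requires an
    annotated recruitment domain (strict mode); the default keys purely on
    the threshold outcomes.
    """
    out = []
    for e in panel:
        try:
            unstim = max(pcts.get(e.name, 0.0) for pcts in results_unstim.values())
            enhanced = max(pcts.get(e.name, 0.0) for pcts in results_enhanced.values())
        except ValueError:
            raise ValueError("empty result set") from None
        for label, results in (("unstimulated", results_unstim),
                               ("enhanced", results_enhanced)):
            missing = [t for t, pcts in results.items() if e.name not in pcts]
            if missing:
                raise KeyError(
                    f"effector {e.name} missing from {label} results for {missing[0]}")
        has_domain = bool(e.domains & RECRUITMENT_DOMAINS)
        if unstim >= threshold_pct:
            group = 1
        elif enhanced >= threshold_pct and (has_domain or not require_domain):
            group = 2
        else:
            group = 3
        out.append(EffectorGroupAssignment(
            effector=e.name,
            group=group,
            max_pct_unstim=unstim,
            max_pct_enhanced=enhanced,
            has_recruitment_domain=has_domain,
            domains=e.domains,
        ))
    return out


def group_sizes(assignments: Iterable[EffectorGroupAssignment]) -> dict[int, int]:
    sizes = {1: 0, 2: 0, 3: 0}
    for a in assignments:
        sizes[a.group] += 1
    return sizes
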