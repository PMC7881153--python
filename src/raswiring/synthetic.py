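"""Synthetic study-condition generator.

Emulates the statistical structure of the tissue proteomics inputs the
analysis expects: 29 tissues x 56 effectors with log-normally spread
abundances satisfying the competition condition (sum of effectors exceeds
active Ras at a 20% GTP load), Ras isoform totals with KRAS dominant except
in a pancreas-like tissue with equal thirds, receptor abundances, Kd values
spanning 0.04–39 µM anchored at the known reference affinities, and cancer
mutation frequencies drawn from a known Gaussian of rewiring score plus
noise (so parameter-recovery is testable against ground truth).

The effector names, 12-class memberships and the recruitment-domain target
sets are real and fixed; abundances and the unanchored affinities are
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import EffectorDef, TissueProfile
from .piggyback import PDZ_TARGETS, SH2_TARGETS

#: the 56 modeled effectors in their 12 pathway classes
EFFECTOR_CLASSES: dict[int, tuple[str, ...]] = {
    1: ("ARAF", "BRAF", "RAF1"),
    2: ("PIK3CA", "PIK3CB", "PIK3CD", "PIK3CG", "PIK3C2B", "PIK3C2G", "PIK3C2A"),
    3: ("RALGDS", "RGL1", "RGL2", "RGL3", "RGL4"),
    4: ("MLLT4",),
    5: ("PLCE1",),
    6: ("RIN1", "RIN2", "RIN3", "SNX27"),
    7: ("TIAM1", "TIAM2", "ARHGAP20", "ARAP1", "ARAP2", "ARAP3", "DGKQ"),
    8: ("RASSF1", "RASSF10", "RASSF2", "RASSF3", "RASSF4", "RASSF5", "RASSF6",
        "RASSF7", "RASSF8", "RASSF9"),
    9: ("RAPGEF2", "RAPGEF3", "RAPGEF4", "RAPGEF5", "RAPGEF6", "KRIT1", "RASIP1",
        "RADIL", "APBB1IP", "RAPH1"),
    10: ("MYO9A", "MYO9B", "MYO10"),
    11: ("RGS12", "RGS14"),
    12: ("GRB7", "GRB10", "GRB14"),
}

#: reference dissociation constants known for specific effectors, µM
KD_ANCHORS_UM: dict[str, float] = {
    "ARAF": 0.07,
    "MLLT4": 3.03,
    "SNX27": 10.0,
    "PIK3CD": 7.5,
    "ARAP1": 7.5,
    "RADIL": 7.5,
    "MYO9A": 7.5,
}

#: the 29 tissue names of the deep proteome panel
TISSUE_NAMES: tuple[str, ...] = (
    "adrenal gland", "appendix", "brain", "colon", "duodenum", "endometrium",
    "esophagus", "fallopian tube", "fat", "gallbladder", "heart", "kidney",
    "liver", "lung", "lymph node", "ovary", "pancreas", "placenta", "prostate",
    "rectum", "salivary gland", "small intestine", "smooth muscle", "spleen",
    "stomach", "testis", "thyroid", "tonsil", "urinary bladder",
)

RECEPTOR_NAMES = ("EGFR", "ERBB2", "PVRL3")

_MEMBRANE_DOMAINS = ("PH", "C1", "C2")


@dataclass(frozen=True)
class SynthesisConfig:
    """Knobs of the generator; defaults are the reference study conditions."""

    n_tissues: int = 29
    seed: int = 0
    abundance_log_mean: float = 3.0     # natural-log nM scale (~20 nM median)
    abundance_log_sd: float = 1.0       # spans ~50-fold cross-tissue variation
    kd_range_um: tuple[float, float] = (0.04, 39.0)
    fraction_high_affinity: float = 0.25   # share of effectors with Kd <= 1 µM
    ras_log_means: tuple[float, float, float] = (
        float(np.log(100.0)), float(np.log(400.0)), float(np.log(100.0)))  # H, K, N
    ras_log_sd: float = 0.4
    receptor_abundance_range_nm: tuple[float, float] = (5.0, 200.0)
    competition_target: bool = True     # force sum(effectors) > 0.2 * sum(Ras)
    gtp_load: float = 0.20
    membrane_domain_prob: float = 0.3   # chance a non-SH2/PDZ effector gets PH/C1/C2
    gaussian_truth: tuple[float, float, float] = (30.0, 2.0, 0.3)  # A, mu, sigma
    frequency_noise_sd: float = 1.5     # percent, 5% of the default amplitude


def generate_panel(config: SynthesisConfig = SynthesisConfig()) -> list[EffectorDef]:
    """The 56-effector panel: real names/classes/domain targets, anchored Kd's,
    remaining affinities sampled log-uniformly within the observed range."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.kd_range_um
    panel = []
    for class_id, names in EFFECTOR_CLASSES.items():
        for name in names:
            if name in KD_ANCHORS_UM:
                kd = KD_ANCHORS_UM[name]
            elif rng.random() < config.fraction_high_affinity:
                kd = float(np.exp(rng.uniform(np.log(lo), np.log(1.0))))
            else:
                kd = float(np.exp(rng.uniform(np.log(1.0), np.log(hi))))
            domains = set()
            if name in SH2_TARGETS:
                domains.add("SH2")
            if name in PDZ_TARGETS:
                domains.add("PDZ")
            if not domains and rng.random() < config.membrane_domain_prob:
                domains.add(_MEMBRANE_DOMAINS[int(rng.integers(len(_MEMBRANE_DOMAINS)))])
            panel.append(EffectorDef(name, class_id, kd, frozenset(domains)))
    return panel


def _tissue_names(n: int) -> list[str]:
    if n <= len(TISSUE_NAMES):
        return list(TISSUE_NAMES[:n])
    extra = [f"tissue_{i}" for i in range(len(TISSUE_NAMES), n)]
    return list(TISSUE_NAMES) + extra


def generate_tissues(config: SynthesisConfig = SynthesisConfig(),
                     panel: list[EffectorDef] | None = None) -> list[TissueProfile]:
    """Tissue profiles with log-normal abundances and KRAS-dominant Ras totals.

    The pancreas-like tissue gets equal isoform thirds.  When
    `competition_target` is set, effector abundances are rescaled so the
    effector sum exceeds twice the active Ras pool at the configured GTP
    load, which both satisfies and comfortably clears the competition
    condition.
    """
    if panel is None:
        panel = generate_panel(config)
    rng = np.random.default_rng(config.seed + 1)
    names = _tissue_names(config.n_tissues)
    profiles = []
    for tissue in names:
        eff = {
            e.name: float(rng.lognormal(config.abundance_log_mean, config.abundance_log_sd))
            for e in panel
        }
        h, k, n = (float(rng.lognormal(m, config.ras_log_sd)) for m in config.ras_log_means)
        k = max(k, 1.2 * max(h, n))  # KRAS-dominant
        if tissue == "pancreas":
            third = (h + k + n) / 3.0
            h = k = n = third
        ras = {"HRAS": h, "KRAS": k, "NRAS": n}
        active = config.gtp_load * sum(ras.values())
        total_eff = sum(eff.values())
        if config.competition_target and total_eff <= 2.0 * active:
            scale = 2.0 * active / total_eff if total_eff > 0 else 1.0
            eff = {name: v * scale * 1.01 for name, v in eff.items()}
        rlo, rhi = config.receptor_abundance_range_nm
        receptors = {
            r: float(np.exp(rng.uniform(np.log(rlo), np.log(rhi))))
            for r in RECEPTOR_NAMES
        }
        profiles.append(TissueProfile(tissue, eff, ras, receptors))
    return profiles


def generate_mutation_frequencies(config: SynthesisConfig,
                                  rewiring_scores: pd.DataFrame
                                  ) -> tuple[pd.DataFrame, dict]:
    """Mutation frequencies from the Gaussian ground truth plus noise.

    `rewiring_scores` needs columns (tissue, isoform, rs).  Returns the
    frequency table (tissue, isoform, frequency_percent) and the truth
    parameters used, for recovery assertions.
    """
    a, mu, sd = config.gaussian_truth
    rng = np.random.default_rng(config.seed + 2)
    rs = rewiring_scores["rs"].to_numpy(dtype=float)
    clean = a * np.exp(-((rs - mu) ** 2) / (2 * sd**2))
    noisy = clean + rng.normal(0.0, config.frequency_noise_sd, size=len(rs))
    freq = np.clip(noisy, 0.0, None)
    out = rewiring_scores[["tissue", "isoform"]].copy()
    out["frequency_percent"] = freq
    truth = {"amplitude": a, "mean": mu, "sd": sd,
             "noise_sd": config.frequency_noise_sd, "seed": config.seed}
    return out, truth
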