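"""Readers and writers for the tabular interchange formats.

All files are plain CSV with a mandatory header, UTF-8, LF line endings.
Concentration columns carry a `_nm` suffix; dissociation constants are
stored in µM (`kd_um`) and converted at load.  Floats are written at full
double precision so write-then-read round trips are lossless.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .composition import MarkerSet
from .model import (
    EffectorDef,
    EquilibriumState,
    RAS_ISOFORMS,
    TissueProfile,
    panel_by_name,
    rank_entities,
)
from .piggyback import StimulusSpec

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- panel

def write_panel(panel: Sequence[EffectorDef], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["effector", "class_id", "kd_um", "domains"])
        for e in panel:
            w.writerow([e.name, e.class_id, repr(e.kd_um), ";".join(sorted(e.domains))])


def read_panel(path: str | Path) -> list[EffectorDef]:
    panel = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader, {"effector", "class_id", "kd_um", "domains"}, path)
        for i, row in enumerate(reader, start=2):
            try:
                domains = frozenset(d for d in row["domains"].split(";") if d)
                panel.append(EffectorDef(row["effector"], int(row["class_id"]),
                                         float(row["kd_um"]), domains))
            except (TypeError, ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{i}: malformed panel row: {exc}") from exc
    panel_by_name(panel)  # enforce unique names
    return panel


# ---------------------------------------------------------------- abundances

def write_abundances(profiles: Iterable[TissueProfile], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["tissue", "protein", "abundance_nm"])
        for p in profiles:
            for group in (p.ras_totals, p.effector_totals, p.receptor_totals):
                for protein, conc in group.items():
                    w.writerow([p.tissue, protein, repr(conc)])


def read_abundances(path: str | Path,
                    panel: Sequence[EffectorDef]) -> dict[str, TissueProfile]:
    """Long-format abundance table -> one profile per tissue.

    Proteins that are neither panel effectors nor Ras isoforms are kept as
    receptor abundances (and flagged in the log).  A tissue missing any
    panel effector is a hard error: the model needs complete panels.
    """
    effector_names = set(panel_by_name(panel))
    raw: dict[str, dict[str, dict[str, float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader, {"tissue", "protein", "abundance_nm"}, path)
        for i, row in enumerate(reader, start=2):
            try:
                tissue, protein = row["tissue"], row["protein"]
                conc = float(row["abundance_nm"])
            except (TypeError, ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{i}: malformed abundance row: {exc}") from exc
            if conc < 0:
                raise ValueError(f"{path}:{i}: negative abundance for "
                                 f"{tissue}/{protein}: {conc}")
            slot = raw.setdefault(tissue, {"eff": {}, "ras": {}, "rec": {}})
            if protein in effector_names:
                slot["eff"][protein] = conc
            elif protein in RAS_ISOFORMS:
                slot["ras"][protein] = conc
            else:
                logger.info("%s: protein %s is not in the panel; kept as receptor",
                            tissue, protein)
                slot["rec"][protein] = conc
    profiles = {}
    for tissue, slot in raw.items():
        missing = effector_names - set(slot["eff"])
        if missing:
            raise ValueError(
                f"{path}: tissue {tissue!r} is missing panel effector "
                f"{sorted(missing)[0]!r} (and {len(missing) - 1} more)")
        profiles[tissue] = TissueProfile(tissue, slot["eff"], slot["ras"], slot["rec"])
    return profiles


# ---------------------------------------------------------------- results

def write_results(states: Mapping[str, EquilibriumState],
                  panel: Sequence[EffectorDef],
                  results_path: str | Path,
                  summary_path: str | Path | None = None) -> None:
    class_of = {e.name: e.class_id for e in panel}
    with open(results_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["tissue", "effector", "class_id", "complex_nm", "complex_pct", "rank"])
        for tissue in sorted(states):
            state = states[tissue]
            ranks = {name: rank for name, _, rank in rank_entities(state.complexes_pct)}
            for name in sorted(state.complexes_nm):
                w.writerow([
                    tissue, name, class_of[name],
                    repr(state.complexes_nm[name]),
                    repr(state.complexes_pct.get(name, 0.0)),
                    ranks.get(name, ""),
                ])
    if summary_path is not None:
        with open(summary_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["tissue", "free_ras_nm", "total_complex_nm"])
            for tissue in sorted(states):
                state = states[tissue]
                w.writerow([tissue, repr(state.free_ras), repr(state.total_complexes)])


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"tissue", "effector", "class_id", "complex_nm", "complex_pct"}
    if not expected <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(expected - set(df.columns))}")
    return df


# ---------------------------------------------------------------- frequencies, markers

def write_mutation_frequencies(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, lineterminator="\n")


def read_mutation_frequencies(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"tissue", "isoform", "frequency_percent"}
    if not expected <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(expected - set(df.columns))}")
    if (df["frequency_percent"] < 0).any():
        raise ValueError(f"{path}: negative mutation frequency")
    return df


def read_marker_sets(path: str | Path) -> list[MarkerSet]:
    """CSV `subtype,marker`, one marker per row."""
    by_subtype: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader, {"subtype", "marker"}, path)
        for i, row in enumerate(reader, start=2):
            if not row.get("subtype") or not row.get("marker"):
                raise ValueError(f"{path}:{i}: malformed marker row")
            by_subtype.setdefault(row["subtype"], []).append(row["marker"])
    return [MarkerSet(subtype, tuple(markers)) for subtype, markers in by_subtype.items()]


# ---------------------------------------------------------------- stimulus config

def read_stimulus(path: str | Path) -> StimulusSpec:
    """YAML stimulus description: name, receptors, targets, kd_um, alpha, gtp."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    known = {"name", "receptors", "targets", "kd_um", "alpha", "gtp"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"{path}: unknown stimulus keys {sorted(unknown)}")
    return StimulusSpec(
        name=cfg["name"],
        receptor_names=tuple(cfg["receptors"]),
        targeted_effectors=frozenset(cfg["targets"]),
        receptor_effector_kd_um=float(cfg.get("kd_um", 1.0)),
        enhancement_factor=float(cfg.get("alpha", 100.0)),
        stimulated_gtp_fraction=float(cfg.get("gtp", 0.9)),
    )


def write_stimulus(stim: StimulusSpec, path: str | Path) -> None:
    cfg = {
        "name": stim.name,
        "receptors": list(stim.receptor_names),
        "targets": sorted(stim.targeted_effectors),
        "kd_um": stim.receptor_effector_kd_um,
        "alpha": stim.enhancement_factor,
        "gtp": stim.stimulated_gtp_fraction,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _require_columns(reader: csv.DictReader, expected: set[str], path) -> None:
    cols = set(reader.fieldnames or ())
    if not expected <= cols:
        raise ValueError(f"{path}: missing columns {sorted(expected - cols)}")
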