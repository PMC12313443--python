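"""Tabular input/output: detection tables, community count tables, results.

All files are plain CSV (UTF-8, comma-separated, mandatory header row).
Detection tables are wide (one binary column per prey target); community
counts are long (unit + taxon + count) because taxon lists differ between
years.  Taxon labels are case-sensitive exact strings declared in the
:class:`~gutweb.design.DesignSpec`; there is no fuzzy matching.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .design import CommunitySample, DesignSpec, DetectionRecord, WebUnitKey

logger = logging.getLogger(__name__)

UNIT_COLUMNS = ["year", "field", "treatment", "plot", "session"]

__all__ = [
    "read_detections",
    "write_detections",
    "read_community",
    "write_community",
    "write_table",
    "load_config",
    "design_from_mapping",
]


def _unit_from_row(row, design: DesignSpec, rownum: int) -> WebUnitKey:
    year = str(row["year"])
    if year not in design.years:
        raise ValueError(f"row {rownum}: unknown year {year!r}")
    treatment = str(row["treatment"])
    if treatment not in design.treatments:
        raise ValueError(f"row {rownum}: unknown treatment {treatment!r}")
    try:
        session = int(row["session"])
    except (TypeError, ValueError):
        raise ValueError(f"row {rownum}: non-integer session {row['session']!r}") from None
    if not 1 <= session <= design.sessions_per_year[year]:
        raise ValueError(
            f"row {rownum}: session {session} out of range 1..{design.sessions_per_year[year]}"
            f" for year {year}"
        )
    return WebUnitKey(year, str(row["field"]), treatment, str(row["plot"]), session)


def read_detections(path: str | Path, design: DesignSpec) -> list[DetectionRecord]:
    """Read a wide-format detection table, validating every row against the design.

    Expected columns: ``year, field, treatment, plot, session, predator_species``
    followed by one 0/1 column per prey target in the design's panel.
    """
    df = pd.read_csv(path, dtype=str)
    expected = UNIT_COLUMNS + ["predator_species"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    missing_prey = [t for t in design.prey_targets if t not in df.columns]
    if missing_prey:
        raise ValueError(f"{path}: missing prey target columns {missing_prey}")

    records: list[DetectionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 is the header
        row = dict(zip(df.columns, row))
        unit = _unit_from_row(row, design, i)
        species = str(row["predator_species"])
        if species not in design.predator_species:
            raise ValueError(f"row {i}: unknown predator species {species!r}")
        detections = {}
        for tgt in design.prey_targets:
            v = row[tgt]
            if v not in ("0", "1"):
                raise ValueError(f"row {i}: non-binary detection value {v!r} for {tgt!r}")
            detections[tgt] = int(v)
        records.append(DetectionRecord(unit, species, detections))
    return records


def write_detections(records: Iterable[DetectionRecord], path: str | Path) -> None:
    """Write detection records as a wide CSV that round-trips through
    :func:`read_detections`."""
    records = list(records)
    if records:
        targets = list(records[0].detections)
    else:
        targets = []
    rows = []
    for r in records:
        row = {
            "year": r.unit.year,
            "field": r.unit.field,
            "treatment": r.unit.treatment,
            "plot": r.unit.plot,
            "session": r.unit.session,
            "predator_species": r.predator_species,
        }
        row.update(r.detections)
        rows.append(row)
    df = pd.DataFrame(rows, columns=UNIT_COLUMNS + ["predator_species"] + targets)
    write_table(df, path)


def read_community(
    pitfall_path: str | Path,
    tiller_path: str | Path,
    design: DesignSpec,
    known_aphids: Sequence[str] | None = None,
) -> list[CommunitySample]:
    """Read long-format pitfall and tiller-count tables into per-unit samples.

    Both files carry the unit columns plus ``taxon`` and ``count``.  A taxon
    absent from a unit's rows is imputed as count 0 downstream; duplicate
    (unit, taxon) rows and negative counts are errors.
    """
    pitfall = _read_long_counts(pitfall_path, design)
    tillers = _read_long_counts(tiller_path, design)
    units = sorted(set(pitfall) | set(tillers))
    if not units:
        logger.warning("community files %s / %s contain no rows", pitfall_path, tiller_path)
    samples = []
    for unit in units:
        s = CommunitySample(unit, pitfall.get(unit, {}), tillers.get(unit, {}))
        s.validate(known_aphids)
        samples.append(s)
    return samples


def _read_long_counts(path: str | Path, design: DesignSpec) -> dict[WebUnitKey, dict[str, int]]:
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        return {}
    missing = [c for c in UNIT_COLUMNS + ["taxon", "count"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[WebUnitKey, dict[str, int]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        unit = _unit_from_row(row, design, i)
        taxon = str(row["taxon"])
        count = int(row["count"])
        if count < 0:
            raise ValueError(f"{path} row {i}: negative count {count} for {taxon!r}")
        unit_counts = out.setdefault(unit, {})
        if taxon in unit_counts:
            raise ValueError(f"{path} row {i}: duplicate ({unit}, {taxon!r}) row")
        unit_counts[taxon] = count
    return out


def write_community(samples: Iterable[CommunitySample], pitfall_path, tiller_path) -> None:
    """Write community samples back to the two long-format CSVs."""
    prows, trows = [], []
    for s in samples:
        base = {
            "year": s.unit.year,
            "field": s.unit.field,
            "treatment": s.unit.treatment,
            "plot": s.unit.plot,
            "session": s.unit.session,
        }
        for taxon, c in s.pitfall_counts.items():
            prows.append({**base, "taxon": taxon, "count": c})
        for taxon, c in s.tiller_aphid_counts.items():
            trows.append({**base, "taxon": taxon, "count": c})
    cols = UNIT_COLUMNS + ["taxon", "count"]
    write_table(pd.DataFrame(prows, columns=cols), pitfall_path)
    write_table(pd.DataFrame(trows, columns=cols), tiller_path)


def write_table(table, path: str | Path) -> None:
    """Write any tabular result to CSV with a stable column order and floats at
    10 significant digits, so that write->read round-trips within 1e-9."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def design_from_mapping(d: dict) -> DesignSpec:
    """Build a DesignSpec from a plain mapping (e.g. parsed YAML)."""
    kwargs = dict(d)
    kwargs["years"] = [str(y) for y in kwargs["years"]]
    kwargs["sessions_per_year"] = {
        str(k): int(v) for k, v in kwargs["sessions_per_year"].items()
    }
    return DesignSpec(**kwargs)


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file; the ``design`` key is materialized into
    a :class:`DesignSpec` and returned under ``config["design"]``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "design" in cfg:
        cfg["design"] = design_from_mapping(cfg["design"])
    return cfg
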