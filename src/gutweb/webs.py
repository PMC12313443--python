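"""Build per-unit predator × prey interaction webs from individual detections.

Each sampling unit's web holds, for every predator species captured there,
the mean detection proportion of each prey target across that species'
individuals: entry a_ij = (# individuals of species i positive for target j)
/ (# individuals of species i in the unit).  Self-detections are removed
beforehand, so a species' own assay target is always exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec, DetectionRecord, WebUnitKey

logger = logging.getLogger(__name__)

__all__ = ["InteractionWeb", "remove_self_detections", "build_webs", "web_marginals", "webs_table"]


@dataclass
class InteractionWeb:
    """Predator-species × prey-target matrix of mean detection proportions."""

    unit: WebUnitKey
    matrix: np.ndarray  # shape (n_species, n_targets), entries in [0, 1]
    row_labels: list[str]
    col_labels: list[str]
    n_individuals: dict[str, int]


def remove_self_detections(
    records: list[DetectionRecord], self_detection_map: dict[str, str]
) -> list[DetectionRecord]:
    """Zero each individual's detection of its own species' assay target.

    Records of species without a mapping pass through untouched.  Returns new
    records; the number of flipped 1 -> 0 cells is logged.
    """
    flipped = 0
    out = []
    for r in records:
        target = self_detection_map.get(r.predator_species)
        if target is not None and r.detections.get(target) == 1:
            det = dict(r.detections)
            det[target] = 0
            flipped += 1
            out.append(DetectionRecord(r.unit, r.predator_species, det))
        else:
            out.append(r)
    logger.info("removed %d self-detections", flipped)
    return out


def build_webs(
    records: list[DetectionRecord],
    design: DesignSpec,
    exclude_targets: list[str] | None = None,
) -> list[InteractionWeb]:
    """One web per sampling unit holding at least one record.

    Species captured in a unit contribute a row even if all their detections
    are zero — they were captured and tested; degenerate webs are flagged
    downstream, not dropped here.  ``exclude_targets`` removes prey columns
    (e.g. to drop intraguild links) before averaging.
    """
    targets = [t for t in design.prey_targets if not (exclude_targets and t in exclude_targets)]
    species_order = {s: i for i, s in enumerate(design.predator_species)}

    by_unit: dict[WebUnitKey, dict[str, list[DetectionRecord]]] = {}
    for r in records:
        by_unit.setdefault(r.unit, {}).setdefault(r.predator_species, []).append(r)

    webs = []
    for unit in sorted(by_unit):
        groups = by_unit[unit]
        rows = sorted(groups, key=lambda s: species_order.get(s, len(species_order)))
        matrix = np.zeros((len(rows), len(targets)))
        n_ind = {}
        for i, sp in enumerate(rows):
            recs = groups[sp]
            n_ind[sp] = len(recs)
            for j, tgt in enumerate(targets):
                matrix[i, j] = sum(r.detections[tgt] for r in recs) / len(recs)
        webs.append(InteractionWeb(unit, matrix, rows, list(targets), n_ind))
    return webs


def web_marginals(web: InteractionWeb) -> tuple[np.ndarray, np.ndarray, float]:
    """Row totals A_i, column totals A_j and grand total m of a web's matrix."""
    row = web.matrix.sum(axis=1)
    col = web.matrix.sum(axis=0)
    m = float(web.matrix.sum())
    return row, col, m


def webs_table(webs: list[InteractionWeb]) -> pd.DataFrame:
    """Long-format view of a collection of webs (one row per species × target)."""
    rows = []
    for w in webs:
        for i, sp in enumerate(w.row_labels):
            for j, tgt in enumerate(w.col_labels):
                rows.append(
                    {
                        "year": w.unit.year,
                        "field": w.unit.field,
                        "treatment": w.unit.treatment,
                        "plot": w.unit.plot,
                        "session": w.unit.session,
                        "predator_species": sp,
                        "prey_target": tgt,
                        "proportion": w.matrix[i, j],
                        "n_individuals": w.n_individuals[sp],
                    }
                )
    cols = [
        "year", "field", "treatment", "plot", "session",
        "predator_species", "prey_target", "proportion", "n_individuals",
    ]
    return pd.DataFrame(rows, columns=cols)
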