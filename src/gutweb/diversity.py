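"""Shannon–Weaver diversity per sampling unit and tidy time-series export.

Predator diversity uses the pitfall-trap counts of the declared predator
taxa.  Prey diversity uses the declared prey taxa after the tiller
substitution: aphids are plant-dwelling, so their pitfall counts are
replaced by the counts obtained from the collected barley tillers before
computing H = -sum p_i ln p_i.  The assembled tidy table (one row per unit,
with SES and both diversities) is the contract for downstream model fitting
and plotting; mixed-model and GAM fits themselves are standard package
territory and are not reimplemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .design import CommunitySample, DesignSpec, WebUnitKey
from .nullmodels import SESResult

__all__ = [
    "DiversityResult",
    "shannon_diversity",
    "substitute_aphid_counts",
    "prey_diversity",
    "predator_diversity",
    "diversity_results",
    "diversity_table",
    "assemble_timeseries",
]


@dataclass
class DiversityResult:
    unit: WebUnitKey
    predator_H: float  # NaN when undefined (no positive counts)
    prey_H: float
    predator_richness: int
    prey_richness: int


def shannon_diversity(counts: Mapping[str, float], base: float = math.e) -> float:
    """Shannon–Weaver H = -sum p_i log p_i over taxa with positive counts.

    Natural log by default; ``base`` is configurable for cross-checks against
    toolchains using log2 or log10.
    """
    values = np.array([c for c in counts.values() if c > 0], dtype=float)
    if values.size == 0 or values.sum() <= 0:
        raise ValueError("undefined: no positive counts")
    return float(_scipy_entropy(values, base=base))


def substitute_aphid_counts(
    sample: CommunitySample, aphid_taxa: Sequence[str]
) -> dict[str, float]:
    """Prey-community count vector with aphid pitfall counts replaced by
    tiller counts (including replacement by zero); non-aphid taxa untouched."""
    out: dict[str, float] = dict(sample.pitfall_counts)
    for taxon in aphid_taxa:
        if taxon in out or taxon in sample.tiller_aphid_counts:
            out[taxon] = sample.tiller_aphid_counts.get(taxon, 0)
    return out


def prey_diversity(
    sample: CommunitySample,
    prey_taxa: Sequence[str],
    aphid_taxa: Sequence[str] = (),
    base: float = math.e,
) -> float:
    """Shannon diversity of the declared prey taxa, after aphid substitution."""
    counts = substitute_aphid_counts(sample, aphid_taxa)
    return shannon_diversity({t: counts.get(t, 0) for t in prey_taxa}, base=base)


def predator_diversity(
    sample: CommunitySample, predator_taxa: Sequence[str], base: float = math.e
) -> float:
    """Shannon diversity of the declared predator taxa from pitfall counts."""
    return shannon_diversity(
        {t: sample.pitfall_counts.get(t, 0) for t in predator_taxa}, base=base
    )


def diversity_results(
    samples: Sequence[CommunitySample],
    predator_taxa: Sequence[str],
    prey_taxa: Sequence[str],
    aphid_taxa: Sequence[str] = (),
    base: float = math.e,
) -> list[DiversityResult]:
    """Per-unit predator and prey diversity; undefined communities yield NaN
    (the unit is flagged, not dropped)."""
    out = []
    for s in samples:
        prey_counts = substitute_aphid_counts(s, aphid_taxa)
        pred = {t: s.pitfall_counts.get(t, 0) for t in predator_taxa}
        prey = {t: prey_counts.get(t, 0) for t in prey_taxa}
        try:
            pH = shannon_diversity(pred, base=base)
        except ValueError:
            pH = float("nan")
        try:
            yH = shannon_diversity(prey, base=base)
        except ValueError:
            yH = float("nan")
        out.append(
            DiversityResult(
                s.unit, pH, yH,
                sum(1 for v in pred.values() if v > 0),
                sum(1 for v in prey.values() if v > 0),
            )
        )
    return out


def diversity_table(results: Sequence[DiversityResult]) -> pd.DataFrame:
    rows = [
        {
            "year": r.unit.year, "field": r.unit.field, "treatment": r.unit.treatment,
            "plot": r.unit.plot, "session": r.unit.session,
            "predator_H": r.predator_H, "prey_H": r.prey_H,
            "predator_richness": r.predator_richness, "prey_richness": r.prey_richness,
        }
        for r in results
    ]
    cols = ["year", "field", "treatment", "plot", "session",
            "predator_H", "prey_H", "predator_richness", "prey_richness"]
    return pd.DataFrame(rows, columns=cols)


def assemble_timeseries(
    ses: Sequence[SESResult],
    diversity: Sequence[DiversityResult],
    design: DesignSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join SES and diversity per unit into the tidy time series.

    Returns ``(tidy, summary)``: one tidy row per unit (year, field,
    treatment, plot, session, ses_d, predator_H, prey_H, flags) and a
    per-year × session × treatment summary (mean, SE, n) — the aggregation
    behind the seasonal SES/diversity figures.  Units present in one input
    but not the other raise an error listing the orphans.
    """
    ses_by_unit = {r.unit: r for r in ses}
    div_by_unit = {r.unit: r for r in diversity}
    orphan_ses = sorted(set(ses_by_unit) - set(div_by_unit))
    orphan_div = sorted(set(div_by_unit) - set(ses_by_unit))
    if orphan_ses or orphan_div:
        parts = []
        if orphan_ses:
            parts.append(f"units with SES but no diversity: {[str(u) for u in orphan_ses]}")
        if orphan_div:
            parts.append(f"units with diversity but no SES: {[str(u) for u in orphan_div]}")
        raise ValueError("; ".join(parts))

    rows = []
    for unit in sorted(ses_by_unit):
        s, d = ses_by_unit[unit], div_by_unit[unit]
        rows.append(
            {
                "year": unit.year, "field": unit.field, "treatment": unit.treatment,
                "plot": unit.plot, "session": unit.session,
                "observed_H2prime": s.observed_H2prime, "ses_d": s.ses_d,
                "predator_H": d.predator_H, "prey_H": d.prey_H,
                "predator_richness": d.predator_richness, "prey_richness": d.prey_richness,
                "flag": s.flag,
            }
        )
    tidy = pd.DataFrame(
        rows,
        columns=["year", "field", "treatment", "plot", "session", "observed_H2prime",
                 "ses_d", "predator_H", "prey_H", "predator_richness", "prey_richness",
                 "flag"],
    )

    grouped = tidy.groupby(["year", "session", "treatment"], sort=True)
    summary_rows = []
    for (year, session, treatment), g in grouped:
        row = {"year": year, "session": session, "treatment": treatment, "n": len(g)}
        for col in ("ses_d", "predator_H", "prey_H"):
            vals = g[col].dropna()
            row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{col}_se"] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        summary_rows.append(row)
    summary = pd.DataFrame(
        summary_rows,
        columns=["year", "session", "treatment", "n",
                 "ses_d_mean", "ses_d_se", "predator_H_mean", "predator_H_se",
                 "prey_H_mean", "prey_H_se"],
    )
    return tidy, summary
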