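"""Randomization null models and Cohen's-d standardized effect sizes for H2'.

Observed specialization on its own has no reference point: a web built from
few individuals can look specialized by chance.  The null model therefore
recombines the individual-level diet data points many times, rebuilds the
web each time, and recomputes H2'; the observed value is then expressed as
a Cohen's-d standardized effect size

    ses_d = (observed H2' - mean(null H2')) / sd(null H2')

with positive values meaning the real web is more specialized than expected
under random recombination.

Three shuffling strategies are provided.  The default, ``prey_label_shuffle``,
permutes each prey target's binary detection column independently across all
individuals of a stratum (year by default): it preserves every prey's total
detection count and every individual's unit/species assignment, isolating
exactly the predator-species × prey association that H2' measures.
``cell_shuffle`` permutes all cells jointly (preserving only the grand total
of detections) and ``within_unit_shuffle`` restricts the column permutation
to each sampling unit.  Cells that would be self-detections are never part
of any permutation, so shuffled data remain self-detection-free and prey
column totals are conserved exactly.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec, DetectionRecord, WebUnitKey
from .specialization import h2_prime
from .webs import InteractionWeb

logger = logging.getLogger(__name__)

__all__ = [
    "NullConfig",
    "SESResult",
    "shuffle_detections",
    "null_distribution",
    "cohens_d_ses",
    "run_ses",
    "ses_table",
]

STRATEGIES = ("prey_label_shuffle", "cell_shuffle", "within_unit_shuffle")
SCOPES = ("year", "treatment", "global")


@dataclass
class NullConfig:
    """Configuration of the randomization null.

    ``n_randomizations`` defaults to a desk-scale 999; the field-study scale
    of 99,999 random webs is available by configuration.
    """

    n_randomizations: int = 999
    strategy: str = "prey_label_shuffle"
    scope: str = "year"
    seed: int = 0
    min_valid: int = 30  # fewer valid null webs than this flags the unit

    def __post_init__(self) -> None:
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}; choose from {SCOPES}")


@dataclass
class SESResult:
    unit: WebUnitKey | None
    observed_H2prime: float
    null_mean: float
    null_sd: float
    n_null_valid: int
    ses_d: float  # NaN when flagged
    flag: str = ""


def _unit_seed(unit: WebUnitKey) -> int:
    """Stable per-unit sub-seed: results are independent of processing order."""
    return zlib.crc32(str(unit).encode()) & 0x7FFFFFFF  # < 2**31


def _stratum_key(unit: WebUnitKey, scope: str):
    if scope == "year":
        return unit.year
    if scope == "treatment":
        return (unit.year, unit.treatment)
    return "all"


class _Stratum:
    """Matrix view of the detection records of one shuffling stratum.

    Rows are individuals in a canonical sort order (unit, species, detection
    vector), making every downstream computation independent of the input
    record order.  Eligibility is per species × column: a species' own
    self-detection column never participates in any shuffle.
    """

    def __init__(self, records: list[DetectionRecord], design: DesignSpec):
        self.design = design
        self.targets = list(design.prey_targets)
        t_index = {t: j for j, t in enumerate(self.targets)}
        sp_order = {s: i for i, s in enumerate(design.predator_species)}

        def sort_key(r: DetectionRecord):
            return (r.unit, sp_order.get(r.predator_species, 99), tuple(
                r.detections[t] for t in self.targets))

        records = sorted(records, key=sort_key)
        self.records = records
        n, T = len(records), len(self.targets)
        self.D = np.zeros((n, T), dtype=np.uint8)
        self.species = np.empty(n, dtype=object)
        self.units = np.empty(n, dtype=object)
        for i, r in enumerate(records):
            self.species[i] = r.predator_species
            self.units[i] = r.unit
            for t, v in r.detections.items():
                self.D[i, t_index[t]] = v

        # per-unit species groups: unit -> ordered list of (species, row indices)
        self.unit_groups: dict[WebUnitKey, list[tuple[str, np.ndarray]]] = {}
        for unit in sorted(set(self.units)):
            mask = np.array([u == unit for u in self.units])
            rows = np.where(mask)[0]
            groups = []
            for sp in design.predator_species:
                g = rows[self.species[rows] == sp]
                if len(g):
                    groups.append((sp, g))
            self.unit_groups[unit] = groups

        # per-column eligible rows (species whose self target is not this column)
        self.self_col = {
            sp: t_index[t] for sp, t in design.self_detection_map.items() if t in t_index
        }
        self.col_eligible_rows = []
        sp_selfcol = np.array([self.self_col.get(s, -1) for s in self.species])
        for j in range(T):
            self.col_eligible_rows.append(np.where(sp_selfcol != j)[0])

    def observed_web(self, unit: WebUnitKey) -> InteractionWeb:
        groups = self.unit_groups[unit]
        matrix = np.array([self.D[g].mean(axis=0) for _, g in groups])
        return InteractionWeb(
            unit, matrix, [sp for sp, _ in groups], list(self.targets),
            {sp: len(g) for sp, g in groups},
        )

    # ---- fast per-unit null draws -------------------------------------
    # A full column permutation followed by reading the unit's rows places
    # the column's 1s uniformly without replacement over the eligible rows;
    # the per-species counts landing in the unit are therefore exactly
    # multivariate-hypergeometric, which is what is sampled here.

    def null_web_matrix(self, unit: WebUnitKey, strategy: str, rng) -> np.ndarray:
        groups = self.unit_groups[unit]
        T = len(self.targets)
        matrix = np.zeros((len(groups), T))
        sizes = np.array([len(g) for _, g in groups])
        if strategy == "prey_label_shuffle":
            for j in range(T):
                elig = self.col_eligible_rows[j]
                K = int(self.D[elig, j].sum())
                colors, gi = [], []
                for k, (sp, g) in enumerate(groups):
                    if self.self_col.get(sp, -1) != j:
                        colors.append(len(g))
                        gi.append(k)
                if not colors:
                    continue
                rest = len(elig) - sum(colors)
                counts = rng.multivariate_hypergeometric(colors + [rest], K)
                for k, cnt in zip(gi, counts[:-1]):
                    matrix[k, j] = cnt / sizes[k]
        elif strategy == "cell_shuffle":
            # pool all eligible cells of the stratum; the grand total of 1s
            # is redistributed uniformly over them
            K = 0
            total_cells = 0
            for j in range(len(self.targets)):
                elig = self.col_eligible_rows[j]
                K += int(self.D[elig, j].sum())
                total_cells += len(elig)
            colors, blocks = [], []
            for k, (sp, g) in enumerate(groups):
                for j in range(T):
                    if self.self_col.get(sp, -1) != j:
                        colors.append(len(g))
                        blocks.append((k, j))
            rest = total_cells - sum(colors)
            counts = rng.multivariate_hypergeometric(colors + [rest], K)
            for (k, j), cnt in zip(blocks, counts[:-1]):
                matrix[k, j] = cnt / sizes[k]
        elif strategy == "within_unit_shuffle":
            for j in range(T):
                colors, gi, K = [], [], 0
                for k, (sp, g) in enumerate(groups):
                    if self.self_col.get(sp, -1) != j:
                        colors.append(len(g))
                        gi.append(k)
                        K += int(self.D[g, j].sum())
                if not colors:
                    continue
                counts = rng.multivariate_hypergeometric(colors, K)
                for k, cnt in zip(gi, counts):
                    matrix[k, j] = cnt / sizes[k]
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        return matrix


def shuffle_detections(
    records: list[DetectionRecord],
    design: DesignSpec,
    config: NullConfig,
    rng: np.random.Generator | None = None,
) -> list[DetectionRecord]:
    """Return one randomly recombined copy of the detection dataset.

    The output has the same records (unit, species) in the same order; only
    the binary detection values move, according to ``config.strategy`` within
    each ``config.scope`` stratum.  Self-detection cells never participate,
    so prey column totals are conserved exactly under the label-preserving
    strategies.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t_index = {t: j for j, t in enumerate(design.prey_targets)}
    self_col = {sp: t_index[t] for sp, t in design.self_detection_map.items() if t in t_index}

    n, T = len(records), len(design.prey_targets)
    D = np.zeros((n, T), dtype=np.uint8)
    for i, r in enumerate(records):
        for t, v in r.detections.items():
            D[i, t_index[t]] = v
    sp_selfcol = np.array([self_col.get(r.predator_species, -1) for r in records])

    if config.strategy == "within_unit_shuffle":
        strata = [np.where([r.unit == u for r in records])[0]
                  for u in sorted({r.unit for r in records})]
    else:
        keys = [_stratum_key(r.unit, config.scope) for r in records]
        strata = [np.array([i for i, k in enumerate(keys) if k == key])
                  for key in sorted(set(keys), key=str)]

    out = D.copy()
    for rows in strata:
        if config.strategy == "cell_shuffle":
            cells = [(i, j) for i in rows for j in range(T) if sp_selfcol[i] != j]
            vals = np.array([D[i, j] for i, j in cells])
            vals = vals[rng.permutation(len(vals))]
            for (i, j), v in zip(cells, vals):
                out[i, j] = v
        else:  # prey_label_shuffle / within_unit_shuffle: column-wise
            for j in range(T):
                elig = rows[sp_selfcol[rows] != j]
                if len(elig) > 1:
                    out[elig, j] = D[elig, j][rng.permutation(len(elig))]

    shuffled = []
    for i, r in enumerate(records):
        det = {t: int(out[i, j]) for t, j in t_index.items()}
        shuffled.append(DetectionRecord(r.unit, r.predator_species, det))
    return shuffled


def null_distribution(
    records: list[DetectionRecord],
    design: DesignSpec,
    unit: WebUnitKey,
    config: NullConfig,
) -> tuple[np.ndarray, int]:
    """Null H2' draws for one sampling unit.

    Repeats ``n_randomizations`` times: recombine the unit's stratum, rebuild
    the unit's web, compute H2'.  Returns the valid draws and the count of
    invalid (degenerate/empty) null webs; raises if every draw is invalid.
    Reproducible from the master seed via a per-unit sub-seed.
    """
    stratum_records = [
        r for r in records
        if _stratum_key(r.unit, config.scope) == _stratum_key(unit, config.scope)
    ]
    stratum = _Stratum(stratum_records, design)
    if unit not in stratum.unit_groups:
        raise ValueError(f"unit {unit} has no detection records")
    draws, n_invalid = _null_draws(stratum, unit, config)
    if len(draws) == 0:
        raise ValueError(f"all {config.n_randomizations} null webs invalid for unit {unit}")
    return draws, n_invalid


def _null_draws(stratum: _Stratum, unit: WebUnitKey, config: NullConfig):
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, _unit_seed(unit)])
    )
    draws = []
    n_invalid = 0
    for _ in range(config.n_randomizations):
        matrix = stratum.null_web_matrix(unit, config.strategy, rng)
        res = h2_prime(matrix, unit=unit)
        if res.valid:
            draws.append(res.H2prime)
        else:
            n_invalid += 1
    return np.array(draws), n_invalid


def cohens_d_ses(observed: float, null_draws: np.ndarray) -> SESResult:
    """Cohen's-d standardized effect size of one observed H2' against its null.

    With a single observed web per unit, the effect is standardized by the
    null distribution's own standard deviation (denominator n-1): positive
    values mean the observed web is more specialized than random.
    """
    null_draws = np.asarray(null_draws, dtype=float)
    if len(null_draws) < 2:
        raise ValueError("need at least 2 valid null draws")
    mean = float(null_draws.mean())
    sd = float(null_draws.std(ddof=1))
    if sd == 0:
        return SESResult(None, observed, mean, sd, len(null_draws), np.nan, "zero_sd")
    return SESResult(None, observed, mean, sd, len(null_draws), (observed - mean) / sd)


def run_ses(
    records: list[DetectionRecord],
    design: DesignSpec,
    config: NullConfig,
) -> list[SESResult]:
    """Per-unit SES over the whole dataset.

    Records must already be self-detection-cleaned.  Each unit consumes an
    independent random stream derived from the master seed and the unit key,
    so the output is identical under any processing order or partitioning.
    Units whose observed web is degenerate are excluded (logged), mirroring
    the exclusion of such webs from downstream models.
    """
    if not records:
        logger.warning("run_ses called with no records")
        return []
    results = []
    by_stratum: dict[object, list[DetectionRecord]] = {}
    for r in records:
        by_stratum.setdefault(_stratum_key(r.unit, config.scope), []).append(r)
    for key in sorted(by_stratum, key=str):
        stratum = _Stratum(by_stratum[key], design)
        for unit in sorted(stratum.unit_groups):
            obs = h2_prime(stratum.observed_web(unit))
            if not obs.valid:
                logger.info("unit %s excluded: observed web %s", unit, obs.reason)
                continue
            draws, n_invalid = _null_draws(stratum, unit, config)
            if len(draws) < 2:
                results.append(
                    SESResult(unit, obs.H2prime, np.nan, np.nan, len(draws), np.nan,
                              "too_few_valid_nulls")
                )
                continue
            res = cohens_d_ses(obs.H2prime, draws)
            flag = res.flag
            if len(draws) < config.min_valid and not flag:
                flag = "too_few_valid_nulls"
            results.append(
                SESResult(unit, obs.H2prime, res.null_mean, res.null_sd,
                          len(draws), res.ses_d, flag)
            )
    results.sort(key=lambda r: r.unit)
    return results


def ses_table(results: list[SESResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        u = r.unit
        rows.append(
            {
                "year": u.year, "field": u.field, "treatment": u.treatment,
                "plot": u.plot, "session": u.session,
                "observed_H2prime": r.observed_H2prime,
                "null_mean": r.null_mean, "null_sd": r.null_sd,
                "n_null_valid": r.n_null_valid, "ses_d": r.ses_d, "flag": r.flag,
            }
        )
    cols = ["year", "field", "treatment", "plot", "session", "observed_H2prime",
            "null_mean", "null_sd", "n_null_valid", "ses_d", "flag"]
    return pd.DataFrame(rows, columns=cols)
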