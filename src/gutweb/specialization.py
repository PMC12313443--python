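"""Network-level specialization H2' of a bipartite interaction web.

H2' standardizes the two-dimensional Shannon entropy H2 of the interaction
matrix by the extremes attainable under the matrix's marginal totals:

    H2' = (H2max - H2) / (H2max - H2min)

so that 0 means maximal generalization (every consumer's diet proportional
to overall resource availability) and 1 maximal specialization (complete
diet partitioning).  The webs here hold real-valued averaged detection
proportions, so the continuous formulation is used throughout: H2max is the
entropy of the independence table implied by the marginals, and H2min comes
from a greedy mass-concentration heuristic.  Natural logarithms everywhere;
H2' itself is base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import WebUnitKey
from .webs import InteractionWeb, web_marginals

__all__ = [
    "SpecializationResult",
    "shannon_2d",
    "h2_max",
    "h2_min",
    "h2_prime",
    "specialization_table",
]

DEGENERACY_TOL = 1e-9


@dataclass
class SpecializationResult:
    unit: WebUnitKey | None
    H2: float
    H2min: float
    H2max: float
    H2prime: float  # NaN when invalid
    valid: bool
    reason: str = ""


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy -sum p ln p with the 0 ln 0 := 0 convention."""
    p = np.asarray(p, dtype=float).ravel()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def shannon_2d(matrix: np.ndarray) -> float:
    """Two-dimensional Shannon entropy of a non-negative matrix.

    Entries are normalized by the grand total m, so the result is invariant
    to rescaling the whole matrix.  Raises for an all-zero matrix.
    """
    a = np.asarray(matrix, dtype=float)
    if np.any(a < 0):
        raise ValueError("matrix entries must be non-negative")
    m = a.sum()
    if m <= 0:
        raise ValueError("undefined: matrix has zero total interaction mass")
    return _entropy(a / m)


def _check_marginals(row_totals, col_totals) -> tuple[np.ndarray, np.ndarray, float]:
    r = np.asarray(row_totals, dtype=float)
    c = np.asarray(col_totals, dtype=float)
    m = r.sum()
    if m <= 0:
        raise ValueError("undefined: marginals sum to zero")
    if abs(m - c.sum()) > 1e-9 * max(1.0, m):
        raise ValueError(f"row total {m} and column total {c.sum()} disagree")
    return r, c, float(m)


def h2_max(row_totals, col_totals) -> float:
    """Maximum two-dimensional entropy consistent with the marginals.

    Attained by the independence table p_ij = (A_i/m)(A_j/m); equals the sum
    of the two marginal entropies.
    """
    r, c, m = _check_marginals(row_totals, col_totals)
    return _entropy(r / m) + _entropy(c / m)


def h2_min(row_totals, col_totals) -> float:
    """Greedy lower entropy extreme consistent with the marginals.

    Mass is concentrated by repeatedly allocating min(remaining row,
    remaining column) to a single cell.  At each step, a row and column with
    exactly equal remaining mass are paired first (this clears both at once
    and places their whole mass in one cell); otherwise the largest remaining
    row total is paired with the largest remaining column total.  Ties break
    on the lowest original index, making the allocation deterministic.

    The result is a vertex of the transportation polytope and therefore an
    upper bound on the true minimum entropy coupling (whose exact computation
    is intractable in general); on small integer-marginal instances the
    allocation attains the exhaustive-enumeration minimum.
    """
    r, c, m = _check_marginals(row_totals, col_totals)
    r = r.copy() / m
    c = c.copy() / m
    tol = 1e-12
    cells: list[float] = []
    # each step zeroes out at least one row or column: at most len(r)+len(c) steps
    for _ in range(len(r) + len(c) + 1):
        live_r = np.where(r > tol)[0]
        live_c = np.where(c > tol)[0]
        if len(live_r) == 0 or len(live_c) == 0:
            break
        pair = None
        for i in live_r:  # exact-match rule, lowest indices first
            for j in live_c:
                if abs(r[i] - c[j]) <= tol:
                    pair = (int(i), int(j))
                    break
            if pair:
                break
        if pair is None:
            i = live_r[int(np.argmax(r[live_r]))]  # first maximum = lowest index
            j = live_c[int(np.argmax(c[live_c]))]
            pair = (int(i), int(j))
        i, j = pair
        q = min(r[i], c[j])
        cells.append(q)
        r[i] -= q
        c[j] -= q
    return _entropy(np.array(cells))


def h2_prime(
    web: InteractionWeb | np.ndarray,
    unit: WebUnitKey | None = None,
    integer_scale: float | None = None,
) -> SpecializationResult:
    """Standardized specialization H2' = (H2max - H2)/(H2max - H2min), in [0, 1].

    Invalidity is a result state, never an exception: ``reason`` is "empty"
    when the web carries no interaction mass and "degenerate" when the
    marginals admit no entropy range (single predator species or single prey
    target), mirroring the exclusion of such units from downstream models.

    ``integer_scale`` optionally applies a scaled-integer approximation for
    cross-checks against count-based implementations: the matrix is
    multiplied by the factor and rounded before the index is computed.
    """
    if isinstance(web, InteractionWeb):
        matrix = web.matrix
        unit = web.unit
    else:
        matrix = np.asarray(web, dtype=float)
    if integer_scale is not None:
        matrix = np.round(matrix * float(integer_scale))

    m = matrix.sum()
    if m <= 0:
        return SpecializationResult(unit, np.nan, np.nan, np.nan, np.nan, False, "empty")
    row = matrix.sum(axis=1)
    col = matrix.sum(axis=0)
    H2 = shannon_2d(matrix)
    H2max = h2_max(row, col)
    H2min = h2_min(row, col)
    if H2max - H2min < DEGENERACY_TOL:
        return SpecializationResult(unit, H2, H2min, H2max, np.nan, False, "degenerate")
    value = (H2max - H2) / (H2max - H2min)
    return SpecializationResult(unit, H2, H2min, H2max, float(np.clip(value, 0.0, 1.0)), True)


def specialization_table(results: list[SpecializationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        u = r.unit
        rows.append(
            {
                "year": u.year if u else "",
                "field": u.field if u else "",
                "treatment": u.treatment if u else "",
                "plot": u.plot if u else "",
                "session": u.session if u else "",
                "H2": r.H2,
                "H2min": r.H2min,
                "H2max": r.H2max,
                "H2prime": r.H2prime,
                "valid": r.valid,
                "reason": r.reason,
            }
        )
    cols = ["year", "field", "treatment", "plot", "session",
            "H2", "H2min", "H2max", "H2prime", "valid", "reason"]
    return pd.DataFrame(rows, columns=cols)
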