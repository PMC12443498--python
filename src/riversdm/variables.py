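"""Collinearity screening of candidate environmental variables.

A Pearson correlation matrix is computed over the site table (presence
plus pseudoabsence cells), then a greedy scan in ecological priority
order keeps each variable only if |r| < threshold (default 0.75) against
every variable already kept.  "Ecological relevance" is operationalized
as the caller-supplied priority order; the default is the input column
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SelectionError


@dataclass
class SelectionResult:
    kept: list[str]
    correlation_matrix: pd.DataFrame
    threshold: float


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson r for every variable pair; errors on zero-variance columns."""
    if table.shape[0] < 2:
        raise SelectionError("variable table needs at least 2 rows")
    if table.isna().any().any():
        raise SelectionError("variable table contains missing values")
    variances = table.var(axis=0, ddof=0)
    dead = variances[variances == 0].index.tolist()
    if dead:
        raise SelectionError(f"zero-variance column(s): {', '.join(dead)}")
    values = table.to_numpy(dtype=float)
    corr = np.corrcoef(values, rowvar=False)
    return pd.DataFrame(corr, index=table.columns, columns=table.columns)


def select_uncorrelated(
    matrix: pd.DataFrame,
    priority_order: list[str] | None = None,
    threshold: float = 0.75,
) -> SelectionResult:
    """Greedy prefix scan: keep a variable iff |r| < threshold against all
    already-kept variables, visiting candidates in priority order."""
    candidates = list(matrix.columns)
    if not candidates:
        raise SelectionError("empty candidate list")
    if priority_order is None:
        priority_order = candidates
    if sorted(priority_order) != sorted(candidates):
        raise SelectionError("priority_order must be a permutation of the candidates")
    kept: list[str] = []
    for name in priority_order:
        if all(abs(matrix.loc[name, other]) < threshold for other in kept):
            kept.append(name)
    return SelectionResult(kept=kept, correlation_matrix=matrix, threshold=threshold)
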