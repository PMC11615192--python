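"""Trait–environment ordinary-least-squares regression matrix.

Each cell of the matrix is a simple OLS fit of one shell trait against one
environmental variable across sites, summarised by its coefficient of
determination r², the slope sign and a two-sided p-value from the classical
slope t-test on n−2 degrees of freedom. No multiple-testing correction is
applied. Cells with negative slopes are annotated as anti-correlations and
the best r² per trait column is marked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "RegressionMatrix",
    "ols_fit",
    "regression_matrix",
    "significance_class",
    "render_matrix",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided, slope t-test, n−2 df
    n: int

    @property
    def sign(self) -> str:
        return "negative" if self.slope < 0 else "positive"


@dataclass
class RegressionMatrix:
    """r² grid: environment variables × traits, with annotations."""

    rows: list[str]  # environment variables
    columns: list[str]  # traits
    cells: dict[tuple[str, str], RegressionResult]
    exclusion_set: tuple[int, ...] = ()

    def r2_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.cells[(r, c)].r_squared for c in self.columns] for r in self.rows],
            index=self.rows, columns=self.columns,
        )

    def best_per_column(self) -> dict[str, str]:
        """Environment variable with the highest r² for each trait."""
        return {
            c: max(self.rows, key=lambda r: self.cells[(r, c)].r_squared)
            for c in self.columns
        }

    def anti_correlations(self) -> set[tuple[str, str]]:
        return {key for key, cell in self.cells.items() if cell.slope < 0}


def ols_fit(x, y) -> RegressionResult:
    """Closed-form OLS of y on x.

    r² equals the squared Pearson correlation; the p-value comes from
    t = r·sqrt((n−2)/(1−r²)). Zero variance in either variable is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
    )


def regression_matrix(
    traits: pd.DataFrame,
    envs: pd.DataFrame,
    exclusion_set=(),
    logger=None,
) -> RegressionMatrix:
    """All pairwise trait × environment OLS fits over shared sites.

    Sites listed in ``exclusion_set`` are dropped from every cell. Within a
    cell, only pairwise-complete sites enter the fit; any exclusion is logged,
    never silent.
    """
    exclusion_set = tuple(exclusion_set)
    shared = traits.index.intersection(envs.index).difference(exclusion_set)
    if len(shared) == 0:
        raise ValueError("no shared sites between trait and environment tables")
    cells: dict[tuple[str, str], RegressionResult] = {}
    for env_name in envs.columns:
        for trait_name in traits.columns:
            x = envs.loc[shared, env_name]
            y = traits.loc[shared, trait_name]
            complete = x.notna() & y.notna()
            dropped = shared[~complete]
            if len(dropped) and logger is not None:
                logger.info(
                    "regression %s ~ %s: dropping incomplete sites %s",
                    trait_name, env_name, list(dropped),
                )
            cells[(env_name, trait_name)] = ols_fit(x[complete], y[complete])
    return RegressionMatrix(
        rows=list(envs.columns),
        columns=list(traits.columns),
        cells=cells,
        exclusion_set=exclusion_set,
    )


def significance_class(p: float) -> str:
    """Smallest applicable significance label: p<0.01, p<0.05, p<0.1, or ns."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    if p < 0.1:
        return "p<0.1"
    return "ns"


def render_matrix(matrix: RegressionMatrix, digits: int = 2) -> str:
    """Plain-text rendering: **bold** best cell per column, *italic* anti-correlation."""
    best = matrix.best_per_column()
    widths = {c: max(len(c), digits + 8) for c in matrix.columns}
    header = "env".ljust(24) + "".join(c.ljust(widths[c] + 2) for c in matrix.columns)
    lines = [header]
    for r in matrix.rows:
        parts = [r.ljust(24)]
        for c in matrix.columns:
            cell = matrix.cells[(r, c)]
            text = f"{cell.r_squared:.{digits}f}"
            if cell.slope < 0:
                text = f"*{text}*"
            if best[c] == r:
                text = f"**{text}**"
            parts.append(text.ljust(widths[c] + 2))
        lines.append("".join(parts))
    return "\n".join(lines)
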