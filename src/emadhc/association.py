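"""Cluster x satisfaction independence analysis.

A 2 x K contingency table (rows: positive, negative ratings; columns: kept
clusters) is tested with the Pearson chi2 test of independence (no
continuity correction, df = K - 1).  Cell-level direction is reported as
adjusted standardized residuals (Haberman form),

    (O - E) / sqrt(E * (1 - row_margin/n) * (1 - col_margin/n)),

which in a two-row table are exactly equal in magnitude and opposite in
sign within each column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import expected_freq

from emadhc.records import POSITIVE, NEGATIVE


class DegenerateTableError(ValueError):
    """Fewer than two clusters: independence is undefined."""


class ZeroMarginError(ValueError):
    """A row or column margin of the contingency table is zero."""


@dataclass
class ContingencyResult:
    """Outcome of the 2 x K chi2 test of independence."""

    table: pd.DataFrame  # rows: positive, negative; columns: cluster ids
    chi2_statistic: float
    df: int
    p_value: float
    stdres: pd.DataFrame  # adjusted standardized residuals, same shape
    row_margins: pd.Series
    col_margins: pd.Series

    @property
    def n(self) -> int:
        return int(self.table.values.sum())

    def to_dict(self) -> dict:
        return {
            "table": {str(c): self.table[c].to_dict() for c in self.table.columns},
            "chi2_statistic": self.chi2_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "stdres": {str(c): self.stdres[c].to_dict() for c in self.stdres.columns},
            "row_margins": self.row_margins.to_dict(),
            "col_margins": {str(k): int(v) for k, v in self.col_margins.items()},
        }


def build_contingency(
    assignment: Mapping[str, int], ratings: Mapping[str, str]
) -> pd.DataFrame:
    """Cross-tabulate kept-cluster assignment against binary ratings.

    Units absent from ``assignment`` (unclassified) are excluded.  Every
    classified unit must have a rating.
    """
    clusters = sorted(set(assignment.values()))
    if len(clusters) < 2:
        raise DegenerateTableError(
            f"need at least 2 clusters for an independence test, got {len(clusters)}"
        )
    table = pd.DataFrame(0, index=[POSITIVE, NEGATIVE], columns=clusters, dtype=int)
    for uid, cid in assignment.items():
        try:
            rating = ratings[uid]
        except KeyError:
            raise ValueError(f"classified unit {uid!r} has no satisfaction rating") from None
        table.loc[rating, cid] += 1
    return table


def chi2_independence(table: pd.DataFrame | np.ndarray) -> ContingencyResult:
    """Pearson chi2 test of independence on a 2 x K table.

    Raises :class:`ZeroMarginError` naming any empty row or column.
    """
    if isinstance(table, pd.DataFrame):
        frame = table.astype(float)
    else:
        arr = np.asarray(table, dtype=float)
        frame = pd.DataFrame(
            arr,
            index=[POSITIVE, NEGATIVE][: arr.shape[0]],
            columns=list(range(arr.shape[1])),
        )
    values = frame.values
    row_margins = values.sum(axis=1)
    col_margins = values.sum(axis=0)
    for label, margin in zip(frame.index, row_margins):
        if margin == 0:
            raise ZeroMarginError(f"row {label!r} has zero margin")
    for label, margin in zip(frame.columns, col_margins):
        if margin == 0:
            raise ZeroMarginError(f"column {label!r} has zero margin")

    n = values.sum()
    expected = expected_freq(values)
    chi2 = float(((values - expected) ** 2 / expected).sum())
    df = (values.shape[0] - 1) * (values.shape[1] - 1)
    p = chi2_upper_p(chi2, df)
    adjust = np.sqrt(
        expected
        * (1.0 - row_margins[:, None] / n)
        * (1.0 - col_margins[None, :] / n)
    )
    stdres = (values - expected) / adjust
    return ContingencyResult(
        table=frame.astype(int),
        chi2_statistic=chi2,
        df=df,
        p_value=p,
        stdres=pd.DataFrame(stdres, index=frame.index, columns=frame.columns),
        row_margins=pd.Series(row_margins.astype(int), index=frame.index),
        col_margins=pd.Series(col_margins.astype(int), index=frame.columns),
    )


def chi2_upper_p(statistic: float, df: int) -> float:
    """Upper-tail probability of the chi2 distribution."""
    return float(stats.chi2.sf(statistic, df))


def residual_heatmap_table(
    result: ContingencyResult, cluster_labels: Mapping[int, str] | Sequence[str] | None = None
) -> pd.DataFrame:
    """Long-format (cluster, rating, residual) table for plotting."""
    if cluster_labels is None:
        labels = {c: str(c) for c in result.stdres.columns}
    elif isinstance(cluster_labels, Mapping):
        labels = {c: cluster_labels.get(c, str(c)) for c in result.stdres.columns}
    else:
        labels = dict(zip(result.stdres.columns, cluster_labels))
    rows = []
    for cid in result.stdres.columns:
        for rating in result.stdres.index:
            rows.append(
                {
                    "cluster": labels[cid],
                    "rating": rating,
                    "residual": float(result.stdres.loc[rating, cid]),
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "rating", "residual"])
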