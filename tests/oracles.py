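"""Independent oracles used by the test suite.

Everything here recomputes quantities by brute force or through
general-purpose scipy routines, independently of the implementation paths
it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2_contingency


def phi2_scipy(top: np.ndarray, bottom: np.ndarray) -> float:
    """chi2/n of a 2 x V table via scipy, skipping zero-total columns."""
    table = np.vstack([top, bottom]).astype(float)
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 0.0
    stat = chi2_contingency(table, correction=False)[0]
    return float(stat / table.sum())


def chi2_2x2_scipy(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi2 of [[a, b], [c, d]] without continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0
    return float(chi2_contingency(table, correction=False)[0])


def exhaustive_best_phi2(X: np.ndarray) -> float:
    """Maximum chi2/n over every bipartition of the rows of ``X``.

    Enumerates all 2^(n-1) - 1 unordered bipartitions (n <= ~16).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    assert n >= 2
    best = 0.0
    # fix row 0 on side A to enumerate unordered bipartitions once
    for mask in range(1, 2 ** (n - 1)):
        side = np.zeros(n, dtype=bool)
        for i in range(n - 1):
            if mask >> i & 1:
                side[i + 1] = True
        a = X[~side].sum(axis=0)
        b = X[side].sum(axis=0)
        best = max(best, _phi2_direct(a, b))
    return best


def _phi2_direct(a: np.ndarray, b: np.ndarray) -> float:
    ra, rb = a.sum(), b.sum()
    if ra == 0 or rb == 0:
        return 0.0
    n = ra + rb
    c = a + b
    keep = c > 0
    ea = ra * c[keep] / n
    eb = rb * c[keep] / n
    chi2 = ((a[keep] - ea) ** 2 / ea).sum() + ((b[keep] - eb) ** 2 / eb).sum()
    return float(chi2 / n)


def random_binary_table(
    rng: np.random.Generator, n_units: int, n_forms: int, p: float = 0.4
) -> np.ndarray:
    """Random 0/1 table with no empty rows and no empty columns."""
    X = (rng.random((n_units, n_forms)) < p).astype(np.int8)
    for i in range(n_units):
        if X[i].sum() == 0:
            X[i, rng.integers(n_forms)] = 1
    for j in range(n_forms):
        if X[:, j].sum() == 0:
            X[rng.integers(n_units), j] = 1
    return X


def block_separable_table(
    rng: np.random.Generator, sizes: tuple[int, ...], forms_per_block: int = 3, p: float = 0.7
) -> tuple[np.ndarray, list[int]]:
    """Blocks of rows with pairwise disjoint vocabularies.

    Returns the table and a block label per row.  Each row has at least one
    form of its own block, so the block partition scores chi2/n = 1 for two
    blocks.
    """
    n = sum(sizes)
    V = forms_per_block * len(sizes)
    X = np.zeros((n, V), dtype=np.int8)
    labels: list[int] = []
    row = 0
    for k, size in enumerate(sizes):
        cols = slice(k * forms_per_block, (k + 1) * forms_per_block)
        for _ in range(size):
            block_row = (rng.random(forms_per_block) < p).astype(np.int8)
            if block_row.sum() == 0:
                block_row[rng.integers(forms_per_block)] = 1
            X[row, cols] = block_row
            labels.append(k)
            row += 1
    return X, labels


def adjusted_residual_direct(table: np.ndarray) -> np.ndarray:
    """Haberman adjusted standardized residuals, computed longhand."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    out = np.zeros_like(table)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = r[i] * c[j] / n
            denom = np.sqrt(e * (1 - r[i] / n) * (1 - c[j] / n))
            out[i, j] = (table[i, j] - e) / denom
    return out
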