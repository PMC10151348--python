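"""Association between hypervolume overlap and forest misclassification.

Both indices are proportions in [0, 1] with exact zeros (species pairs that
never overlap / are never confused), so each is shifted by a Stahel constant
c = q1^2 / q3 computed over its nonzero values before taking natural logs:
T = log(value + c). The association is then the correlation over all
k(k-1) directed heterospecific pairs (Pearson by default; Spearman exposed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["stahel_constant", "log_transform", "directed_pairs", "associate"]


def stahel_constant(values) -> float:
    """Stahel's shift for log-transforming data with zeros: the squared first
    quartile divided by the third quartile of the nonzero values (type-7
    linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float).ravel()
    nz = v[v != 0]
    if nz.size == 0:
        raise ValueError("all values are zero; Stahel constant undefined")
    q1 = float(np.quantile(nz, 0.25))
    q3 = float(np.quantile(nz, 0.75))
    return q1**2 / q3


def log_transform(values, constant: float) -> np.ndarray:
    """Elementwise natural log of (value + constant); monotone, finite at 0."""
    return np.log(np.asarray(values, dtype=float) + constant)


def directed_pairs(matrix: pd.DataFrame) -> np.ndarray:
    """Off-diagonal entries in a fixed row-major order: all k(k-1) directed
    heterospecific pairs."""
    m = matrix.to_numpy()
    k = m.shape[0]
    return np.array([m[i, j] for i in range(k) for j in range(k) if i != j])


def associate(
    t_hy: pd.DataFrame | np.ndarray,
    t_rm: pd.DataFrame | np.ndarray,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Correlation between transformed overlap and misclassification across
    all directed pairs: (r, p, N). Matrices must share species order."""
    a = directed_pairs(t_hy) if isinstance(t_hy, pd.DataFrame) else np.asarray(t_hy).ravel()
    b = directed_pairs(t_rm) if isinstance(t_rm, pd.DataFrame) else np.asarray(t_rm).ravel()
    if a.size != b.size:
        raise ValueError("matrices must cover the same ordered species pairs")
    if method == "pearson":
        res = stats.pearsonr(a, b)
    elif method == "spearman":
        res = stats.spearmanr(a, b)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue), int(a.size)
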