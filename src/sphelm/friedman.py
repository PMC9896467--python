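"""Tie-corrected Friedman rank test for comparing methods across datasets.

Given a k-methods x n-datasets score table, methods are ranked within
each dataset column ascending by score — the best method receives rank
k — with tied scores sharing the average of their rank positions.  The
Friedman statistic on the rank sums R_j,

    chi2_raw = 12 / (n k (k+1)) * sum_j R_j^2  -  3 n (k+1),

is divided by the tie-correction factor

    C = 1 - sum (t^3 - t) / (n (k^3 - k))

over all tie groups of size t, and referred to the chi-square
distribution with k-1 degrees of freedom.

The package ships the published benchmark AUC and AUPR tables for nine
DTI prediction methods over the four gold-standard datasets (enzyme,
GPCR, ion channel, nuclear receptor), loadable via
:func:`load_benchmark_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

__all__ = [
    "FriedmanResult",
    "friedman_ranks",
    "friedman_chi_square",
    "load_benchmark_table",
]


@dataclass
class FriedmanResult:
    methods: list[str]
    average_ranks: np.ndarray
    rank_sums: np.ndarray
    chi_square: float
    chi_square_raw: float
    tie_correction: float
    df: int
    p_value: float
    tie_groups: list[list[int]]  # per dataset, sizes t >= 2

    def to_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "average_ranks": self.average_ranks.tolist(),
            "chi_square": self.chi_square,
            "chi_square_raw": self.chi_square_raw,
            "tie_correction": self.tie_correction,
            "df": self.df,
            "p_value": self.p_value,
            "tie_groups": self.tie_groups,
        }

    def summary(self) -> str:
        lines = ["Friedman rank test (tie-corrected)", "-" * 40]
        order = np.argsort(-self.average_ranks, kind="stable")
        for i in order:
            lines.append(f"{self.methods[i]:<16s} average rank {self.average_ranks[i]:.2f}")
        lines.append("-" * 40)
        lines.append(
            f"chi-square = {self.chi_square:.3f}  (df = {self.df}, p = {self.p_value:.3g})"
        )
        return "\n".join(lines)


def _as_table(score_table) -> pd.DataFrame:
    if isinstance(score_table, pd.DataFrame):
        df = score_table.copy()
    else:
        arr = np.asarray(score_table, dtype=float)
        df = pd.DataFrame(arr)
        df.index = [f"method_{i}" for i in range(arr.shape[0])]
    values = df.to_numpy()
    if values.dtype.kind not in "fiu" or not np.isfinite(values.astype(float)).all():
        raise ValueError("score table must be fully numeric and finite")
    return df


def _rank_matrix(df: pd.DataFrame) -> np.ndarray:
    """(k, n) matrix of within-column ranks, best score = rank k."""
    return np.column_stack(
        [rankdata(df.iloc[:, col].to_numpy()) for col in range(df.shape[1])]
    )


def friedman_ranks(score_table) -> pd.Series:
    """Per-method average rank across datasets (higher = better score)."""
    df = _as_table(score_table)
    ranks = _rank_matrix(df)
    return pd.Series(ranks.mean(axis=1), index=df.index, name="average_rank")


def friedman_chi_square(score_table) -> FriedmanResult:
    """Tie-corrected Friedman statistic, df and p-value for a score table."""
    df_table = _as_table(score_table)
    k, n = df_table.shape
    if k < 3:
        raise ValueError("need at least 3 methods")
    if n < 2:
        raise ValueError("need at least 2 datasets")
    ranks = _rank_matrix(df_table)
    rank_sums = ranks.sum(axis=1)
    chi_raw = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)

    tie_groups: list[list[int]] = []
    tie_term = 0.0
    for col in range(n):
        _, counts = np.unique(df_table.iloc[:, col].to_numpy(), return_counts=True)
        groups = [int(t) for t in counts if t > 1]
        tie_groups.append(groups)
        tie_term += sum(t**3 - t for t in groups)
    correction = 1.0 - tie_term / (n * (k**3 - k))
    if correction <= 0.0:
        raise ValueError("statistic undefined under complete ties")
    chi_corrected = chi_raw / correction
    dof = k - 1
    return FriedmanResult(
        methods=list(df_table.index.astype(str)),
        average_ranks=ranks.mean(axis=1),
        rank_sums=rank_sums.astype(float),
        chi_square=float(chi_corrected),
        chi_square_raw=float(chi_raw),
        tie_correction=float(correction),
        df=dof,
        p_value=float(chi2.sf(chi_corrected, dof)),
        tie_groups=tie_groups,
    )


def load_benchmark_table(metric: str = "auc") -> pd.DataFrame:
    """Published benchmark scores: nine DTI methods x four datasets.

    ``metric`` is ``"auc"`` or ``"aupr"``; rows are methods, columns the
    E/GPCR/IC/NR gold-standard classes.
    """
    metric = metric.lower()
    if metric not in ("auc", "aupr"):
        raise ValueError("metric must be 'auc' or 'aupr'")
    ref = resources.files("sphelm.data") / f"benchmark_{metric}.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col=0)
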