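"""Coexpression screen: row-wise z-scores and mean-correlation ranking."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ExpressionMatrix", "load_expression", "zscore_rows", "coexpression_rank"]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with no missing entries."""

    values: pd.DataFrame  # index = gene names, columns = sample names

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)


def load_expression(path: Union[str, Path], sep: str = "\t") -> ExpressionMatrix:
    """Load a delimited genes x samples matrix; rows with missing data are
    dropped and logged."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    n_bad = int(df.isna().any(axis=1).sum())
    if n_bad:
        logger.warning("dropping %d rows with missing values", n_bad)
        df = df.dropna(axis=0)
    return ExpressionMatrix(df.astype(float))


def zscore_rows(m: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Standardize each row to mean 0, sd 1 (sample sd by default).

    Constant rows cannot be standardized; they are dropped with a warning
    rather than aborting the run.
    """
    sd = m.values.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping %d constant rows: %s", int(constant.sum()),
                       ", ".join(m.values.index[constant][:10]))
    kept = m.values.loc[~constant]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    return ExpressionMatrix(z)


def coexpression_rank(
    m: ExpressionMatrix,
    candidates: Sequence[str],
    replication_set: Sequence[str],
    top_k: int = 10,
    method: str = "pearson",
) -> List[Tuple[str, float]]:
    """Rank candidates by mean correlation with a replication gene set.

    Each candidate row is correlated with every replication-set row and the
    correlations averaged; candidates sorted descending, top_k returned.
    """
    if not replication_set:
        raise ValueError("replication gene set is empty")
    missing = [g for g in list(candidates) + list(replication_set) if g not in m.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")

    rep = m.values.loc[list(replication_set)].to_numpy()
    scores = []
    for gene in candidates:
        row = m.values.loc[gene].to_numpy()
        if method == "spearman":
            cors = [stats.spearmanr(row, r).statistic for r in rep]
        else:
            cors = [np.corrcoef(row, r)[0, 1] for r in rep]
        scores.append((gene, float(np.mean(cors))))
    scores.sort(key=lambda t: (-t[1], t[0]))
    return scores[:top_k]
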