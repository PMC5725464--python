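"""PCA-based alternative selection: per-gene first-principal-component
scores over the method profiles, thresholded with boxplot fences.

Genes are the observations and methods the variables; the direction of
maximal variance across methods summarizes each gene in one score, and
genes whose scores fall outside the whisker fences are kept as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arm import SelectionResult, iqr_select
from .errors import DataError, NumericalError
from .io import ProfileMatrix


@dataclass
class PcaSelection:
    """PC1 scores, the variance fraction PC1 explains, and the fence selection."""

    pc1_scores: pd.Series
    explained_frac: float
    loadings: pd.Series
    sign_anchor: str
    selection: SelectionResult


def pc1_select(matrix: ProfileMatrix, k: float = 1.5, scale: bool = False) -> PcaSelection:
    """Project complete-case genes on the first principal axis and select
    boxplot outliers of the scores.

    Columns (methods) are centered — and unit-scaled when ``scale`` — and
    PC1 is taken from the SVD of the centered submatrix. The score sign is
    fixed so the method with the largest |loading| loads positively, making
    output reproducible across linear-algebra backends. log2FC columns are
    unit-comparable, so the covariance (unscaled) PCA is the default.
    """
    sub = matrix.data.dropna(axis=0)
    if sub.shape[0] < 4:
        raise DataError(
            f"pc1_select needs >= 4 complete-case genes, got {sub.shape[0]}"
        )
    col_var = sub.var(axis=0, ddof=1)
    if float(col_var.sum()) == 0.0:
        raise NumericalError("profile matrix has zero total variance")
    if int((col_var > 0).sum()) < 2:
        raise NumericalError("pc1_select needs >= 2 methods with nonzero variance")

    centered = sub - sub.mean(axis=0)
    if scale:
        sd = sub.std(axis=0, ddof=1)
        if (sd == 0).any():
            zero = list(sd.index[sd == 0])
            raise NumericalError(f"cannot unit-scale zero-variance methods: {zero}")
        centered = centered / sd

    u, s, vt = np.linalg.svd(centered.to_numpy(float), full_matrices=False)
    loadings = vt[0]
    anchor_idx = int(np.argmax(np.abs(loadings)))
    sign = 1.0 if loadings[anchor_idx] > 0 else -1.0
    scores = pd.Series(sign * u[:, 0] * s[0], index=sub.index, name="pc1_score")
    explained = float(s[0] ** 2 / np.sum(s**2))
    selection = iqr_select(scores, k, statistic_name="pc1_score")
    return PcaSelection(
        pc1_scores=scores,
        explained_frac=explained,
        loadings=pd.Series(sign * loadings, index=sub.columns, name="pc1_loading"),
        sign_anchor=str(sub.columns[anchor_idx]),
        selection=selection,
    )
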