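"""Land-cover gradient scoring.

Reduces per-site proportions of seven land-cover classes to two principal
component scores that serve as regression predictors downstream. Proportions
are first renormalized over the land classes (coastal buffers can include
ocean), variance-stabilized with the arcsine-square-root transform, and
passed through an unscaled (covariance-matrix) PCA. Sign conventions are
fixed so PC1 reads forested (high) to developed (low) and PC2 rural (high)
to urban (low) in every landscape, making fitted slopes comparable across
runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import LANDCOVER_CLASSES

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Raised when the input has no variation to decompose."""


def arcsine_sqrt(p):
    """Arcsine-square-root transform ``arcsin(sqrt(p))`` for proportions.

    Monotone on [0, 1], mapping 0 -> 0 and 1 -> pi/2. Accepts scalars or
    arrays; values outside [0, 1] raise ``ValueError``.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return out.item() if np.isscalar(p) else out


@dataclass(frozen=True)
class LandcoverScores:
    """PCA scores and loadings of the land-cover composition.

    ``scores`` is a (site -> PC1, PC2) frame; ``loadings`` holds all
    principal axes (7 x n_components) so the transform is invertible;
    ``variance_explained`` gives the PC1 and PC2 fractions;
    ``column_means`` are the centring means of the transformed matrix.
    """

    scores: pd.DataFrame  # index: site, columns: PC1, PC2
    loadings: pd.DataFrame  # index: land-cover class, columns: PC1..PCk
    variance_explained: np.ndarray  # all components, descending
    column_means: np.ndarray
    full_scores: np.ndarray  # all components, site x k

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]

    @property
    def pc2(self) -> pd.Series:
        return self.scores["PC2"]

    def reconstruct(self) -> np.ndarray:
        """Back-transform all components to the arcsine-transformed matrix."""
        return self.full_scores @ self.loadings.to_numpy().T + self.column_means


def pca_scores(meta: pd.DataFrame) -> LandcoverScores:
    """Score sites on the anthropogenic land-cover gradient.

    Renormalizes the seven land-cover proportions to sum to one per site,
    applies the arcsine-square-root transform, and performs covariance PCA
    (column-centred, unscaled). PC1's sign is fixed so the forest loading is
    positive; PC2's so the grass+agriculture loading sum is positive.

    Raises
    ------
    DegenerateInputError
        If fewer than 3 sites or the composition matrix is constant.
    """
    if len(meta) < 3:
        raise DegenerateInputError("need at least 3 sites for a land-cover PCA")
    classes = list(LANDCOVER_CLASSES)
    P = meta[classes].to_numpy(dtype=float)
    row_sums = P.sum(axis=1)
    if np.any(row_sums <= 0):
        raise DegenerateInputError("a site has zero total land-cover proportion")
    P = P / row_sums[:, None]

    X = arcsine_sqrt(P)
    mu = X.mean(axis=0)
    Xc = X - mu
    total_var = (Xc**2).sum() / (len(meta) - 1)
    if total_var < 1e-24:
        raise DegenerateInputError("land-cover composition is identical across sites")

    # covariance PCA via SVD (equivalent to prcomp with default scaling)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (len(meta) - 1)
    explained = var / var.sum()
    scores = U * s  # site x k
    loadings = Vt.T  # class x k

    forest_idx = classes.index("forest")
    if loadings[forest_idx, 0] < 0:
        loadings[:, 0] *= -1
        scores[:, 0] *= -1
    rural = classes.index("grass"), classes.index("agriculture")
    if loadings.shape[1] > 1 and (loadings[rural[0], 1] + loadings[rural[1], 1]) < 0:
        loadings[:, 1] *= -1
        scores[:, 1] *= -1

    sites = meta["site"].to_numpy()
    return LandcoverScores(
        scores=pd.DataFrame(
            {"PC1": scores[:, 0], "PC2": scores[:, 1]}, index=pd.Index(sites, name="site")
        ),
        loadings=pd.DataFrame(
            loadings,
            index=pd.Index(classes, name="class"),
            columns=[f"PC{i + 1}" for i in range(loadings.shape[1])],
        ),
        variance_explained=explained,
        column_means=mu,
        full_scores=scores,
    )


def attach_scores(meta: pd.DataFrame, lc: LandcoverScores) -> pd.DataFrame:
    """Return a copy of the site metadata with PC1/PC2 columns appended."""
    out = meta.copy()
    out["PC1"] = lc.scores.loc[out["site"], "PC1"].to_numpy()
    out["PC2"] = lc.scores.loc[out["site"], "PC2"].to_numpy()
    return out
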