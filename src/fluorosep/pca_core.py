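"""Mean-centered PCA producing the 2-D score clouds the metrics operate on.

The spectral matrix is column-centered (no scaling) and decomposed by SVD;
wells become points in the plane of the first two principal components.
Model adequacy is judged by the residual dispersion — the fraction of total
variance not captured by the retained components — with a 5% default gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .spectra_io import SpectraMatrix

logger = logging.getLogger(__name__)

#: residual-dispersion fraction above which a model-adequacy warning is logged
RESIDUAL_WARN_THRESHOLD = 0.05


@dataclass
class ScoreCloud:
    """PCA scores of one spectral matrix, with metadata carried through.

    ``scores[i]`` is well *i* projected on the top-``k`` principal
    components; ``explained_fraction`` holds the per-component variance
    fractions and ``loadings`` the corresponding orthonormal spectral
    directions (rows).
    """

    scores: np.ndarray
    explained_fraction: np.ndarray
    loadings: np.ndarray
    well_meta: pd.DataFrame = field(repr=False)

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def sample_points(self, n_components: int = 2) -> dict[str, np.ndarray]:
        """Replicate score coordinates per non-blank sample, insertion-ordered."""
        meta = self.well_meta
        pts: dict[str, np.ndarray] = {}
        for sid in meta.loc[~meta["is_blank"], "sample_id"].unique():
            mask = ((meta["sample_id"] == sid) & ~meta["is_blank"]).to_numpy()
            pts[str(sid)] = self.scores[mask, :n_components]
        return pts

    def labels(self) -> tuple[np.ndarray, np.ndarray]:
        """(points, sample labels) for the non-blank wells."""
        mask = ~self.well_meta["is_blank"].to_numpy()
        return self.scores[mask], self.well_meta.loc[mask, "sample_id"].to_numpy(str)

    def to_frame(self) -> pd.DataFrame:
        frame = self.well_meta[["well_id", "sample_id", "condition"]].copy()
        for j in range(self.k):
            frame[f"PC{j + 1}"] = self.scores[:, j]
        return frame


def fit_pca(data: SpectraMatrix, k: int = 2) -> ScoreCloud:
    """Center the matrix and project it on its top-``k`` principal axes.

    The sign of each component is fixed so that its largest-magnitude
    loading element is positive, making scores reproducible across runs.
    Blank wells take part in the fit (they are ordinary rows of the data
    matrix) but are excluded from all separability metrics downstream.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1 (got {k})")
    x = data.values
    if x.shape[0] < k:
        raise ValidationError(f"k={k} exceeds the number of wells ({x.shape[0]})")
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(x.shape) * np.finfo(float).eps)) if s[0] > 0 else 0
    if k > rank:
        raise ValidationError(f"k={k} exceeds the rank of the centered matrix ({rank})")
    # deterministic sign: largest-|loading| element of each component positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :k] * s[:k]
    total = float(np.sum(s**2))
    explained = s[:k] ** 2 / total
    cloud = ScoreCloud(scores, explained, vt[:k].copy(), data.well_meta.copy())
    resid = residual_dispersion(cloud)
    if resid > RESIDUAL_WARN_THRESHOLD:
        logger.warning(
            "residual dispersion %.1f%% exceeds %.0f%% with k=%d components",
            100 * resid, 100 * RESIDUAL_WARN_THRESHOLD, k,
        )
    return cloud


def residual_dispersion(cloud: ScoreCloud) -> float:
    """Fraction of total variance left out by the retained components."""
    return float(max(0.0, 1.0 - float(np.sum(cloud.explained_fraction))))


def write_scores(cloud: ScoreCloud, path) -> None:
    cloud.to_frame().to_csv(path, index=False, float_format="%.6g")
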