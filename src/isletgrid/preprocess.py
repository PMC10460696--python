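"""Missingness accounting, pooled median imputation and PCA quality control.

Each image is its own TMT plex, so abundances carry batch structure and
abundance-dependent missingness.  The pipeline deliberately does NOT
median-center across plexes (the log-ratio distributions are not normal
enough to justify it); instead the plex enters the differential-expression
model as a covariate.  Missing values are imputed per protein with the
median of that protein's observed values pooled across all voxels of all
images.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DimensionError, InputError
from .grid import Study


def missingness_summary(study: Study) -> tuple[pd.DataFrame, pd.Series]:
    """Per-voxel missing-value counts and per-image medians.

    Counts are taken over the study-wide protein index, so proteins never
    quantified in an image count as missing in each of its voxels.  Returns
    ``(per_voxel, per_image_median)`` where ``per_voxel`` has columns
    ``image_id, row, col, n_missing, fraction_missing``.
    """
    if not study.images:
        raise InputError("empty study")
    index = study.protein_index
    n_prot = len(index)
    rows = []
    for im in study.images:
        block = im.abundance.reindex(index)
        n_missing = block.isna().sum(axis=0)
        for (r, c), (_, nm) in zip(im.grid.coords(), n_missing.items()):
            rows.append(
                {"image_id": im.image_id, "row": r, "col": c,
                 "n_missing": int(nm), "fraction_missing": nm / n_prot}
            )
    per_voxel = pd.DataFrame(rows)
    per_image = per_voxel.groupby("image_id", sort=False)["n_missing"].median()
    per_image.name = "median_n_missing"
    return per_voxel, per_image


def impute_median(study: Study) -> pd.DataFrame:
    """Complete the pooled matrix by per-protein pooled-median imputation.

    Every missing entry of protein ``p`` is replaced by the median of
    ``p``'s observed values across ALL voxels of ALL images; observed
    entries are untouched, so the operation is idempotent.  Proteins
    observed nowhere cannot be imputed and are dropped with a warning.
    Even observation counts use the standard midpoint-of-central-pair
    median.
    """
    pooled = study.pooled_matrix()
    observed_counts = pooled.notna().sum(axis=1)
    unobserved = pooled.index[observed_counts == 0]
    if len(unobserved):
        warnings.warn(
            f"dropping {len(unobserved)} protein(s) observed in no voxel, "
            f"e.g. {list(unobserved[:5])}"
        )
        pooled = pooled.drop(index=unobserved)
    medians = pooled.median(axis=1, skipna=True)
    return pooled.apply(lambda col: col.fillna(medians))


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each voxel column's median (available but OFF by default).

    Cross-plex median centering was evaluated and rejected for this design;
    it is kept so that the comparison can be reproduced.
    """
    return matrix - matrix.median(axis=0, skipna=True)


def pca_embedding(
    completed: pd.DataFrame, n_components: int | None = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Voxel scores on the leading principal components of a completed matrix.

    Voxels (columns) are the observations; proteins are mean-centered
    features.  Returns ``(scores, explained_variance_ratio)`` with
    components ordered by decreasing explained variance.  Pass
    ``n_components=None`` for all available components (their variance
    fractions then sum to 1).
    """
    if completed.isna().any().any():
        raise InputError("matrix must be complete (impute first)")
    X = completed.to_numpy().T  # voxels x proteins
    max_k = min(X.shape)
    k = max_k if n_components is None else n_components
    if k > X.shape[0]:
        raise DimensionError(
            f"requested {k} components but only {X.shape[0]} voxels"
        )
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    scores = pd.DataFrame(
        coords, index=completed.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    scores.index.name = "voxel"
    return scores, pca.explained_variance_ratio_
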