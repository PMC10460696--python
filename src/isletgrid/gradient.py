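"""Spatial protein scorings: variance ranking and distance-gradient consensus.

Two complementary protein scorings feed rank-based pathway enrichment:

* study-wide variance of each protein across all voxels, highlighting
  pathways whose members change most across the sampled regions;
* per-image Spearman rank correlation of each protein's abundance with the
  voxel's centroid distance to the islet voxel — the "sphere of influence"
  analysis.  Distance is treated as continuous; the discrete region labels
  play no role here.

With only nine voxels per image the large-sample Spearman test is invalid,
so two-sided p-values are computed by exact enumeration of all n! distance
orderings (n <= 9).  Because the permutation distribution of the rank
inner product depends only on the multisets of the two rank vectors, the
null is computed once per distinct abundance tie pattern and shared across
proteins, which keeps full enumeration cheap even for thousands of
proteins.

Cross-image consensus flags pathways whose rank enrichment is significant
(BH-adjusted, by default) in at least ``min_images`` of the images.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import PathwayDB, enrichment_in_order
from .errors import ConfigurationError, InputError
from .grid import ProteomeImage, Study, column_name

#: Largest image size for which the exact permutation null is enumerated.
EXACT_PERMUTATION_MAX_N = 9

_RHO_CLIP = 1.0 - 1e-12


def protein_variance_scores(completed: pd.DataFrame) -> pd.Series:
    """Sample variance (n-1 denominator) of each protein across all voxels."""
    if completed.shape[1] < 2:
        raise InputError("need at least two voxels to compute a variance")
    scores = completed.var(axis=1, ddof=1)
    scores.name = "variance"
    return scores


@lru_cache(maxsize=4)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _t_stat(rho: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(rho, -_RHO_CLIP, _RHO_CLIP)
    return r * np.sqrt((n - 2) / (1.0 - r ** 2))


def _exact_spearman(
    ranks: np.ndarray, d_ranks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact two-sided permutation Spearman for complete rows.

    ``ranks``: proteins x n mid-rank matrix; ``d_ranks``: distance
    mid-ranks.  Returns (rho, p).  The null distribution of the centered
    rank inner product under uniform permutation of the distance ordering
    depends only on the sorted rank vectors, so rows are grouped by their
    tie pattern and each group's null is enumerated once.
    """
    n = ranks.shape[1]
    drc = d_ranks - d_ranks.mean()
    denom_d = np.sqrt((drc ** 2).sum())
    if denom_d == 0:
        raise InputError("distances are all tied; correlation undefined")
    arc = ranks - ranks.mean(axis=1, keepdims=True)
    denom_a = np.sqrt((arc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom_a > 0, arc @ drc / (denom_a * denom_d), np.nan)

    pvals = np.full(len(ranks), np.nan)
    perms = _perm_matrix(n)
    n_perm = float(factorial(n))
    D = drc[perms]  # n! x n permuted centered distance ranks
    keys = [tuple(np.round(np.sort(row), 6)) for row in arc]
    by_key: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        if denom_a[i] > 0:
            by_key.setdefault(key, []).append(i)
    for key, idx in by_key.items():
        a = np.array(key, dtype=float)
        null_abs = np.sort(np.abs(D @ a) / (np.sqrt((a ** 2).sum()) * denom_d))
        obs = np.abs(rho[idx])
        # two-sided: count of permutations with |rho_null| >= |rho_obs|
        ge = len(null_abs) - np.searchsorted(null_abs, obs - 1e-12, side="left")
        pvals[idx] = ge / n_perm
    return rho, pvals


def distance_correlation(
    image: ProteomeImage,
    metric: str = "euclidean_centroid_um",
    abundance: pd.DataFrame | None = None,
    min_voxels: int = 3,
) -> pd.DataFrame:
    """Per-protein Spearman correlation with distance from the islet voxel.

    ``abundance`` defaults to the image's own (possibly incomplete) matrix;
    pass the matching slice of the imputed study matrix to analyse
    completed data.  Proteins observed in fewer than ``min_voxels`` voxels
    or with zero abundance variance are flagged ``undefined`` and carry NaN
    statistics.  P-values are exact permutation two-sided for n <= 9 and
    t-approximated otherwise.

    Returns columns ``image_id, protein, rho, stat, p, n, undefined``.
    """
    dists = image.distances(metric)
    if np.allclose(dists, dists[0]):
        raise InputError(f"image {image.image_id}: all voxel distances equal")
    mat = image.abundance if abundance is None else abundance
    values = mat.to_numpy(dtype=float)
    n_vox = values.shape[1]
    if n_vox != len(dists):
        raise InputError("abundance columns do not match image voxels")

    rho = np.full(len(mat), np.nan)
    pvals = np.full(len(mat), np.nan)
    stat = np.full(len(mat), np.nan)
    nobs = np.zeros(len(mat), dtype=int)

    complete = ~np.isnan(values).any(axis=1)
    nobs[complete] = n_vox
    if complete.any():
        ranks = stats.rankdata(values[complete], axis=1)
        if n_vox <= EXACT_PERMUTATION_MAX_N:
            r, p = _exact_spearman(ranks, stats.rankdata(dists))
        else:
            r = np.full(complete.sum(), np.nan)
            p = np.full(complete.sum(), np.nan)
            for j, row in enumerate(values[complete]):
                res = stats.spearmanr(row, dists)
                r[j], p[j] = res.statistic, res.pvalue
        rho[complete] = r
        pvals[complete] = p
        stat[complete] = _t_stat(r, n_vox)

    for i in np.where(~complete)[0]:
        row = values[i]
        mask = ~np.isnan(row)
        n = int(mask.sum())
        nobs[i] = n
        if n < min_voxels:
            continue
        sub_d = dists[mask]
        if np.allclose(sub_d, sub_d[0]):
            continue
        ranks_i = stats.rankdata(row[mask])[None, :]
        if n <= EXACT_PERMUTATION_MAX_N:
            r, p = _exact_spearman(ranks_i, stats.rankdata(sub_d))
            rho[i], pvals[i] = r[0], p[0]
        else:
            res = stats.spearmanr(row[mask], sub_d)
            rho[i], pvals[i] = res.statistic, res.pvalue
        if not np.isnan(rho[i]):
            stat[i] = _t_stat(np.array([rho[i]]), n)[0]

    return pd.DataFrame(
        {"image_id": image.image_id, "protein": mat.index, "rho": rho,
         "stat": stat, "p": pvals, "n": nobs, "undefined": np.isnan(rho)}
    )


def study_distance_correlations(
    study: Study,
    metric: str = "euclidean_centroid_um",
    completed: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Run :func:`distance_correlation` for every image of a study.

    When ``completed`` (the imputed pooled matrix) is given, each image is
    analysed on its completed columns.
    """
    out = {}
    for im in study.images:
        abundance = None
        if completed is not None:
            cols = [column_name(im.image_id, r, c) for r, c in im.grid.coords()]
            abundance = completed[cols]
        out[im.image_id] = distance_correlation(im, metric, abundance)
    return out


def distance_order_enrichment(
    corr_results: dict[str, pd.DataFrame],
    db: PathwayDB,
    method: str = "normal",
) -> dict[str, pd.DataFrame]:
    """Per-image rank enrichment of the signed correlation test statistic.

    The score passed to :func:`enrichment_in_order` is the signed t-form
    statistic of the Spearman correlation (monotone in rho), so positive z
    means pathway members are more abundant farther from the islet.
    """
    out = {}
    for image_id, corr in corr_results.items():
        scored = corr[~corr["undefined"]]
        scores = pd.Series(scored["stat"].to_numpy(), index=scored["protein"])
        out[image_id] = enrichment_in_order(scores, db, method=method)
    return out


def consensus_pathways(
    per_image: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    min_images: int = 4,
    use_adjusted: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-image consensus of per-image rank enrichments.

    A pathway is flagged when its enrichment is significant (``adj_p <
    alpha`` per image by default, raw p with ``use_adjusted=False``) in at
    least ``min_images`` images.  Returns ``(summary, z_matrix)`` where
    ``z_matrix`` is pathway x image.
    """
    n_images = len(per_image)
    if min_images > n_images:
        raise ConfigurationError(
            f"min_images={min_images} exceeds the {n_images} available images"
        )
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha {alpha} outside (0, 1)")
    col = "adj_p" if use_adjusted else "p"
    z = pd.DataFrame(
        {img: frame.set_index("pathway")["z"] for img, frame in per_image.items()}
    )
    sig = pd.DataFrame(
        {img: frame.set_index("pathway")[col] < alpha
         for img, frame in per_image.items()}
    ).fillna(False)
    n_sig = sig.sum(axis=1).astype(int)
    summary = pd.DataFrame(
        {"pathway": z.index, "n_significant": n_sig.reindex(z.index).to_numpy(),
         "consensus": (n_sig.reindex(z.index) >= min_images).to_numpy()}
    ).reset_index(drop=True)
    z.index.name = "pathway"
    return summary, z


def pathway_protein_profiles(
    pathway: str,
    db: PathwayDB,
    corr_results: dict[str, pd.DataFrame],
    study: Study,
    completed: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
    metric: str = "euclidean_centroid_um",
) -> pd.DataFrame:
    """Abundance-by-distance profiles of a pathway's correlated proteins.

    For each image, the pathway members whose raw correlation p-value is at
    or below ``p_threshold`` in that image, with their abundances ordered
    by voxel distance from the islet.  Returns a long DataFrame with
    columns ``image_id, protein, row, col, distance_um, abundance, rho, p``.
    """
    if pathway not in db.sets:
        raise InputError(f"pathway {pathway!r} not in database")
    members = set(db.sets[pathway])
    rows = []
    for im in study.images:
        corr = corr_results.get(im.image_id)
        if corr is None:
            continue
        hits = corr[
            corr["protein"].isin(members)
            & ~corr["undefined"]
            & (corr["p"] <= p_threshold)
        ]
        dists = im.distances(metric)
        order = np.argsort(dists, kind="stable")
        coords = im.grid.coords()
        if completed is not None:
            cols = [column_name(im.image_id, r, c) for r, c in coords]
            block = completed[cols]
            block.columns = im.abundance.columns
        else:
            block = im.abundance
        for _, hit in hits.iterrows():
            prot = hit["protein"]
            if prot not in block.index:
                continue
            vals = block.loc[prot].to_numpy()
            for k in order:
                r, c = coords[k]
                rows.append(
                    {"image_id": im.image_id, "protein": prot, "row": r,
                     "col": c, "distance_um": dists[k], "abundance": vals[k],
                     "rho": hit["rho"], "p": hit["p"]}
                )
    return pd.DataFrame(
        rows, columns=["image_id", "protein", "row", "col", "distance_um",
                       "abundance", "rho", "p"]
    )
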