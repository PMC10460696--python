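"""Pooled differential expression between grid regions with plex covariates.

Because each image measures the islet in a single voxel, per-image
statistics are impossible; instead all voxels are pooled and a linear model

    abundance ~ region + image

is fitted per protein by least squares, treating every image as one
biological replicate and absorbing the TMT-plex batch shift in the image
term.  Residual variances are shrunk toward a pooled prior with the
standard empirical-Bayes inverse-chi-square (moderated-t) scheme: the prior
degrees of freedom and scale are estimated by moment matching on the log
residual variances across proteins, the posterior variance is the
df-weighted average of prior and observed variance, and the moderated t is
referred to a t distribution with residual + prior degrees of freedom.
P-values are Benjamini-Hochberg adjusted per contrast.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, InputError
from .grid import DISTAL, ISLET, PROXIMAL

#: The four region contrasts reported by default.
CONTRASTS = (
    "islet_vs_proximal",
    "islet_vs_distal",
    "islet_vs_rest",
    "proximal_vs_distal",
)

#: Cap applied to an effectively infinite prior df when forming df_total.
_DF_PRIOR_CAP = 1e6


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-protein residual variances.

    Fits a scaled inverse-chi-square prior to the observed variances by
    moment matching on ``log(s2)`` and returns ``(df_prior, s2_prior,
    s2_posterior)``.  ``df_prior`` is ``inf`` when the observed variances
    are no more dispersed than sampling noise allows (complete pooling).
    Zero observed variances receive the prior scale directly.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise InputError("all residual variances are zero; cannot fit a prior")
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0)) \
        if len(e) > 1 else -1.0
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        s2_prior = float(
            np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(emean))
    if np.isfinite(df_prior):
        s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)
    else:
        s2_post = np.full_like(s2, s2_prior)
    s2_post[~positive] = s2_prior
    return df_prior, s2_prior, s2_post


def design_matrix(
    labels: np.ndarray, image_ids: np.ndarray, include_image: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design: intercept + region (ref distal) + image.

    The first image id in sorted order is the image reference level.
    """
    labels = np.asarray(labels)
    image_ids = np.asarray(image_ids)
    cols = [np.ones(len(labels))]
    names = ["intercept"]
    for level in (ISLET, PROXIMAL):
        cols.append((labels == level).astype(float))
        names.append(f"region_{level}")
    if include_image:
        for img in sorted(set(image_ids))[1:]:
            cols.append((image_ids == img).astype(float))
            names.append(f"image_{img}")
    return np.column_stack(cols), names


def contrast_vector(name: str, coef_names: list[str]) -> np.ndarray:
    """Coefficient-space contrast for a named region comparison."""
    c = np.zeros(len(coef_names))
    i_islet = coef_names.index(f"region_{ISLET}")
    i_prox = coef_names.index(f"region_{PROXIMAL}")
    if name == "islet_vs_proximal":
        c[i_islet], c[i_prox] = 1.0, -1.0
    elif name == "islet_vs_distal":
        c[i_islet] = 1.0
    elif name == "proximal_vs_distal":
        c[i_prox] = 1.0
    elif name == "islet_vs_rest":
        # islet minus the unweighted mean of proximal and distal
        c[i_islet], c[i_prox] = 1.0, -0.5
    else:
        raise InputError(f"unknown contrast {name!r}; choose from {CONTRASTS}")
    return c


def _validate_design(labels, image_ids, include_image):
    labels = np.asarray(labels)
    image_ids = np.asarray(image_ids)
    if include_image:
        for level in set(labels):
            imgs = set(image_ids[labels == level])
            if len(imgs) < 2 and len(set(image_ids)) > 1:
                raise DesignError(
                    f"region level {level!r} observed only in image(s) "
                    f"{sorted(imgs)}: confounded with the image term"
                )


def fit_region_model(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    image_ids: np.ndarray,
    contrasts: tuple[str, ...] = CONTRASTS,
    include_image: bool = True,
    moderation: str = "eb",
    df_prior: float | None = None,
    s2_prior: float | None = None,
) -> pd.DataFrame:
    """Fit ``abundance ~ region + image`` per protein and test contrasts.

    Parameters
    ----------
    matrix : complete proteins x voxels DataFrame (impute first).
    labels, image_ids : per-voxel region labels and image identifiers.
    moderation : ``"eb"`` for the moderated t (default) or ``"none"`` for
        the ordinary least-squares t.
    df_prior, s2_prior : explicit prior overrides (advanced; ``df_prior=0``
        reproduces the ordinary t exactly).

    Returns a long DataFrame with one row per (protein, contrast):
    ``protein, contrast, logFC, t, p, adj_p, df_residual, df_prior,
    df_total``.
    """
    if matrix.isna().any().any():
        raise InputError("matrix contains missing values; impute first")
    labels = np.asarray(labels)
    image_ids = np.asarray(image_ids)
    if not (len(labels) == len(image_ids) == matrix.shape[1]):
        raise InputError("labels/image_ids length must match matrix columns")
    if moderation not in ("eb", "none"):
        raise InputError(f"unknown moderation {moderation!r}")
    _validate_design(labels, image_ids, include_image)

    X, names = design_matrix(labels, image_ids, include_image)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DesignError(
            f"design matrix rank {rank} < {X.shape[1]} columns {names}: "
            "rank-deficient design"
        )
    n, p = X.shape
    df_res = float(n - p)
    if df_res <= 0:
        raise DesignError("no residual degrees of freedom")

    Y = matrix.to_numpy().T  # voxels x proteins
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    s2 = (resid ** 2).sum(axis=0) / df_res
    # clamp numerically-null variances (exactly fitted proteins) to zero
    tiny = np.finfo(float).eps * max(1.0, float(np.abs(Y).max())) ** 2 * len(Y)
    s2[s2 < tiny] = 0.0

    if moderation == "eb" and df_prior is None and not (s2 > 0).any():
        # degenerate data: every protein fits exactly; fall back to plain t
        moderation = "none"
    if moderation == "none":
        d0, s2_post = 0.0, s2.copy()
    elif df_prior is not None:
        d0 = float(df_prior)
        s0 = s2_prior if s2_prior is not None else float(np.median(s2))
        if np.isfinite(d0) and d0 > 0:
            s2_post = (d0 * s0 + df_res * s2) / (d0 + df_res)
        elif d0 == 0:
            s2_post = s2.copy()
        else:
            s2_post = np.full_like(s2, s0)
    else:
        d0, _, s2_post = squeeze_variances(s2, df_res)

    df_total = df_res + min(d0, _DF_PRIOR_CAP)
    out = []
    est_tiny = np.sqrt(tiny)
    for cname in contrasts:
        c = contrast_vector(cname, names)
        est = c @ beta
        est[np.abs(est) < est_tiny] = 0.0
        scale = float(c @ xtx_inv @ c)
        se = np.sqrt(s2_post * scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / np.where(se > 0, se, 1.0),
                         np.where(est == 0, 0.0, np.sign(est) * np.inf))
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
        adj = multipletests(pvals, method="fdr_bh")[1]
        out.append(
            pd.DataFrame(
                {"protein": matrix.index, "contrast": cname, "logFC": est,
                 "t": t, "p": pvals, "adj_p": adj, "df_residual": df_res,
                 "df_prior": d0, "df_total": df_total}
            )
        )
    return pd.concat(out, ignore_index=True)


def significant_sets(
    de_table: pd.DataFrame, threshold: float = 0.05
) -> dict[str, set[str]]:
    """Per-contrast sets of proteins with adjusted p below the threshold."""
    if not 0.0 < threshold < 1.0:
        raise InputError(f"threshold {threshold} outside (0, 1)")
    sig = de_table[de_table["adj_p"] < threshold]
    out: dict[str, set[str]] = {c: set() for c in de_table["contrast"].unique()}
    for contrast, grp in sig.groupby("contrast"):
        out[contrast] = set(grp["protein"])
    return out


def overlap_counts(
    de_table: pd.DataFrame,
    contrasts: tuple[str, ...] | None = None,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Upset-style exclusive intersection counts of significance sets.

    For every non-empty combination of contrasts, the number of proteins
    significant in exactly that combination; combination counts sum to the
    size of the union of all significance sets.
    """
    available = list(dict.fromkeys(de_table["contrast"]))
    contrasts = tuple(contrasts) if contrasts is not None else tuple(available)
    unknown = set(contrasts) - set(available)
    if unknown:
        raise InputError(f"unknown contrast(s) {sorted(unknown)}; have {available}")
    sets = significant_sets(de_table, threshold)
    rows = []
    for k in range(1, len(contrasts) + 1):
        for combo in itertools.combinations(contrasts, k):
            exact = set.intersection(*(sets[c] for c in combo))
            for other in contrasts:
                if other not in combo:
                    exact -= sets[other]
            if exact:
                rows.append({"combination": "&".join(combo), "degree": k,
                             "count": len(exact)})
    return pd.DataFrame(rows, columns=["combination", "degree", "count"])
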