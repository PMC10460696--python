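"""Pathway enrichment in two modes.

``enrichment_in_sets`` tests over-representation of a selected protein set
(e.g. the significantly differential proteins) among each pathway's members
with a one-sided hypergeometric test against the quantified background.

``enrichment_in_order`` tests whether a pathway's members concentrate at one
end of a protein ranking (variance scores, distance-correlation statistics)
with a tie-corrected normal-approximation rank-sum test; the signed z-score
is positive when members sit at high scores.

Both modes apply Benjamini-Hochberg adjustment across the tested sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ValidationError


@dataclass
class PathwayDB:
    """Named protein sets, typically read from a GMT file."""

    sets: dict[str, list[str]]
    source: str = "synthetic"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"pathway {name!r} has no members")
            # collapse duplicate members, preserving order
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path, source: str | None = None) -> PathwayDB:
    """Read a GMT file (tab-separated: name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"malformed GMT line: {line[:80]!r}")
            name, desc, *members = parts
            if name in sets:
                raise ValidationError(f"duplicate pathway name {name!r} in {path}")
            sets[name] = members
            descriptions[name] = desc
    return PathwayDB(sets, source=source or str(path), descriptions=descriptions)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in db.sets.items():
            desc = db.descriptions.get(name, db.source)
            fh.write("\t".join([name, desc, *members]) + "\n")


def _bh_adjust(frame: pd.DataFrame) -> pd.DataFrame:
    tested = frame["p"].notna()
    adj = np.full(len(frame), np.nan)
    if tested.any():
        adj[tested.to_numpy()] = multipletests(
            frame.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    frame["adj_p"] = adj
    return frame


def enrichment_in_sets(
    selected: set[str] | list[str],
    background: set[str] | list[str],
    db: PathwayDB,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per pathway.

    Pathways are intersected with the background (all quantified proteins)
    before testing; pathways with no member in the background are reported
    untested (NaN statistics).  Returns one row per pathway with columns
    ``n_background, n_set, n_selected, n_overlap, z, p, adj_p``.
    """
    selected = set(selected)
    background = set(background)
    extra = selected - background
    if extra:
        raise InputError(
            f"{len(extra)} selected proteins not in background, "
            f"e.g. {sorted(extra)[:5]}"
        )
    N, n = len(background), len(selected)
    rows = []
    for name, members in db.sets.items():
        in_bg = background.intersection(members)
        K = len(in_bg)
        if K == 0:
            rows.append(
                {"pathway": name, "n_background": N, "n_set": 0, "n_selected": n,
                 "n_overlap": 0, "z": np.nan, "p": np.nan}
            )
            continue
        k = len(selected.intersection(in_bg))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        mean = n * K / N
        sd = stats.hypergeom.std(N, K, n)
        z = (k - mean) / sd if sd > 0 else np.nan
        rows.append(
            {"pathway": name, "n_background": N, "n_set": K, "n_selected": n,
             "n_overlap": k, "z": z, "p": min(p, 1.0)}
        )
    return _bh_adjust(pd.DataFrame(rows))


def enrichment_in_order(
    scores: pd.Series,
    db: PathwayDB,
    method: str = "normal",
    min_set_size: int = 2,
) -> pd.DataFrame:
    """Rank-sum enrichment of each pathway along a protein scoring.

    Proteins are ranked by score (mid-ranks for ties); for each pathway the
    in-set rank sum is compared with its sampling-without-replacement null.
    ``z`` is signed (positive = members concentrated at high scores); the
    two-sided p comes from the normal approximation, or from the exact
    rank-sum distribution when ``method="exact"`` (small sets, no ties).
    Sets with fewer than ``min_set_size`` scored members or non-members are
    skipped with a warning and reported untested.
    """
    scores = scores.dropna()
    if len(scores) < 2:
        raise InputError("need scores for at least two proteins")
    if method not in ("normal", "exact"):
        raise InputError(f"unknown method {method!r}")
    ranks = pd.Series(stats.rankdata(scores.to_numpy()), index=scores.index)
    N = len(ranks)
    pop_var = float(np.mean((ranks.to_numpy() - ranks.mean()) ** 2))
    rows, skipped = [], 0
    for name, members in db.sets.items():
        in_set = ranks.index.intersection(members)
        m = len(in_set)
        if m < min_set_size or N - m < min_set_size:
            skipped += 1
            rows.append(
                {"pathway": name, "n_scored": m, "rank_sum": np.nan,
                 "z": np.nan, "p": np.nan, "direction": ""}
            )
            continue
        T = float(ranks.loc[in_set].sum())
        mean = m * (N + 1) / 2.0
        # variance of a sum of m ranks drawn without replacement
        var = m * (N - m) / (N - 1.0) * pop_var
        z = (T - mean) / np.sqrt(var) if var > 0 else 0.0
        if method == "exact":
            in_mask = ranks.index.isin(in_set)
            res = stats.mannwhitneyu(
                scores.to_numpy()[in_mask], scores.to_numpy()[~in_mask],
                alternative="two-sided", method="exact",
            )
            p = float(res.pvalue)
        else:
            p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            {"pathway": name, "n_scored": m, "rank_sum": T, "z": z,
             "p": min(p, 1.0), "direction": "up" if z > 0 else ("down" if z < 0 else "")}
        )
    if skipped:
        warnings.warn(
            f"{skipped} pathway(s) skipped with <{min_set_size} scored members "
            "or non-members"
        )
    return _bh_adjust(pd.DataFrame(rows))
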