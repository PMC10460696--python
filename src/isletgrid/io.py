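"""Readers and writers for the plain-text interchange formats.

Abundance matrices, voxel metadata sidecars, ground truth, enrichment and
DE tables are tab-separated text; pathway collections are GMT; interactomes
are 3-column edge lists.  Missing abundances are accepted as empty cells or
``NA`` on read and written as ``NA``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import ISLET, ProteomeImage, Study, VoxelGrid, column_name, voxel_name

_NA_VALUES = ["", "NA"]


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a proteins x voxels matrix as TSV (missing entries as NA)."""
    out = matrix.copy()
    out.index.name = "protein"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_matrix(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False
    )
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique()
        raise ValidationError(f"duplicated protein row(s): {list(dupes)[:10]}")
    matrix.index.name = "protein"
    return matrix


def write_study(study: Study, matrix_path: str | Path, meta_path: str | Path) -> None:
    """Write the pooled abundance matrix and the voxel metadata sidecar."""
    write_matrix(study.pooled_matrix(), matrix_path)
    study.voxel_table().to_csv(meta_path, sep="\t", index=False)


def _infer_grid(meta: pd.DataFrame, image_id: str) -> VoxelGrid:
    islet_rows = meta[meta["label"] == ISLET]
    if len(islet_rows) != 1:
        raise ValidationError(
            f"image {image_id!r} has {len(islet_rows)} islet voxel(s); "
            "expected exactly one"
        )
    ir, ic = int(islet_rows["row"].iloc[0]), int(islet_rows["col"].iloc[0])
    n_rows = int(meta["row"].max()) + 1
    n_cols = int(meta["col"].max()) + 1
    # recover the physical pitch from an orthogonally adjacent voxel's distance
    width, height = 200.0, 300.0
    horiz = meta[(meta["row"] == ir) & ((meta["col"] - ic).abs() == 1)]
    if len(horiz) and "distance_um" in meta:
        width = float(horiz["distance_um"].iloc[0])
    vert = meta[(meta["col"] == ic) & ((meta["row"] - ir).abs() == 1)]
    if len(vert) and "distance_um" in meta:
        height = float(vert["distance_um"].iloc[0])
    return VoxelGrid(
        n_rows=n_rows, n_cols=n_cols, voxel_width_um=width,
        voxel_height_um=height, islet_index=(ir, ic),
    )


def read_study(matrix_path: str | Path, meta_path: str | Path) -> Study:
    """Reconstruct a Study from a pooled matrix and its metadata sidecar.

    Validates that matrix columns match the metadata voxels, that protein
    ids are unique and that every image has exactly one islet voxel.
    """
    matrix = read_matrix(matrix_path)
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"image_id", "row", "col", "label"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"metadata needs columns {sorted(required)}, got {list(meta.columns)}"
        )
    expected = [
        column_name(r.image_id, r.row, r.col) for r in meta.itertuples()
    ]
    missing = sorted(set(expected) - set(matrix.columns))
    extra = sorted(set(matrix.columns) - set(expected))
    if missing or extra:
        raise ValidationError(
            f"matrix/metadata mismatch; columns missing from matrix: "
            f"{missing[:10]}; unexpected matrix columns: {extra[:10]}"
        )
    images = []
    for image_id, sub in meta.groupby("image_id", sort=False):
        grid = _infer_grid(sub, str(image_id))
        cols = [column_name(image_id, r, c) for r, c in grid.coords()]
        block = matrix[cols].copy()
        block.columns = [voxel_name(r, c) for r, c in grid.coords()]
        images.append(
            ProteomeImage(image_id=str(image_id), grid=grid, abundance=block)
        )
    return Study(images)


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a 3-column interactome TSV (header optional)."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = not _is_number(first.iloc[0, first.shape[1] - 1])
    edges = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    if edges.shape[1] < 3:
        raise ValidationError(
            f"edge list must have 3 columns (node, node, confidence), "
            f"got {edges.shape[1]}"
        )
    edges = edges.iloc[:, :3]
    edges.columns = ["protein_a", "protein_b", "confidence"]
    return edges


def _is_number(value) -> bool:
    try:
        float(value)
        return True
    except (TypeError, ValueError):
        return False


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis result table as TSV (NaN as NA)."""
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")
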