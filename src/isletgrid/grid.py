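"""Voxel-grid data model: sampling geometry, region annotation and distances.

A proteome image is one multiplexed (TMT) plex covering a small rectangular
grid of laser-dissected tissue voxels — by default a 3x3 grid of
200 um x 300 um voxels in which exactly one voxel contains an islet of
Langerhans and the surrounding voxels contain acinar tissue.  Every
downstream stage (imputation, differential expression, distance gradients,
network integration) consumes the region labels and centroid distances
defined here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoordinateError, ValidationError

#: Region labels partitioning each grid.
ISLET = "islet"
PROXIMAL = "proximal"
DISTAL = "distal"
REGION_LEVELS = (ISLET, PROXIMAL, DISTAL)

#: Supported distance metrics between voxel centroids.
DISTANCE_METRICS = ("euclidean_centroid_um", "euclidean_unit", "grid_chebyshev")

#: The four edge-middle positions of a 3x3 grid (islet placements that
#: yield the canonical 1 islet / 5 proximal / 3 distal split).
EDGE_MIDDLE_POSITIONS = ((0, 1), (1, 0), (1, 2), (2, 1))


@dataclass(frozen=True)
class VoxelGrid:
    """Rectangular sampling grid with a designated islet-containing voxel.

    Coordinates are 0-based ``(row, col)`` in row-major order.  The physical
    pitch (``voxel_width_um`` horizontally, ``voxel_height_um`` vertically)
    is used for centroid distances.
    """

    n_rows: int = 3
    n_cols: int = 3
    voxel_width_um: float = 200.0
    voxel_height_um: float = 300.0
    islet_index: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if self.voxel_width_um <= 0 or self.voxel_height_um <= 0:
            raise ConfigurationError("voxel dimensions must be strictly positive")
        r, c = self.islet_index
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise CoordinateError(
                f"islet_index {self.islet_index} outside "
                f"{self.n_rows}x{self.n_cols} grid"
            )

    @property
    def n_voxels(self) -> int:
        return self.n_rows * self.n_cols

    def coords(self) -> list[tuple[int, int]]:
        """All voxel coordinates in row-major order."""
        return list(itertools.product(range(self.n_rows), range(self.n_cols)))

    def _check(self, voxel: tuple[int, int]) -> None:
        r, c = voxel
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise CoordinateError(f"voxel {voxel} outside {self.n_rows}x{self.n_cols} grid")


def voxel_name(row: int, col: int) -> str:
    return f"r{row}c{col}"


def column_name(image_id: str, row: int, col: int) -> str:
    """Study-wide matrix column name for one voxel."""
    return f"{image_id}_{voxel_name(row, col)}"


def annotate_voxels(grid: VoxelGrid, connectivity: int = 8) -> np.ndarray:
    """Label every voxel islet / proximal / distal.

    The islet voxel keeps its own label; voxels adjacent to it under the
    chosen connectivity (8 = including diagonals, 4 = orthogonal only) are
    ``proximal``; everything else is ``distal``.  On a 3x3 grid with
    8-connectivity an edge-middle islet yields 5 proximal and 3 distal
    voxels.

    Returns an ``(n_rows, n_cols)`` object array of labels.
    """
    if connectivity not in (4, 8):
        raise ConfigurationError(f"connectivity must be 4 or 8, got {connectivity!r}")
    ir, ic = grid.islet_index
    grid._check((ir, ic))
    labels = np.full((grid.n_rows, grid.n_cols), DISTAL, dtype=object)
    for r, c in grid.coords():
        dr, dc = abs(r - ir), abs(c - ic)
        if (dr, dc) == (0, 0):
            labels[r, c] = ISLET
        elif connectivity == 8 and max(dr, dc) == 1:
            labels[r, c] = PROXIMAL
        elif connectivity == 4 and dr + dc == 1:
            labels[r, c] = PROXIMAL
    return labels


def voxel_distance(
    grid: VoxelGrid,
    voxel: tuple[int, int],
    metric: str = "euclidean_centroid_um",
) -> float:
    """Distance from a voxel's centroid to the islet voxel's centroid.

    Metrics: ``euclidean_centroid_um`` (physical pitch, default),
    ``euclidean_unit`` (unit grid spacing) and ``grid_chebyshev``
    (king-move count).  Zero iff the voxel is the islet voxel.
    """
    grid._check(voxel)
    if metric not in DISTANCE_METRICS:
        raise ConfigurationError(
            f"unknown metric {metric!r}; choose one of {DISTANCE_METRICS}"
        )
    ir, ic = grid.islet_index
    dr, dc = voxel[0] - ir, voxel[1] - ic
    if metric == "euclidean_centroid_um":
        return float(np.hypot(dr * grid.voxel_height_um, dc * grid.voxel_width_um))
    if metric == "euclidean_unit":
        return float(np.hypot(dr, dc))
    return float(max(abs(dr), abs(dc)))


@dataclass
class ProteomeImage:
    """One TMT plex: a voxel grid of log2 protein abundances.

    ``abundance`` is a proteins x voxels DataFrame whose columns are the
    row-major voxel names ``r{row}c{col}``; missing measurements are NaN.
    """

    image_id: str
    grid: VoxelGrid
    abundance: pd.DataFrame
    connectivity: int = 8

    def __post_init__(self) -> None:
        expected = [voxel_name(r, c) for r, c in self.grid.coords()]
        got = list(self.abundance.columns)
        if got != expected:
            raise ValidationError(
                f"image {self.image_id}: abundance columns {got} do not match "
                f"grid voxels {expected}"
            )
        if self.abundance.index.duplicated().any():
            dupes = self.abundance.index[self.abundance.index.duplicated()].unique()
            raise ValidationError(
                f"image {self.image_id}: duplicated protein ids {list(dupes)[:5]}"
            )

    @property
    def n_voxels(self) -> int:
        return self.grid.n_voxels

    @property
    def proteins(self) -> pd.Index:
        return self.abundance.index

    def labels(self) -> np.ndarray:
        """Row-major flat array of region labels."""
        return annotate_voxels(self.grid, self.connectivity).ravel()

    def distances(self, metric: str = "euclidean_centroid_um") -> np.ndarray:
        """Row-major flat array of voxel-to-islet centroid distances."""
        return np.array(
            [voxel_distance(self.grid, v, metric) for v in self.grid.coords()]
        )


@dataclass
class Study:
    """Ordered collection of proteome images sharing a protein index.

    The study is the unit of pooled inference: with seven 3x3 images it
    contributes 63 voxels, each image acting as one biological replicate of
    the islet / proximal / distal contrast.
    """

    images: list[ProteomeImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.images:
            raise ValidationError("a study needs at least one image")
        ids = [im.image_id for im in self.images]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate image ids in {ids}")

    @property
    def image_ids(self) -> list[str]:
        return [im.image_id for im in self.images]

    @property
    def n_voxels(self) -> int:
        return sum(im.n_voxels for im in self.images)

    @property
    def protein_index(self) -> pd.Index:
        """Sorted union of protein identifiers across images."""
        union: set[str] = set()
        for im in self.images:
            union.update(im.proteins)
        return pd.Index(sorted(union), name="protein")

    def iter_voxels(self) -> Iterator[tuple[ProteomeImage, int, int]]:
        for im in self.images:
            for r, c in im.grid.coords():
                yield im, r, c

    def pooled_matrix(self) -> pd.DataFrame:
        """Proteins x all-voxels matrix over the study-wide protein index.

        Proteins unmeasured in an image appear as NaN in that image's
        columns; columns are named ``{image_id}_r{row}c{col}``.
        """
        blocks = []
        index = self.protein_index
        for im in self.images:
            block = im.abundance.reindex(index)
            block.columns = [column_name(im.image_id, r, c) for r, c in im.grid.coords()]
            blocks.append(block)
        return pd.concat(blocks, axis=1)

    def voxel_table(self, metric: str = "euclidean_centroid_um") -> pd.DataFrame:
        """Voxel metadata sidecar: image_id, row, col, label, distance_um."""
        rows = []
        for im in self.images:
            labels = im.labels()
            dists = im.distances(metric)
            for i, (r, c) in enumerate(im.grid.coords()):
                rows.append(
                    {
                        "image_id": im.image_id,
                        "row": r,
                        "col": c,
                        "label": labels[i],
                        "distance_um": dists[i],
                    }
                )
        return pd.DataFrame(rows)

    def voxel_labels(self) -> np.ndarray:
        return np.concatenate([im.labels() for im in self.images])

    def voxel_image_ids(self) -> np.ndarray:
        return np.concatenate(
            [np.repeat(im.image_id, im.n_voxels) for im in self.images]
        )
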