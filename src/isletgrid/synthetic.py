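"""Synthetic study generator with planted ground truth.

Emulates the statistical structure of a grid-sampled spatial proteomics
study of the islet microenvironment: seven 3x3-voxel images measured as
separate TMT plexes, one islet voxel per image, a small fraction of
islet-marker proteins elevated in the islet voxel only, a fraction of
gradient proteins whose abundance varies linearly with physical distance
from the islet, a per-plex location shift (batch effect), Gaussian
measurement noise, and abundance-dependent (left-censoring flavoured)
missingness.  Matched pathway and interactome fixtures carry the planted
signal so that every downstream stage can be validated against ground
truth without external databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .enrichment import PathwayDB
from .errors import ConfigurationError
from .grid import EDGE_MIDDLE_POSITIONS, ProteomeImage, Study, VoxelGrid, voxel_name

#: Ground-truth protein classes.
CLASS_ISLET_MARKER = "islet_marker"
CLASS_GRADIENT = "gradient"
CLASS_BACKGROUND = "background"

#: Names of the planted pathway sets.
MARKER_SET = "islet_markers"
GRADIENT_SET = "gradient_proteins"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-generation parameters (log2 units throughout).

    Defaults mirror the target study design: 7 images of 3x3 voxels with
    one edge-middle islet voxel each; ~2% islet markers elevated by 2 log2
    units in the islet voxel; ~5% gradient proteins with a -0.002 log2/um
    slope (about -1.2 log2 across the grid diagonal); per-plex shifts of
    sd 0.3; residual noise sd 0.5; ~2% baseline missingness increasing for
    low-abundance measurements.
    """

    n_images: int = 7
    n_proteins: int = 2000
    frac_islet_markers: float = 0.02
    frac_gradient: float = 0.05
    islet_effect: float = 2.0
    gradient_slope: float = -0.002
    plex_shift_sd: float = 0.3
    noise_sd: float = 0.5
    baseline_sd: float = 1.0
    missing_rate_base: float = 0.02
    missing_abundance_coupling: float = 1.0
    seed: int = 0
    voxel_width_um: float = 200.0
    voxel_height_um: float = 300.0

    def __post_init__(self) -> None:
        if self.n_images < 1 or self.n_proteins < 1:
            raise ConfigurationError("need at least one image and one protein")
        for name in ("frac_islet_markers", "frac_gradient", "missing_rate_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.frac_islet_markers + self.frac_gradient > 1.0:
            raise ConfigurationError("marker and gradient fractions exceed 1")
        for name in ("plex_shift_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic study."""

    config: SyntheticConfig
    protein_class: pd.Series  # protein -> class label
    plex_shift: pd.Series  # image_id -> log2 shift
    true_abundance: pd.DataFrame  # noiseless, shift-free proteins x voxels
    pathways: dict[str, list[str]] = field(default_factory=dict)

    @property
    def islet_markers(self) -> list[str]:
        return list(self.protein_class.index[self.protein_class == CLASS_ISLET_MARKER])

    @property
    def gradient_proteins(self) -> list[str]:
        return list(self.protein_class.index[self.protein_class == CLASS_GRADIENT])

    def frame(self) -> pd.DataFrame:
        """Ground truth as a flat table for TSV export."""
        return pd.DataFrame(
            {"protein": self.protein_class.index, "class": self.protein_class.values}
        )


def missingness_probability(
    true_value: np.ndarray, config: SyntheticConfig
) -> np.ndarray:
    """Dropout probability for a given true log2 abundance.

    Logistic in the true value: equals ``missing_rate_base`` at the centre
    of the baseline distribution (0) and rises as abundance falls, with
    slope ``missing_abundance_coupling`` per log2 unit.
    """
    alpha = logit(config.missing_rate_base)
    return expit(alpha - config.missing_abundance_coupling * np.asarray(true_value))


def generate_study(config: SyntheticConfig) -> tuple[Study, GroundTruth]:
    """Simulate a study and its ground truth, fully determined by the seed.

    Per-image random substreams are spawned deterministically from the
    global seed.  Islet voxels cycle through the four edge-middle positions
    so that every image shows the canonical 1/5/3 region split.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    assign_ss, *image_ss = root.spawn(1 + cfg.n_images)
    rng = np.random.default_rng(assign_ss)

    width = len(str(max(cfg.n_proteins - 1, 1)))
    proteins = pd.Index(
        [f"P{i:0{width}d}" for i in range(cfg.n_proteins)], name="protein"
    )
    n_markers = int(round(cfg.frac_islet_markers * cfg.n_proteins))
    n_gradient = int(round(cfg.frac_gradient * cfg.n_proteins))
    order = rng.permutation(cfg.n_proteins)
    classes = pd.Series(CLASS_BACKGROUND, index=proteins, name="class")
    classes.iloc[order[:n_markers]] = CLASS_ISLET_MARKER
    classes.iloc[order[n_markers : n_markers + n_gradient]] = CLASS_GRADIENT

    baseline = rng.normal(0.0, cfg.baseline_sd, size=cfg.n_proteins)
    shifts = rng.normal(0.0, cfg.plex_shift_sd, size=cfg.n_images)

    marker_mask = (classes == CLASS_ISLET_MARKER).to_numpy()
    gradient_mask = (classes == CLASS_GRADIENT).to_numpy()

    images: list[ProteomeImage] = []
    truth_blocks: list[pd.DataFrame] = []
    image_ids = [f"image{i}" for i in range(cfg.n_images)]
    for i, (image_id, ss) in enumerate(zip(image_ids, image_ss)):
        irng = np.random.default_rng(ss)
        grid = VoxelGrid(
            voxel_width_um=cfg.voxel_width_um,
            voxel_height_um=cfg.voxel_height_um,
            islet_index=EDGE_MIDDLE_POSITIONS[i % len(EDGE_MIDDLE_POSITIONS)],
        )
        labels = np.array([grid.islet_index == v for v in grid.coords()])
        dists = np.array(
            [np.hypot((v[0] - grid.islet_index[0]) * cfg.voxel_height_um,
                      (v[1] - grid.islet_index[1]) * cfg.voxel_width_um)
             for v in grid.coords()]
        )
        # noiseless signal without the plex shift (stored as ground truth)
        true = np.tile(baseline[:, None], (1, grid.n_voxels))
        true[marker_mask] += cfg.islet_effect * labels[None, :]
        true[gradient_mask] += cfg.gradient_slope * dists[None, :]

        observed = true + shifts[i] + irng.normal(0.0, cfg.noise_sd, size=true.shape)
        p_miss = missingness_probability(true, cfg)
        dropout = irng.random(true.shape) < p_miss
        observed[dropout] = np.nan

        cols = [voxel_name(r, c) for r, c in grid.coords()]
        images.append(
            ProteomeImage(
                image_id=image_id,
                grid=grid,
                abundance=pd.DataFrame(observed, index=proteins, columns=cols),
            )
        )
        truth_blocks.append(
            pd.DataFrame(true, index=proteins,
                         columns=[f"{image_id}_{c}" for c in cols])
        )

    truth = GroundTruth(
        config=cfg,
        protein_class=classes,
        plex_shift=pd.Series(shifts, index=image_ids, name="plex_shift"),
        true_abundance=pd.concat(truth_blocks, axis=1),
    )
    return Study(images), truth


def generate_pathways(
    ground_truth: GroundTruth,
    n_random_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 50),
    seed: Optional[int] = None,
) -> PathwayDB:
    """Pathway fixture: the planted marker set, the planted gradient set,
    and ``n_random_sets`` uniformly drawn decoy sets.

    The random-set seed is derived from the study seed unless given.
    """
    cfg = ground_truth.config
    lo, hi = set_size_range
    if hi > cfg.n_proteins:
        raise ConfigurationError(
            f"set size {hi} exceeds n_proteins={cfg.n_proteins}"
        )
    if lo < 1 or lo > hi:
        raise ConfigurationError(f"bad set_size_range {set_size_range}")
    rng = np.random.default_rng(
        np.random.SeedSequence((cfg.seed, 1001)) if seed is None else seed
    )
    proteins = np.asarray(ground_truth.protein_class.index)
    sets: dict[str, list[str]] = {}
    if ground_truth.islet_markers:
        sets[MARKER_SET] = ground_truth.islet_markers
    if ground_truth.gradient_proteins:
        sets[GRADIENT_SET] = ground_truth.gradient_proteins
    width = len(str(max(n_random_sets, 1)))
    for j in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(proteins, size=size, replace=False))
        sets[f"random_set_{j:0{width}d}"] = members
    db = PathwayDB(sets, source="synthetic")
    ground_truth.pathways = {k: list(v) for k, v in sets.items()}
    return db


def generate_interactome(
    ground_truth: GroundTruth,
    background_density: float = 0.01,
    confidence_range: tuple[float, float] = (0.4, 0.9),
    n_hidden_hubs: int = 2,
    n_background_nodes: int = 150,
    hub_confidence: float = 0.99,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """STRING-like weighted edge list with a planted marker subnetwork.

    The islet-marker proteins form a connected random tree (confidences
    0.7-0.95).  Each hidden hub ("HUB*", absent from the measured protein
    index) bridges one pair of tree-non-adjacent markers with high
    confidence, so it lies on a shortest confidence-weighted path between
    them and exercises Steiner-node recovery.  Background edges between a
    sample of measured proteins are added independently at
    ``background_density`` with confidences in ``confidence_range``.

    Returns a DataFrame with columns ``protein_a, protein_b, confidence``.
    """
    if not 0.0 <= background_density <= 1.0:
        raise ConfigurationError(f"background_density={background_density} outside [0, 1]")
    lo, hi = confidence_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ConfigurationError(f"bad confidence_range {confidence_range}")
    cfg = ground_truth.config
    rng = np.random.default_rng(
        np.random.SeedSequence((cfg.seed, 1002)) if seed is None else seed
    )
    markers = ground_truth.islet_markers
    edges: list[tuple[str, str, float]] = []

    # planted random tree over the markers
    adjacency: dict[str, set[str]] = {m: set() for m in markers}
    for j in range(1, len(markers)):
        parent = markers[int(rng.integers(0, j))]
        conf = float(rng.uniform(0.7, 0.95))
        edges.append((parent, markers[j], conf))
        adjacency[parent].add(markers[j])
        adjacency[markers[j]].add(parent)

    # hidden hubs bridging tree-non-adjacent marker pairs
    used_pairs: set[frozenset[str]] = set()
    n_hubs = n_hidden_hubs if len(markers) >= 4 else 0
    for h in range(n_hubs):
        for _ in range(200):
            a, b = rng.choice(markers, size=2, replace=False)
            pair = frozenset((a, b))
            if b not in adjacency[a] and pair not in used_pairs:
                used_pairs.add(pair)
                hub = f"HUB{h:02d}"
                edges.append((a, hub, hub_confidence))
                edges.append((hub, b, hub_confidence))
                break

    # background edges over a sample of measured non-marker proteins
    others = [p for p in ground_truth.protein_class.index if p not in set(markers)]
    n_bg = min(n_background_nodes, len(others))
    bg_nodes = list(rng.choice(np.asarray(others), size=n_bg, replace=False))
    universe = sorted(set(markers) | set(bg_nodes))
    if background_density > 0 and len(universe) > 1:
        planted = {frozenset((a, b)) for a, b, _ in edges}
        nodes = np.asarray(universe)
        iu, ju = np.triu_indices(len(nodes), k=1)
        keep = rng.random(len(iu)) < background_density
        for a, b in zip(nodes[iu[keep]], nodes[ju[keep]]):
            if frozenset((a, b)) in planted:
                continue
            edges.append((str(a), str(b), float(rng.uniform(lo, hi))))

    return pd.DataFrame(edges, columns=["protein_a", "protein_b", "confidence"])
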