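"""End-to-end pipeline: preprocess -> DE -> enrichment -> gradient -> network.

A single configuration object (YAML on disk, sections per stage) drives the
whole analysis.  Given input files the pipeline reads them; otherwise it
simulates a synthetic study with matched pathway and interactome fixtures.
All stage outputs are written as TSV plus a JSON run manifest; identical
configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .diffexp import CONTRASTS, fit_region_model, overlap_counts, significant_sets
from .enrichment import enrichment_in_order, enrichment_in_sets, read_gmt, write_gmt
from .errors import IsletGridError
from .gradient import (
    consensus_pathways,
    distance_order_enrichment,
    pathway_protein_profiles,
    protein_variance_scores,
    study_distance_correlations,
)
from .grid import Study
from .io import (
    read_edge_list,
    read_study,
    write_edge_list,
    write_matrix,
    write_study,
    write_table,
)
from .pcsf import (
    DOWN_IN_ISLET,
    UP_IN_ISLET,
    Interactome,
    PCSFParams,
    build_prizes,
    classify_nodes,
    solution_graph,
    solve_pcsf,
)
from .preprocess import impute_median, median_center, missingness_summary, pca_embedding
from .synthetic import (
    SyntheticConfig,
    generate_interactome,
    generate_pathways,
    generate_study,
)

logger = logging.getLogger("isletgrid")

_SECTIONS = ("input", "simulate", "preprocess", "diffexp", "gradient", "network")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; YAML files use one section per stage."""

    seed: int = 0
    # input files (all four required to skip simulation)
    matrix_path: str | None = None
    meta_path: str | None = None
    gmt_path: str | None = None
    edges_path: str | None = None
    # simulate
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    n_random_sets: int = 20
    set_size_range: tuple[int, int] = (10, 50)
    background_density: float = 0.01
    # preprocess
    center: bool = False
    pca_components: int = 2
    # diffexp
    contrasts: tuple[str, ...] = CONTRASTS
    alpha: float = 0.05
    moderation: str = "eb"
    include_image: bool = True
    # gradient
    metric: str = "euclidean_centroid_um"
    min_images: int = 4
    use_adjusted: bool = True
    profile_threshold: float = 0.05
    # network
    beta: float = 1.0
    omega: float | None = None
    epsilon: float = 0.01
    network_contrast: str = "islet_vs_rest"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        flat: dict = {}
        for key, value in data.items():
            if key in _SECTIONS and isinstance(value, dict):
                if key == "simulate":
                    flat["synthetic"] = {
                        k: v for k, v in value.items()
                        if k in {f.name for f in dataclasses.fields(SyntheticConfig)}
                    }
                    for k in ("n_random_sets", "set_size_range", "background_density"):
                        if k in value:
                            flat[k] = value[k]
                elif key == "input":
                    for k, v in value.items():
                        flat[f"{k}_path"] = v
                else:
                    flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise IsletGridError(f"unknown configuration key(s): {sorted(unknown)}")
        if "set_size_range" in flat:
            flat["set_size_range"] = tuple(flat["set_size_range"])
        if "contrasts" in flat:
            flat["contrasts"] = tuple(flat["contrasts"])
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["set_size_range"] = list(d["set_size_range"])
        d["contrasts"] = list(d["contrasts"])
        return d


class StageError(IsletGridError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def load_or_simulate(config: PipelineConfig, outdir: Path):
    """Return (study, pathway db, interactome edges, ground_truth or None)."""
    if config.matrix_path and config.meta_path:
        study = read_study(config.matrix_path, config.meta_path)
        db = read_gmt(config.gmt_path) if config.gmt_path else None
        edges = read_edge_list(config.edges_path) if config.edges_path else None
        return study, db, edges, None
    syn = SyntheticConfig(**{**config.synthetic, "seed": config.seed})
    study, truth = generate_study(syn)
    db = generate_pathways(
        truth, n_random_sets=config.n_random_sets,
        set_size_range=config.set_size_range,
    )
    edges = generate_interactome(truth, background_density=config.background_density)
    write_study(study, outdir / "study_matrix.tsv", outdir / "voxel_meta.tsv")
    write_table(truth.frame(), outdir / "ground_truth.tsv")
    write_gmt(db, outdir / "pathways.gmt")
    write_edge_list(edges, outdir / "interactome.tsv")
    return study, db, edges, truth


@_stage("preprocess")
def _run_preprocess(config: PipelineConfig, study: Study, outdir: Path):
    per_voxel, per_image = missingness_summary(study)
    write_table(per_voxel, outdir / "missingness_voxel.tsv")
    write_table(per_image.reset_index(), outdir / "missingness_image.tsv")
    completed = impute_median(study)
    if config.center:
        completed = median_center(completed)
    write_matrix(completed, outdir / "completed_matrix.tsv")
    scores, evr = pca_embedding(completed, config.pca_components)
    scores = scores.reset_index()
    write_table(scores, outdir / "pca_scores.tsv")
    return completed


@_stage("diffexp")
def _run_diffexp(config: PipelineConfig, study: Study, completed, outdir: Path):
    de = fit_region_model(
        completed, study.voxel_labels(), study.voxel_image_ids(),
        contrasts=config.contrasts, include_image=config.include_image,
        moderation=config.moderation,
    )
    write_table(de, outdir / "de_table.tsv")
    write_table(overlap_counts(de, threshold=config.alpha),
                outdir / "upset_counts.tsv")
    return de


@_stage("enrichment")
def _run_enrichment(config: PipelineConfig, de, completed, db, outdir: Path):
    background = list(completed.index)
    sets = significant_sets(de, config.alpha)
    contrast = config.network_contrast
    sub = de[de["contrast"] == contrast]
    up = sorted(set(sub.loc[sub["logFC"] > 0, "protein"]) & sets[contrast])
    down = sorted(set(sub.loc[sub["logFC"] < 0, "protein"]) & sets[contrast])
    for tag, selected in (("up", up), ("down", down)):
        if selected:
            res = enrichment_in_sets(selected, background, db)
        else:
            res = pd.DataFrame(
                columns=["pathway", "n_background", "n_set", "n_selected",
                         "n_overlap", "z", "p", "adj_p"]
            )
        write_table(res, outdir / f"enrichment_sets_{tag}.tsv")
    variance = protein_variance_scores(completed)
    order = enrichment_in_order(variance, db)
    write_table(order, outdir / "enrichment_order_variance.tsv")
    return order


@_stage("gradient")
def _run_gradient(config: PipelineConfig, study: Study, completed, db, outdir: Path):
    corr = study_distance_correlations(study, config.metric, completed)
    write_table(pd.concat(corr.values(), ignore_index=True),
                outdir / "distance_corr.tsv")
    per_image = distance_order_enrichment(corr, db)
    long = pd.concat(
        [frame.assign(image_id=img) for img, frame in per_image.items()],
        ignore_index=True,
    )
    write_table(long, outdir / "order_enrichment_per_image.tsv")
    summary, zmat = consensus_pathways(
        per_image, alpha=config.alpha, min_images=config.min_images,
        use_adjusted=config.use_adjusted,
    )
    write_table(summary, outdir / "consensus_summary.tsv")
    zmat.reset_index().to_csv(outdir / "consensus_z.tsv", sep="\t",
                              index=False, na_rep="NA")
    flagged = summary.loc[summary["consensus"], "pathway"].tolist()
    profiles = []
    for pathway in flagged:
        prof = pathway_protein_profiles(
            pathway, db, corr, study, completed,
            p_threshold=config.profile_threshold, metric=config.metric,
        )
        profiles.append(prof.assign(pathway=pathway))
    if profiles:
        write_table(pd.concat(profiles, ignore_index=True),
                    outdir / "pathway_profiles.tsv")
    return summary, flagged


@_stage("network")
def _run_network(config: PipelineConfig, de, edges, outdir: Path):
    interactome = Interactome(edges, epsilon=config.epsilon)
    params = PCSFParams(beta=config.beta, omega=config.omega,
                        epsilon=config.epsilon)
    results = {}
    for tag, direction in (("up", UP_IN_ISLET), ("down", DOWN_IN_ISLET)):
        prizes = build_prizes(de, config.network_contrast, direction, config.alpha)
        n_prized = int((prizes > 0).sum())
        if n_prized == 0 or not prizes[prizes > 0].index.isin(
            interactome.graph.nodes
        ).any():
            logger.info("network %s: no prized protein in the interactome", tag)
            results[tag] = None
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            solution = solve_pcsf(interactome, prizes, params)
        write_table(classify_nodes(solution, prizes, de, config.network_contrast),
                    outdir / f"network_{tag}_nodes.tsv")
        write_table(
            pd.DataFrame(solution.edges,
                         columns=["protein_a", "protein_b", "cost"]),
            outdir / f"network_{tag}_edges.tsv",
        )
        nx.write_gml(solution_graph(solution), outdir / f"network_{tag}.gml")
        results[tag] = {
            "n_prized": n_prized,
            "n_nodes": len(solution.node_flags),
            "n_terminals": len(solution.terminals),
            "n_steiner": len(solution.steiner_nodes),
            "n_edges": len(solution.edges),
            "n_trees": solution.n_trees,
            "objective": solution.objective,
        }
    return results


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, seed: int | None = None
) -> dict:
    """Execute every stage and write a run manifest.

    Any stage failure aborts with a stage-named :class:`StageError`;
    partial outputs are retained next to a ``FAILED`` marker file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    try:
        study, db, edges, truth = load_or_simulate(config, outdir)
        completed = _run_preprocess(config, study, outdir)
        de = _run_diffexp(config, study, completed, outdir)
        if db is not None:
            _run_enrichment(config, de, completed, db, outdir)
            _, flagged = _run_gradient(config, study, completed, db, outdir)
        else:
            flagged = []
        network = _run_network(config, de, edges, outdir) if edges is not None else {}
    except Exception:
        (outdir / "FAILED").write_text("pipeline failed; partial outputs retained\n")
        raise
    sig = significant_sets(de, config.alpha)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.as_dict(),
        "n_images": len(study.images),
        "n_voxels": study.n_voxels,
        "n_proteins": len(study.protein_index),
        "n_proteins_completed": len(completed),
        "significant_counts": {c: len(s) for c, s in sorted(sig.items())},
        "consensus_pathways": flagged,
        "networks": network,
        "outputs": sorted(
            p.name for p in outdir.iterdir()
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d images, %d voxels",
                manifest["n_images"], manifest["n_voxels"])
    return manifest
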