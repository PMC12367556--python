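"""End-to-end pipeline: simulate → QC/bin → assign → score → zonate → niches → size-correlation.

The pipeline runs the full spatial analysis over one synthetic tissue
section per condition (or over user-supplied bundles), writing every
stage's outputs as TSV/CSV/JSON plus a manifest recording the resolved
configuration, input hashes and record counts at every filter, so each
printed threshold is auditable.  Deterministic stages reproduce bit-for-bit
given the same configuration and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import (
    assign_to_boundaries,
    assign_to_nuclei,
    build_count_matrix,
)
from .niches import cluster_niches, colocalization_enrichment, neighborhood_composition
from .scoring import score_gene_set, stress_map
from .size_expression import compute_areas, gene_area_correlation
from .synthetic import ADIPOCYTE_STATES, STRESS_GENES, SyntheticTissue, TissueConfig, generate_tissue, write_bundle
from .transcripts import bin_transcripts, filter_by_qv
from .zonation import quantile_zonation

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and toggles of the pipeline, YAML-serialisable.

    Defaults carry the workflow's printed thresholds: QV > 35, 50-µm bins
    kept at > 10 transcripts, 2-µm assignment radius, nuclei kept at > 40
    transcripts, adipocyte area gate (1,000, 25,000) µm², 300-µm niche
    radius, control size 50, gene-selection p < 1e-5.
    """

    conditions: tuple[str, ...] = ("lean", "obese", "weight_loss")
    qv_threshold: float = 35.0
    bin_size: float = 50.0
    bin_min: int = 10
    assign_radius: float = 2.0
    cell_min: int = 40
    area_min: float = 1_000.0
    area_max: float = 25_000.0
    niche_radius: float = 300.0
    coloc_radius: float = 30.0
    control_size: int = 50
    n_expression_bins: int = 25
    selection_p: float = 1e-5
    merge_tau: float = 0.05
    k_neighbors: int = 30
    resolution: float = 0.2
    n_permutations: int = 250
    n_quantiles: int = 4
    normalize_target: float = 1e4
    seed: int = 0
    stress_genes: tuple[str, ...] = tuple(STRESS_GENES)
    stages: tuple[str, ...] = (
        "simulate", "qc", "assign", "score", "zonate", "niches", "sizecorr",
    )

    def __post_init__(self) -> None:
        for name in ("qv_threshold",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("bin_size", "assign_radius", "niche_radius", "coloc_radius",
                     "normalize_target", "selection_p", "resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.area_min < self.area_max):
            raise ValueError("need 0 < area_min < area_max")
        unknown = set(self.stages) - {
            "simulate", "qc", "assign", "score", "zonate", "niches", "sizecorr"
        }
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("conditions", "stress_genes", "stages"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("conditions", "stress_genes", "stages"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: dict, counts: dict) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "parameters": params,
        "counts": counts,
        "outputs": {
            p.name: _sha256(p) for p in sorted(stage_dir.iterdir()) if p.is_file()
        },
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the enabled stages in dependency order.

    Returns a dict of in-memory results per stage; every stage also writes
    its outputs and a manifest under ``out_dir/<stage>/``.  The fully
    resolved configuration is emitted alongside the outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "resolved_config.yaml")

    ordered = ["simulate", "qc", "assign", "score", "zonate", "niches", "sizecorr"]
    stages = [s for s in ordered if s in config.stages]
    results: dict = {}

    # --- simulate -----------------------------------------------------------
    if "simulate" in stages:
        stage_dir = out_dir / "simulate"
        stage_dir.mkdir(exist_ok=True)
        tissues: dict[str, SyntheticTissue] = {}
        for i, cond in enumerate(config.conditions):
            tc = TissueConfig(condition=cond, seed=config.seed + i)
            tissues[cond] = generate_tissue(tc)
            write_bundle(tissues[cond], stage_dir / cond)
        results["simulate"] = tissues
        _write_manifest(
            stage_dir, "simulate",
            {"seed": config.seed, "conditions": list(config.conditions)},
            {c: len(t.transcripts) for c, t in tissues.items()},
        )
    else:
        raise ValueError("pipeline currently requires the simulate stage as input source")

    # --- qc: QV filter + binning -------------------------------------------
    filtered: dict[str, pd.DataFrame] = {}
    grids = {}
    if "qc" in stages:
        stage_dir = out_dir / "qc"
        stage_dir.mkdir(exist_ok=True)
        counts = {}
        for cond, tissue in tissues.items():
            ft = filter_by_qv(tissue.transcripts, config.qv_threshold)
            grid = bin_transcripts(ft, config.bin_size, config.bin_min)
            filtered[cond] = ft
            grids[cond] = grid
            grid.to_frame().to_csv(stage_dir / f"bins_{cond}.tsv", sep="\t", index=False)
            counts[cond] = {
                "transcripts_in": len(tissue.transcripts),
                "transcripts_kept": len(ft),
                "bins": len(grid.bins),
                "bins_kept": int(grid.bins["kept"].sum()),
            }
        results["qc"] = {"filtered": filtered, "grids": grids}
        _write_manifest(stage_dir, "qc",
                        {"qv_threshold": config.qv_threshold,
                         "bin_size": config.bin_size, "bin_min": config.bin_min},
                        counts)

    # --- assign: both modes + matrices --------------------------------------
    matrices = {}
    boundary_matrices = {}
    if "assign" in stages:
        if "qc" not in stages:
            raise ValueError("stage 'assign' requires upstream stage 'qc'")
        stage_dir = out_dir / "assign"
        stage_dir.mkdir(exist_ok=True)
        counts = {}
        for cond, tissue in tissues.items():
            ft = filtered[cond]
            na = assign_to_nuclei(ft, tissue.nuclei, config.assign_radius)
            states = tissue.truth_states
            meta = tissue.truth.set_index("cell_id")[["state", "niche", "area", "x", "y"]]
            meta = meta.assign(sample=cond, condition=cond)
            adata = build_count_matrix(
                na, ft, min_transcripts=config.cell_min,
                normalize_target=config.normalize_target, metadata=meta,
            )
            non_adip = na[~na["object_id"].map(states).isin(ADIPOCYTE_STATES)]
            ba = assign_to_boundaries(
                ft, tissue.boundaries, config.assign_radius, exclude=non_adip,
                area_min=config.area_min, area_max=config.area_max,
            )
            bdata = build_count_matrix(
                ba, ft, min_transcripts=0, normalize_target=1.0, metadata=meta,
            )
            matrices[cond] = adata
            boundary_matrices[cond] = bdata
            na.to_csv(stage_dir / f"nucleus_assignment_{cond}.tsv", sep="\t", index=False)
            counts[cond] = {
                "nucleus_assigned": len(na),
                "boundary_pairs": len(ba),
                "cells_nucleus_mode": adata.n_obs,
                "cells_boundary_mode": bdata.n_obs,
            }
        results["assign"] = {"nucleus": matrices, "boundary": boundary_matrices}
        _write_manifest(stage_dir, "assign",
                        {"assign_radius": config.assign_radius,
                         "cell_min": config.cell_min,
                         "area_min": config.area_min, "area_max": config.area_max},
                        counts)

    # --- score: bin-level stress maps + cell-level stress scores -------------
    cell_scores = {}
    if "score" in stages:
        if "assign" not in stages:
            raise ValueError("stage 'score' requires upstream stage 'assign'")
        stage_dir = out_dir / "score"
        stage_dir.mkdir(exist_ok=True)
        counts = {}
        maps = {}
        for cond in tissues:
            adata = matrices[cond]
            sc = score_gene_set(
                adata, list(config.stress_genes), config.control_size,
                config.n_expression_bins, seed=config.seed,
            )
            cell_scores[cond] = sc.scores
            # bin-level: aggregate kept-bin counts into a bin × gene matrix
            grid = grids[cond]
            kept = grid.bins[grid.bins["kept"]]
            bin_mat = _bin_matrix(grid, config.normalize_target)
            bsc = score_gene_set(
                bin_mat, list(config.stress_genes), config.control_size,
                config.n_expression_bins, seed=config.seed,
            )
            smap = stress_map(bsc, kept.reset_index(drop=True))
            maps[cond] = smap
            smap.to_csv(stage_dir / f"stress_map_{cond}.tsv", sep="\t", index=False)
            sc.scores.rename("score").to_csv(
                stage_dir / f"cell_scores_{cond}.tsv", sep="\t"
            )
            counts[cond] = {"cells_scored": len(sc.scores), "bins_scored": len(smap)}
        results["score"] = {"cells": cell_scores, "maps": maps}
        _write_manifest(stage_dir, "score",
                        {"control_size": config.control_size,
                         "n_expression_bins": config.n_expression_bins,
                         "stress_genes": list(config.stress_genes)},
                        counts)

    # --- zonate --------------------------------------------------------------
    if "zonate" in stages:
        if "score" not in stages:
            raise ValueError("stage 'zonate' requires upstream stage 'score'")
        stage_dir = out_dir / "zonate"
        stage_dir.mkdir(exist_ok=True)
        frames = []
        for cond in tissues:
            adata = matrices[cond]
            df = adata.obs[["x", "y", "state"]].copy()
            df["score"] = cell_scores[cond].to_numpy()
            frames.append(df)
        pooled = pd.concat(frames, ignore_index=True)
        zon = quantile_zonation(pooled, bin_size=config.bin_size,
                                n_quantiles=config.n_quantiles)
        zon.bin_scores.to_csv(stage_dir / "bin_scores.tsv", sep="\t", index=False)
        zon.composition.to_csv(stage_dir / "composition.tsv", sep="\t")
        results["zonate"] = zon
        _write_manifest(stage_dir, "zonate",
                        {"bin_size": config.bin_size, "n_quantiles": config.n_quantiles},
                        {"cells": len(pooled), "unzoned": zon.n_unzoned})

    # --- niches ---------------------------------------------------------------
    if "niches" in stages:
        stage_dir = out_dir / "niches"
        stage_dir.mkdir(exist_ok=True)
        cells = pd.concat(
            [t.truth.assign(sample=c) for c, t in tissues.items()], ignore_index=True
        )
        nb = neighborhood_composition(
            cells, radius=config.niche_radius, sample_col="sample"
        )
        na = cluster_niches(
            nb, k_neighbors=config.k_neighbors, resolution=config.resolution,
            merge_tau=config.merge_tau, batch=cells["sample"], seed=config.seed,
        )
        coloc = colocalization_enrichment(
            cells, radius=config.coloc_radius,
            n_permutations=config.n_permutations, seed=config.seed,
            sample_col="sample",
        )
        pd.DataFrame({"cell_id": cells["cell_id"], "sample": cells["sample"],
                      "niche": na.labels}).to_csv(
            stage_dir / "niche_labels.tsv", sep="\t", index=False)
        na.summary.to_csv(stage_dir / "niche_summary.tsv", sep="\t")
        coloc.z.to_csv(stage_dir / "colocalization_z.tsv", sep="\t")
        results["niches"] = {"assignment": na, "neighborhood": nb, "coloc": coloc}
        _write_manifest(stage_dir, "niches",
                        {"niche_radius": config.niche_radius,
                         "coloc_radius": config.coloc_radius,
                         "resolution": config.resolution,
                         "merge_tau": config.merge_tau,
                         "n_permutations": config.n_permutations},
                        {"cells": len(cells), "niches": int(na.labels.nunique())})

    # --- sizecorr --------------------------------------------------------------
    if "sizecorr" in stages:
        if "assign" not in stages:
            raise ValueError("stage 'sizecorr' requires upstream stage 'assign'")
        stage_dir = out_dir / "sizecorr"
        stage_dir.mkdir(exist_ok=True)
        import anndata as ad

        parts = []
        for cond, bdata in boundary_matrices.items():
            part = bdata.copy()
            part.obs_names = [f"{cond}:{i}" for i in part.obs_names]
            parts.append(part)
        joined = ad.concat(parts, join="outer", merge="same")
        area_tables = []
        for cond, tissue in tissues.items():
            at = compute_areas(
                tissue.boundaries, config.area_min, config.area_max,
            )
            at["condition"] = cond
            at.index = pd.Index([f"{cond}:{i}" for i in at.index], name="object_id")
            area_tables.append(at)
        areas = pd.concat(area_tables)
        corr = gene_area_correlation(
            joined, areas, selection_p=config.selection_p,
        )
        corr.to_csv(stage_dir / "gene_area_correlation.tsv", sep="\t", index=False)
        results["sizecorr"] = corr
        _write_manifest(stage_dir, "sizecorr",
                        {"selection_p": config.selection_p,
                         "area_min": config.area_min, "area_max": config.area_max},
                        {"genes": int(corr["gene"].nunique()),
                         "selected": int(corr.loc[corr["selected"], "gene"].nunique())})

    return results


def _bin_matrix(grid, normalize_target: float):
    """Kept bins × genes AnnData with normalized/lognorm layers."""
    import anndata as ad
    from scipy.sparse import csr_matrix

    kept = grid.bins[grid.bins["kept"]].reset_index(drop=True)
    key = kept[["ix", "iy"]].apply(tuple, axis=1)
    pos = {k: i for i, k in enumerate(key)}
    sub = grid.assignments
    sub = sub[[(a, b) in pos for a, b in zip(sub["ix"], sub["iy"])]]
    genes = sorted(sub["gene"].unique())
    gi = {g: k for k, g in enumerate(genes)}
    rows = [pos[(a, b)] for a, b in zip(sub["ix"], sub["iy"])]
    cols = [gi[g] for g in sub["gene"]]
    X = csr_matrix(
        (np.ones(len(sub)), (rows, cols)), shape=(len(kept), len(genes))
    ).astype(np.int64)
    obs = pd.DataFrame(index=pd.Index(
        [f"bin_{a}_{b}" for a, b in zip(kept['ix'], kept['iy'])], name="bin_id"))
    adata = ad.AnnData(X=X, obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    tot = np.asarray(X.sum(axis=1)).ravel()
    scale = np.divide(normalize_target, tot, out=np.zeros_like(tot, dtype=float),
                      where=tot > 0)
    normalized = X.multiply(scale[:, None]).tocsr()
    adata.layers["normalized"] = normalized
    adata.layers["lognorm"] = normalized.copy()
    adata.layers["lognorm"].data = np.log1p(adata.layers["lognorm"].data)
    return adata
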