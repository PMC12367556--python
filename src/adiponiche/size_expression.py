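"""Adipocyte area computation and gene–area Spearman correlation.

Areas come from membrane-segmentation pixel masks (pixel count × pixel
area), gated to the (1,000, 25,000) µm² adipocyte range.  For each gene,
normalized per-cell expression is correlated with area by Spearman rank
correlation in each condition separately and across all conditions
combined.  A gene is *selected* when its p-value beats the threshold
(1 × 10⁻⁵ by default) in more than one of those correlations; selected
genes are ranked high-to-low by the combined-stratum coefficient.
"""

from __future__ import annotations

import logging
import warnings

import anndata as ad
import numpy as np
import pandas as pd

from .assignment import AREA_MIN, AREA_MAX
from .containers import SegmentedObjectSet
from .stats import spearman_rho

__all__ = ["compute_areas", "gene_area_correlation"]

logger = logging.getLogger(__name__)

COMBINED = "combined"


def compute_areas(
    cells: SegmentedObjectSet,
    area_min: float = AREA_MIN,
    area_max: float = AREA_MAX,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Area table of boundary cells passing the strict area gate.

    Returns a frame indexed by object_id with columns area (µm², pixel
    count × pixel area), x and y (pixel-mean centroid), joined with any
    supplied per-object metadata (condition, sample).
    """
    if cells.kind != "boundary_cell":
        raise ValueError("areas require boundary-segmented cells")
    if cells.pixel_size is None or cells.pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    areas = cells.areas()
    cent = cells.pixels.groupby("object_id")[["px", "py"]].mean()
    cent = (cent + 0.5) * cells.pixel_size
    out = pd.DataFrame(
        {"area": areas, "x": cent["px"].reindex(areas.index),
         "y": cent["py"].reindex(areas.index)}
    )
    out = out[(out["area"] > area_min) & (out["area"] < area_max)]
    out.index.name = "object_id"
    if metadata is not None:
        out = out.join(metadata, how="left")
    logger.info(
        "area table: %d of %d objects inside (%g, %g) µm²",
        len(out), len(cells), area_min, area_max,
    )
    return out


def gene_area_correlation(
    adata: ad.AnnData,
    areas: pd.DataFrame,
    condition_key: str = "condition",
    selection_p: float = 1e-5,
    min_hits: int = 2,
    min_stratum_n: int = 5,
    layer: str = "normalized",
) -> pd.DataFrame:
    """Spearman correlation of normalized gene expression with cell area.

    Strata are each condition level plus all conditions combined.  A gene is
    selected when p < ``selection_p`` in at least ``min_hits`` strata; the
    selected genes get ranks 1..n by decreasing combined-stratum rho.

    Returns a long frame (gene, stratum, rho, p, n, selected, rank); a
    constant gene within a stratum yields missing rho/p and can never be
    selected.
    """
    common = adata.obs_names.intersection(areas.index)
    if len(common) == 0:
        raise ValueError("no cells shared between matrix and area table")
    sub = adata[common]
    area_vec = areas.loc[common, "area"].to_numpy(dtype=float)
    if condition_key in sub.obs.columns:
        cond = sub.obs[condition_key].astype(str).to_numpy()
    elif condition_key in areas.columns:
        cond = areas.loc[common, condition_key].astype(str).to_numpy()
    else:
        cond = np.repeat(COMBINED, len(common))
    X = sub.layers[layer] if layer in sub.layers else sub.X
    X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)

    strata: dict[str, np.ndarray] = {COMBINED: np.arange(len(common))}
    for level in sorted(set(cond)):
        if level != COMBINED:
            strata[level] = np.flatnonzero(cond == level)

    records = []
    for g_idx, gene in enumerate(sub.var_names):
        expr = X[:, g_idx]
        for stratum, idx in strata.items():
            n = len(idx)
            if n < min_stratum_n:
                warnings.warn(f"stratum '{stratum}' has n={n} < {min_stratum_n}, skipped")
                continue
            e = expr[idx]
            a = area_vec[idx]
            if np.all(e == e[0]) or np.all(a == a[0]):
                records.append((gene, stratum, np.nan, np.nan, n))
                continue
            rho, p = spearman_rho(a, e)
            records.append((gene, stratum, rho, p, n))
    out = pd.DataFrame(records, columns=["gene", "stratum", "rho", "p", "n"])

    hits = (
        out.dropna(subset=["p"])
        .assign(hit=lambda d: d["p"] < selection_p)
        .groupby("gene")["hit"]
        .sum()
    )
    selected_genes = set(hits[hits >= min_hits].index)
    out["selected"] = out["gene"].isin(selected_genes)

    combined_rho = (
        out[(out["stratum"] == COMBINED) & out["gene"].isin(selected_genes)]
        .dropna(subset=["rho"])
        .set_index("gene")["rho"]
        .sort_values(ascending=False)
    )
    rank_map = {g: i + 1 for i, g in enumerate(combined_rho.index)}
    out["rank"] = out["gene"].map(rank_map).astype("Int64")
    logger.info(
        "size correlation: %d genes, %d selected (p < %g in ≥ %d strata)",
        out["gene"].nunique(), len(selected_genes), selection_p, min_hits,
    )
    return out
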