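"""Transcript-to-cell assignment and count-matrix construction.

Two assignment geometries are provided, mirroring the two segmentation
modes of the spatial workflow:

* **nucleus mode** — each transcript is assigned to the single nearest
  nucleus whose geometry lies within 2 µm (distance 0 inside the polygon);
  ties break to the smaller object id.
* **boundary mode** — adipocytes are membrane-stain pixel masks; cells
  outside the (1,000, 25,000) µm² area gate are removed, transcripts that
  the caller has already attributed to non-adipocytes are dropped, and each
  remaining transcript is assigned to every retained adipocyte whose
  nearest mask pixel lies within 2 µm (multi-assignment permitted; a
  transcript strictly inside a single cell's footprint belongs to that cell
  alone).

Both modes use KD-tree / STR-tree spatial indexes but are defined to agree
exactly with an exhaustive all-pairs scan, which the test suite verifies.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import shapely
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

from .containers import SegmentedObjectSet, validate_transcript_table

__all__ = [
    "assign_to_nuclei",
    "assign_to_boundaries",
    "build_count_matrix",
    "flag_contaminants",
    "AREA_MIN",
    "AREA_MAX",
]

logger = logging.getLogger(__name__)

#: Adipocyte area gate (µm², both bounds strict).
AREA_MIN = 1_000.0
AREA_MAX = 25_000.0

_ASSIGN_COLUMNS = ["transcript_id", "object_id", "distance", "mode"]


def _empty_assignment(mode: str) -> pd.DataFrame:
    df = pd.DataFrame(columns=_ASSIGN_COLUMNS)
    df.attrs["mode"] = mode
    return df


def assign_to_nuclei(
    transcripts: pd.DataFrame,
    nuclei: SegmentedObjectSet,
    max_dist: float = 2.0,
) -> pd.DataFrame:
    """Assign each transcript to the nearest nucleus within ``max_dist`` µm.

    Distance is measured to the nucleus polygon (0 inside) when polygons are
    available, otherwise to the centroid; the convention used is recorded in
    ``result.attrs["distance_to"]``.  "Within" is closed: a transcript at
    exactly ``max_dist`` is assigned.  Transcripts with no nucleus in range
    are simply absent from the result.

    Returns a DataFrame (transcript_id, object_id, distance, mode) with at
    most one row per transcript.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be non-negative")
    validate_transcript_table(transcripts)
    out = _empty_assignment("nucleus")
    if len(transcripts) == 0 or len(nuclei) == 0:
        out.attrs["distance_to"] = "polygon" if nuclei.polygons else "centroid"
        return out

    pts = shapely.points(
        transcripts["x"].to_numpy(dtype=float), transcripts["y"].to_numpy(dtype=float)
    )
    use_polygons = nuclei.polygons is not None and len(nuclei.polygons) == len(nuclei)
    if use_polygons:
        geoms = np.array(
            [shapely.polygons(p) for p in nuclei.polygons], dtype=object
        )
    else:
        geoms = shapely.points(nuclei.centroids[:, 0], nuclei.centroids[:, 1])

    tree = shapely.STRtree(geoms)
    # candidate pairs within the closed radius (pad for float-edge safety,
    # exact distances decide below)
    t_idx, n_idx = tree.query(pts, predicate="dwithin", distance=max_dist * (1 + 1e-12) + 1e-9)
    rows = []
    if len(t_idx):
        dist = shapely.distance(pts[t_idx], geoms[n_idx])
        pairs = pd.DataFrame(
            {"t": t_idx, "n": n_idx, "d": dist, "oid": nuclei.ids[n_idx]}
        )
        pairs = pairs[pairs["d"] <= max_dist]
        # nearest nucleus; ties by smaller object id
        pairs = pairs.sort_values(["t", "d", "oid"], kind="mergesort")
        best = pairs.groupby("t", sort=True).first().reset_index()
        rows = pd.DataFrame(
            {
                "transcript_id": transcripts["transcript_id"].to_numpy()[best["t"]],
                "object_id": best["oid"],
                "distance": best["d"],
                "mode": "nucleus",
            }
        )
    out = rows if len(rows) else out
    out = out.reset_index(drop=True)
    out.attrs["mode"] = "nucleus"
    out.attrs["distance_to"] = "polygon" if use_polygons else "centroid"
    logger.info(
        "nucleus assignment: %d of %d transcripts within %g µm",
        len(out), len(transcripts), max_dist,
    )
    return out


def filter_by_area(
    cells: SegmentedObjectSet,
    area_min: float = AREA_MIN,
    area_max: float = AREA_MAX,
) -> np.ndarray:
    """Ids of boundary cells passing the strict area gate (min, max) µm²."""
    areas = cells.areas()
    keep = (areas > area_min) & (areas < area_max)
    return cells.ids[keep.to_numpy()]


def assign_to_boundaries(
    transcripts: pd.DataFrame,
    cells: SegmentedObjectSet,
    max_dist: float = 2.0,
    exclude: pd.DataFrame | None = None,
    area_min: float = AREA_MIN,
    area_max: float = AREA_MAX,
) -> pd.DataFrame:
    """Assign transcripts to membrane-segmented adipocytes.

    Cells with area ≤ ``area_min`` or ≥ ``area_max`` are removed before
    assignment.  Transcripts listed in ``exclude`` (an assignment table,
    typically nucleus-mode assignments to non-adipocyte cells) are dropped
    first.  A transcript whose containing pixel belongs to exactly one
    retained cell is assigned to that cell at distance 0; otherwise it is
    assigned to every retained cell whose nearest mask pixel (centre) lies
    within ``max_dist`` (closed).

    Returns a DataFrame (transcript_id, object_id, distance, mode); a
    transcript may appear in several rows.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be non-negative")
    if cells.kind != "boundary_cell":
        raise ValueError("boundary assignment requires boundary cells")
    if cells.pixel_size is None or cells.pixel_size <= 0:
        raise ValueError("pixel size must be set and positive")
    validate_transcript_table(transcripts)

    keep_ids = set(filter_by_area(cells, area_min, area_max))
    logger.info(
        "area gate (%g, %g) µm²: %d of %d cells retained",
        area_min, area_max, len(keep_ids), len(cells),
    )
    t = transcripts
    if exclude is not None and len(exclude):
        drop = set(exclude["transcript_id"])
        t = t[~t["transcript_id"].isin(drop)]
    pix = cells.pixels[cells.pixels["object_id"].isin(keep_ids)]
    out = _empty_assignment("boundary")
    out.attrs["mode"] = "boundary"
    if len(t) == 0 or len(pix) == 0:
        return out

    ps = cells.pixel_size
    tx = t["x"].to_numpy(dtype=float)
    ty = t["y"].to_numpy(dtype=float)
    tids = t["transcript_id"].to_numpy()

    # pixel-footprint containment: join the transcript's integer pixel
    # against the mask table (overlapping masks may give several owners)
    foot = pd.DataFrame(
        {
            "t": np.arange(len(t)),
            "px": np.floor(tx / ps).astype(int),
            "py": np.floor(ty / ps).astype(int),
        }
    )
    contained = foot.merge(pix, on=["px", "py"])[["t", "object_id"]].drop_duplicates()
    contained_t = set(contained["t"])

    # proximity: all (transcript, pixel) pairs within the padded radius via
    # KD-trees, reduced to the per-object minimum pixel distance
    centers = np.column_stack(
        [(pix["px"].to_numpy() + 0.5) * ps, (pix["py"].to_numpy() + 0.5) * ps]
    )
    tree_t = cKDTree(np.column_stack([tx, ty]))
    tree_p = cKDTree(centers)
    coo = tree_t.sparse_distance_matrix(
        tree_p, max_distance=max_dist * (1 + 1e-12) + 1e-9, output_type="coo_matrix"
    )
    prox = pd.DataFrame(
        {
            "t": coo.row,
            "object_id": pix.iloc[coo.col]["object_id"].to_numpy(),
            "d": coo.data,
        }
    )
    prox = prox[~prox["t"].isin(contained_t)]
    prox = prox.groupby(["t", "object_id"], as_index=False)["d"].min()
    prox = prox[prox["d"] <= max_dist]

    contained["d"] = 0.0
    pairs = pd.concat(
        [contained[["t", "object_id", "d"]], prox], ignore_index=True
    ).sort_values(["t", "object_id"], kind="mergesort")
    out = pd.DataFrame(
        {
            "transcript_id": tids[pairs["t"].to_numpy(dtype=int)],
            "object_id": pairs["object_id"].to_numpy(),
            "distance": pairs["d"].to_numpy(),
            "mode": "boundary",
        }
    )
    out.attrs["mode"] = "boundary"
    logger.info(
        "boundary assignment: %d (transcript, cell) pairs from %d transcripts",
        len(out), len(t),
    )
    return out


def build_count_matrix(
    assignment: pd.DataFrame,
    transcripts: pd.DataFrame,
    min_transcripts: int = 40,
    normalize_target: float = 1e4,
    genes: list[str] | None = None,
    metadata: pd.DataFrame | None = None,
) -> ad.AnnData:
    """Build a cells × genes AnnData from an assignment table.

    Multi-assigned transcripts contribute a full count to every assigned
    cell.  Cells with total counts ≤ ``min_transcripts`` are removed
    (strict: the default 40 keeps cells with 41+).  ``X`` holds raw integer
    counts; layer ``"normalized"`` scales each cell to ``normalize_target``
    total counts, and layer ``"lognorm"`` is ``log1p`` of that.

    ``genes`` fixes the variable axis (a transcript gene absent from it is
    an error); by default the observed genes are used, sorted.  ``metadata``
    (indexed by cell id) is joined onto ``obs``.
    """
    if min_transcripts < 0:
        raise ValueError("min_transcripts must be >= 0")
    if normalize_target <= 0:
        raise ValueError("normalize_target must be positive")
    merged = assignment.merge(
        transcripts[["transcript_id", "gene"]], on="transcript_id", how="left"
    )
    if merged["gene"].isna().any():
        raise ValueError("assignment references transcripts absent from the table")
    observed = sorted(merged["gene"].unique()) if len(merged) else []
    if genes is None:
        genes = observed
    else:
        unknown = set(observed) - set(genes)
        if unknown:
            raise ValueError(f"genes absent from panel: {sorted(unknown)[:5]}")
    gene_pos = {g: k for k, g in enumerate(genes)}
    cell_ids = sorted(merged["object_id"].unique()) if len(merged) else []
    cell_pos = {c: k for k, c in enumerate(cell_ids)}

    rows = merged["object_id"].map(cell_pos).to_numpy(dtype=int) if len(merged) else []
    cols = merged["gene"].map(gene_pos).to_numpy(dtype=int) if len(merged) else []
    X = csr_matrix(
        (np.ones(len(merged)), (rows, cols)), shape=(len(cell_ids), len(genes))
    )

    totals = np.asarray(X.sum(axis=1)).ravel()
    keep = totals > min_transcripts
    if not keep.any():
        logger.warning("all cells filtered at min_transcripts=%d", min_transcripts)
    X = X[keep]
    obs = pd.DataFrame(index=pd.Index(np.array(cell_ids, dtype=object)[keep], name="cell_id"))
    obs["total_counts"] = totals[keep]
    if metadata is not None:
        obs = obs.join(metadata, how="left")

    adata = ad.AnnData(
        X=X.astype(np.int64), obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    tot = np.asarray(adata.X.sum(axis=1)).ravel()
    scale = np.divide(
        normalize_target, tot, out=np.zeros_like(tot, dtype=float), where=tot > 0
    )
    normalized = adata.X.multiply(scale[:, None]).tocsr()
    adata.layers["normalized"] = normalized
    adata.layers["lognorm"] = normalized.copy()
    adata.layers["lognorm"].data = np.log1p(adata.layers["lognorm"].data)
    adata.uns["normalize_target"] = normalize_target
    adata.uns["min_transcripts"] = min_transcripts
    adata.uns["mode"] = assignment.attrs.get("mode", "unknown")
    logger.info(
        "count matrix: %d cells × %d genes (removed %d cells with ≤ %d counts)",
        adata.n_obs, adata.n_vars, int((~keep).sum()), min_transcripts,
    )
    return adata


def flag_contaminants(
    adata: ad.AnnData, marker_genes: list[str], max_fraction: float = 0.2
) -> np.ndarray:
    """Flag cells whose non-adipocyte marker count fraction is too high.

    A lightweight stand-in for manual removal of mixed-transcript cells:
    cells in which the given marker genes account for more than
    ``max_fraction`` of raw counts are flagged (True = contaminant).
    """
    present = [g for g in marker_genes if g in adata.var_names]
    if not present:
        return np.zeros(adata.n_obs, dtype=bool)
    sub = np.asarray(adata[:, present].X.sum(axis=1)).ravel()
    tot = np.asarray(adata.X.sum(axis=1)).ravel()
    frac = np.divide(sub, tot, out=np.zeros_like(sub, dtype=float), where=tot > 0)
    return frac > max_fraction
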