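"""Core in-memory containers shared across pipeline stages.

Transcript tables are plain pandas DataFrames validated against a required
schema (mirroring the Xenium per-transcript CSV dialect).  Segmented objects
(nuclei, membrane-segmented adipocytes) and the 50-µm bin grid get small
dataclass wrappers because they carry geometry that a bare DataFrame cannot
express.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRANSCRIPT_COLUMNS",
    "validate_transcript_table",
    "SegmentedObjectSet",
    "BinGrid",
]

#: Required columns of a transcript table, in canonical order.
TRANSCRIPT_COLUMNS = ["transcript_id", "gene", "x", "y", "qv"]


def validate_transcript_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the transcript-table schema and coordinate sanity.

    Raises ``ValueError`` naming the first missing column, or pointing at the
    first row with a non-finite coordinate.  Returns the (unmodified) frame
    for call chaining.
    """
    for col in TRANSCRIPT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"transcript table is missing required column '{col}'")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float, na_value=np.nan))
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-numeric or non-finite coordinate '{col}' at row {idx}")
    if (pd.to_numeric(df["qv"], errors="coerce") < 0).any():
        raise ValueError("quality values must be non-negative")
    if df["gene"].astype(str).eq("").any():
        raise ValueError("empty gene name in transcript table")
    return df


@dataclass
class SegmentedObjectSet:
    """A set of segmented objects: nuclei or boundary-segmented cells.

    Parameters
    ----------
    kind : {"nucleus", "boundary_cell"}
    ids : array of object identifiers (strings)
    centroids : (n, 2) array of µm coordinates
    polygons : per-object (m, 2) vertex arrays (nuclei only, optional)
    pixels : DataFrame with columns object_id, px, py — integer pixel
        coordinates of the mask (boundary cells only)
    pixel_size : µm per pixel edge (boundary cells only)
    """

    kind: str
    ids: np.ndarray
    centroids: np.ndarray
    polygons: list[np.ndarray] | None = None
    pixels: pd.DataFrame | None = None
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("nucleus", "boundary_cell"):
            raise ValueError(f"unknown object kind '{self.kind}'")
        self.ids = np.asarray(self.ids, dtype=object)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("object ids must be unique")
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if self.centroids.shape[0] != self.ids.shape[0]:
            raise ValueError("ids and centroids length mismatch")
        if self.kind == "boundary_cell":
            if self.pixels is None or self.pixel_size is None:
                raise ValueError("boundary cells require pixels and pixel_size")
            if self.pixel_size <= 0:
                raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return len(self.ids)

    def areas(self) -> pd.Series:
        """Object areas in µm² (pixel count × pixel area); boundary cells only."""
        if self.kind != "boundary_cell":
            raise ValueError("areas are defined for boundary cells only")
        counts = self.pixels.groupby("object_id").size()
        counts = counts.reindex(self.ids, fill_value=0)
        return counts * (self.pixel_size**2)


@dataclass
class BinGrid:
    """Square tessellation of the field with per-bin transcript tallies.

    Bins are half-open squares ``[x0+i*s, x0+(i+1)*s) × [y0+j*s, y0+(j+1)*s)``.
    ``bins`` has one row per non-empty bin with columns ix, iy, x_center,
    y_center, total and kept; ``assignments`` records the (ix, iy) bin of
    every retained transcript so per-gene maps can be extracted for any gene
    list after the fact.
    """

    origin: tuple[float, float]
    bin_size: float
    bins: pd.DataFrame
    assignments: pd.DataFrame = field(repr=False)

    def gene_counts(self, genes) -> pd.DataFrame:
        """Per-bin counts for the requested genes, aligned to ``bins`` rows."""
        genes = list(genes)
        missing = set(genes) - set(self.assignments["gene"].unique())
        out = self.bins[["ix", "iy"]].copy()
        sub = self.assignments[self.assignments["gene"].isin(genes)]
        pivot = (
            sub.groupby(["ix", "iy", "gene"]).size().unstack("gene", fill_value=0)
        )
        for g in genes:
            if g in pivot.columns:
                vals = pivot[g].reindex(
                    pd.MultiIndex.from_frame(out[["ix", "iy"]]), fill_value=0
                )
                out[g] = vals.to_numpy()
            else:
                out[g] = 0
        if missing:
            # absent genes yield all-zero columns rather than an error: a gene
            # may simply not occur in this section
            pass
        return out

    def to_frame(self, genes=()) -> pd.DataFrame:
        """Bin table (ix, iy, centers, total, kept, then per-gene columns)."""
        out = self.bins.copy()
        if genes:
            gc = self.gene_counts(genes)
            for g in genes:
                out[g] = gc[g].to_numpy()
        return out
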