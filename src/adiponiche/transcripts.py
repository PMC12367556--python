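"""Transcript loading, quality filtering and segmentation-free binning.

Decoded transcripts are retained only when their decoding quality value is
strictly greater than the threshold (QV > 35 by default).  The
segmentation-free tissue map tessellates the field into 50-µm half-open
square bins; bins are kept downstream only when they contain strictly more
than ``min_count`` transcripts.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BinGrid, validate_transcript_table

__all__ = ["load_transcripts", "filter_by_qv", "load_and_filter_transcripts", "bin_transcripts"]

logger = logging.getLogger(__name__)

_XENIUM_RENAME = {
    "feature_name": "gene",
    "x_location": "x",
    "y_location": "y",
}


def load_transcripts(path) -> pd.DataFrame:
    """Read a transcript table in the Xenium CSV dialect (or canonical form).

    Accepts either the canonical columns (transcript_id, gene, x, y, qv) or
    the Xenium names (feature_name, x_location, y_location); extra columns
    such as cell_id are preserved.  Raises a schema error naming the first
    missing required column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, keep_default_na=False, dtype={"transcript_id": str},
                     float_precision="round_trip")
    df = df.rename(columns=_XENIUM_RENAME)
    for col in ("x", "y", "qv"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    validate_transcript_table(df)
    return df


def filter_by_qv(table: pd.DataFrame, qv_threshold: float = 35.0) -> pd.DataFrame:
    """Keep transcripts with quality value strictly greater than the threshold.

    Preserves input order and is idempotent.  The number of removed
    transcripts is logged.
    """
    validate_transcript_table(table)
    kept = table[table["qv"] > qv_threshold].reset_index(drop=True)
    logger.info(
        "QV filter (> %g): kept %d of %d transcripts (%d removed)",
        qv_threshold, len(kept), len(table), len(table) - len(kept),
    )
    return kept


def load_and_filter_transcripts(path, qv_threshold: float = 35.0) -> pd.DataFrame:
    """Load a transcript file and apply the strict QV filter."""
    return filter_by_qv(load_transcripts(path), qv_threshold)


def bin_transcripts(
    table: pd.DataFrame,
    bin_size: float = 50.0,
    min_count: int = 10,
    origin: tuple[float, float] | None = None,
) -> BinGrid:
    """Tessellate transcripts into half-open square bins.

    The grid origin defaults to the minimum retained x/y floored to a
    multiple of ``bin_size``, which makes the grid deterministic per sample
    and stable under duplication of the data.  A bin is flagged ``kept``
    only when its total transcript count is strictly greater than
    ``min_count``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    validate_transcript_table(table)

    if len(table) == 0:
        empty = pd.DataFrame(
            columns=["ix", "iy", "x_center", "y_center", "total", "kept"]
        )
        assignments = table.copy()
        assignments["ix"] = pd.Series(dtype=int)
        assignments["iy"] = pd.Series(dtype=int)
        return BinGrid(origin=origin or (0.0, 0.0), bin_size=bin_size,
                       bins=empty, assignments=assignments)

    x = table["x"].to_numpy(dtype=float)
    y = table["y"].to_numpy(dtype=float)
    if origin is None:
        x0 = math.floor(x.min() / bin_size) * bin_size
        y0 = math.floor(y.min() / bin_size) * bin_size
    else:
        x0, y0 = origin
    ix = np.floor((x - x0) / bin_size).astype(int)
    iy = np.floor((y - y0) / bin_size).astype(int)

    assignments = table.copy()
    assignments["ix"] = ix
    assignments["iy"] = iy

    bins = (
        assignments.groupby(["ix", "iy"]).size().rename("total").reset_index()
    )
    bins["x_center"] = x0 + (bins["ix"] + 0.5) * bin_size
    bins["y_center"] = y0 + (bins["iy"] + 0.5) * bin_size
    bins["kept"] = bins["total"] > min_count
    bins = bins[["ix", "iy", "x_center", "y_center", "total", "kept"]]
    logger.info(
        "binning (%g µm): %d bins, %d kept (> %d transcripts)",
        bin_size, len(bins), int(bins["kept"].sum()), min_count,
    )
    return BinGrid(origin=(x0, y0), bin_size=bin_size, bins=bins, assignments=assignments)
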