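"""Stress zonation: bin-level mean scores and quantile composition.

Cells are binned on the 50-µm grid, each bin's mean stress score is pushed
back onto its resident cells, and quartile cut points over all cells
(pooled across conditions) partition the tissue into Q1 (low) … Q4 (high)
stress zones.  The per-state composition — what percentage of each cell
state sits in each quartile — is the zonation readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ZonationResult", "quantile_zonation"]


@dataclass
class ZonationResult:
    """Zonation output.

    Attributes
    ----------
    bin_scores : per-bin frame (ix, iy, mean_score, n_cells).
    cell_quantiles : per-cell quantile label ("Q1".."Qn"), NaN for cells in
        dropped bins (reported in ``n_unzoned``).
    composition : state × quantile percentage matrix; each populated state's
        row sums to 100.
    n_unzoned : cells excluded because their bin was dropped.
    """

    bin_scores: pd.DataFrame
    cell_quantiles: pd.Series
    composition: pd.DataFrame
    n_unzoned: int


def quantile_zonation(
    cells: pd.DataFrame,
    bin_size: float = 50.0,
    n_quantiles: int = 4,
    score_col: str = "score",
    state_col: str = "state",
    keep_bins: set[tuple[int, int]] | None = None,
    origin: tuple[float, float] | None = None,
) -> ZonationResult:
    """Quantile zonation of per-cell stress scores.

    ``cells`` needs columns x, y, ``score_col`` and ``state_col``.  Cut
    points are the empirical quantiles over cells (pooled); intervals are
    left-closed ``[q_{k-1}, q_k)`` with the top interval closed on both
    sides, so ties fall into the lower quantile and a constant score puts
    every cell in Q1.  ``keep_bins`` optionally restricts zonation to kept
    (high-count) bins; cells in dropped bins are counted as unzoned.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    for col in ("x", "y", score_col, state_col):
        if col not in cells.columns:
            raise ValueError(f"cells frame is missing '{col}'")
    if len(cells) == 0:
        raise ValueError("no cells to zonate")

    x = cells["x"].to_numpy(dtype=float)
    y = cells["y"].to_numpy(dtype=float)
    if origin is None:
        x0 = math.floor(x.min() / bin_size) * bin_size
        y0 = math.floor(y.min() / bin_size) * bin_size
    else:
        x0, y0 = origin
    ix = np.floor((x - x0) / bin_size).astype(int)
    iy = np.floor((y - y0) / bin_size).astype(int)

    df = cells[[score_col, state_col]].copy()
    df.columns = ["score", "state"]
    df["ix"], df["iy"] = ix, iy
    if keep_bins is not None:
        in_kept = [
            (a, b) in keep_bins for a, b in zip(ix, iy)
        ]
        df["zoned"] = in_kept
    else:
        df["zoned"] = True
    n_unzoned = int((~df["zoned"]).sum())
    zoned = df[df["zoned"]]

    bin_scores = (
        zoned.groupby(["ix", "iy"])
        .agg(mean_score=("score", "mean"), n_cells=("score", "size"))
        .reset_index()
    )

    # each cell inherits its bin's mean score
    merged = zoned.merge(bin_scores, on=["ix", "iy"], how="left")
    v = merged["mean_score"].to_numpy(dtype=float)
    qs = np.quantile(v, np.linspace(0.0, 1.0, n_quantiles + 1))
    # left-closed intervals, ties to the lower quantile: count strictly
    # smaller interior cut points below the value
    labels_idx = np.zeros(len(v), dtype=int)
    for cut in qs[1:-1]:
        labels_idx += (v > cut).astype(int)
    labels_idx = np.minimum(labels_idx, n_quantiles - 1)
    labels = pd.Series(
        [f"Q{k + 1}" for k in labels_idx], index=merged.index, name="quantile"
    )

    cell_q = pd.Series(pd.NA, index=cells.index, dtype=object, name="quantile")
    cell_q.iloc[np.flatnonzero(df["zoned"].to_numpy())] = labels.to_numpy()

    qcols = [f"Q{k + 1}" for k in range(n_quantiles)]
    comp = (
        pd.crosstab(merged["state"], labels)
        .reindex(columns=qcols, fill_value=0)
    )
    comp = comp.div(comp.sum(axis=1), axis=0) * 100.0
    comp.columns.name = "quantile"
    return ZonationResult(
        bin_scores=bin_scores,
        cell_quantiles=cell_q,
        composition=comp,
        n_unzoned=n_unzoned,
    )
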