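"""Control-matched gene-set scoring and marker-positivity analysis.

The gene-set score of a cell (or bin) is the mean ln-normalized expression
of the target genes minus the mean over a pooled set of control genes drawn
from the same expression strata: genes are partitioned into equal-frequency
bins by their mean ln expression over all cells, and for every target gene
``control_size`` controls are sampled (without replacement where possible)
from its stratum, excluding the targets themselves.  This matches the
widely used single-cell scoring scheme with a control size of 50 and 25
expression bins.

Positivity analysis calls a cell positive when its raw count of a marker
gene (e.g. CDKN1A/p21) reaches a threshold, summarises positive fractions
per sample and group, and compares groups with rank tests under
Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .stats import bh_adjust, rank_test

__all__ = [
    "GeneSetScoreResult",
    "score_gene_set",
    "stress_map",
    "PositivityResult",
    "call_positive_fraction",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetScoreResult:
    """Per-cell gene-set scores and the sampling parameters that made them."""

    scores: pd.Series  # indexed by cell/bin id
    gene_set: list[str]
    control_genes: list[str]
    control_size: int
    n_expression_bins: int
    seed: int


def _dense_lognorm(adata: ad.AnnData) -> np.ndarray:
    if "lognorm" not in adata.layers:
        raise ValueError("matrix must carry a 'lognorm' layer")
    X = adata.layers["lognorm"]
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X)


def score_gene_set(
    adata: ad.AnnData,
    gene_set,
    control_size: int = 50,
    n_expression_bins: int = 25,
    seed: int = 0,
) -> GeneSetScoreResult:
    """Score cells for a gene set against expression-matched controls.

    score(cell) = mean ln expression over target genes
                − mean ln expression over the pooled control genes.

    Target genes absent from the matrix are dropped with a warning; an empty
    intersection is an error.  When a stratum's eligible pool is smaller
    than ``control_size`` the draw falls back to sampling with replacement
    (with a warning).  Deterministic given ``seed``.
    """
    genes = list(adata.var_names)
    requested = list(dict.fromkeys(gene_set))
    present = [g for g in requested if g in adata.var_names]
    missing = [g for g in requested if g not in adata.var_names]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) not in matrix, dropped: {missing[:5]}")
    if not present:
        raise ValueError("gene set is empty after intersection with the panel")

    X = _dense_lognorm(adata)
    gene_mean = X.mean(axis=0)
    n_bins = min(n_expression_bins, len(genes))
    # equal-frequency strata by mean expression; min-ranking keeps tied
    # genes in the same stratum (a constant matrix is one big stratum)
    rank = pd.Series(gene_mean, index=genes).rank(method="min")
    n_items = int(np.ceil(len(genes) / n_bins))
    strata = ((rank - 1) // n_items).astype(int)

    rng = np.random.default_rng(seed)
    target_set = set(present)
    controls: list[str] = []
    for g in present:
        stratum = strata[g]
        pool = [
            h for h in genes if strata[h] == stratum and h not in target_set
        ]
        if len(pool) == 0:
            warnings.warn(f"no eligible control genes in the stratum of {g}")
            continue
        if len(pool) < control_size:
            warnings.warn(
                f"control pool for {g} has {len(pool)} genes < control_size="
                f"{control_size}; sampling with replacement"
            )
            draw = rng.choice(pool, size=control_size, replace=True)
        else:
            draw = rng.choice(pool, size=control_size, replace=False)
        controls.extend(draw.tolist())
    if not controls:
        raise ValueError("no control genes could be drawn")

    gi = {g: k for k, g in enumerate(genes)}
    target_idx = [gi[g] for g in present]
    control_idx = [gi[g] for g in controls]
    scores = X[:, target_idx].mean(axis=1) - X[:, control_idx].mean(axis=1)
    return GeneSetScoreResult(
        scores=pd.Series(scores, index=adata.obs_names, name="score"),
        gene_set=present,
        control_genes=controls,
        control_size=control_size,
        n_expression_bins=n_expression_bins,
        seed=seed,
    )


def stress_map(
    score: GeneSetScoreResult,
    bin_table: pd.DataFrame,
    transform: str = "log1p_clipped",
    condition: pd.Series | None = None,
) -> pd.DataFrame:
    """Turn bin-level scores into a stress map layer.

    ``bin_table`` is the kept-bin frame (ix, iy, ...) whose row order matches
    ``score.scores``.  The default transform clips scores below at 0 and
    applies ``log1p`` (scores can be negative; the clipped-log display keeps
    the zero-stress baseline at 0); ``identity`` leaves scores untouched.
    Returns the bin table with a ``stress`` column; per-condition means are
    attached in ``.attrs["condition_means"]`` when a condition label per bin
    is supplied.
    """
    if len(bin_table) == 0:
        raise ValueError("no kept bins to map")
    if len(bin_table) != len(score.scores):
        raise ValueError("bin table and scores are misaligned")
    vals = score.scores.to_numpy(dtype=float)
    if transform == "log1p_clipped":
        stress = np.log1p(np.clip(vals, 0.0, None))
    elif transform == "identity":
        stress = vals
    else:
        raise ValueError(f"unknown transform '{transform}'")
    out = bin_table.copy()
    out["stress"] = stress
    out.attrs["transform"] = transform
    if condition is not None:
        cm = out.assign(condition=np.asarray(condition)).groupby("condition")[
            "stress"
        ].mean()
        out.attrs["condition_means"] = cm.to_dict()
    return out


@dataclass
class PositivityResult:
    """Marker positivity per cell, fractions per sample × group, and tests."""

    positive: pd.Series
    fractions: pd.DataFrame  # columns: sample, group, fraction, n_cells
    comparisons: pd.DataFrame = field(default=None)  # group_a, group_b, paired, p, p_adj


def call_positive_fraction(
    adata: ad.AnnData,
    gene: str,
    threshold_counts: int = 1,
    sample_key: str = "sample",
    group_key: str = "condition",
    paired_pairs: list[tuple[str, str]] = (),
    unpaired_pairs: list[tuple[str, str]] = (),
) -> PositivityResult:
    """Fraction of marker-positive cells per sample and group, with tests.

    A cell is positive iff its raw count of ``gene`` is ≥
    ``threshold_counts``.  For each requested group pair an unpaired
    rank-sum (or paired signed-rank, with samples matched by order within
    group) test is run on the per-sample fractions; p-values are
    Benjamini–Hochberg adjusted across the reported comparisons.
    """
    if gene not in adata.var_names:
        raise ValueError(f"gene '{gene}' absent from the matrix")
    raw = adata[:, gene].X
    raw = raw.toarray().ravel() if hasattr(raw, "toarray") else np.asarray(raw).ravel()
    positive = pd.Series(raw >= threshold_counts, index=adata.obs_names, name="positive")

    obs = adata.obs
    for key in (sample_key, group_key):
        if key not in obs.columns:
            raise ValueError(f"obs is missing '{key}'")
    df = pd.DataFrame(
        {"sample": obs[sample_key].to_numpy(), "group": obs[group_key].to_numpy(),
         "positive": positive.to_numpy()}
    )
    fractions = (
        df.groupby(["sample", "group"], observed=True)["positive"]
        .agg(fraction="mean", n_cells="size")
        .reset_index()
    )

    comparisons = []
    for pairs, paired in ((unpaired_pairs, False), (paired_pairs, True)):
        for a, b in pairs:
            fa = fractions.loc[fractions["group"] == a, "fraction"].to_numpy()
            fb = fractions.loc[fractions["group"] == b, "fraction"].to_numpy()
            if len(fa) < 2 or len(fb) < 2 or (paired and len(fa) != len(fb)):
                warnings.warn(f"comparison {a} vs {b} skipped (too few samples)")
                continue
            p = rank_test(fa, fb, paired=paired)
            comparisons.append({"group_a": a, "group_b": b, "paired": paired, "p": p})
    comp = pd.DataFrame(comparisons)
    if len(comp):
        comp["p_adj"] = bh_adjust(comp["p"].to_numpy())
    return PositivityResult(positive=positive, fractions=fractions, comparisons=comp)
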