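"""Synthetic Xenium-like adipose tissue with planted ground truth.

The generator emulates the statistical structure of imaging-based spatial
transcriptomics sections of human subcutaneous adipose tissue across three
conditions (lean, obese, weight loss):

* condition-dependent adipocyte sizes (log-normal diameters; obese cells are
  about twice the lean diameter, so fewer cells fit the same field and each
  cell has roughly half as many 300-µm neighbours),
* planted spatial niches (horizontal bands, each with its own cell-state
  composition vector),
* a stress gene set whose per-cell rate is coupled to adipocyte area through
  a latent Gaussian copula with a target Spearman coefficient,
* decoding-quality noise (a two-component QV mixture straddling the QV = 35
  gate) and uniform background transcripts belonging to no cell.

Cells are modelled as discs: adipocytes as large discs rasterised into
pixel masks at a configurable pixel size (the membrane-stain segmentation
substrate), all cells as small nucleus polygons.  Every dataset is
reproducible bit-for-bit from ``(config, seed)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SegmentedObjectSet

__all__ = [
    "NicheSpec",
    "TissueConfig",
    "SyntheticTissue",
    "generate_tissue",
    "area_coupling_config",
    "write_bundle",
    "read_bundle",
    "DEFAULT_STATES",
    "STRESS_GENES",
]

#: Cell states used by the default panel; the two adipocyte states are
#: rendered as large discs with pixel masks, the rest as small cells.
DEFAULT_STATES = [
    "adipocyte",
    "stressed_adipocyte",
    "preadipocyte",
    "stem",
    "arterial_ec",
    "venous_ec",
    "macrophage",
    "tcell",
]

ADIPOCYTE_STATES = ("adipocyte", "stressed_adipocyte")

#: Default stress gene set (immediate-early, heat-shock, cell-cycle-arrest
#: and secretory stress genes typical of a stressed-adipose signature).
STRESS_GENES = [
    "JUN", "FOS", "JUNB", "FOSB", "ATF3", "EGR1", "NFKBIZ", "CDKN1A",
    "GADD45B", "DNAJB1", "HSPA1A", "HSPA1B", "SOCS3", "KLF6", "ZFP36",
    "IER3", "AREG", "CXCL2", "THBS1", "NAMPT", "IL6ST", "OSMR",
    "ADAMTS1", "SERPINE1",
]

_STATE_MARKERS = {
    "adipocyte": ["ADIPOQ", "PLIN1"],
    "stressed_adipocyte": ["ADIPOQ2", "PLIN4"],
    "preadipocyte": ["PDGFRA", "DCN"],
    "stem": ["DPP4", "CD55"],
    "arterial_ec": ["HEY1", "SEMA3G"],
    "venous_ec": ["ACKR1", "VWF"],
    "macrophage": ["CD68", "TREM2"],
    "tcell": ["CD3E", "IL7R"],
}

#: Median adipocyte diameter (µm) per condition; obese is twice lean.
_CONDITION_DIAMETER = {"lean": 55.0, "obese": 110.0, "weight_loss": 75.0}
#: Total cells per condition in the default 2,000 × 5,000 µm field; the
#: lean:obese ratio of 2 reproduces the ~2× neighbour-density asymmetry.
_CONDITION_NCELLS = {"lean": 2000, "obese": 1000, "weight_loss": 1400}


@dataclass(frozen=True)
class NicheSpec:
    """A planted niche: a horizontal band plus a state-composition vector."""

    name: str
    y_range: tuple[float, float]
    composition: dict[str, float]

    def __post_init__(self):
        total = sum(self.composition.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"niche '{self.name}' composition sums to {total}, expected 1"
            )
        if any(v < 0 for v in self.composition.values()):
            raise ValueError(f"niche '{self.name}' has negative composition")


def _default_niche_layout(height: float) -> list[NicheSpec]:
    bands = np.linspace(0.0, height, 6)
    comps = {
        "adipocyte": {
            "adipocyte": 0.55, "stressed_adipocyte": 0.05, "preadipocyte": 0.10,
            "stem": 0.05, "arterial_ec": 0.05, "venous_ec": 0.05,
            "macrophage": 0.10, "tcell": 0.05,
        },
        "stress": {
            "adipocyte": 0.10, "stressed_adipocyte": 0.35, "preadipocyte": 0.15,
            "stem": 0.02, "arterial_ec": 0.03, "venous_ec": 0.05,
            "macrophage": 0.20, "tcell": 0.10,
        },
        "stem": {
            "adipocyte": 0.15, "stressed_adipocyte": 0.03, "preadipocyte": 0.20,
            "stem": 0.40, "arterial_ec": 0.02, "venous_ec": 0.05,
            "macrophage": 0.10, "tcell": 0.05,
        },
        "arterial": {
            "adipocyte": 0.15, "stressed_adipocyte": 0.08, "preadipocyte": 0.12,
            "stem": 0.05, "arterial_ec": 0.40, "venous_ec": 0.05,
            "macrophage": 0.05, "tcell": 0.10,
        },
        "venous": {
            "adipocyte": 0.15, "stressed_adipocyte": 0.05, "preadipocyte": 0.05,
            "stem": 0.05, "arterial_ec": 0.05, "venous_ec": 0.40,
            "macrophage": 0.10, "tcell": 0.15,
        },
    }
    return [
        NicheSpec(name, (float(bands[i]), float(bands[i + 1])), comps[name])
        for i, name in enumerate(["adipocyte", "stress", "stem", "arterial", "venous"])
    ]


def _default_panel() -> tuple[list[str], dict[str, dict[str, float]]]:
    """Gene panel and per-state mean rates (expected transcripts per cell).

    Markers are strongly expressed in their own state; stress genes are
    moderately expressed in adipocytes and strongly in stressed adipocytes;
    filler genes span four expression strata so the control-gene pool of the
    scoring stage covers the stress genes' strata.
    """
    genes: list[str] = []
    rates: dict[str, dict[str, float]] = {s: {} for s in DEFAULT_STATES}
    for g in STRESS_GENES:
        genes.append(g)
        for s in DEFAULT_STATES:
            if s == "stressed_adipocyte":
                rates[s][g] = 6.0
            elif s == "adipocyte":
                rates[s][g] = 2.0
            else:
                rates[s][g] = 0.5
    for s, markers in _STATE_MARKERS.items():
        for g in markers:
            genes.append(g)
            for s2 in DEFAULT_STATES:
                rates[s2][g] = 10.0 if s2 == s else 0.1
    strata = [0.2, 0.5, 1.0, 2.0, 4.0]
    for i in range(90):
        g = f"G{i + 1:03d}"
        genes.append(g)
        r = strata[i % len(strata)]
        for s in DEFAULT_STATES:
            rates[s][g] = r
    return genes, rates


@dataclass
class TissueConfig:
    """Parameters of a synthetic tissue section.

    Attributes
    ----------
    condition : {"lean", "obese", "weight_loss"}
    field_size : (width, height) in µm.
    n_cells : total number of cells, split evenly across niches.
    diameter_lognorm : (median µm, sigma of log) of the adipocyte diameter
        distribution.
    niche_layout : planted niches; horizontal bands by default.
    gene_panel / state_rates : gene names and per-state mean transcript
        counts per cell.
    stress_genes : genes whose adipocyte rate is coupled to cell area.
    rho_target : target Spearman correlation between adipocyte area and
        stress-gene expression rate.
    f_lowqv : fraction of transcripts with QV <= 35 (two-component normal
        mixture: high ~ N(40, 2), low ~ N(25, 5)).
    background_rate : noise transcripts per µm², uniform over the field,
        belonging to no cell.
    pixel_size : µm per pixel for adipocyte boundary masks.
    localization_sigma : Gaussian jitter (µm) added to transcript positions.
    perinuclear_fraction : fraction of a cell's transcripts placed within
        its nucleus disc rather than uniformly in the cell body.
    min_separation : minimum centroid distance between nuclei (µm).
    seed : generator seed; identical (config, seed) gives identical output.
    """

    condition: str = "lean"
    field_size: tuple[float, float] = (2000.0, 5000.0)
    n_cells: int | None = None
    diameter_lognorm: tuple[float, float] | None = None
    niche_layout: list[NicheSpec] | None = None
    gene_panel: list[str] | None = None
    state_rates: dict[str, dict[str, float]] | None = None
    stress_genes: list[str] = field(default_factory=lambda: list(STRESS_GENES))
    rho_target: float = 0.5
    f_lowqv: float = 0.10
    background_rate: float = 2e-5
    pixel_size: float = 1.0
    localization_sigma: float = 0.5
    perinuclear_fraction: float = 0.4
    nucleus_radius: float = 4.0
    small_cell_radius: float = 6.0
    min_separation: float = 12.0
    min_niche_l1: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in _CONDITION_DIAMETER:
            raise ValueError(f"unknown condition '{self.condition}'")
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_cells is None:
            self.n_cells = _CONDITION_NCELLS[self.condition]
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.diameter_lognorm is None:
            self.diameter_lognorm = (_CONDITION_DIAMETER[self.condition], 0.25)
        if self.diameter_lognorm[0] <= 0 or self.diameter_lognorm[1] < 0:
            raise ValueError("diameter distribution must be strictly positive")
        if self.niche_layout is None:
            self.niche_layout = _default_niche_layout(h)
        if self.gene_panel is None or self.state_rates is None:
            genes, rates = _default_panel()
            if self.gene_panel is None:
                self.gene_panel = genes
            if self.state_rates is None:
                self.state_rates = rates
        if len(self.gene_panel) == 0:
            raise ValueError("gene panel must contain at least one gene")
        if not 0.0 <= self.f_lowqv <= 0.95:
            raise ValueError("f_lowqv must be in [0, 0.95]")
        if not -1.0 < self.rho_target < 1.0:
            raise ValueError("rho_target must be in (-1, 1)")
        # planted niches must be separable by the configured L1 margin
        comps = [c.composition for c in self.niche_layout]
        states = sorted({s for c in comps for s in c})
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                l1 = sum(
                    abs(comps[i].get(s, 0.0) - comps[j].get(s, 0.0)) for s in states
                )
                if l1 < self.min_niche_l1:
                    raise ValueError(
                        f"niches '{self.niche_layout[i].name}' and "
                        f"'{self.niche_layout[j].name}' differ by L1={l1:.3f} "
                        f"< required {self.min_niche_l1}"
                    )

    @property
    def states(self) -> list[str]:
        return list(self.state_rates.keys())


@dataclass
class SyntheticTissue:
    """A generated tissue: transcripts, geometry and planted ground truth."""

    config: TissueConfig
    transcripts: pd.DataFrame
    nuclei: SegmentedObjectSet
    boundaries: SegmentedObjectSet
    truth: pd.DataFrame  # cell_id, state, niche, area, x, y, radius

    @property
    def truth_states(self) -> pd.Series:
        return self.truth.set_index("cell_id")["state"]

    @property
    def truth_niches(self) -> pd.Series:
        return self.truth.set_index("cell_id")["niche"]

    @property
    def truth_areas(self) -> pd.Series:
        return self.truth.set_index("cell_id")["area"]


def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` proportional to `fractions` (sums exactly)."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="mergesort")
    base[order[:rem]] += 1
    return base


def _place_points(
    rng: np.random.Generator,
    n: int,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    min_sep: float,
    max_attempts: int = 200,
) -> np.ndarray:
    """Dart-throwing placement with a minimum separation (nucleus non-overlap)."""
    from scipy.spatial import cKDTree

    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < n:
        if attempts > max_attempts:
            raise ValueError(
                f"infeasible packing: placed {len(accepted)} of {n} cells in "
                f"{x_range} × {y_range} with min separation {min_sep} µm"
            )
        batch = max(n - len(accepted), 16)
        cand = np.column_stack(
            [rng.uniform(*x_range, size=batch), rng.uniform(*y_range, size=batch)]
        )
        if accepted:
            tree = cKDTree(np.vstack(accepted))
            near = tree.query_ball_point(cand, r=min_sep)
            cand = cand[[len(m) == 0 for m in near]]
        # thin candidates that clash within the batch itself (greedy order)
        for p in cand:
            if accepted:
                d = np.min(np.linalg.norm(np.vstack(accepted[-400:]) - p, axis=1))
                # only the recent window is checked here; the KD-tree above
                # already screened against the full accepted set
                if d < min_sep:
                    continue
            accepted.append(p)
            if len(accepted) == n:
                break
        attempts += 1
    return np.vstack(accepted)


def _nucleus_polygon(center: np.ndarray, radius: float, n_vertices: int = 12) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def _rasterize_disc(cx: float, cy: float, radius: float, px_size: float) -> np.ndarray:
    """Integer pixel coordinates whose centres lie within the disc."""
    lo_x = int(math.floor((cx - radius) / px_size))
    hi_x = int(math.ceil((cx + radius) / px_size))
    lo_y = int(math.floor((cy - radius) / px_size))
    hi_y = int(math.ceil((cy + radius) / px_size))
    xs = np.arange(lo_x, hi_x + 1)
    ys = np.arange(lo_y, hi_y + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    cxs = (gx + 0.5) * px_size
    cys = (gy + 0.5) * px_size
    inside = (cxs - cx) ** 2 + (cys - cy) ** 2 <= radius**2
    return np.column_stack([gx[inside], gy[inside]])


def generate_tissue(config: TissueConfig) -> SyntheticTissue:
    """Generate a synthetic tissue section from the configuration.

    Deterministic given ``(config, config.seed)``.  Raises ``ValueError`` on
    infeasible packing or an empty gene panel (checked at config time).
    """
    rng = np.random.default_rng(config.seed)
    width, height = config.field_size
    states = config.states
    niches = config.niche_layout

    # --- cell placement: per niche band, per state (largest-remainder split)
    per_niche = _largest_remainder_counts(
        np.full(len(niches), 1.0 / len(niches)), config.n_cells
    )
    rows = []
    for niche, n_in_niche in zip(niches, per_niche):
        fracs = np.array([niche.composition.get(s, 0.0) for s in states])
        counts = _largest_remainder_counts(fracs, int(n_in_niche))
        if n_in_niche == 0:
            continue
        pts = _place_points(
            rng, int(n_in_niche), (0.0, width), niche.y_range, config.min_separation
        )
        state_labels = np.repeat(states, counts)
        rng.shuffle(state_labels)
        for (x, y), s in zip(pts, state_labels):
            rows.append((niche.name, s, x, y))
    if rows:
        cells = pd.DataFrame(rows, columns=["niche", "state", "x", "y"])
    else:
        cells = pd.DataFrame(columns=["niche", "state", "x", "y"])
    n = len(cells)
    cells["cell_id"] = [f"C{i + 1:05d}" for i in range(n)]

    # --- sizes: adipocyte diameters log-normal; latent z reused for the
    # stress-gene coupling (Gaussian copula against area)
    med, sig = config.diameter_lognorm
    z_size = rng.standard_normal(n)
    is_adipo = cells["state"].isin(ADIPOCYTE_STATES).to_numpy()
    radius = np.full(n, config.small_cell_radius)
    radius[is_adipo] = 0.5 * med * np.exp(sig * z_size[is_adipo])

    # --- stress-rate multiplier coupled to size rank with target Spearman.
    # Spearman between two jointly normal latents with Pearson c is
    # (6/pi) asin(c/2); invert so the rate–area Spearman hits rho_target.
    rho_s = config.rho_target
    c = 2.0 * math.sin(math.pi * rho_s / 6.0)
    eps = rng.standard_normal(n)
    latent = c * z_size + math.sqrt(max(0.0, 1.0 - c * c)) * eps
    tau = 0.8  # log-scale spread of the stress multiplier
    stress_mult = np.where(is_adipo, np.exp(tau * latent - 0.5 * tau * tau), 1.0)

    # --- pixel masks and areas for adipocyte-kind cells
    px_rows = []
    area = np.pi * radius**2
    for i in np.flatnonzero(is_adipo):
        pix = _rasterize_disc(
            cells["x"].iat[i], cells["y"].iat[i], radius[i], config.pixel_size
        )
        px_rows.append(
            pd.DataFrame(
                {"object_id": cells["cell_id"].iat[i], "px": pix[:, 0], "py": pix[:, 1]}
            )
        )
        area[i] = len(pix) * config.pixel_size**2
    pixels = (
        pd.concat(px_rows, ignore_index=True)
        if px_rows
        else pd.DataFrame(columns=["object_id", "px", "py"])
    )

    boundaries = SegmentedObjectSet(
        kind="boundary_cell",
        ids=cells["cell_id"].to_numpy()[is_adipo],
        centroids=cells[["x", "y"]].to_numpy()[is_adipo],
        pixels=pixels,
        pixel_size=config.pixel_size,
    )
    nuclei = SegmentedObjectSet(
        kind="nucleus",
        ids=cells["cell_id"].to_numpy(),
        centroids=cells[["x", "y"]].to_numpy(),
        polygons=[
            _nucleus_polygon(p, config.nucleus_radius)
            for p in cells[["x", "y"]].to_numpy()
        ],
    )

    # --- transcripts: per cell × gene Poisson counts at state rates, with
    # the stress genes scaled by the size-coupled multiplier in adipocytes
    genes = list(config.gene_panel)
    gene_index = {g: k for k, g in enumerate(genes)}
    stress_mask = np.zeros(len(genes), dtype=bool)
    for g in config.stress_genes:
        if g in gene_index:
            stress_mask[gene_index[g]] = True

    rate_by_state = {
        s: np.array([config.state_rates[s].get(g, 0.0) for g in genes])
        for s in states
    }
    t_cell, t_gene, t_x, t_y = [], [], [], []
    for i in range(n):
        lam = rate_by_state[cells["state"].iat[i]].copy()
        if is_adipo[i]:
            lam = np.where(stress_mask, lam * stress_mult[i], lam)
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        gene_ids = np.repeat(np.arange(len(genes)), counts)
        # position: perinuclear (within nucleus disc) vs uniform in cell disc
        peri = rng.random(total) < config.perinuclear_fraction
        rr = np.where(
            peri,
            config.nucleus_radius * np.sqrt(rng.random(total)),
            radius[i] * np.sqrt(rng.random(total)),
        )
        th = rng.uniform(0.0, 2.0 * np.pi, total)
        xs = cells["x"].iat[i] + rr * np.cos(th)
        ys = cells["y"].iat[i] + rr * np.sin(th)
        if config.localization_sigma > 0:
            xs = xs + rng.normal(0.0, config.localization_sigma, total)
            ys = ys + rng.normal(0.0, config.localization_sigma, total)
        t_cell.append(np.repeat(cells["cell_id"].iat[i], total))
        t_gene.append(gene_ids)
        t_x.append(xs)
        t_y.append(ys)

    # --- background transcripts: uniform positions, uniform genes, no cell
    n_bg = int(rng.poisson(config.background_rate * width * height))
    if n_bg > 0:
        t_cell.append(np.repeat("", n_bg))
        t_gene.append(rng.integers(0, len(genes), n_bg))
        t_x.append(rng.uniform(0.0, width, n_bg))
        t_y.append(rng.uniform(0.0, height, n_bg))

    if t_cell:
        cell_col = np.concatenate(t_cell)
        gene_col = np.concatenate(t_gene).astype(int)
        x_col = np.clip(np.concatenate(t_x), 0.0, width)
        y_col = np.clip(np.concatenate(t_y), 0.0, height)
    else:
        cell_col = np.array([], dtype=object)
        gene_col = np.array([], dtype=int)
        x_col = np.array([])
        y_col = np.array([])
    m = len(cell_col)

    # --- QV mixture: solve the low-component weight so that
    # P(qv <= 35) = f_lowqv under high ~ N(40,2), low ~ N(25,5)
    from scipy.stats import norm

    p_low_hit = norm.cdf((35.0 - 25.0) / 5.0)
    p_high_hit = norm.cdf((35.0 - 40.0) / 2.0)
    w_low = 0.0
    if config.f_lowqv > 0:
        w_low = min(1.0, max(0.0, (config.f_lowqv - p_high_hit) / (p_low_hit - p_high_hit)))
    low = rng.random(m) < w_low
    qv = np.where(low, rng.normal(25.0, 5.0, m), rng.normal(40.0, 2.0, m))
    qv = np.clip(qv, 0.0, None)

    transcripts = pd.DataFrame(
        {
            "transcript_id": [f"T{i + 1:07d}" for i in range(m)],
            "cell_id": cell_col,
            "gene": [genes[k] for k in gene_col],
            "x": x_col,
            "y": y_col,
            "qv": qv,
        }
    )

    truth = cells[["cell_id", "state", "niche", "x", "y"]].copy()
    truth["area"] = area
    truth["radius"] = radius
    return SyntheticTissue(
        config=config,
        transcripts=transcripts,
        nuclei=nuclei,
        boundaries=boundaries,
        truth=truth,
    )


def area_coupling_config(
    rho_target: float = 0.5,
    n_cells: int = 500,
    seed: int = 0,
    stress_genes: tuple[str, ...] = ("JUN", "FOS", "AREG", "CXCL2"),
) -> TissueConfig:
    """Single-niche all-adipocyte tissue for size–expression coupling studies.

    Stress genes are strongly expressed (mean 30 transcripts per cell) so
    Poisson discretisation barely attenuates the planted rank coupling, and
    60 background genes keep the stress set a minor fraction of per-cell
    totals so count normalization does not distort the area relationship.
    """
    rates: dict[str, dict[str, float]] = {"adipocyte": {}}
    panel: list[str] = []
    for g in stress_genes:
        panel.append(g)
        rates["adipocyte"][g] = 30.0
    for i in range(60):
        g = f"G{i:03d}"
        panel.append(g)
        rates["adipocyte"][g] = 8.0
    layout = [NicheSpec("all", (0.0, 2500.0), {"adipocyte": 1.0})]
    return TissueConfig(
        condition="lean",
        field_size=(2000.0, 2500.0),
        n_cells=n_cells,
        niche_layout=layout,
        gene_panel=panel,
        state_rates=rates,
        stress_genes=list(stress_genes),
        rho_target=rho_target,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# bundle I/O (Xenium-dialect CSVs plus truth TSVs)


def _poly_to_str(poly: np.ndarray) -> str:
    return ";".join(f"{float(x)!r} {float(y)!r}" for x, y in poly)


def _poly_from_str(s: str) -> np.ndarray:
    if not s:
        return np.empty((0, 2))
    pts = [tuple(float(v) for v in pair.split()) for pair in s.split(";")]
    return np.asarray(pts)


def write_bundle(tissue: SyntheticTissue, directory) -> dict[str, Path]:
    """Write a tissue to disk in the Xenium-dialect file set.

    Emits transcripts.csv (transcript_id, cell_id, overlaps_nucleus,
    feature_name, x_location, y_location, z_location, qv), nuclei.csv,
    boundary_pixels.csv and three truth TSVs.  A round-trip through
    :func:`read_bundle` reproduces the tables exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    t = tissue.transcripts
    xen = pd.DataFrame(
        {
            "transcript_id": t["transcript_id"],
            "cell_id": t["cell_id"],
            "overlaps_nucleus": 0,
            "feature_name": t["gene"],
            "x_location": t["x"].map(lambda v: repr(float(v))),
            "y_location": t["y"].map(lambda v: repr(float(v))),
            "z_location": 0,
            "qv": t["qv"].map(lambda v: repr(float(v))),
        }
    )
    paths["transcripts"] = directory / "transcripts.csv"
    xen.to_csv(paths["transcripts"], index=False)

    nuc = tissue.nuclei
    polys = nuc.polygons or [np.empty((0, 2))] * len(nuc)
    nuc_df = pd.DataFrame(
        {
            "nucleus_id": nuc.ids,
            "x": [repr(float(v)) for v in nuc.centroids[:, 0]],
            "y": [repr(float(v)) for v in nuc.centroids[:, 1]],
            "vertices": [_poly_to_str(p) for p in polys],
        }
    )
    paths["nuclei"] = directory / "nuclei.csv"
    nuc_df.to_csv(paths["nuclei"], index=False)

    paths["boundary_pixels"] = directory / "boundary_pixels.csv"
    tissue.boundaries.pixels.to_csv(paths["boundary_pixels"], index=False)

    tr = tissue.truth
    for name, col in [("states", "state"), ("niches", "niche")]:
        p = directory / f"truth_{name}.tsv"
        tr[["cell_id", col]].to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    p = directory / "truth_areas.tsv"
    out = tr[["cell_id"]].copy()
    out["area"] = tr["area"].map(lambda v: repr(float(v)))
    out.to_csv(p, sep="\t", index=False)
    paths["truth_areas"] = p

    meta = {
        "pixel_size": tissue.config.pixel_size,
        "condition": tissue.config.condition,
        "field_size": list(tissue.config.field_size),
        "seed": tissue.config.seed,
    }
    paths["meta"] = directory / "meta.json"
    paths["meta"].write_text(json.dumps(meta, indent=1))
    return paths


def read_bundle(directory) -> dict:
    """Read a bundle written by :func:`write_bundle`.

    Returns a dict with keys transcripts (DataFrame in canonical columns),
    nuclei and boundaries (SegmentedObjectSet) and truth (DataFrame).
    """
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())

    xen = pd.read_csv(
        directory / "transcripts.csv",
        dtype={"transcript_id": str, "cell_id": str, "feature_name": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    transcripts = pd.DataFrame(
        {
            "transcript_id": xen["transcript_id"],
            "cell_id": xen["cell_id"],
            "gene": xen["feature_name"],
            "x": xen["x_location"].astype(float),
            "y": xen["y_location"].astype(float),
            "qv": xen["qv"].astype(float),
        }
    )

    nuc_df = pd.read_csv(
        directory / "nuclei.csv", dtype={"nucleus_id": str},
        keep_default_na=False, float_precision="round_trip",
    )
    nuclei = SegmentedObjectSet(
        kind="nucleus",
        ids=nuc_df["nucleus_id"].to_numpy(),
        centroids=np.column_stack(
            [nuc_df["x"].astype(float), nuc_df["y"].astype(float)]
        )
        if len(nuc_df)
        else np.empty((0, 2)),
        polygons=[_poly_from_str(s) for s in nuc_df["vertices"]],
    )

    pixels = pd.read_csv(
        directory / "boundary_pixels.csv", dtype={"object_id": str}
    )
    if pixels.empty:
        pixels = pd.DataFrame(columns=["object_id", "px", "py"])
    obj_ids = pixels["object_id"].unique()
    if len(obj_ids):
        cents = pixels.groupby("object_id")[["px", "py"]].mean()
        cents = (cents.loc[obj_ids].to_numpy() + 0.5) * meta["pixel_size"]
    else:
        cents = np.empty((0, 2))
    boundaries = SegmentedObjectSet(
        kind="boundary_cell",
        ids=obj_ids,
        centroids=cents,
        pixels=pixels,
        pixel_size=meta["pixel_size"],
    )

    truth_states = pd.read_csv(directory / "truth_states.tsv", sep="\t", dtype=str)
    truth_niches = pd.read_csv(directory / "truth_niches.tsv", sep="\t", dtype=str)
    truth_areas = pd.read_csv(directory / "truth_areas.tsv", sep="\t", dtype=str)
    truth = truth_states.merge(truth_niches, on="cell_id").merge(
        truth_areas, on="cell_id"
    )
    truth["area"] = truth["area"].astype(float)
    return {
        "transcripts": transcripts,
        "nuclei": nuclei,
        "boundaries": boundaries,
        "truth": truth,
        "meta": meta,
    }
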