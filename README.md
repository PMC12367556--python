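# adiponiche

Spatial analysis of adipose tissue remodelling for imaging-based spatial
transcriptomics (Xenium-style per-transcript data). The package implements
the full analysis chain used to study how human subcutaneous adipose tissue
reorganises in obesity and therapeutic weight loss:

* **Transcript QC and binning** — keep transcripts with decoding quality
  QV > 35; tessellate the section into 50-µm bins, keeping bins with > 10
  transcripts.
* **Two transcript-to-cell assignment geometries** — *nucleus mode* (each
  transcript goes to the single nearest segmented nucleus within 2 µm;
  nuclei with > 40 transcripts kept) and *boundary mode* (transcripts go to
  every membrane-segmented adipocyte whose nearest mask pixel is within
  2 µm, after gating adipocytes to areas in (1,000, 25,000) µm²).
* **Control-matched stress scoring** — score(cell) = mean ln-normalized
  expression of a stress gene set minus the mean of 50 control genes drawn
  per target from the same expression stratum (25 equal-frequency bins).
* **Stress zonation** — per-bin mean scores, tissue-wide quartiles Q1–Q4,
  and the percentage of each cell state per quartile.
* **Niche detection** — each cell is described by the percentage of its
  neighbours (within 300 µm, self excluded) in each cell state; the
  percentage normalization removes the density asymmetry between lean and
  obese tissue (lean cells have roughly twice as many neighbours).
  Composition vectors are Leiden-clustered, near-duplicate clusters merged
  (Jensen–Shannon distance), and the partition refined by nearest-centroid
  sweeps.
* **Colocalization** — contact-scale (30 µm) state-pair adjacency
  enrichment against a label-permutation null (z-scores, empirical p).
* **Size–expression correlation** — Spearman ρ of per-cell normalized
  expression against adipocyte area, per condition and combined; genes with
  p < 10⁻⁵ in more than one correlation are selected and ranked by the
  combined ρ.
* **Exact sign tests** — two-sided binomial tests (minimum-likelihood
  rule) computed in log space, exact down to p ≈ 10⁻³⁰⁰ and beyond,
  plus Benjamini–Hochberg FDR adjustment and tie-aware Spearman
  correlation.

Because the real study data are deposited elsewhere, the package ships a
first-class **synthetic tissue generator** that emulates their statistical
structure — condition-dependent log-normal adipocyte sizes, five planted
niches, area-coupled stress-gene expression, QV noise and background
transcripts — with exact ground truth, so every stage is testable end to
end.

## Worked example

Exact sign test for 213 of 333 genes moving in the same direction:

```bash
$ adiponiche binom -k 213 -n 333
{"k": 213, "n": 333, "p0": 0.5, "p_two_sided": 3.910589972391683e-07,
 "log10_p": -6.407757717687068}
```

The two-sided p ≈ 3.9 × 10⁻⁷ says a 213/333 split is vanishingly unlikely
under a fair-coin null — the gene set moves coherently in one direction.

Full pipeline on synthetic tissue (one lean, one obese and one weight-loss
section), writing TSV/JSON outputs and per-stage manifests:

```bash
$ adiponiche run --out results/demo --seed 1
outputs written to results/demo
```

From Python:

```python
from adiponiche.synthetic import TissueConfig, generate_tissue, STRESS_GENES
from adiponiche.niches import neighborhood_composition, cluster_niches

tissue = generate_tissue(TissueConfig(condition="lean", seed=0))
nb = neighborhood_composition(tissue.truth)     # 300-µm composition rows
niches = cluster_niches(nb, seed=0)             # Leiden + merge + refine
print(niches.labels.value_counts())
```

prints the five recovered niche sizes, e.g.

```
niche
niche_0    414
niche_1    407
niche_2    401
niche_3    394
niche_4    384
Name: count, dtype: int64
```

which match the five planted communities (adjusted Rand index ≈ 0.9
against the generator's ground truth).

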