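"""Gene-set scoring, stress maps and marker positivity."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from adiponiche.scoring import call_positive_fraction, score_gene_set, stress_map
from adiponiche.stats import bh_adjust


def _adata(lognorm, genes, raw=None, obs=None):
    A = ad.AnnData(
        X=raw if raw is not None else np.zeros_like(lognorm),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        obs=obs,
    )
    A.layers["lognorm"] = lognorm
    return A


class TestScoreGeneSet:
    def test_constant_matrix_scores_zero(self):
        genes = [f"g{i}" for i in range(60)]
        X = np.full((20, 60), 2.5)
        A = _adata(X, genes)
        res = score_gene_set(A, genes[:5], control_size=10, seed=0)
        assert np.allclose(res.scores, 0.0)

    def test_recovers_planted_shift(self):
        # two well-separated expression strata; targets shifted within theirs
        rng = np.random.default_rng(0)
        n_cells = 300
        lo = rng.normal(0.0, 0.2, size=(n_cells, 100))
        hi = rng.normal(5.0, 0.2, size=(n_cells, 100))
        X = np.hstack([lo, hi])
        genes = [f"lo{i}" for i in range(100)] + [f"hi{i}" for i in range(100)]
        delta = 0.5
        X[:, :8] += delta
        A = _adata(X, genes)
        means = [
            score_gene_set(A, genes[:8], control_size=20, n_expression_bins=2,
                           seed=s).scores.mean()
            for s in range(20)
        ]
        assert np.mean(means) == pytest.approx(delta, abs=0.05)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(80)]
        X = rng.normal(size=(30, 80))
        A = _adata(X, genes)
        a = score_gene_set(A, genes[:6], control_size=10, seed=42)
        b = score_gene_set(A, genes[:6], control_size=10, seed=42)
        assert np.array_equal(a.scores, b.scores)
        assert a.control_genes == b.control_genes

    def test_location_invariance_in_expectation(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(80)]
        X = rng.normal(size=(40, 80))
        A = _adata(X, genes)
        B = _adata(X + 3.0, genes)
        sa = np.mean([score_gene_set(A, genes[:5], control_size=15, seed=s).scores
                      for s in range(10)], axis=0)
        sb = np.mean([score_gene_set(B, genes[:5], control_size=15, seed=s).scores
                      for s in range(10)], axis=0)
        assert np.allclose(sa, sb, atol=1e-9)

    def test_controls_disjoint_from_targets(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(100)]
        A = _adata(rng.normal(size=(10, 100)), genes)
        res = score_gene_set(A, genes[:10], control_size=20, seed=0)
        assert not set(res.control_genes) & set(res.gene_set)

    def test_small_pool_warns_and_replaces(self):
        genes = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(4)
        A = _adata(rng.normal(size=(10, 12)), genes)
        with pytest.warns(UserWarning, match="replacement"):
            score_gene_set(A, genes[:2], control_size=50,
                           n_expression_bins=2, seed=0)

    def test_empty_intersection_raises(self):
        A = _adata(np.zeros((5, 3)), ["a", "b", "c"])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                score_gene_set(A, ["zz"], seed=0)

    def test_tracks_scanpy_reference(self):
        """Independent cross-check against the reference implementation."""
        sc = pytest.importorskip("scanpy")
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(150)]
        X = rng.normal(1.0, 0.5, size=(100, 150))
        targets = genes[::15]
        A = _adata(X, genes)
        ours = np.mean([score_gene_set(A, targets, control_size=25, seed=s).scores
                        for s in range(15)], axis=0)
        ref = []
        for s in range(15):
            B = ad.AnnData(X=X.copy(),
                           var=pd.DataFrame(index=pd.Index(genes)))
            sc.tl.score_genes(B, targets, ctrl_size=25, n_bins=25, random_state=s)
            ref.append(B.obs["score"].to_numpy())
        ref = np.mean(ref, axis=0)
        assert np.corrcoef(ours, ref)[0, 1] > 0.95


class TestStressMap:
    def _score_result(self, values):
        from adiponiche.scoring import GeneSetScoreResult

        return GeneSetScoreResult(
            scores=pd.Series(values), gene_set=["JUN"], control_genes=["x"],
            control_size=1, n_expression_bins=2, seed=0,
        )

    def test_zero_scores_map_to_zero(self):
        bins = pd.DataFrame({"ix": [0, 1], "iy": [0, 0]})
        out = stress_map(self._score_result([0.0, 0.0]), bins)
        assert np.allclose(out["stress"], 0.0)

    def test_log1p_closed_form(self):
        bins = pd.DataFrame({"ix": [0], "iy": [0]})
        out = stress_map(self._score_result([1.0]), bins)
        assert out["stress"].iloc[0] == pytest.approx(np.log(2.0))

    def test_negative_scores_clipped(self):
        bins = pd.DataFrame({"ix": [0], "iy": [0]})
        out = stress_map(self._score_result([-2.0]), bins)
        assert out["stress"].iloc[0] == 0.0

    def test_identity_transform(self):
        bins = pd.DataFrame({"ix": [0], "iy": [0]})
        out = stress_map(self._score_result([-2.0]), bins, transform="identity")
        assert out["stress"].iloc[0] == -2.0

    def test_no_bins_raises(self):
        with pytest.raises(ValueError):
            stress_map(self._score_result([]), pd.DataFrame(columns=["ix", "iy"]))

    def test_planted_stress_band_contrast(self, obese_tissue):
        """Bins inside the planted stress band score higher than outside."""
        from scipy.stats import mannwhitneyu

        from adiponiche.pipeline import _bin_matrix
        from adiponiche.synthetic import STRESS_GENES
        from adiponiche.transcripts import bin_transcripts, filter_by_qv

        ft = filter_by_qv(obese_tissue.transcripts)
        grid = bin_transcripts(ft)
        bm = _bin_matrix(grid, 1e4)
        res = score_gene_set(bm, STRESS_GENES, seed=0)
        kept = grid.bins[grid.bins["kept"]].reset_index(drop=True)
        smap = stress_map(res, kept)
        band = [n for n in obese_tissue.config.niche_layout if n.name == "stress"][0]
        inside = smap["y_center"].between(*band.y_range)
        p = mannwhitneyu(
            smap.loc[inside, "stress"], smap.loc[~inside, "stress"],
            alternative="greater",
        ).pvalue
        assert p < 0.01


class TestPositivity:
    def _matrix(self, counts, samples, groups, gene="CDKN1A"):
        n = len(counts)
        A = ad.AnnData(
            X=np.asarray(counts, dtype=float).reshape(-1, 1),
            var=pd.DataFrame(index=pd.Index([gene], name="gene")),
            obs=pd.DataFrame({"sample": samples, "condition": groups},
                             index=[f"c{i}" for i in range(n)]),
        )
        return A

    def test_all_zero_counts_fraction_zero(self):
        A = self._matrix([0] * 10, ["s1"] * 10, ["lean"] * 10)
        res = call_positive_fraction(A, "CDKN1A")
        assert (res.fractions["fraction"] == 0).all()

    def test_direct_fraction(self):
        A = self._matrix([1, 2, 1, 0, 0, 0, 0, 0, 0, 0],
                         ["s1"] * 10, ["obese"] * 10)
        res = call_positive_fraction(A, "CDKN1A")
        assert res.fractions["fraction"].iloc[0] == pytest.approx(0.3)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(1.0, 200)
        A = self._matrix(counts, ["s1"] * 200, ["obese"] * 200)
        f1 = call_positive_fraction(A, "CDKN1A", threshold_counts=1)
        f2 = call_positive_fraction(A, "CDKN1A", threshold_counts=2)
        assert (f2.fractions["fraction"] <= f1.fractions["fraction"]).all()

    def test_gene_absent_raises(self):
        A = self._matrix([1], ["s1"], ["obese"])
        with pytest.raises(ValueError):
            call_positive_fraction(A, "NOPE")

    def test_paired_power_on_planted_difference(self):
        """Planted 0.4 vs 0.05 positivity over 10 paired samples: the paired
        signed-rank test rejects at FDR < 0.05 in ≥ 95% of replicates."""
        rng = np.random.default_rng(7)
        n_rep, hits = 60, 0
        for _ in range(n_rep):
            counts, samples, groups = [], [], []
            for i in range(10):
                c_ob = rng.binomial(1, 0.4, 40)
                c_wl = rng.binomial(1, 0.05, 40)
                counts += c_ob.tolist() + c_wl.tolist()
                samples += [f"p{i}"] * 80
                groups += ["obese"] * 40 + ["weight_loss"] * 40
            A = self._matrix(counts, samples, groups)
            res = call_positive_fraction(
                A, "CDKN1A", paired_pairs=[("obese", "weight_loss")]
            )
            if res.comparisons["p_adj"].iloc[0] < 0.05:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_fdr_control_under_global_null(self):
        """No group difference: ≤ ~5% of adjusted p-values fall below 0.05."""
        rng = np.random.default_rng(8)
        n_rep = 200
        rejections = 0
        comparisons = 0
        for _ in range(n_rep):
            counts, samples, groups = [], [], []
            for i in range(8):
                counts += rng.binomial(1, 0.2, 30).tolist()
                samples += [f"s{i}"] * 30
                groups += (["a"] if i < 4 else ["b"]) * 30
            A = self._matrix(counts, samples, groups)
            res = call_positive_fraction(A, "CDKN1A",
                                         unpaired_pairs=[("a", "b")])
            comparisons += len(res.comparisons)
            rejections += int((res.comparisons["p_adj"] < 0.05).sum())
        assert rejections / comparisons <= 0.05 + 0.03  # Monte-Carlo margin
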