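"""Transcript-to-cell assignment: geometric conventions and oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
import shapely

from adiponiche.assignment import (
    assign_to_boundaries,
    assign_to_nuclei,
    build_count_matrix,
    filter_by_area,
    flag_contaminants,
)
from adiponiche.containers import SegmentedObjectSet


def _transcripts(xy, genes=None):
    n = len(xy)
    return pd.DataFrame(
        {
            "transcript_id": [f"t{i}" for i in range(n)],
            "gene": genes if genes is not None else ["G"] * n,
            "x": [p[0] for p in xy],
            "y": [p[1] for p in xy],
            "qv": [40.0] * n,
        }
    )


def _square_nucleus(cx, cy, half=2.0):
    return np.array(
        [[cx - half, cy - half], [cx + half, cy - half],
         [cx + half, cy + half], [cx - half, cy + half]]
    )


def _nuclei(centers, half=2.0):
    return SegmentedObjectSet(
        kind="nucleus",
        ids=np.array([f"N{i}" for i in range(len(centers))], dtype=object),
        centroids=np.asarray(centers, dtype=float),
        polygons=[_square_nucleus(cx, cy, half) for cx, cy in centers],
    )


def _boundary_cells(pixel_lists, pixel_size=1.0):
    frames = []
    cents = []
    for i, pix in enumerate(pixel_lists):
        pix = np.asarray(pix)
        frames.append(pd.DataFrame(
            {"object_id": f"B{i}", "px": pix[:, 0], "py": pix[:, 1]}))
        cents.append(((pix[:, 0].mean() + 0.5) * pixel_size,
                      (pix[:, 1].mean() + 0.5) * pixel_size))
    return SegmentedObjectSet(
        kind="boundary_cell",
        ids=np.array([f"B{i}" for i in range(len(pixel_lists))], dtype=object),
        centroids=np.asarray(cents),
        pixels=pd.concat(frames, ignore_index=True),
        pixel_size=pixel_size,
    )


def _square_pixels(x0, y0, side):
    xs, ys = np.meshgrid(np.arange(x0, x0 + side), np.arange(y0, y0 + side))
    return np.column_stack([xs.ravel(), ys.ravel()])


class TestNucleusAssignment:
    def test_within_two_micron_closed_convention(self):
        nuc = _nuclei([(0.0, 0.0)], half=2.0)  # polygon edge at x = 2
        t = _transcripts([(4.0, 0.0), (4.01, 0.0)])  # 2.0 and 2.01 µm away
        out = assign_to_nuclei(t, nuc, max_dist=2.0)
        assert list(out["transcript_id"]) == ["t0"]
        assert out["distance"].iloc[0] == pytest.approx(2.0)

    def test_inside_polygon_distance_zero(self):
        nuc = _nuclei([(0.0, 0.0)])
        out = assign_to_nuclei(_transcripts([(0.5, -0.5)]), nuc)
        assert out["distance"].iloc[0] == 0.0

    def test_tie_breaks_to_smaller_object_id(self):
        nuc = _nuclei([(0.0, 0.0), (10.0, 0.0)])
        out = assign_to_nuclei(_transcripts([(5.0, 0.0)]), nuc, max_dist=5.0)
        assert out["object_id"].iloc[0] == "N0"

    def test_empty_nucleus_set_returns_no_assignments(self):
        nuc = SegmentedObjectSet(kind="nucleus", ids=np.array([], dtype=object),
                                 centroids=np.empty((0, 2)), polygons=[])
        out = assign_to_nuclei(_transcripts([(0, 0)]), nuc)
        assert len(out) == 0

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            assign_to_nuclei(_transcripts([(0, 0)]), _nuclei([(0, 0)]), max_dist=-1)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            n_t, n_n = 200, 15
            centers = rng.uniform(0, 100, size=(n_n, 2))
            nuc = _nuclei(centers, half=2.0)
            t = _transcripts(rng.uniform(0, 100, size=(n_t, 2)))
            out = assign_to_nuclei(t, nuc, max_dist=2.0)
            got = dict(zip(out["transcript_id"], out["object_id"]))
            # oracle: exhaustive polygon distances
            polys = [shapely.polygons(p) for p in nuc.polygons]
            for i in range(n_t):
                pt = shapely.points(t["x"][i], t["y"][i])
                d = np.array([shapely.distance(pt, poly) for poly in polys])
                within = d <= 2.0
                if within.any():
                    best = np.flatnonzero(d == d[within].min())[0]
                    assert got[f"t{i}"] == f"N{best}"
                else:
                    assert f"t{i}" not in got

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(11)
        nuc = _nuclei(rng.uniform(0, 80, size=(10, 2)))
        t = _transcripts(rng.uniform(0, 80, size=(300, 2)))
        small = set(assign_to_nuclei(t, nuc, max_dist=2.0)["transcript_id"])
        large = set(assign_to_nuclei(t, nuc, max_dist=6.0)["transcript_id"])
        assert small <= large


class TestBoundaryAssignment:
    def test_area_gate_is_strict(self):
        # 1000 px and 25000 px at 1 µm² sit exactly on the bounds -> excluded
        cells = _boundary_cells([
            _square_pixels(0, 0, 10),        # 100 µm² (too small)
            _square_pixels(100, 0, 32),      # 1024 µm² (retained)
            np.column_stack([np.repeat(np.arange(200, 225), 40),
                             np.tile(np.arange(40), 25)]),  # 1000 µm² exactly
        ])
        kept = set(filter_by_area(cells))
        assert kept == {"B1"}

    def test_exactly_25000_pixels_excluded(self):
        big = np.column_stack([np.repeat(np.arange(250), 100),
                               np.tile(np.arange(100), 250)])
        ok = np.column_stack([np.repeat(np.arange(300, 400), 100),
                              np.tile(np.arange(100), 100)])  # 10,000 µm²
        cells = _boundary_cells([big, ok])
        assert set(filter_by_area(cells)) == {"B1"}

    def test_equidistant_transcript_assigned_to_both(self):
        # two 40×40 cells with facing edges at x = 40 and x = 43
        a = _square_pixels(0, 0, 40)
        b = _square_pixels(43, 0, 40)
        cells = _boundary_cells([a, b])
        # nearest pixel centres are x = 39.5 and x = 43.5; transcript at 41.5
        # (y on a pixel-centre line) is exactly 2.0 µm from both
        out = assign_to_boundaries(_transcripts([(41.5, 20.5)]), cells, max_dist=2.0)
        assert set(out["object_id"]) == {"B0", "B1"}

    def test_inside_footprint_single_owner(self):
        cells = _boundary_cells([_square_pixels(0, 0, 40),
                                 _square_pixels(50, 0, 40)])
        out = assign_to_boundaries(_transcripts([(5.5, 5.5)]), cells)
        assert list(out["object_id"]) == ["B0"]
        assert out["distance"].iloc[0] == 0.0

    def test_excluded_transcripts_are_dropped_first(self):
        cells = _boundary_cells([_square_pixels(0, 0, 40)])
        t = _transcripts([(5.0, 5.0), (6.0, 6.0)])
        excl = pd.DataFrame({"transcript_id": ["t0"], "object_id": ["N9"],
                             "distance": [0.0], "mode": ["nucleus"]})
        out = assign_to_boundaries(t, cells, exclude=excl)
        assert list(out["transcript_id"]) == ["t1"]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(8):
            sides = rng.integers(32, 45, size=4)
            origins = [(0, 0), (60, 0), (0, 60), (60, 60)]
            pixel_lists = [_square_pixels(ox, oy, s)
                           for (ox, oy), s in zip(origins, sides)]
            cells = _boundary_cells(pixel_lists)
            t = _transcripts(rng.uniform(-3, 110, size=(150, 2)))
            out = assign_to_boundaries(t, cells, max_dist=2.0)
            got = set(zip(out["transcript_id"], out["object_id"]))
            expected = set()
            centers = {f"B{i}": (np.asarray(p) + 0.5) for i, p in
                       enumerate(pixel_lists)}
            pixsets = {f"B{i}": {tuple(q) for q in p}
                       for i, p in enumerate(pixel_lists)}
            keep = set(filter_by_area(cells))
            for i in range(len(t)):
                x, y = t["x"][i], t["y"][i]
                owners = [o for o in keep
                          if (int(np.floor(x)), int(np.floor(y))) in pixsets[o]]
                if owners:
                    expected |= {(f"t{i}", o) for o in owners}
                    continue
                for o in keep:
                    d = np.hypot(centers[o][:, 0] - x, centers[o][:, 1] - y).min()
                    if d <= 2.0:
                        expected.add((f"t{i}", o))
            assert got == expected


class TestCountMatrix:
    def _assignment(self, pairs):
        return pd.DataFrame(
            {"transcript_id": [p[0] for p in pairs],
             "object_id": [p[1] for p in pairs],
             "distance": 0.0, "mode": "nucleus"}
        )

    def test_min_transcripts_strict_at_forty(self):
        t = _transcripts([(0, 0)] * 81)
        a40 = self._assignment([(f"t{i}", "C0") for i in range(40)])
        a41 = self._assignment([(f"t{i}", "C1") for i in range(40, 81)])
        both = pd.concat([a40, a41], ignore_index=True)
        m = build_count_matrix(both, t, min_transcripts=40)
        assert list(m.obs_names) == ["C1"]

    def test_proportional_scaling(self):
        t = _transcripts([(0, 0)] * 4, genes=["A", "A", "A", "B"])
        a = self._assignment([(f"t{i}", "C0") for i in range(4)])
        m = build_count_matrix(a, t, min_transcripts=0, normalize_target=10_000)
        normalized = m.layers["normalized"].toarray().ravel()
        assert sorted(normalized) == [2_500.0, 7_500.0]

    def test_normalized_rows_sum_to_target(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(20)]
        t = _transcripts([(0, 0)] * 500,
                         genes=rng.choice(genes, 500).tolist())
        cells = rng.choice([f"C{j}" for j in range(8)], 500)
        a = self._assignment(list(zip(t["transcript_id"], cells)))
        m = build_count_matrix(a, t, min_transcripts=0, normalize_target=1e4)
        sums = np.asarray(m.layers["normalized"].sum(axis=1)).ravel()
        assert np.allclose(sums, 1e4, atol=1e-9)

    def test_lognorm_is_log1p_of_normalized(self):
        t = _transcripts([(0, 0)] * 10, genes=["A"] * 6 + ["B"] * 4)
        a = self._assignment([(f"t{i}", "C0") for i in range(10)])
        m = build_count_matrix(a, t, min_transcripts=0, normalize_target=1.0)
        assert np.allclose(
            m.layers["lognorm"].toarray(),
            np.log1p(m.layers["normalized"].toarray()),
        )

    def test_multi_assignment_counts_fully_in_each_cell(self):
        t = _transcripts([(0, 0)], genes=["A"])
        a = self._assignment([("t0", "C0"), ("t0", "C1")])
        m = build_count_matrix(a, t, min_transcripts=0, normalize_target=1.0)
        assert m.X.sum() == 2

    def test_gene_absent_from_panel_errors(self):
        t = _transcripts([(0, 0)], genes=["A"])
        a = self._assignment([("t0", "C0")])
        with pytest.raises(ValueError, match="panel"):
            build_count_matrix(a, t, min_transcripts=0, genes=["B"])

    def test_count_conservation_nucleus_mode(self, small_tissue):
        from adiponiche.transcripts import filter_by_qv

        ft = filter_by_qv(small_tissue.transcripts)
        out = assign_to_nuclei(ft, small_tissue.nuclei)
        m = build_count_matrix(out, ft, min_transcripts=0)
        assert m.X.sum() == len(out)

    def test_contaminant_flag(self):
        t = _transcripts([(0, 0)] * 10, genes=["CD68"] * 5 + ["ADIPOQ"] * 5)
        a = self._assignment([(f"t{i}", "C0") for i in range(10)])
        m = build_count_matrix(a, t, min_transcripts=0)
        assert flag_contaminants(m, ["CD68"], max_fraction=0.4).tolist() == [True]
        assert flag_contaminants(m, ["CD68"], max_fraction=0.6).tolist() == [False]
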