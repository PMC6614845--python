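"""Clustering, cluster labelling, class intersection and the geometry model."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from h1splice.exon_classes import (
    NucleosomeGeometry,
    correlate_distance_inclusion,
    exon_h1_distances,
    h1_distance,
    hypergeometric_tail,
    intersect_classes,
    kmeans_profiles,
    label_clusters,
    optimal_exon_length,
)
from h1splice.metaprofile import AnchorSpec, SignalMatrix
from h1splice.pipeline import SPEC_3SS, SPEC_5SS


def matrix_3ss(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"e{i}" for i in range(len(values))]
    return SignalMatrix(values, ids, SPEC_3SS)


def matrix_5ss(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"e{i}" for i in range(len(values))]
    return SignalMatrix(values, ids, SPEC_5SS)


WIDTH = SPEC_3SS.width  # 450


def bumpy_row(peak_col, height=10.0, width=20, ncols=WIDTH):
    row = np.zeros(ncols)
    lo, hi = max(0, peak_col - width), min(ncols, peak_col + width + 1)
    row[lo:hi] = height * np.exp(
        -0.5 * ((np.arange(lo, hi) - peak_col) / (width / 2.0)) ** 2
    )
    return row


class TestKmeans:
    def test_duplicate_prototypes_recovered_exactly(self):
        rows = [bumpy_row(300), bumpy_row(300), bumpy_row(50), bumpy_row(50)]
        asg = kmeans_profiles(matrix_3ss(rows), "anchored_3ss", k=2, seed=0)
        assert asg.labels[0] == asg.labels[1]
        assert asg.labels[2] == asg.labels[3]
        assert asg.labels[0] != asg.labels[2]
        assert asg.inertia == pytest.approx(0.0, abs=1e-9)

    def test_well_separated_gaussian_prototypes_recovered(self):
        rng = np.random.default_rng(1)
        prototypes = [bumpy_row(c, height=50.0) for c in (30, 130, 230, 330, 420)]
        planted, rows = [], []
        for i, proto in enumerate(prototypes):
            for _ in range(12):
                rows.append(proto + rng.normal(0, 1.0, WIDTH))
                planted.append(i)
        asg = kmeans_profiles(matrix_3ss(rows), "anchored_3ss", k=5, seed=0)
        assert adjusted_rand_score(planted, asg.labels) >= 0.95

    def test_objective_equals_recomputed_within_cluster_ss(self):
        rng = np.random.default_rng(2)
        rows = rng.random((40, WIDTH))
        asg = kmeans_profiles(matrix_3ss(rows), "anchored_3ss", k=5, seed=3)
        ss = sum(
            ((rows[asg.labels == c] - asg.centroids[c]) ** 2).sum()
            for c in range(5)
        )
        assert asg.inertia == pytest.approx(ss, rel=1e-6)

    def test_more_restarts_never_worsen_the_objective(self):
        rng = np.random.default_rng(4)
        rows = rng.random((60, WIDTH))
        single = kmeans_profiles(matrix_3ss(rows), "anchored_3ss", k=5, seed=0, n_restarts=1)
        multi = kmeans_profiles(matrix_3ss(rows), "anchored_3ss", k=5, seed=0, n_restarts=10)
        assert multi.inertia <= single.inertia + 1e-9

    def test_all_missing_rows_are_excluded(self):
        rows = np.vstack([bumpy_row(300), np.full(WIDTH, np.nan), bumpy_row(50)])
        asg = kmeans_profiles(matrix_3ss(rows), "anchored_3ss", k=2, seed=0)
        assert asg.row_ids == ["e0", "e2"]


class TestLabelClusters:
    def _assignment(self, centroids, run="anchored_3ss"):
        mat = matrix_3ss(centroids) if run == "anchored_3ss" else matrix_5ss(centroids)
        k = len(centroids)
        return kmeans_profiles(mat, run, k=k, seed=0, n_restarts=1)

    def test_peak_near_anchored_junction(self):
        # 10 bp intron-side of the 3'ss junction (anchor col 300)
        asg = self._assignment([bumpy_row(290), np.zeros(WIDTH)])
        labels = {l.label for l in label_clusters(asg)}
        assert "near_3ss" in labels

    def test_flat_centroid_below_global_mean_is_low(self):
        asg = self._assignment([bumpy_row(300, height=40.0), np.full(WIDTH, 1.0)])
        by_peak = {round(l.peak_height): l.label for l in label_clusters(asg)}
        assert by_peak[1] == "low"

    def test_deep_intronic_peak_is_distant(self):
        # 280 bp into the intron
        asg = self._assignment([bumpy_row(20), np.zeros(WIDTH)])
        labels = {l.label for l in label_clusters(asg)}
        assert "distant" in labels

    def test_far_exonic_edge_attributed_to_opposite_site(self):
        # 3'ss-anchored window, peak 140 bp into the exon: the opposite
        # (5'ss) junction of a typical short exon lies near that edge
        asg = self._assignment([bumpy_row(440), np.zeros(WIDTH)])
        labels = {l.label for l in label_clusters(asg)}
        assert "near_5ss" in labels

    def test_intermediate_intronic_peak_goes_to_nearest_junction(self):
        asg = self._assignment([bumpy_row(300 - 120), np.zeros(WIDTH)])
        labels = {l.label for l in label_clusters(asg)}
        assert "near_3ss" in labels


class TestIntersectClasses:
    def _two_runs(self, labels_a, labels_b, n=8):
        """Build runs where exon i belongs to cluster labels_x[i]."""
        ids = [f"e{i}" for i in range(n)]
        # peak positions that carry each label in the given window: the
        # 3'ss run anchors at col 300 (intron left, exon right), the 5'ss
        # run at col 150 (exon left, intron right)
        centroid_for = {
            "anchored_3ss": {
                "near_3ss": bumpy_row(295),
                "near_5ss": bumpy_row(445),
                "distant": bumpy_row(40),
                "low": np.zeros(WIDTH),
            },
            "anchored_5ss": {
                "near_5ss": bumpy_row(145),
                "near_3ss": bumpy_row(25),
                "distant": bumpy_row(410),
                "low": np.zeros(WIDTH),
            },
        }

        def build(run, labs):
            vals = np.vstack([centroid_for[run][l] for l in labs])
            mat = matrix_3ss(vals, ids) if run == "anchored_3ss" else matrix_5ss(vals, ids)
            return kmeans_profiles(mat, run, k=len(set(labs)), seed=0, n_restarts=2)

        run_a = build("anchored_3ss", labels_a)
        run_b = build("anchored_5ss", labels_b)
        la = label_clusters(run_a)
        lb = label_clusters(run_b)
        return run_a, la, run_b, lb

    def test_full_overlap_recovers_marked_set(self):
        labels = ["near_3ss"] * 4 + ["low"] * 4
        run_a, la, run_b, lb = self._two_runs(labels, labels)
        classes, pvals = intersect_classes(run_a, la, run_b, lb)
        marked = {e for e, c in classes.items() if c == "marked_3ss"}
        assert marked == {"e0", "e1", "e2", "e3"}
        assert pvals["marked_3ss"] == pytest.approx(
            hypergeometric_tail(4, 4, 4, 8)
        )

    def test_disjoint_near_sets_leave_no_marked_exons(self):
        a = ["near_3ss"] * 4 + ["low"] * 4
        b = ["low"] * 4 + ["near_3ss"] * 4
        run_a, la, run_b, lb = self._two_runs(a, b)
        classes, _ = intersect_classes(run_a, la, run_b, lb)
        assert "marked_3ss" not in classes.values()

    def test_classes_partition_the_universe(self):
        a = ["near_3ss", "near_3ss", "distant", "distant", "near_5ss", "low", "low", "low"]
        b = ["near_3ss", "low", "distant", "distant", "near_5ss", "near_5ss", "low", "low"]
        run_a, la, run_b, lb = self._two_runs(a, b)
        classes, _ = intersect_classes(run_a, la, run_b, lb)
        assert set(classes) == {f"e{i}" for i in range(8)}
        assert classes["e0"] == "marked_3ss"
        assert classes["e1"] == "unmarked"
        assert classes["e2"] == "distant"
        assert classes["e4"] == "marked_5ss"

    def test_universe_mismatch_is_an_error(self):
        a = ["near_3ss"] * 4 + ["low"] * 4
        run_a, la, run_b, lb = self._two_runs(a, a)
        run_b.row_ids = run_b.row_ids[:-1] + ["other"]
        with pytest.raises(ValueError):
            intersect_classes(run_a, la, run_b, lb)


class TestHypergeometricTail:
    def test_zero_overlap_when_attainable_gives_one(self):
        assert hypergeometric_tail(0, 3, 3, 10) == pytest.approx(1.0)

    def test_five_of_five_in_ten_is_one_over_252(self):
        assert hypergeometric_tail(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_matches_exhaustive_enumeration_for_all_small_cases(self):
        # enumerate every (universe <= 12, nA, nB, overlap) configuration
        for universe in range(1, 13):
            items = range(universe)
            for n_a in range(universe + 1):
                set_a = set(range(n_a))
                for n_b in range(universe + 1):
                    total = math.comb(universe, n_b)
                    tail_counts = {}
                    for combo in itertools.combinations(items, n_b):
                        k = len(set_a & set(combo))
                        tail_counts[k] = tail_counts.get(k, 0) + 1
                    lo = max(0, n_a + n_b - universe)
                    for overlap in range(lo, min(n_a, n_b) + 1):
                        expected = (
                            sum(v for k, v in tail_counts.items() if k >= overlap)
                            / total
                        )
                        assert hypergeometric_tail(
                            overlap, n_a, n_b, universe
                        ) == pytest.approx(expected, rel=1e-9), (
                            universe, n_a, n_b, overlap,
                        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(4, 3, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_tail(0, 8, 8, 10)  # minimum overlap is 6


class TestH1Distance:
    def test_spike_forty_bp_into_the_intron(self):
        row = np.zeros(WIDTH)
        row[300 - 40] = 5.0
        assert h1_distance(row, 300, "3ss").distance == 40

    def test_spike_at_the_junction_is_zero(self):
        row = np.zeros(WIDTH)
        row[300] = 5.0
        assert h1_distance(row, 300, "3ss").distance == 0

    def test_ties_break_toward_the_junction(self):
        row = np.zeros(WIDTH)
        row[300 + 20] = 5.0
        row[300 - 60] = 5.0
        assert h1_distance(row, 300, "3ss").distance == 20

    def test_all_missing_row_yields_none(self):
        assert h1_distance(np.full(WIDTH, np.nan), 300, "3ss") is None

    def test_exon_h1_distances_skips_missing_rows(self):
        rows = np.vstack([bumpy_row(280), np.full(WIDTH, np.nan)])
        out = exon_h1_distances(matrix_3ss(rows), "3ss")
        assert set(out) == {"e0"} and out["e0"] == 20


class TestGeometryModel:
    def test_standard_geometry_gives_110_and_100(self):
        geom = NucleosomeGeometry(146, 35, 45)
        assert optimal_exon_length(geom, "5ss") == 110
        assert optimal_exon_length(geom, "3ss") == 100

    def test_zero_offsets_return_the_wrap_length(self):
        geom = NucleosomeGeometry(100, 0, 0)
        assert optimal_exon_length(geom, "5ss") == 100
        assert optimal_exon_length(geom, "3ss") == 100

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            NucleosomeGeometry(100, 120, 45)


class TestCorrelateDistanceInclusion:
    def test_perfect_antimonotone_pairs(self):
        d = {f"e{i}": float(i) for i in range(10)}
        p = {f"e{i}": 1.0 - 0.05 * i for i in range(10)}
        r, _ = correlate_distance_inclusion(d, p)
        assert r == pytest.approx(-1.0)

    def test_permutation_null_is_centered_at_zero(self):
        rng = np.random.default_rng(0)
        d = {f"e{i}": float(v) for i, v in enumerate(rng.random(30))}
        base = rng.random(30)
        rs = []
        for _ in range(500):
            rng.shuffle(base)
            p = {f"e{i}": float(v) for i, v in enumerate(base)}
            rs.append(correlate_distance_inclusion(d, p)[0])
        assert abs(np.mean(rs)) < 0.02
        # 95th percentile of |r| under the null matches the t approximation
        crit = np.percentile(np.abs(rs), 95)
        assert 0.25 < crit < 0.48

    def test_zero_variance_rejected(self):
        d = {"a": 1.0, "b": 1.0, "c": 1.0}
        p = {"a": 0.1, "b": 0.5, "c": 0.9}
        with pytest.raises(ValueError):
            correlate_distance_inclusion(d, p)
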