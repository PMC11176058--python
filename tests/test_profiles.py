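"""Meta-profiles, motif matrices, insertion preference, CpG binning, AUC."""

import numpy as np
import pandas as pd
import pytest

from chromfiber import hmm, profiles
from chromfiber.errors import CapacityError
from chromfiber.evaluate import adjusted_rand_index
from chromfiber.io import Fiber, GenomicInterval
from chromfiber.profiles import (
    classify_cpg,
    cluster_cpg_overlay,
    cluster_motif_matrix,
    correlate_tracks,
    cpg_call_auc,
    five_prime_meta,
    fragment_ends,
    insertion_preference,
    motif_matrix,
)
from chromfiber.simulate import FiberTypeSpec, NoiseModel, simulate_fiber


class TestFivePrimeMeta:
    def test_all_accessible_gives_constant_one(self):
        tracks = [np.ones(1500, dtype=np.int8) for _ in range(5)]
        meta = five_prime_meta(tracks, span=1000)
        assert meta.shape == (1000,)
        assert np.all(meta == 1.0)

    def test_empty_input_gives_empty_profile(self):
        assert five_prime_meta([], span=1000).size == 0
        assert five_prime_meta([None, None], span=1000).size == 0

    def test_short_tracks_contribute_partially(self):
        tracks = [np.ones(300, dtype=np.int8), np.zeros(1000, dtype=np.int8)]
        meta = five_prime_meta(tracks, span=1000)
        assert meta[0] == 0.5
        assert meta[500] == 0.0


class TestMotifMatrix:
    def _make(self, seed=11, n_each=120, window=750):
        rng = np.random.default_rng(seed)
        noise = NoiseModel()
        specs = [
            FiberTypeSpec("bound", "ctcf_bound", nrl_mean=185.0),
            FiberTypeSpec("open", "hyperaccessible", nrl_mean=185.0),
            FiberTypeSpec("nucleosomal", "regular", nrl_mean=185.0),
        ]
        fibers, anchors = [], []
        k = 0
        for spec in specs:
            for i in range(n_each):
                start = k * 5000
                fb, _ = simulate_fiber(
                    spec, 2000, noise, rng, molecule_id=f"{spec.label}_{i:03d}",
                    start=start, cpg_island=True, cpg_methylated=True,
                )
                fibers.append(fb)
                anchors.append(
                    GenomicInterval("chrS", start + 990, start + 1010, f"a{k}", "+")
                )
                k += 1
        params, _ = hmm.fit_hmm(fibers[:100])
        tracks = [
            hmm.accessibility_track(f, hmm.decode_accessibility(f, params)) for f in fibers
        ]
        return fibers, tracks, anchors

    def test_non_spanning_fibers_excluded_and_rows_conserved(self):
        fibers, tracks, anchors = self._make(n_each=10)
        # an anchor nobody spans
        anchors.append(GenomicInterval("chrS", 10_000_000, 10_000_020, "far", "+"))
        mm = motif_matrix(fibers, tracks, anchors)
        assert mm.data.shape == (30, 750)  # one spanning pair per fiber
        assert not np.isnan(mm.data).any()

    def test_strand_flip_twice_is_identity(self):
        fibers, tracks, anchors = self._make(n_each=5)
        minus = [
            GenomicInterval(a.chrom, a.start, a.end, a.name, "-") for a in anchors
        ]
        plus_mm = motif_matrix(fibers, tracks, anchors)
        minus_mm = motif_matrix(fibers, tracks, minus)
        assert np.array_equal(plus_mm.data, minus_mm.data[:, ::-1])

    def test_bound_fibers_dip_at_center(self):
        fibers, tracks, anchors = self._make(n_each=40)
        bound = [i for i, f in enumerate(fibers) if f.molecule_id.startswith("bound")]
        mm = motif_matrix([fibers[i] for i in bound], [tracks[i] for i in bound],
                          [anchors[i] for i in bound])
        col_mean = mm.data.mean(axis=0)
        center = col_mean[370:380].mean()
        flank = np.concatenate([col_mean[250:330], col_mean[420:500]]).mean()
        assert center < flank

    def test_cluster_rows_recover_planted_states(self):
        fibers, tracks, anchors = self._make(seed=11)
        mm = motif_matrix(fibers, tracks, anchors)
        labels = cluster_motif_matrix(mm, seed=0)
        truth = np.array([m.rsplit("_", 1)[0] for m in mm.molecule_ids])
        keep = labels >= 0
        assert adjusted_rand_index(truth[keep], labels[keep]) >= 0.7

    def test_cluster_requires_enough_rows(self):
        fibers, tracks, anchors = self._make(n_each=10)
        mm = motif_matrix(fibers, tracks, anchors)
        with pytest.raises(CapacityError):
            cluster_motif_matrix(mm)

    def test_cpg_overlay_separates_bound_from_nucleosomal(self):
        fibers, tracks, anchors = self._make(seed=11)
        mm = motif_matrix(fibers, tracks, anchors)
        labels = cluster_motif_matrix(mm, seed=0)
        overlay = cluster_cpg_overlay(mm, labels, {f.molecule_id: f for f in fibers})
        truth = np.array([m.rsplit("_", 1)[0] for m in mm.molecule_ids])
        by_type = {}
        for label, prof in overlay.items():
            vals, counts = np.unique(truth[labels == label], return_counts=True)
            dominant = vals[np.argmax(counts)]
            by_type[dominant] = np.nanmean(prof[300:450])
            assert np.nanmin(prof) >= 0 and np.nanmax(prof) <= 1
        assert by_type["bound"] < by_type["nucleosomal"]

    def test_overlay_missing_when_no_cpgs(self):
        fiber = Fiber("f0", "chrS", 0, 2000,
                      a_positions=np.arange(0, 2000, 4),
                      m6da_prob=np.tile([0.9, 0.1], 250))
        track = np.ones(2000, dtype=np.int8)
        mm = motif_matrix([fiber], [track], [GenomicInterval("chrS", 995, 1005, "a", "+")])
        overlay = cluster_cpg_overlay(mm, np.zeros(1, dtype=int), {"f0": fiber})
        assert np.all(np.isnan(overlay[0]))


class TestInsertionPreference:
    def test_all_ends_at_anchors_gives_fraction_one(self):
        ends = pd.DataFrame({"chrom": ["c"] * 10, "pos": [5000] * 10})
        anchors = [GenomicInterval("c", 4990, 5010, "a", "+")]
        prof = insertion_preference(ends, anchors, mappable_span_nt=1_000_000)
        assert prof.frit_score == 1.0
        assert prof.fold_enrichment > 1.0

    def test_uniform_ends_fold_enrichment_near_one(self):
        rng = np.random.default_rng(2)
        span = 2_000_000
        ends = pd.DataFrame({"chrom": "c", "pos": rng.integers(0, span, size=20_000)})
        anchors = [GenomicInterval("c", c, c + 20, f"a{i}", "+")
                   for i, c in enumerate(range(100_000, 1_900_000, 100_000))]
        prof = insertion_preference(ends, anchors, mappable_span_nt=span)
        n = len(ends)
        p = prof.frit_score
        se = np.sqrt(p * (1 - p) / n)
        expected = sum(min(a.center + 2500, span) - max(a.center - 2500, 0)
                       for a in anchors) / span
        assert abs(p - expected) < 3 * se + 1e-9
        assert abs(prof.fold_enrichment - 1.0) < 0.1

    def test_smoothing_preserves_mass(self):
        ends = pd.DataFrame({"chrom": "c", "pos": [10_000 + k for k in range(-500, 500)]})
        anchors = [GenomicInterval("c", 9990, 10_010, "a", "+")]
        prof = insertion_preference(ends, anchors, mappable_span_nt=1_000_000)
        assert prof.profile.sum() == pytest.approx(1000, rel=0.01)

    def test_wider_window_never_decreases_fraction(self, rng):
        ends = pd.DataFrame({"chrom": "c", "pos": rng.integers(0, 500_000, 2000)})
        anchors = [GenomicInterval("c", c, c + 10, "a", "+")
                   for c in range(50_000, 450_000, 50_000)]
        narrow = insertion_preference(ends, anchors, 500_000, window=2000)
        wide = insertion_preference(ends, anchors, 500_000, window=8000)
        assert wide.frit_score >= narrow.frit_score

    def test_anchor_order_invariance(self, rng):
        ends = pd.DataFrame({"chrom": "c", "pos": rng.integers(0, 100_000, 500)})
        anchors = [GenomicInterval("c", c, c + 10, f"a{c}", "+")
                   for c in (10_000, 40_000, 70_000)]
        a = insertion_preference(ends, anchors, 100_000)
        b = insertion_preference(ends, anchors[::-1], 100_000)
        assert a.frit_score == b.frit_score

    def test_empty_anchor_set_rejected(self):
        ends = pd.DataFrame({"chrom": ["c"], "pos": [1]})
        with pytest.raises(ValueError):
            insertion_preference(ends, [], 1000)

    def test_fragment_ends_two_per_fragment(self):
        fibers = [Fiber("a", "c", 100, 600), Fiber("b", "c", 700, 1400)]
        ends = fragment_ends(fibers)
        assert sorted(ends["pos"]) == [100, 599, 700, 1399]


class TestClassifyCpg:
    def _fiber(self, length, n_cpg, score):
        pos = np.arange(n_cpg) * 3
        return Fiber("f", "c", 0, length, cpg_positions=pos,
                     m5dc_prob=np.full(n_cpg, score))

    @pytest.mark.parametrize(
        "length,n_cpg,score,expected",
        [
            (2000, 30, 0.8, "high-CpG/high-meth"),
            (2000, 20, 0.5, "low-CpG/low-meth"),  # both exactly at thresholds -> low
            (1000, 11, 0.51, "high-CpG/high-meth"),
            (1000, 10, 0.9, "low-CpG/high-meth"),
            (1000, 30, 0.2, "high-CpG/low-meth"),
        ],
    )
    def test_threshold_boundaries(self, length, n_cpg, score, expected):
        assert classify_cpg(self._fiber(length, n_cpg, score)).label == expected

    def test_no_cpg_fiber_excluded(self):
        assert classify_cpg(Fiber("f", "c", 0, 1000)) is None

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        labels = set()
        for _ in range(100):
            f = self._fiber(1000, int(rng.integers(1, 40)), float(rng.random()))
            labels.add(classify_cpg(f).label)
        assert labels <= {
            "high-CpG/high-meth", "high-CpG/low-meth",
            "low-CpG/high-meth", "low-CpG/low-meth",
        }
        assert len(labels) == 4


class TestTrackCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.random(50) * 100
        assert correlate_tracks(x, x) == pytest.approx(1.0)

    def test_anticorrelated_tracks_negative(self):
        x = np.arange(1, 51, dtype=float)
        assert correlate_tracks(x, x[::-1]) < 0

    def test_accessibility_recovers_planted_open_regions(self, rng):
        open_region = rng.random(200) > 0.5
        signal = np.where(open_region, 50, 2) * np.exp(rng.normal(0, 0.2, 200))
        r = correlate_tracks(signal, np.where(open_region, 100.0, 1.0))
        assert r >= 0.8

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            correlate_tracks(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestAuc:
    def test_perfect_separation(self):
        assert cpg_call_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(6)
        scores = rng.random(10_000)
        labels = np.arange(10_000) % 2
        assert abs(cpg_call_auc(scores, labels) - 0.5) < 0.02

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 100))
            scores = np.round(rng.random(n), 1)  # ties on purpose
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert cpg_call_auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cpg_call_auc([0.1, 0.9], [1, 1])
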