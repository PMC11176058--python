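"""Ground-truth simulator: barcodes, fiber geometry, tagmentation, datasets."""

import numpy as np
import pytest
from scipy.stats import kstest

from chromfiber import io, simulate
from chromfiber.errors import CapacityError
from chromfiber.simulate import (
    DUPLICATION_LEN,
    FiberTypeSpec,
    NoiseModel,
    SimConfig,
    design_barcodes,
    simulate_dataset,
    simulate_fiber,
    simulate_tagmentation,
)


class TestDesignBarcodes:
    def test_min_pairwise_distance_holds_exhaustively(self):
        bset = design_barcodes(20, length=8, min_dist=4, seed=11)
        assert len(bset.barcodes) == 20
        assert bset.min_pairwise_distance() >= 4
        assert all(simulate._max_homopolymer(b) <= 3 for b in bset.barcodes)

    def test_deterministic_given_seed(self):
        assert design_barcodes(6, seed=3).barcodes == design_barcodes(6, seed=3).barcodes

    def test_single_barcode_vacuously_valid(self):
        bset = design_barcodes(1, seed=0)
        assert len(bset.barcodes) == 1 and len(bset.barcodes[0]) == 8

    def test_full_distance_pair(self):
        bset = design_barcodes(2, length=8, min_dist=8, seed=1)
        assert io.hamming(*bset.barcodes) == 8

    def test_infeasible_request_raises(self):
        # at length 4 and distance 4 at most 4 codes exist
        with pytest.raises(CapacityError):
            design_barcodes(10, length=4, min_dist=4, seed=0, max_attempts=5000)


class TestSimulateFiber:
    def test_deterministic_tiling_at_zero_sd(self, rng):
        spec = FiberTypeSpec("r", "regular", nrl_mean=185.0, nrl_sd=0.0,
                             linker_accessible_prob=1.0)
        _, truth = simulate_fiber(spec, 2000, NoiseModel(), rng)
        starts = np.array([s for s, _ in truth.nucleosomes])
        assert np.all(np.diff(starts) == 185)

    def test_protected_fraction_matches_duty_cycle(self):
        # mean protected fraction over many fibers ~ 147/NRL
        rng = np.random.default_rng(77)
        spec = FiberTypeSpec("r", "regular", nrl_mean=185.0, nrl_sd=5.0)
        fracs = []
        for _ in range(500):
            _, truth = simulate_fiber(spec, 5000, NoiseModel(), rng)
            fracs.append(sum(e - s for s, e in truth.nucleosomes) / 5000)
        assert abs(np.mean(fracs) - 147 / 185) < 0.02

    def test_noiseless_probabilities_reproduce_truth(self, rng):
        noise = NoiseModel(p_meth_accessible=1.0, p_meth_footprint=0.0,
                           prob_dispersion=np.inf)
        fiber, truth = simulate_fiber(
            FiberTypeSpec("r", "regular", nrl_mean=185.0), 3000, noise, rng
        )
        bounds = np.array(truth.protected_intervals).ravel()
        inside = (np.searchsorted(bounds, fiber.a_positions, side="right") % 2).astype(bool)
        assert np.all(fiber.m6da_prob[inside] == 0.0)
        assert np.all(fiber.m6da_prob[~inside] == 1.0)

    def test_emission_means_recovered_by_truth_stratification(self):
        rng = np.random.default_rng(5)
        noise = NoiseModel()
        acc, prot = [], []
        for _ in range(50):
            fiber, truth = simulate_fiber(
                FiberTypeSpec("r", "regular", nrl_mean=185.0), 4000, noise, rng
            )
            bounds = np.array(truth.protected_intervals).ravel()
            inside = (np.searchsorted(bounds, fiber.a_positions, side="right") % 2).astype(bool)
            acc.extend(fiber.m6da_prob[~inside])
            prot.extend(fiber.m6da_prob[inside])
        for sample, mean in ((acc, noise.p_meth_accessible), (prot, noise.p_meth_footprint)):
            se = np.std(sample) / np.sqrt(len(sample))
            assert abs(np.mean(sample) - mean) < 3 * se + 1e-3

    def test_hyperaccessible_mostly_nucleosome_free(self, rng):
        spec = FiberTypeSpec("ha", "hyperaccessible")
        for _ in range(20):
            _, truth = simulate_fiber(spec, 5000, NoiseModel(), rng)
            assert sum(e - s for s, e in truth.nucleosomes) <= 0.2 * 5000

    def test_ctcf_bound_plants_central_footprint(self, rng):
        spec = FiberTypeSpec("b", "ctcf_bound", nrl_mean=185.0, ctcf_footprint_len=45)
        _, truth = simulate_fiber(spec, 2000, NoiseModel(), rng)
        assert truth.ctcf_interval == (1000 - 22, 1000 - 22 + 45)
        assert all(e <= truth.ctcf_interval[0] or s >= truth.ctcf_interval[1]
                   for s, e in truth.nucleosomes)

    def test_truth_intervals_disjoint_and_in_bounds(self, rng):
        for kind in ("regular", "irregular", "hyperaccessible", "ctcf_bound"):
            spec = FiberTypeSpec("x", kind, nrl_mean=200.0)
            _, truth = simulate_fiber(spec, 4000, NoiseModel(), rng)
            iv = truth.protected_intervals
            assert all(0 <= s < e <= 4000 for s, e in iv)
            assert all(a[1] <= b[0] for a, b in zip(iv, iv[1:]))


class TestTagmentation:
    def _parents(self, rng, mode_spec=None, n=20, length=20_000):
        spec = mode_spec or FiberTypeSpec("r", "regular", nrl_mean=185.0)
        return [
            simulate_fiber(spec, length, NoiseModel(), rng, molecule_id=f"p{i}")
            for i in range(n)
        ]

    def test_in_situ_never_inserts_into_protected(self):
        rng = np.random.default_rng(8)
        parents = self._parents(rng)
        bc = design_barcodes(4, seed=0)
        simulate_tagmentation(parents, "in_situ", 1.0, bc, rng)
        for _, truth in parents:
            bounds = np.array(truth.protected_intervals).ravel()
            sites = np.array(truth.insertion_sites)
            if len(sites):
                assert np.sum(np.searchsorted(bounds, sites, side="right") % 2) == 0

    def test_ex_situ_sites_uniform_by_ks(self):
        rng = np.random.default_rng(9)
        parents = self._parents(rng, n=30, length=50_000)
        bc = design_barcodes(4, seed=0)
        simulate_tagmentation(parents, "ex_situ", 0.5, bc, rng)
        rel = np.concatenate(
            [np.array(t.insertion_sites) / (f.length_nt - DUPLICATION_LEN)
             for f, t in parents if t.insertion_sites]
        )
        assert kstest(rel, "uniform").pvalue > 0.01

    def test_adjacent_fragments_share_nine_nt_junction(self):
        rng = np.random.default_rng(10)
        parents = self._parents(rng, n=10)
        bc = design_barcodes(4, seed=0)
        frags, truths = simulate_tagmentation(
            parents, "ex_situ", 1.0, bc, rng, min_fragment_len=1
        )
        by_source = {}
        for t in truths:
            by_source.setdefault(t.source_molecule_id, []).append(t)
        checked = 0
        frag_by_id = {f.molecule_id: f for f in frags}
        for source, ts in by_source.items():
            ts.sort(key=lambda t: t.span)
            for a, b in zip(ts, ts[1:]):
                if a.span[1] - DUPLICATION_LEN != b.span[0]:
                    continue  # an intervening fragment was length-filtered
                assert a.span[1] - b.span[0] == DUPLICATION_LEN
                fa, fb = frag_by_id[a.fragment_id], frag_by_id[b.fragment_id]
                assert fa.sequence[-DUPLICATION_LEN:] == fb.sequence[:DUPLICATION_LEN]
                checked += 1
        assert checked > 10

    def test_zero_density_yields_no_fragments(self, rng):
        parents = self._parents(rng, n=3)
        bc = design_barcodes(2, seed=0)
        frags, _ = simulate_tagmentation(parents, "in_situ", 0.0, bc, rng)
        assert frags == []

    def test_fragments_map_within_source_fiber(self):
        rng = np.random.default_rng(12)
        parents = self._parents(rng, n=10)
        bc = design_barcodes(4, seed=0)
        frags, truths = simulate_tagmentation(parents, "in_situ", 1.0, bc, rng)
        parent_by_id = {f.molecule_id: f for f, _ in parents}
        for frag, t in zip(frags, truths):
            parent = parent_by_id[t.source_molecule_id]
            assert parent.start <= frag.start < frag.end <= parent.end
            assert frag.length_nt >= 500


class TestSimulateDataset:
    def test_empty_dataset_is_valid(self, tmp_path):
        cfg = SimConfig(seed=1, n_fibers=0)
        ds = simulate_dataset(cfg, tmp_path)
        assert ds.fragments == []
        assert io.read_fibers(ds.paths["alignment"]) == []
        assert io.read_bed(ds.paths["footprints"]) == []

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=9, n_fibers=8, fiber_length=8000, tn5_density=1.0,
                        min_fragment_len=300)
        d1 = simulate_dataset(cfg, tmp_path / "a")
        d2 = simulate_dataset(cfg, tmp_path / "b")
        for key in d1.paths:
            assert simulate.file_digest(d1.paths[key]) == simulate.file_digest(d2.paths[key])

    def test_alignment_roundtrips_through_standard_reader(self, tmp_path):
        cfg = SimConfig(seed=4, n_fibers=6, fiber_length=10_000, tn5_density=1.0,
                        min_fragment_len=400)
        ds = simulate_dataset(cfg, tmp_path)
        back = io.read_fibers(ds.paths["alignment"])
        assert len(back) == len(ds.fragments)
        for orig, parsed in zip(ds.fragments, back):
            assert parsed.molecule_id == orig.molecule_id
            assert np.array_equal(parsed.a_positions, orig.a_positions)
            assert np.max(np.abs(parsed.m6da_prob - orig.m6da_prob), initial=0) < 1 / 256

    def test_in_situ_fragment_lengths_show_oligonucleosomal_banding(self):
        # fragment sizes concentrate at multiples of the repeat length
        rng = np.random.default_rng(30)
        spec = FiberTypeSpec("r", "regular", nrl_mean=185.0, nrl_sd=3.0,
                             linker_accessible_prob=1.0)
        parents = [
            simulate_fiber(spec, 30_000, NoiseModel(), rng, molecule_id=f"p{i}")
            for i in range(60)
        ]
        bc = design_barcodes(4, seed=0)
        frags, _ = simulate_tagmentation(parents, "in_situ", 2.0, bc, rng,
                                         min_fragment_len=1)
        sizes = np.array([f.length_nt for f in frags])
        # phase of each size within one repeat: should cluster near the duplication
        # offset rather than spread uniformly
        phase = (sizes - DUPLICATION_LEN) % 185
        centered = np.minimum(phase, 185 - phase)
        assert np.mean(centered < 46) > 0.6  # far above the uniform expectation of 0.5
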