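"""Planted-truth simulator: genomes, fragmentation, link statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from ltscaf import simulate as sim
from ltscaf.link_clustering import (cluster_pair, compute_paired_distances,
                                    compute_tgs_distances)
from ltscaf.model_io import Library
from ltscaf.orientation import orientation_supported
from ltscaf.preprocess import InsertModel


class TestMakeGenome:
    def test_length_and_alphabet(self):
        g = sim.make_genome(10_000, seed=1)
        assert len(g) == 10_000
        assert set(g) == set("ACGT")

    def test_repeat_block_exact_copies(self):
        g = sim.make_genome(5000, repeats=[(600, 4, 1000)], seed=2)
        unit = g[1000:1600]
        assert g[1000:3400] == unit * 4

    def test_deterministic_per_seed(self):
        assert sim.make_genome(2000, seed=7) == sim.make_genome(2000, seed=7)
        assert sim.make_genome(2000, seed=7) != sim.make_genome(2000, seed=8)


class TestFragment:
    def test_even_fragmentation_arithmetic(self):
        g = sim.make_genome(200_000, seed=3)
        contigs, truth = sim.fragment_evenly(g, 40, gap_length=500)
        assert len(truth) == 40
        starts = truth["start"].to_numpy()
        span = truth["end"][0] - truth["start"][0]
        assert np.all(np.diff(starts) == span + 500)

    def test_reverse_complement_recorded(self):
        g = sim.make_genome(10_000, seed=4)
        contigs, truth = sim.fragment(
            g, [("a", 0, 4000, 1), ("b", 5000, 9000, -1)])
        assert truth.set_index("contig")["orient"].to_dict() == \
            {"a": 1, "b": -1}
        from ltscaf.model_io import revcomp
        assert contigs["b"].sequence == revcomp(g[5000:9000])

    def test_dropped_interval_absent_from_contigs(self):
        g = sim.make_genome(10_000, repeats=[(600, 4, 4000)], seed=5)
        contigs, truth = sim.fragment(
            g, [("a", 0, 4000, 1), ("b", 4600, 10_000, 1)])
        # the first repeat copy [4000, 4600) is in no contig
        total = sum(c.length for c in contigs.values())
        assert total == 10_000 - 600


def _distances(bundle_paired, truth, libraries, sigma_models):
    lengths = dict(zip(truth["contig"],
                       (truth["end"] - truth["start"]).astype(int)))
    D = {c: 1 for c in truth["contig"]}
    sup = orientation_supported(bundle_paired, D)
    return compute_paired_distances(sup, D, lengths, sigma_models, libraries)


class TestSimulatePairedLinks:
    def planted(self, seed=0, orient_b=1, kind="MP", coverage=30):
        g_len = 12_000
        truth = pd.DataFrame(
            [("a", 0, 3000, 1), ("b", 3300, 12_000, orient_b)],
            columns=sim.TRUTH_COLUMNS)
        lib = Library("x", kind, 3000, 100, read_length=100)
        paired, ins = sim.simulate_paired_links(g_len, truth, lib, coverage,
                                                seed=seed)
        return truth, lib, paired, ins

    @pytest.mark.parametrize("orient_b", [1, -1])
    @pytest.mark.parametrize("kind", ["MP", "PE"])
    def test_planted_offset_recovered(self, orient_b, kind):
        truth, lib, paired, _ = self.planted(orient_b=orient_b, kind=kind)
        assert len(paired) > 100
        # relative orientation reflects the planted strands
        assert (paired["d"] == orient_b).all()
        D = {"a": 1, "b": orient_b}
        lengths = {"a": 3000, "b": 8700}
        F = compute_paired_distances(
            orientation_supported(paired, D), D, lengths,
            {"x": InsertModel("x", 3000, 100, 0, True)}, {"x": lib})
        assert np.median(F["F"]) == pytest.approx(
            3300, abs=4 * 100 / np.sqrt(len(F)))

    def test_same_contig_pairs_become_insert_obs(self):
        truth, lib, paired, ins = self.planted()
        assert len(ins) > 0
        assert np.median(ins["insert"]) == pytest.approx(3000, abs=30)

    def test_insert_normality_ks(self):
        # clean-pair linking distances ~ N(offset, sigma^2) (alpha = 0.01)
        truth, lib, paired, _ = self.planted(coverage=160)
        D = {"a": 1, "b": 1}
        F = compute_paired_distances(
            orientation_supported(paired, D), D, {"a": 3000, "b": 8700},
            {"x": InsertModel("x", 3000, 100, 0, True)}, {"x": lib})
        x = F["F"].to_numpy(dtype=float)[:2000]
        assert len(x) == 2000
        stat = kstest((x - 3300.0) / 100.0, "norm")
        assert stat.pvalue > 0.01

    def test_contamination_creates_second_mode(self):
        g_len = 12_000
        truth = pd.DataFrame([("a", 0, 5950, 1), ("b", 6000, 12_000, 1)],
                             columns=sim.TRUTH_COLUMNS)
        lib = Library("x", "MP", 3000, 300, read_length=100)
        paired, _ = sim.simulate_paired_links(
            g_len, truth, lib, coverage=120, contamination_fraction=0.4,
            seed=9)
        D = {"a": 1, "b": 1}
        F = compute_paired_distances(
            orientation_supported(paired, D), D, {"a": 5950, "b": 6000},
            {"x": InsertModel("x", 3000, 300, 0, True)}, {"x": lib})
        clusters = cluster_pair(F["F"].to_numpy(dtype=float), 300)
        assert len(clusters) == 2
        meds = sorted(float(np.median(F["F"].to_numpy()[c]))
                      for c in clusters)
        # contaminant pairs computed with the nominal 3000 bp insert sit
        # ~2700 bp above the true mode
        assert meds[1] - meds[0] == pytest.approx(2700, abs=150)

    def test_deterministic_per_seed(self):
        _, _, p1, _ = self.planted(seed=5)
        _, _, p2, _ = self.planted(seed=5)
        pd.testing.assert_frame_equal(p1, p2)

    def test_zero_coverage_empty(self):
        truth = pd.DataFrame([("a", 0, 3000, 1)], columns=sim.TRUTH_COLUMNS)
        lib = Library("x", "MP", 3000, 100, read_length=100)
        paired, ins = sim.simulate_paired_links(3000, truth, lib, 0, seed=1)
        assert len(paired) == 0 and len(ins) == 0


class TestSimulateTgsLinks:
    def test_planted_distance_exact(self):
        truth = pd.DataFrame([("a", 0, 2000, 1), ("b", 2900, 9000, 1)],
                             columns=sim.TRUTH_COLUMNS)
        lib = Library("t", "TGS")
        tgs = sim.simulate_tgs_links(9000, truth, lib, coverage=10,
                                     read_length_mean=4000, seed=3)
        assert len(tgs) > 0
        D = {"a": 1, "b": 1}
        F = compute_tgs_distances(orientation_supported(tgs, D), D,
                                  {"a": 2000, "b": 6100})
        assert (F["F"] == 2900).all()

    def test_read_inside_one_contig_makes_no_link(self):
        truth = pd.DataFrame([("a", 0, 9000, 1)], columns=sim.TRUTH_COLUMNS)
        tgs = sim.simulate_tgs_links(9000, truth, Library("t", "TGS"),
                                     coverage=10, read_length_mean=3000,
                                     seed=4)
        assert len(tgs) == 0

    def test_zero_coverage_empty(self):
        truth = pd.DataFrame([("a", 0, 9000, 1)], columns=sim.TRUTH_COLUMNS)
        tgs = sim.simulate_tgs_links(9000, truth, Library("t", "TGS"),
                                     coverage=0, seed=4)
        assert len(tgs) == 0


class TestMismap:
    def test_false_modes_offset_by_repeat_units(self):
        b = sim.tandem_repeat_scenario(seed=3)
        lengths = {c.id: c.length for c in b.contigs.values()}
        D = {c: 1 for c in b.contigs}
        models = {lid: InsertModel(lid, lib.insert_mean, lib.insert_sd, 0,
                                   True) for lid, lib in b.libraries.items()}
        F = compute_paired_distances(
            orientation_supported(b.paired, D), D, lengths, models,
            b.libraries)
        bc = F[(F["i"] == "c13") & (F["j"] == "c14") & (F["lib"] == "mp1")]
        clusters = cluster_pair(bc["F"].to_numpy(dtype=float), 150)
        meds = sorted(float(np.median(bc["F"].to_numpy()[c]))
                      for c in clusters)
        # true mode plus one false mode per missing repeat copy
        assert len(meds) == 4
        diffs = np.diff(meds)
        # successive false modes sit one repeat unit (600 bp) apart
        assert np.allclose(diffs, 600, atol=60)

    def test_mismap_disabled_drops_repeat_reads(self):
        clean = sim.tandem_repeat_scenario(seed=3, mismap_rate=0.0)
        noisy = sim.tandem_repeat_scenario(seed=3, mismap_rate=1.0)
        assert len(noisy.paired) > len(clean.paired)
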