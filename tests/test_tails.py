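"""Tail-length analytics: means, differences, metagenes, phasing, binning."""

import numpy as np
import pandas as pd
import pytest

from occutail.simulate import SimConfig, generate
from occutail.tails import (
    bin_occupancy_by_tail,
    detect_phasing_peaks,
    mean_tails,
    metagene_distribution,
    phasing_profile,
    site_tail_change,
    tail_diff,
    window_depletion,
)
from oracles import pairwise_diff_freqs_naive


def table(gene_tails: dict[str, list[int]]) -> pd.DataFrame:
    rows = [(g, t) for g, tails in gene_tails.items() for t in tails]
    return pd.DataFrame(rows, columns=["gene_id", "tail_length"])


class TestMeanTails:
    def test_tag_threshold_excludes(self):
        t = table({"g1": [50] * 99, "g2": [60] * 100})
        stats, excluded = mean_tails(t, min_tags=100)
        assert list(stats["gene_id"]) == ["g2"]
        assert list(excluded["gene_id"]) == ["g1"]

    def test_mean_with_low_threshold(self):
        stats, _ = mean_tails(table({"g1": [10, 20, 30]}), min_tags=1)
        assert stats.loc[0, "mean_tail"] == pytest.approx(20.0)

    def test_all_below_threshold(self):
        stats, excluded = mean_tails(table({"g1": [10], "g2": [20]}), min_tags=5)
        assert stats.empty
        assert len(excluded) == 2


class TestTailDiff:
    @staticmethod
    def _stats(means: dict[str, float]) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(means), "mean_tail": list(means.values()), "n_tags": 100}
        )

    def test_identical_samples(self):
        s = self._stats({"g1": 70.0, "g2": 90.0, "g3": 50.0})
        per_gene, summary = tail_diff(s, s)
        assert (per_gene["difference"] == 0).all()
        assert summary["fraction_shorter"] == 0.0

    def test_two_gene_median(self):
        bound = self._stats({"g1": 60.0, "g2": 74.0})
        total = self._stats({"g1": 70.0, "g2": 70.0})
        _, summary = tail_diff(bound, total)
        assert summary["median"] == pytest.approx(-3.0)

    def test_quartiles_match_sorted_list_oracle(self):
        rng = np.random.default_rng(8)
        diffs = rng.normal(-20, 10, size=57)
        bound = self._stats({f"g{i}": 100.0 + d for i, d in enumerate(diffs)})
        total = self._stats({f"g{i}": 100.0 for i in range(57)})
        _, summary = tail_diff(bound, total)
        assert summary["median"] == pytest.approx(np.percentile(diffs, 50))
        assert summary["q1"] == pytest.approx(np.percentile(diffs, 25))
        assert summary["q3"] == pytest.approx(np.percentile(diffs, 75))

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            tail_diff(self._stats({"g1": 1.0}), self._stats({"g2": 1.0}))


class TestMetagene:
    def test_single_gene_two_bins(self):
        hist = metagene_distribution(table({"g1": [10, 10, 30, 30]}), min_tags=1)
        freq = hist.set_index("bin_start")["frequency"]
        assert freq.loc[10] == pytest.approx(0.5)
        assert freq.loc[30] == pytest.approx(0.5)
        assert hist["frequency"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_equal_gene_weighting_ignores_depth(self):
        t = table({"g1": [10] * 1000, "g2": [30] * 10})
        hist = metagene_distribution(t, min_tags=1)
        freq = hist.set_index("bin_start")["frequency"]
        assert freq.loc[10] == pytest.approx(0.5)
        assert freq.loc[30] == pytest.approx(0.5)

    def test_tag_weighting_option(self):
        t = table({"g1": [10] * 30, "g2": [30] * 10})
        hist = metagene_distribution(t, min_tags=1, per_gene_weighting=False)
        freq = hist.set_index("bin_start")["frequency"]
        assert freq.loc[10] == pytest.approx(0.75)

    def test_short_tail_depletion_detected(self):
        """The bound-fraction short-tail down-weighting shows up as a depleted
        below-50-nt fraction in a paired across-gene comparison."""
        cfg = SimConfig(
            n_genes=120,
            seed=9,
            target_fraction=0.2,
            n_random_sets=5,
            tail_mu_range=(40.0, 90.0),
        )
        sim = generate(cfg)
        res = window_depletion(
            sim.tails["PABP_mock"], sim.tails["total_mock"], window=(0, 50), min_tags=50
        )
        assert res["median_fraction_a"] < res["median_fraction_b"]
        assert res["p_value"] < 0.01


class TestSiteTailChange:
    @staticmethod
    def _stats(means):
        return pd.DataFrame({"gene_id": list(means), "mean_tail": list(means.values()), "n_tags": 100})

    def test_null(self):
        rng = np.random.default_rng(4)
        mock = {f"g{i}": 80 + rng.normal() for i in range(200)}
        mirna = {g: v + rng.normal() for g, v in mock.items()}
        genes = list(mock)
        res = site_tail_change(self._stats(mock), self._stats(mirna), genes[:100], genes[100:])
        assert abs(res["median_difference"]) < 0.5
        # null p-values fluctuate uniformly; assert no strong false positive
        assert res["ks_p"] > 0.01

    def test_shift_detected(self):
        rng = np.random.default_rng(4)
        mock = {f"g{i}": 80 + rng.normal() for i in range(200)}
        mirna = {g: v - (4.0 if int(g[1:]) < 100 else 0.0) + rng.normal() for g, v in mock.items()}
        genes = list(mock)
        res = site_tail_change(self._stats(mock), self._stats(mirna), genes[:100], genes[100:])
        assert res["median_difference"] == pytest.approx(-4.0, abs=1.0)
        assert res["ks_p"] < 0.05

    def test_empty_site_set_rejected(self):
        s = self._stats({"g1": 80.0})
        with pytest.raises(ValueError, match="site genes"):
            site_tail_change(s, s, [], ["g1"])


class TestPhasing:
    def test_hand_enumerated_example(self):
        prof = phasing_profile(table({"g1": [10, 10, 36, 36]}), n_genes=1, min_tags=1, max_diff=30)
        avg = prof[prof["gene_id"] == "AVERAGE"].set_index("difference")["frequency"]
        assert avg.loc[0] == pytest.approx(2 / 6)
        assert avg.loc[26] == pytest.approx(4 / 6)
        assert avg.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(12)
        genes = {f"g{i}": list(rng.integers(0, 200, size=int(rng.integers(5, 50)))) for i in range(12)}
        prof = phasing_profile(table(genes), n_genes=12, min_tags=1, max_diff=60, seed=0)
        for g, tl in genes.items():
            expected = pairwise_diff_freqs_naive(tl, 60)
            got = prof[prof["gene_id"] == g].set_index("difference")["frequency"]
            for d in range(61):
                assert got.loc[d] == pytest.approx(expected[d]), (g, d)

    def test_deterministic_sampling_under_seed(self):
        rng = np.random.default_rng(13)
        genes = {f"g{i}": list(rng.integers(0, 100, size=20)) for i in range(30)}
        t = table(genes)
        p1 = phasing_profile(t, n_genes=10, min_tags=1, seed=5)
        p2 = phasing_profile(t, n_genes=10, min_tags=1, seed=5)
        pd.testing.assert_frame_equal(p1, p2)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="pass min_tags"):
            phasing_profile(table({"g1": [1, 2, 3]}), n_genes=5, min_tags=1)

    def test_period_generator_peaks_at_multiples(self):
        cfg = SimConfig(
            n_genes=60,
            seed=21,
            target_fraction=0.4,
            n_random_sets=2,
            phasing_period=26,
            phasing_jitter_sd=0.0,
            tags_per_gene_range=(100, 150),
        )
        sim = generate(cfg)
        prof = phasing_profile(sim.tails["total_mock"], n_genes=40, min_tags=100, seed=1)
        # every within-gene pairwise difference is a multiple of the period
        per_gene = prof[prof["gene_id"] != "AVERAGE"]
        nonzero = per_gene[per_gene["frequency"] > 0]
        assert (nonzero["difference"] % 26 == 0).all()
        peaks = detect_phasing_peaks(prof)
        assert 26 in peaks and 52 in peaks

    def test_null_generator_shows_no_peaks(self):
        cfg = SimConfig(
            n_genes=60, seed=22, target_fraction=0.4, n_random_sets=2,
            tags_per_gene_range=(150, 250),
        )
        sim = generate(cfg)
        prof = phasing_profile(sim.tails["total_mock"], n_genes=40, min_tags=100, seed=1)
        assert detect_phasing_peaks(prof) == []


class TestBinOccupancy:
    def test_footprint_bin_assignment(self):
        occ = pd.DataFrame({"gene_id": ["g1"], "occupancy": [1.0]})
        tails = pd.DataFrame({"gene_id": ["g1"], "mean_tail": [30.0], "n_tags": [100]})
        summaries, _, _ = bin_occupancy_by_tail(occ, tails, footprint=26)
        assert summaries.loc[0, "bin"] == "[25,50)"

    def test_null_coupling_no_monotone_trend(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(600)]
        occ = pd.DataFrame({"gene_id": genes, "occupancy": rng.lognormal(0, 1, 600)})
        tails = pd.DataFrame(
            {"gene_id": genes, "mean_tail": rng.uniform(10, 140, 600), "n_tags": 100}
        )
        _, pairwise, overall = bin_occupancy_by_tail(occ, tails)
        assert abs(overall["spearman_rho"]) < 0.1

    def test_positive_coupling_gives_monotone_bins(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(600)]
        tails_v = rng.uniform(10, 140, 600)
        occ_v = 2.0 ** (0.02 * tails_v + rng.normal(0, 0.3, 600))
        occ = pd.DataFrame({"gene_id": genes, "occupancy": occ_v})
        tails = pd.DataFrame({"gene_id": genes, "mean_tail": tails_v, "n_tags": 100})
        summaries, _, overall = bin_occupancy_by_tail(occ, tails)
        medians = summaries["median"].to_numpy()
        assert (np.diff(medians) > 0).all()
        assert overall["spearman_rho"] > 0.5
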