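"""Expression filtering, relative occupancy and NanoString normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from occutail.occupancy import (
    filter_expressed,
    nanostring_normalize,
    nanostring_occupancy,
    occupancy_table,
    relative_occupancy,
)
from occutail.simulate import SimConfig, generate


def tidy(values: dict) -> pd.DataFrame:
    """values: {(gene, condition, fraction): value} for one protein."""
    rows = [
        {"gene_id": g, "protein": "PABP", "condition": c, "fraction": f, "value": v}
        for (g, c, f), v in values.items()
    ]
    return pd.DataFrame(rows)


class TestFilter:
    def test_nonzero_suffices_outside_mock(self):
        expr = tidy(
            {
                ("g1", "mock", "input"): 5,
                ("g1", "mock", "IP"): 2,
                ("g1", "miR", "input"): 0.1,
                ("g1", "miR", "IP"): 0.1,
            }
        )
        kept = filter_expressed(expr, "PABP", mode="mirna_experiment")
        assert list(kept) == ["g1"]

    def test_mock_ip_below_one_dropped_in_both_modes(self):
        expr = tidy(
            {
                ("g1", "mock", "input"): 5,
                ("g1", "mock", "IP"): 0.9,
                ("g1", "miR", "input"): 3,
                ("g1", "miR", "IP"): 3,
            }
        )
        assert len(filter_expressed(expr, "PABP", mode="plain")) == 0
        assert len(filter_expressed(expr, "PABP", mode="mirna_experiment")) == 0

    def test_zero_in_other_library_dropped(self):
        expr = tidy(
            {
                ("g1", "mock", "input"): 5,
                ("g1", "mock", "IP"): 2,
                ("g1", "miR", "input"): 0.0,
                ("g1", "miR", "IP"): 1.0,
            }
        )
        assert len(filter_expressed(expr, "PABP", mode="mirna_experiment")) == 0

    def test_missing_library_named_in_error(self):
        expr = tidy({("g1", "mock", "input"): 5})
        with pytest.raises(KeyError, match="IP"):
            filter_expressed(expr, "PABP", mode="plain")

    def test_filter_idempotent(self):
        rng = np.random.default_rng(3)
        expr = tidy(
            {
                (f"g{i}", c, f): float(v)
                for i in range(30)
                for (c, f), v in zip(
                    [("mock", "input"), ("mock", "IP"), ("miR", "input"), ("miR", "IP")],
                    rng.lognormal(0.5, 1.2, size=4),
                )
            }
        )
        kept = filter_expressed(expr, "PABP", mode="mirna_experiment")
        again = filter_expressed(
            expr[expr["gene_id"].isin(kept)], "PABP", mode="mirna_experiment"
        )
        assert list(kept) == list(again)


class TestRelativeOccupancy:
    @staticmethod
    def _expr(ratios):
        return tidy(
            {
                **{(f"g{i}", "mock", "input"): 10.0 for i in range(len(ratios))},
                **{(f"g{i}", "mock", "IP"): 10.0 * r for i, r in enumerate(ratios)},
            }
        )

    def test_median_division(self):
        expr = self._expr([1, 2, 4])
        occ = relative_occupancy(expr, pd.Index(["g0", "g1", "g2"]), "PABP", "mock")
        assert occ["occupancy"].tolist() == pytest.approx([0.5, 1.0, 2.0])

    def test_identical_ratios_center_to_one(self):
        expr = self._expr([3, 3, 3])
        occ = relative_occupancy(expr, pd.Index(["g0", "g1", "g2"]), "PABP", "mock")
        assert occ["occupancy"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_even_count_median_is_mean_of_central_two(self):
        expr = self._expr([1, 2, 3, 4])
        occ = relative_occupancy(expr, pd.Index([f"g{i}" for i in range(4)]), "PABP", "mock")
        assert occ["occupancy"].tolist() == pytest.approx([0.4, 0.8, 1.2, 1.6])

    def test_post_centering_median_is_exactly_one(self):
        rng = np.random.default_rng(5)
        ratios = rng.lognormal(0, 1, size=31)
        expr = self._expr(ratios)
        occ = relative_occupancy(
            expr, pd.Index([f"g{i}" for i in range(31)]), "PABP", "mock"
        )
        assert np.median(occ["occupancy"]) == 1.0


class TestNanoString:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"s1": [100, 200, 50], "s2": [100, 200, 50]}, index=["r1", "r2", "g1"])
        normalized, factors = nanostring_normalize(counts, ["r1", "r2"])
        assert factors.tolist() == pytest.approx([1.0, 1.0])
        pd.testing.assert_frame_equal(normalized, counts.astype(float))

    def test_doubled_sample_rescaled_to_match(self):
        counts = pd.DataFrame({"s1": [100, 200, 50], "s2": [200, 400, 100]}, index=["r1", "r2", "g1"])
        normalized, factors = nanostring_normalize(counts, ["r1", "r2"])
        assert factors["s2"] == pytest.approx(factors["s1"] / 2)
        assert normalized["s1"].tolist() == pytest.approx(normalized["s2"].tolist())

    def test_single_sample_self_normalizes(self):
        counts = pd.DataFrame({"s1": [100, 50]}, index=["r1", "g1"])
        _, factors = nanostring_normalize(counts, ["r1"])
        assert factors["s1"] == pytest.approx(1.0)

    def test_zero_reference_count_rejected(self):
        counts = pd.DataFrame({"s1": [0, 50]}, index=["r1", "g1"])
        with pytest.raises(ValueError, match="zero reference"):
            nanostring_normalize(counts, ["r1"])

    def test_occupancy_identity_when_ip_equals_input(self):
        s = pd.Series([10.0, 20.0, 30.0], index=["a", "b", "c"])
        assert nanostring_occupancy(s, s).tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_doubled_ip_gene_stands_out(self):
        inp = pd.Series([10.0, 10.0, 10.0], index=["a", "b", "c"])
        ip = pd.Series([20.0, 10.0, 10.0], index=["a", "b", "c"])
        occ = nanostring_occupancy(ip, inp)
        assert occ["a"] == pytest.approx(2 * occ["b"])

    def test_gene_missing_from_input_dropped(self):
        inp = pd.Series([10.0, 10.0], index=["a", "b"])
        ip = pd.Series([10.0, 10.0, 10.0], index=["a", "b", "c"])
        assert list(nanostring_occupancy(ip, inp).index) == ["a", "b"]

    def test_scale_factor_recovery_in_simulation(self, small_sim):
        """Per-sample scale factors injected by the generator are undone to
        within Poisson noise by reference-gene normalization."""
        cfg = small_sim.config
        counts = small_sim.nanostring["PABP"]
        normalized, factors = nanostring_normalize(counts, list(cfg.reference_genes))
        truth_scale = small_sim.truth.nanostring_scale["PABP"]
        implied = 1.0 / np.array([truth_scale[s] for s in counts.columns])
        ratio = factors.to_numpy() * np.array([truth_scale[s] for s in counts.columns])
        # all samples recover the same pre-scale baseline (constant ratio)
        assert np.std(ratio) / np.mean(ratio) < 0.02
        assert spearmanr(factors.to_numpy(), implied)[0] > 0.99


class TestClosedLoop:
    def test_zero_noise_recovers_truth_up_to_centering(self):
        cfg = SimConfig(
            n_genes=120, seed=3, target_fraction=0.2, expression_noise_sd=0.0, n_random_sets=5
        )
        sim = generate(cfg)
        occ = occupancy_table(sim.expression, mode="mirna_experiment")
        sub = occ[(occ["protein"] == "PABP") & (occ["condition"] == "mock")]
        est = sub.set_index("gene_id")["occupancy"]
        truth = sim.truth.occupancy["PABP"].loc[est.index]
        ratio = est / truth
        assert np.max(np.abs(ratio / ratio.median() - 1)) < 1e-9

    def test_default_noise_rank_recovery(self, small_sim):
        occ = occupancy_table(small_sim.expression, mode="mirna_experiment")
        for protein in ("PABP", "AGO2"):
            sub = occ[(occ["protein"] == protein) & (occ["condition"] == "mock")]
            est = sub.set_index("gene_id")["occupancy"]
            truth = small_sim.truth.occupancy[protein].loc[est.index]
            assert spearmanr(est, truth)[0] >= 0.95
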