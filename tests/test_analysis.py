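"""Cross-over detection, MST self-consistency, extrapolation."""

from dataclasses import replace

import numpy as np
import pytest

import sccosol as sc
from sccosol.analysis import NONE_ABOVE, NONE_BELOW, GridError


def _grid_dataset(y_of_TP):
    recs = tuple(sc.SolubilityRecord(T=t, P=p, y=y_of_TP(t, p))
                 for t in (308.0, 318.0, 328.0, 338.0)
                 for p in (12.0, 20.0, 28.0, 36.0))
    return sc.SolubilityDataset("synthetic solute", 228.21, recs)


class TestCrossover:
    def test_decitabine_crossover_at_16_mpa(self, decitabine):
        rep = sc.crossover_pressure(decitabine)
        assert rep.crossover_P == 16.0
        t = rep.per_pressure_trend
        assert t[12.0] == "strictly_decreasing"
        assert t[16.0] == "non_monotonic"
        assert all(t[p] == "strictly_increasing"
                   for p in (20.0, 24.0, 28.0, 32.0, 36.0, 40.0))

    def test_uniform_trends_give_sentinels(self):
        inc = _grid_dataset(lambda t, p: 1e-5 * (t - 300) * p)
        dec = _grid_dataset(lambda t, p: 1e-5 * (350 - t) * p)
        assert sc.crossover_pressure(inc).crossover_P == NONE_BELOW
        assert sc.crossover_pressure(dec).crossover_P == NONE_ABOVE

    def test_invariance_to_row_order_and_scale(self, decitabine):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(decitabine.records))
        shuffled = replace(decitabine,
                           records=tuple(decitabine.records[i]
                                         for i in perm))
        scaled = replace(decitabine, records=tuple(
            replace(r, y=r.y * 0.37, u_y=None)
            for r in decitabine.records))
        assert sc.crossover_pressure(shuffled).crossover_P == 16.0
        assert sc.crossover_pressure(scaled).crossover_P == 16.0

    def test_incomplete_grid_reports_missing_cells(self, decitabine):
        holey = decitabine.subset(lambda t, p: not (t == 318 and p == 20))
        with pytest.raises(GridError, match=r"318.*20"):
            sc.crossover_pressure(holey)

    def test_model_based_crossover_near_grid_value(self, decitabine):
        """Bisection on fitted KJ isotherms lands near the grid answer."""
        res = sc.fit("kj", decitabine, "reference", "relative")
        p_cross = sc.model_crossover_pressure(
            "kj", res.params, "reference", 308.0, 338.0, 228.21)
        assert 12.0 < p_cross < 20.0


class TestSelfConsistency:
    def test_noiseless_mst_data_collapse(self, noiseless):
        cfg, ds = noiseless["mst"]
        mst_fit = sc.fit("mst", ds, cfg.provider_id)
        rep = sc.self_consistency(mst_fit, ds, cfg.provider_id)
        assert rep.r_squared == pytest.approx(1.0, abs=1e-9)
        # the recovered line is the ground-truth (a, b)
        assert rep.line_fit[0] == pytest.approx(cfg.true_params.a, rel=1e-6)
        assert rep.line_fit[1] == pytest.approx(cfg.true_params.b, rel=1e-6)

    def test_decitabine_deviation_grows_with_temperature(self, decitabine):
        mst_fit = sc.fit("mst", decitabine, "reference")
        rep = sc.self_consistency(mst_fit, decitabine, "reference")
        assert 0.0 <= rep.r_squared <= 1.0
        assert max(rep.per_isotherm_mad, key=rep.per_isotherm_mad.get) \
            == 338.0

    def test_single_isotherm_is_degenerate(self, decitabine):
        one = decitabine.subset(lambda t, p: t == 318)
        mst_fit = sc.fit("mst", decitabine, "reference")
        with pytest.raises(ValueError, match="single isotherm"):
            sc.self_consistency(mst_fit, one, "reference")

    def test_collapse_degrades_with_noise(self):
        """Mean R^2 over seeds decreases as lognormal noise grows."""
        means = []
        for sigma in (0.02, 0.1, 0.3):
            r2 = []
            for seed in range(20):
                cfg = sc.SyntheticConfig(
                    model_id="mst",
                    true_params=sc.ModelParameters(-12000.0, 25.0, 3.6),
                    noise_sigma=sigma, seed=seed)
                ds = sc.generate(cfg)
                mst_fit = sc.fit("mst", ds, "reference")
                r2.append(sc.self_consistency(mst_fit, ds,
                                              "reference").r_squared)
            means.append(np.mean(r2))
        assert means[0] > means[1] > means[2]


class TestExtrapolation:
    def test_noiseless_holdout_is_exact(self, noiseless):
        for mid, (cfg, ds) in noiseless.items():
            err = sc.extrapolation_test(mid, ds, cfg.provider_id,
                                        lambda t, p: p == 40.0)
            assert err == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_split_equals_training_aard(self, decitabine):
        full = sc.fit("mst", decitabine, "reference").aard_percent
        assert sc.extrapolation_test(
            "mst", decitabine, "reference",
            lambda t, p: False) == pytest.approx(full, rel=1e-12)

    def test_decitabine_highest_pressure_holdout_finite(self, decitabine):
        err = sc.extrapolation_test("mst", decitabine, "reference",
                                    lambda t, p: p == 40.0)
        assert np.isfinite(err) and err > 0
        # regression snapshot for the packaged data
        assert err == pytest.approx(31.26, abs=0.5)
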