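"""Probit occurrence sampler, discrimination metrics and derived optima."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from aerospora import occupancy


class TestSchedule:
    def test_published_schedule_yields_1000_draws(self):
        sched = occupancy.published_schedule()
        assert sched.draws_per_chain == 250
        assert sched.total_draws == 1000

    def test_burnin_must_be_smaller(self):
        with pytest.raises(ValueError):
            occupancy.MCMCSchedule(2, 100, 100, 1)


class TestCommonSpecies:
    def test_inclusive_threshold(self):
        pres = pd.DataFrame(
            {"a": [True] * 49 + [False], "b": [True] * 50}, index=range(50)
        )
        pres = pd.concat([pres] * 1).head(50)
        out = occupancy.select_common_species(pres, 50)
        assert out == ["b"]

    def test_empty_table(self):
        assert occupancy.select_common_species(pd.DataFrame()) == []


class TestTjur:
    def test_perfect_prediction(self):
        assert occupancy.tjur_r2([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_constant_prediction_zero(self):
        assert occupancy.tjur_r2([1, 0], [0.5, 0.5]) == 0.0

    def test_hand_arithmetic(self):
        obs = [1, 1, 0, 0]
        pred = [0.8, 0.6, 0.3, 0.1]
        assert occupancy.tjur_r2(obs, pred) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            occupancy.tjur_r2([1, 1], [0.5, 0.6])


class TestAUC:
    def test_perfect_and_reversed(self):
        assert occupancy.auc([1, 1, 0], [0.9, 0.8, 0.1]) == 1.0
        assert occupancy.auc([1, 1, 0], [0.1, 0.2, 0.9]) == 0.0

    def test_hand_pair_count(self):
        # pairs: (.9>.5), (.9>.1), (.4<.5), (.4>.1) -> 3/4
        assert occupancy.auc([1, 0, 1, 0], [0.9, 0.5, 0.4, 0.1]) == pytest.approx(0.75)

    def test_matches_brute_force_pair_count(self, rng):
        """All-pairs oracle with half credit for ties, n <= 100."""
        for _ in range(5):
            n = 60
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            p = np.round(rng.random(n), 1)  # coarse grid forces ties
            wins = half = 0
            for i in np.flatnonzero(y):
                for j in np.flatnonzero(~y):
                    wins += p[i] > p[j]
                    half += p[i] == p[j]
            expected = (wins + 0.5 * half) / (y.sum() * (~y).sum())
            assert occupancy.auc(y, p) == pytest.approx(expected)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            occupancy.auc([0, 0], [0.2, 0.4])


class TestVariancePartition:
    def _coefs(self, **kw):
        base = dict(intercept=0.0, b_mat=0.0, b_mat2=0.0, b_latsin=0.0,
                    b_latcos=0.0, b_logdepth=0.0)
        base.update(kw)
        return pd.Series(base)

    def _design(self, rng, n=200):
        return np.column_stack([
            np.ones(n), rng.normal(10, 8, n), rng.normal(150, 100, n),
            rng.normal(0, 30, n), rng.normal(0, 30, n), rng.normal(0, 0.5, n),
        ])

    def test_only_mat_nonzero_gives_full_share(self, rng):
        X = self._design(rng)
        shares = occupancy.variance_partition_fixed(
            self._coefs(b_mat=0.1), X, site_re_variance=0.0
        )
        assert shares["mat"] == pytest.approx(1.0)

    def test_zero_mat_coefficients_zero_share(self, rng):
        X = self._design(rng)
        shares = occupancy.variance_partition_fixed(
            self._coefs(b_latsin=0.02, b_logdepth=0.3), X, site_re_variance=0.1
        )
        assert shares["mat"] == 0.0
        assert shares.sum() == pytest.approx(1.0)

    def test_balanced_groups_equal_shares(self, rng):
        """Seasonal contribution built to match the MAT contribution."""
        n = 4000
        X = self._design(rng, n)
        c = self._coefs(b_mat=0.1)
        var_mat = np.var(X[:, 1] * 0.1)
        scale = np.sqrt(var_mat / np.var(X[:, 3]))
        c["b_latsin"] = scale
        shares = occupancy.variance_partition_fixed(c, X, 0.0)
        assert shares["mat"] == pytest.approx(shares["seasonal"], rel=0.05)


class TestSensitivities:
    def test_product_rule(self):
        shares = pd.Series({"mat": 0.5, "seasonal": 0.3, "log_depth": 0.1, "site": 0.1})
        cs, ss = occupancy.sensitivities(shares, 0.2)
        assert cs == pytest.approx(0.1)
        assert ss == pytest.approx(0.06)

    def test_zero_tjur_zero_sensitivity(self):
        shares = pd.Series({"mat": 0.5, "seasonal": 0.5, "log_depth": 0, "site": 0})
        assert occupancy.sensitivities(shares, 0.0) == (0.0, 0.0)

    def test_negative_tjur_floored(self):
        shares = pd.Series({"mat": 0.5, "seasonal": 0.5, "log_depth": 0, "site": 0})
        assert occupancy.sensitivities(shares, -0.3) == (0.0, 0.0)


class TestOptima:
    def _coefs(self, b1, b2, bs=0.0, bc=0.0):
        return pd.Series({"b_mat": b1, "b_mat2": b2, "b_latsin": bs, "b_latcos": bc})

    def test_interior_vertex(self):
        out = occupancy.optimal_mat(self._coefs(2.0, -0.05), (-15, 28), 0.2)
        assert out == pytest.approx(20.0)

    def test_convex_takes_better_boundary(self):
        out = occupancy.optimal_mat(self._coefs(0.0, 0.01), (-10, 25), 0.2)
        assert out == 25.0  # larger |MAT| wins for upward parabola centred at 0

    def test_low_sensitivity_undefined(self):
        assert np.isnan(occupancy.optimal_mat(self._coefs(2.0, -0.05), (-15, 28), 0.03))

    def test_vertex_truncated_to_observed_range(self):
        out = occupancy.optimal_mat(self._coefs(4.0, -0.05), (-15, 28), 0.2)
        assert out == 28.0  # vertex at 40 truncated

    @pytest.mark.parametrize(
        "bs,bc,day,season",
        [(0.0, 1.0, 0.0, "winter"), (1.0, 0.0, 91.25, "spring")],
    )
    def test_peak_day_north(self, bs, bc, day, season):
        d, s = occupancy.optimal_day(self._coefs(0, 0, bs, bc), 0.2)
        assert d == pytest.approx(day)
        assert s == season

    def test_peak_day_southern_shift(self):
        d, s = occupancy.optimal_day(self._coefs(0, 0, 1.0, 0.0), 0.2, hemisphere="south")
        assert d == pytest.approx(91.25 + 182.5)
        assert s == "autumn"

    def test_zero_seasonal_coefficients_undefined(self):
        d, _ = occupancy.optimal_day(self._coefs(0, 0, 0.0, 0.0), 0.2)
        assert np.isnan(d)


class TestPSRF:
    def test_identical_chains_near_one(self, rng):
        chain = rng.normal(size=(1, 500, 3))
        draws = np.concatenate([chain, chain], axis=0)
        assert (occupancy.psrf(draws) < 1.01).all()

    def test_disjoint_chains_large(self, rng):
        a = rng.normal(0, 0.1, size=(1, 200, 1))
        b = rng.normal(50, 0.1, size=(1, 200, 1))
        assert occupancy.psrf(np.concatenate([a, b]))[0] > 10

    def test_single_chain_errors(self, rng):
        with pytest.raises(ValueError):
            occupancy.psrf(rng.normal(size=(1, 100, 2)))

    def test_well_mixed_toy_target_below_105(self, rng):
        draws = rng.normal(size=(4, 2000, 2))
        assert (occupancy.psrf(draws) < 1.05).all()


class TestSampler:
    def _simulate(self, rng, n=2000, n_sites=10, site_sd=0.4):
        X = np.column_stack([
            np.ones(n), rng.normal(10, 8, n), np.zeros(n),
            rng.normal(0, 25, n), rng.normal(0, 25, n), rng.normal(0, 0.6, n),
        ])
        X[:, 2] = (X[:, 1] - 10) ** 2  # curvature around 10 degC
        beta = np.array([-0.3, 0.04, -0.004, 0.02, -0.015, 0.3])
        sites = rng.integers(0, n_sites, n)
        alpha = rng.normal(0, site_sd, n_sites)
        eta = X @ beta + alpha[sites]
        y = rng.random(n) < ndtr(eta)
        return y.astype(int), X, sites, beta, site_sd

    def test_recovers_known_coefficients(self, rng):
        y, X, sites, beta, _ = self._simulate(rng)
        model = occupancy.ProbitOccupancyModel(y, X, sites, "toy")
        res = model.fit(occupancy.MCMCSchedule(2, 1200, 400, 4), seed=5)
        sd = res.draws[..., :6].reshape(-1, 6).std(axis=0)
        # transform draw sd back to the original scale
        sd = sd / model._sd
        standardized = np.abs(res.coefs.to_numpy() - beta) / sd
        assert np.median(standardized) < 2.0
        assert (standardized < 3.5).all()

    def test_zero_site_variance_concentrates_near_zero(self, rng):
        y, X, sites, _, _ = self._simulate(rng, site_sd=0.0)
        res = occupancy.ProbitOccupancyModel(y, X, sites, "toy").fit(
            occupancy.MCMCSchedule(2, 800, 300, 4), seed=6
        )
        assert res.site_re_variance < 0.1

    def test_single_class_rejected(self, rng):
        X = np.ones((50, 2))
        with pytest.raises(ValueError):
            occupancy.ProbitOccupancyModel(np.ones(50, dtype=int), X, np.zeros(50, int))


class TestOrderSummaries:
    def test_orders_below_threshold_omitted(self, small_ds):
        metrics = pd.DataFrame(
            {
                "species_id": small_ds.taxonomy["otu_id"],
                "climatic_sensitivity": 0.1,
                "seasonal_sensitivity": 0.2,
            }
        )
        sizes = small_ds.taxonomy.groupby("order").size()  # 6 species per order
        out = occupancy.order_summaries(metrics, small_ds.taxonomy, min_species=5)
        assert set(out["order"]) == set(sizes.index[sizes >= 5])
        empty = occupancy.order_summaries(metrics, small_ds.taxonomy, min_species=7)
        assert len(empty) == 0

    def test_constant_sensitivity_zero_iqr(self, small_ds):
        metrics = pd.DataFrame(
            {
                "species_id": small_ds.taxonomy["otu_id"],
                "climatic_sensitivity": 0.25,
                "seasonal_sensitivity": 0.25,
            }
        )
        out = occupancy.order_summaries(metrics, small_ds.taxonomy, min_species=5)
        assert (out["climatic_sensitivity_q3"] == out["climatic_sensitivity_q1"]).all()
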