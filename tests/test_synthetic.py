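"""Ground-truth generators: city, surface, campaigns, cohort."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from citylur.predictors import assemble_predictor_table
from citylur.scene import ConfigurationError
from citylur.synthetic import (
    CityConfig,
    SamplerSpec,
    SurfaceParams,
    generate_city,
    place_sites,
    simulate_campaign,
    simulate_cohort,
    simulate_true_surface,
)


def _scene_fingerprint(city):
    roads = [(r.start, r.end, r.vehicles_per_day) for r in city.roads]
    blocks = [(b.id, b.residents, b.area, b.altitude, b.green_adjacent) for b in city.blocks]
    return json.dumps({"roads": roads, "blocks": blocks}, default=float)


class TestGenerateCity:
    def test_deterministic(self):
        cfg = CityConfig(extent=10_000, n_radial=5, n_ring=2, blocks_per_side=10)
        a, b = generate_city(cfg, seed=3), generate_city(cfg, seed=3)
        assert _scene_fingerprint(a) == _scene_fingerprint(b)

    def test_segment_count_and_extent(self):
        cfg = CityConfig(extent=10_000, n_radial=8, n_ring=2, blocks_per_side=10, ring_segments=12)
        city = generate_city(cfg, seed=1)
        assert len(city.roads) == 8 * 3 + 2 * 12
        for r in city.roads:
            for x, y in (r.start, r.end):
                assert 0 <= x <= cfg.extent and 0 <= y <= cfg.extent

    def test_has_both_road_classes(self, city):
        assert any(r.is_high_traffic for r in city.roads)
        assert any(not r.is_high_traffic for r in city.roads)

    def test_density_decays_from_centre(self):
        city = generate_city(CityConfig(blocks_per_side=23), seed=5)  # 529 blocks
        dens = np.array([b.residents / b.area for b in city.blocks])
        dist = np.array(
            [math.hypot(b.polygon.centroid.x - city.centre[0], b.polygon.centroid.y - city.centre[1])
             for b in city.blocks]
        )
        assert stats.spearmanr(dens, dist).statistic < 0

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigurationError):
            CityConfig(extent=-1.0)
        with pytest.raises(ConfigurationError):
            CityConfig(blocks_per_side=0)


class TestSurface:
    def test_constant_when_all_betas_zero(self, city):
        params = SurfaceParams(beta0=2.0, betas={}, noise_sd=0.0)
        surf = simulate_true_surface(city, params, seed=1)
        pts = np.array([[2000.0, 2000.0], [9_000.0, 4_000.0], city.centre])
        np.testing.assert_allclose(surf.concentration(pts), np.exp(2.0))

    def test_noiseless_value_reproducible_by_hand(self, city):
        params = SurfaceParams(
            beta0=3.5, betas={"dist_centre": -2e-5, "altitude": -1e-3}, noise_sd=0.0
        )
        surf = simulate_true_surface(city, params, seed=1)
        pt = np.array([[4_000.0, 5_000.0]])
        tab = assemble_predictor_table(pt, city)
        by_hand = math.exp(
            3.5 - 2e-5 * tab.loc[0, "dist_centre"] - 1e-3 * tab.loc[0, "altitude"]
        )
        assert surf.concentration(pt)[0] == pytest.approx(by_hand, rel=1e-12)

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            SurfaceParams(betas={"no_such_predictor": 1.0})

    def test_noise_correlation_decays_with_distance(self):
        """Exponential-covariance field: pairs ~200 m apart correlate more
        strongly than pairs ~2,000 m apart (Monte Carlo over realisations)."""
        city = generate_city(CityConfig(extent=8_000.0, blocks_per_side=8), seed=2)
        rng = np.random.default_rng(9)
        prods_near, prods_far, var = [], [], []
        for rep in range(8):
            surf = simulate_true_surface(
                city, SurfaceParams(betas={}, noise_sd=0.1, noise_range=1_000.0), seed=100 + rep
            )
            base = rng.uniform(500, 5_500, size=(1_250, 2))
            for d, sink in ((200.0, prods_near), (2_000.0, prods_far)):
                ang = rng.uniform(0, 2 * np.pi, len(base))
                other = base + d * np.column_stack([np.cos(ang), np.sin(ang)])
                za = surf.noise_at(base[:, 0], base[:, 1])
                zb = surf.noise_at(other[:, 0], other[:, 1])
                sink.extend(za * zb)
                var.extend(za * za)
        v = np.mean(var)
        assert np.mean(prods_near) / v > np.mean(prods_far) / v

    def test_zero_drift_makes_campaigns_identical(self, city):
        params = SurfaceParams(noise_sd=0.05, drift_shift=0.0, drift_traffic_coef=0.0)
        surf = simulate_true_surface(city, params, seed=4)
        pts = np.array([[3_000.0, 3_000.0], [8_000.0, 6_000.0]])
        np.testing.assert_allclose(
            surf.concentration(pts, campaign_index=1), surf.concentration(pts, campaign_index=2)
        )


class TestCampaign:
    def test_ideal_sampler_reads_truth(self, city, noiseless_surface, sites):
        s = SamplerSpec("ideal", 1.0, 0.0, 0.0)
        ms = simulate_campaign(
            city, noiseless_surface, sites, 3, s, 1, seed=1, period_effects=(0.0, 0.0, 0.0)
        )
        true = noiseless_surface.concentration(sites[["x", "y"]].to_numpy())
        wide = ms.records.pivot(index="site_id", columns="period", values="value")
        wide = wide.loc[sites["site_id"]]
        for p in (1, 2, 3):
            np.testing.assert_allclose(wide[p].to_numpy(), true, rtol=1e-12)

    def test_record_conservation(self, city, surface, sites):
        ms = simulate_campaign(city, surface, sites, 3, SamplerSpec("s", 1, 0, 1.0), 1,
                               seed=2, missing_rate=0.2)
        n_missing = len(sites) * 3 - len(ms.records)
        assert len(ms.records) == len(sites) * 3 - n_missing
        assert not ms.records.duplicated(["site_id", "period"]).any()

    def test_missingness_rate_matches_expectation(self, city, surface, sites):
        """With rate 3/70, about 3 sites in 70 lose a period (in expectation)."""
        incomplete = []
        for rep in range(60):
            ms = simulate_campaign(city, surface, sites.head(60), 3, SamplerSpec("s", 1, 0, 1.0),
                                   1, seed=3_000 + rep, missing_rate=3 / 70)
            counts = ms.records.groupby("site_id").size()
            incomplete.append(60 - (counts == 3).sum())
        expected = 60 * 3 / 70
        assert expected * 0.5 < np.mean(incomplete) < expected * 1.7

    def test_negative_drift_lowers_campaign2(self, city, sites):
        surf = simulate_true_surface(
            city, SurfaceParams(noise_sd=0.05, drift_shift=-0.08, drift_traffic_coef=0.0), seed=6
        )
        ideal = SamplerSpec("ideal", 1.0, 0.0, 0.0)
        m1 = simulate_campaign(city, surf, sites, 3, ideal, 1, seed=7, period_effects=(0, 0, 0))
        m2 = simulate_campaign(city, surf, sites, 3, ideal, 2, seed=8, period_effects=(0, 0, 0))
        assert m2.records["value"].mean() < m1.records["value"].mean()

    def test_site_outside_extent_rejected(self, city, surface):
        bad = pd.DataFrame({"site_id": ["z1"], "x": [-10.0], "y": [10.0], "site_type": ["background"]})
        with pytest.raises(ConfigurationError, match="outside"):
            simulate_campaign(city, surface, bad, 3, SamplerSpec("s", 1, 0, 0), 1, seed=1)


class TestCohort:
    def test_validation(self, city, surface):
        with pytest.raises(ValueError):
            simulate_cohort(city, surface, 50, 0.0, seed=1)
        with pytest.raises(ValueError):
            simulate_cohort(city, surface, 200, 0.0, horizon_years=-1.0, seed=1)

    def test_censoring_contract(self, city, surface):
        coh, _ = simulate_cohort(city, surface, 500, math.log(1.06), horizon_years=5.2, seed=2)
        assert coh["followup_time"].max() <= 5.2
        assert (coh.loc[coh["event"], "followup_time"] <= 5.2).all()
        assert (coh["followup_time"] > 0).all()

    def test_deterministic(self, city, surface):
        a, _ = simulate_cohort(city, surface, 300, 0.05, seed=9)
        b, _ = simulate_cohort(city, surface, 300, 0.05, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_null_exposure_balances_events_across_quintiles(self, city, surface):
        zero = {k: (0.0,) * 5 for k in ("sep",)}
        zero.update({
            "age_band": (0.0,) * 3, "gender": (0.0,) * 2, "marital_status": (0.0,) * 3,
            "place_of_birth": (0.0,) * 3, "education": (0.0,) * 4, "occupation": (0.0,) * 4,
        })
        pvals = []
        for rep in range(20):
            coh, _ = simulate_cohort(city, surface, 2_000, 0.0, covariate_effects=zero,
                                     confounding_strength=0.0, seed=400 + rep)
            q = pd.qcut(coh["no2_true"], 5, labels=False)
            table = pd.crosstab(q, coh["event"])
            pvals.append(stats.chi2_contingency(table).pvalue)
        # null chi-square p-values should not pile up near zero
        assert np.mean(np.array(pvals) < 0.05) < 0.25

    def test_zero_confounding_decouples_sep_from_exposure(self, city, surface):
        coh, _ = simulate_cohort(city, surface, 20_000, 0.0, confounding_strength=0.0, seed=10)
        r = np.corrcoef(coh["sep"], coh["no2_true"])[0, 1]
        assert abs(r) < 0.05

    def test_confounding_couples_sep_to_exposure(self, city, surface):
        coh, _ = simulate_cohort(city, surface, 10_000, 0.0, confounding_strength=0.8, seed=11)
        assert np.corrcoef(coh["sep"], coh["no2_true"])[0, 1] > 0.1


def test_place_sites_types_and_bounds(city, sites):
    assert (sites["site_type"].value_counts()["background"]) == 40
    assert city.contains_points(sites["x"].to_numpy(), sites["y"].to_numpy()).all()
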