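"""Statistical and determinism properties of the synthetic-data generators."""

import math

import numpy as np
import pytest
from scipy import stats

from icedust.synthetic import (SyntheticSpec, gen_met_series,
                               gen_opc_campaign, gen_particle_set,
                               gen_snow_samples, gen_taxon_counts,
                               lognormal_moments_from_params,
                               lognormal_params_from_moments,
                               truncated_normal_mean)


class TestMomentMatching:
    def test_round_trip(self):
        ml, sl = lognormal_params_from_moments(0.76, 0.87)
        mean, sd = lognormal_moments_from_params(ml, sl)
        assert mean == pytest.approx(0.76, rel=1e-12)
        assert sd == pytest.approx(0.87, rel=1e-12)

    def test_degenerate_sd_zero(self):
        ml, sl = lognormal_params_from_moments(2.0, 0.0)
        assert sl == 0.0
        assert math.exp(ml) == pytest.approx(2.0)


class TestParticleSet:
    def test_degenerate_all_unit_diameter(self):
        spec = SyntheticSpec(seed=1, n_particles=100, meanlog=0.0, sdlog=0.0)
        ps = gen_particle_set(spec)
        np.testing.assert_allclose(ps.diameters, 1.0)

    def test_same_seed_identical(self):
        spec = SyntheticSpec(seed=42, n_particles=1000)
        a = gen_particle_set(spec)
        b = gen_particle_set(spec)
        np.testing.assert_array_equal(a.diameters, b.diameters)

    def test_different_seed_differs(self):
        a = gen_particle_set(SyntheticSpec(seed=1, n_particles=100))
        b = gen_particle_set(SyntheticSpec(seed=2, n_particles=100))
        assert not np.array_equal(a.diameters, b.diameters)

    def test_moment_match_2017_filter_sample(self):
        """50k draws from the moment-matched law recover mean 0.76 to 2%."""
        ml, sl = lognormal_params_from_moments(0.76, 0.87)
        spec = SyntheticSpec(seed=3, n_particles=50_000, meanlog=ml, sdlog=sl)
        d = gen_particle_set(spec).diameters
        assert d.mean() == pytest.approx(0.76, rel=0.02)
        assert d.std(ddof=1) == pytest.approx(0.87, rel=0.05)

    def test_cutoff_respected(self):
        spec = SyntheticSpec(seed=5, n_particles=20_000)
        assert gen_particle_set(spec).diameters.max() <= spec.diameter_cutoff

    def test_invalid_n_particles(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_particles=0)

    def test_meanlog_sdlog_recovered_within_3se(self):
        """Fitted lognormal parameters fall within 3 SE at n = 1e4."""
        n = 10_000
        spec = SyntheticSpec(seed=11, n_particles=n)
        logs = np.log(gen_particle_set(spec).diameters)
        se_mean = spec.sdlog / math.sqrt(n)
        se_sd = spec.sdlog / math.sqrt(2 * n)
        assert abs(logs.mean() - spec.meanlog) < 3 * se_mean
        assert abs(logs.std(ddof=1) - spec.sdlog) < 3 * se_sd


class TestOPCCampaign:
    def test_single_wide_bin_collects_everything(self):
        spec = SyntheticSpec(seed=2, campaign_days=1)
        opc = gen_opc_campaign(spec, bin_edges=np.array([0.38, 17.0]))
        assert opc.counts.shape[1] == 1
        assert opc.counts.sum() > 0

    def test_zero_duration_empty_series(self):
        spec = SyntheticSpec(seed=2, campaign_days=0)
        opc = gen_opc_campaign(spec)
        assert opc.counts.shape[0] == 0
        assert len(opc.timestamps) == 0

    def test_unsorted_edges_error(self, default_spec):
        with pytest.raises(ValueError):
            gen_opc_campaign(default_spec, bin_edges=np.array([1.0, 0.5, 2.0]))

    def test_submicron_fraction_matches_lognormal_cdf(self):
        """Counts below 1 µm match the closed-form CDF within sampling error."""
        spec = SyntheticSpec(seed=9, campaign_days=7, dust_mass_ug_m3=2.0)
        edges = np.array([0.38, 1.0, 17.0])
        opc = gen_opc_campaign(spec, bin_edges=edges)
        total = opc.counts.sum()
        assert total > 1e4
        dist = stats.lognorm(s=spec.sdlog, scale=math.exp(spec.meanlog))
        cdf = dist.cdf(edges)
        expected = (cdf[1] - cdf[0]) / (cdf[2] - cdf[0])
        observed = opc.counts[:, 0].sum() / total
        se = math.sqrt(expected * (1 - expected) / total)
        assert abs(observed - expected) < 4 * se

    def test_determinism(self, default_spec):
        a = gen_opc_campaign(default_spec)
        b = gen_opc_campaign(default_spec)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_counts_nonnegative(self, default_spec):
        assert (gen_opc_campaign(default_spec).counts >= 0).all()


class TestMetSeries:
    def test_zero_sd_constant_wind(self):
        spec = SyntheticSpec(seed=4, campaign_days=1, wind_sd=0.0)
        met = gen_met_series(spec)
        np.testing.assert_allclose(met.wind_speed, spec.mean_wind)

    def test_mean_wind_recovered_clt(self):
        """Sample mean speed matches the truncated-normal mean within 3 SE."""
        spec = SyntheticSpec(seed=8, campaign_days=7)
        met = gen_met_series(spec)
        n = met.wind_speed.size
        target = truncated_normal_mean(spec.mean_wind, spec.wind_sd)
        se = spec.wind_sd / math.sqrt(n)
        assert abs(met.wind_speed.mean() - target) < 3 * se

    def test_no_storms_no_pressure_dips(self):
        spec = SyntheticSpec(seed=6, campaign_days=10, storm_days=frozenset())
        met = gen_met_series(spec)
        floor = spec.mean_pressure - 3 * spec.pressure_sd
        assert np.asarray(met.pressure).min() > floor

    def test_storm_days_lower_pressure_and_turn_wind(self):
        spec = SyntheticSpec(seed=6, campaign_days=4, storm_days=frozenset({1}))
        met = gen_met_series(spec)
        day = np.arange(met.wind_speed.size) // 1440
        p = np.asarray(met.pressure)
        assert p[day == 1].min() < spec.mean_pressure - 3 * spec.pressure_sd
        d = np.asarray(met.wind_direction)
        assert abs(np.median(d[day == 1]) - 270.0) < 45.0

    def test_wind_nonnegative_and_deterministic(self, default_spec):
        a = gen_met_series(default_spec)
        b = gen_met_series(default_spec)
        assert (a.wind_speed >= 0).all()
        np.testing.assert_array_equal(a.wind_speed, b.wind_speed)
        np.testing.assert_array_equal(a.pressure, b.pressure)


class TestSnowSamples:
    def test_zero_sd_all_equal_mean(self):
        spec = SyntheticSpec(seed=3, load_sd=0.0, dissolvedP_sd=0.0)
        samples = gen_snow_samples(spec, n_fresh=5, n_weathered=0)
        assert all(s.load_mg_kg == pytest.approx(spec.load_mean) for s in samples)
        assert all(s.dissolved_p_ug_l == pytest.approx(spec.dissolvedP_mean)
                   for s in samples)

    def test_truncation_no_negatives(self):
        spec = SyntheticSpec(seed=13, load_mean=0.5, load_sd=2.0,
                             dissolvedP_mean=0.2, dissolvedP_sd=1.0)
        samples = gen_snow_samples(spec, n_fresh=5000, n_weathered=5000)
        assert all(s.load_mg_kg >= 0 and s.dissolved_p_ug_l >= 0 for s in samples)

    def test_mean_load_recovered(self):
        spec = SyntheticSpec(seed=14)
        samples = gen_snow_samples(spec, n_fresh=1000, n_weathered=0)
        loads = np.array([s.load_mg_kg for s in samples])
        target = truncated_normal_mean(spec.load_mean, spec.load_sd)
        se = spec.load_sd / math.sqrt(loads.size)
        assert abs(loads.mean() - target) < 2.5 * se

    def test_types_labelled(self):
        samples = gen_snow_samples(SyntheticSpec(seed=1), 2, 3)
        assert [s.sample_type for s in samples] == (
            ["fresh_snow"] * 2 + ["weathered_snow"] * 3)


class TestTaxonCounts:
    def test_single_taxon_gets_all_reads(self):
        spec = SyntheticSpec(seed=1, taxon_profile={"OnlyOne": 1.0})
        table = gen_taxon_counts(spec, depth=5000, n_samples=3)
        assert (table["OnlyOne"] == 5000).all()

    def test_row_sums_equal_depth(self, default_spec):
        table = gen_taxon_counts(default_spec, depth=20_000, n_samples=4)
        assert (table.sum(axis=1) == 20_000).all()

    def test_profile_recovered_within_multinomial_se(self):
        depth = 100_000
        spec = SyntheticSpec(seed=21)
        table = gen_taxon_counts(spec, depth=depth, n_samples=1)
        props = table.iloc[0] / depth
        for taxon, p in spec.taxon_profile.items():
            se = math.sqrt(p * (1 - p) / depth)
            assert abs(props[taxon] - p) < 4 * se

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(taxon_profile={"A": 0.7, "B": 0.2})
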