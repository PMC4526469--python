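"""Ground-truth contracts of the synthetic data generators."""

import numpy as np
import pandas as pd
import pytest

from sealniche.chronology import refine_period
from sealniche.geo import LocalProjection, haversine_m
from sealniche.niche import NicheDecomposition
from sealniche.synthetic import (
    IndividualTruth,
    SyntheticTruth,
    generate_population,
    generate_tracks,
    generate_whisker,
    grouped_niche_samples,
    make_bathymetry,
)


def _ind(sex="M", growth=0.17, mean13=-16.8, mean15=16.8, phase=0.0, years=3.0):
    return IndividualTruth(individual="X1", sex=sex, growth_rate=growth,
                           n_years=years, mean_d13c=mean13, mean_d15n=mean15,
                           phase_offset_days=phase)


@pytest.mark.parametrize(
    "growth,n_years,expected_sections",
    [
        (0.17, 3, 62),   # floor(0.17 * 1095 / 3)
        (0.09, 5, 54),   # floor(0.09 * 1825 / 3)
        (0.15, 2, 36),
    ],
)
def test_whisker_section_count(growth, n_years, expected_sections):
    truth = SyntheticTruth(rng_seed=0)
    w = generate_whisker(truth, _ind(growth=growth, years=n_years), n_years=n_years)
    assert w.n_sections == expected_sections
    assert np.allclose(np.diff(w.midpoints_mm), 3.0)


def test_whisker_period_along_length_is_growth_times_year():
    """Annual cycles appear along the whisker with period g * 365 mm."""
    truth = SyntheticTruth(rng_seed=0)
    truth.females.within_sd_d13c = 0.0
    w = generate_whisker(truth, _ind(sex="F", growth=0.09, years=5), n_years=5)
    period = refine_period(w.d13c, 3.0, period0_mm=0.09 * 365)
    assert period == pytest.approx(0.09 * 365, rel=0.02)


def test_degenerate_whisker_is_constant():
    truth = SyntheticTruth(rng_seed=0)
    truth.males.amplitude_d13c = 0.0
    truth.males.within_sd_d13c = 0.0
    w = generate_whisker(truth, _ind(mean13=-17.0), n_years=3)
    assert np.allclose(w.d13c, -17.0)


def test_whisker_invalid_parameters():
    truth = SyntheticTruth(rng_seed=0)
    with pytest.raises(ValueError):
        generate_whisker(truth, _ind(growth=-0.1), n_years=3)
    truth.males.amplitude_d15n = -1.0
    with pytest.raises(ValueError):
        generate_whisker(truth, _ind(), n_years=3)


def test_truth_parameter_validation():
    with pytest.raises(ValueError):
        SyntheticTruth(outlier_rate=1.5)
    with pytest.raises(ValueError):
        SyntheticTruth(fix_interval_s=0.0)


def test_population_counts_and_determinism():
    t = SyntheticTruth(rng_seed=7)
    pop_a = generate_population(t)
    pop_b = generate_population(SyntheticTruth(rng_seed=7))
    assert len(pop_a.whiskers) == 12
    assert (pop_a.blood["tissue"] == "plasma").sum() == 12
    assert (pop_a.blood["tissue"] == "red_cells").sum() == 12
    pd.testing.assert_frame_equal(pop_a.blood, pop_b.blood)
    for wa, wb in zip(pop_a.whiskers, pop_b.whiskers):
        assert np.array_equal(wa.d13c, wb.d13c)
        assert np.array_equal(wa.d15n, wb.d15n)


def test_population_minimum_group_size():
    with pytest.raises(ValueError):
        generate_population(SyntheticTruth(), n_males=1)


def test_zero_between_variance_collapses_individual_means():
    t = SyntheticTruth(rng_seed=3)
    t.males.between_sd_d13c = 0.0
    pop = generate_population(t)
    means = [i.mean_d13c for i in pop.individuals if i.sex == "M"]
    assert np.allclose(means, t.males.mean_d13c)


def test_blood_moments_match_stated_distributions(pop1, truth1):
    """Group draws are standardized: realized moments equal the stated ones."""
    for sex, params in (("M", truth1.males), ("F", truth1.females)):
        for tissue, per_iso in params.blood.items():
            sub = pop1.blood.query("sex == @sex and tissue == @tissue")
            for iso, (mean, sd) in per_iso.items():
                assert sub[iso].mean() == pytest.approx(mean, abs=1e-9)
                assert sub[iso].std(ddof=1) == pytest.approx(sd, abs=1e-9)


def test_grouped_samples_recover_closed_form_ratio():
    """Empirical WIC/TNW converges to the generating ratio as N grows."""
    for ratio in (0.3, 0.7):
        df, true_ratio = grouped_niche_samples(ratio, n_individuals=40,
                                               n_obs=200, seed=5)
        est = NicheDecomposition.from_dataframe(df, "value").fit(n_replicates=0)
        assert est.ratio == pytest.approx(true_ratio, abs=0.02)


def test_track_fix_count_and_cadence(truth1):
    inds = [_ind()]
    gps = generate_tracks(truth1, individuals=inds, n_days=35)
    assert len(gps) == 35 * 144 + 1
    dt = gps["timestamp"].diff().dropna().dt.total_seconds()
    assert (dt == 600.0).all()


def test_outlier_free_track_respects_generating_speed():
    t = SyntheticTruth(rng_seed=2, outlier_rate=0.0)
    gps = generate_tracks(t, individuals=[_ind(sex="F")], n_days=10)
    sp = haversine_m(gps.lon[:-1].to_numpy(), gps.lat[:-1].to_numpy(),
                     gps.lon[1:].to_numpy(), gps.lat[1:].to_numpy()) / 600.0
    assert sp.max() <= t.females.transit_speed_ms + 0.2  # + GPS jitter


def test_injected_outliers_exceed_speed_threshold():
    t = SyntheticTruth(rng_seed=4, outlier_rate=0.02)
    gps = generate_tracks(t, individuals=[_ind(sex="F")], n_days=10)
    lon, lat = gps["lon"].to_numpy(), gps["lat"].to_numpy()
    sp_in = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:]) / 600.0
    flags = gps["is_outlier"].to_numpy()
    assert flags.sum() == round(0.02 * len(gps))
    # every flagged fix implies a segment speed over 8 m/s on both sides
    for i in np.flatnonzero(flags):
        assert sp_in[i - 1] > 8.0 and sp_in[i] > 8.0


def test_colony_must_be_at_sea():
    t = SyntheticTruth(rng_seed=0, coast_north_km=-50.0)  # coast south of colony
    mask = make_bathymetry(t)
    with pytest.raises(ValueError, match="sea"):
        generate_tracks(t, individuals=[_ind()], n_days=2, mask=mask)


def test_projection_roundtrip():
    proj = LocalProjection(146.3, -39.1667)
    lon = np.array([146.3, 147.0, 145.2])
    lat = np.array([-39.1667, -39.9, -38.5])
    x, y = proj.forward(lon, lat)
    lon2, lat2 = proj.inverse(x, y)
    assert np.allclose(lon, lon2, atol=1e-9)
    assert np.allclose(lat, lat2, atol=1e-9)
    # distances from the centre are exact under aeqd
    assert np.allclose(np.hypot(x, y)[1:], haversine_m(146.3, -39.1667, lon, lat)[1:])
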