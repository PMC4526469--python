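"""End-to-end orchestration of the niche-segregation analysis.

Ties the stages together exactly as the pipeline is meant to be run on the
supplementary-style tables: whisker chronologies -> synchronized 2.5-year
window -> isotopic statistics; GPS fixes -> filtered/interpolated tracks ->
sex-level UDs -> UDOI.  ``run_synthetic_study`` performs the whole analysis
on the synthetic emulation of the study conditions and returns a flat report
of the headline quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import chronology as chron
from . import niche
from .geo import LocalProjection
from .io import StudyConfig
from .mixed import SexEffectMixedModel
from .spatial import estimate_ud, interpolate_track, isopleth, speed_filter, udoi
from .synthetic import SyntheticTruth, generate_population, generate_tracks, make_bathymetry

__all__ = ["run_chronology", "run_niche", "run_overlap", "run_synthetic_study"]


def run_chronology(whiskers, days_per_year=365.0, window_years=2.5, seed=0,
                   reference=None):
    """Fit every whisker, synchronize, truncate to the common window.

    Returns (results, summary table, windowed long table).
    """
    results = []
    for w in whiskers:
        results.append(chron.WhiskerChronology(w, days_per_year=days_per_year).fit(seed=seed))
    chron.synchronize_population(results, reference=reference)
    window = chron.truncate_common_window(results, window_years=window_years,
                                          days_per_year=days_per_year)
    return results, chron.chronology_summary(results), window


def run_niche(blood: pd.DataFrame, window: pd.DataFrame, n_replicates=10_000, seed=0):
    """All isotopic statistics on blood and windowed whisker values."""
    out = {"blood_tests": {}, "range_tests": {}, "ranges": None,
           "decompositions": {}, "lmm": {}}
    for tissue in sorted(blood["tissue"].unique()):
        sub = blood[blood["tissue"] == tissue]
        for iso in ("d13c", "d15n"):
            f = sub.loc[sub["sex"] == "F", iso]
            m = sub.loc[sub["sex"] == "M", iso]
            out["blood_tests"][(tissue, iso)] = niche.welch_t_test(
                f, m, label_a="F", label_b="M")
    ranges = niche.individual_ranges(window)
    out["ranges"] = ranges
    for iso in ("d13c", "d15n"):
        col = f"range_{iso}"
        out["range_tests"][iso] = niche.welch_t_test(
            ranges.loc[ranges["sex"] == "F", col],
            ranges.loc[ranges["sex"] == "M", col],
            label_a="F", label_b="M")
    for k, sex in enumerate(("M", "F")):
        sub = window[window["sex"] == sex]
        for j, iso in enumerate(("d13c", "d15n")):
            model = niche.NicheDecomposition.from_dataframe(sub, iso)
            out["decompositions"][(sex, iso)] = model.fit(
                n_replicates=n_replicates, seed=seed + 10 * k + j + 1)
    for iso in ("d13c", "d15n"):
        out["lmm"][iso] = SexEffectMixedModel.from_dataframe(window, iso).fit()
    return out


def run_overlap(gps: pd.DataFrame, mask=None, config: StudyConfig | None = None):
    """Sex-level kernel UDs and their overlap from a raw GPS fix table."""
    cfg = config or StudyConfig()
    proj = LocalProjection(cfg.colony_lon, cfg.colony_lat)
    kept, removal_log = speed_filter(gps, vmax=cfg.vmax_ms)
    positions = interpolate_track(kept, proj, interval_s=cfg.fix_interval_s)

    by_sex = {}
    for sex, sub in positions.groupby("sex"):
        by_sex[sex] = (sub["x"].to_numpy(), sub["y"].to_numpy())
    if set(by_sex) != {"F", "M"}:
        raise ValueError("overlap analysis needs both sexes present")

    from .spatial import adhoc_bandwidth, _grid_from_bbox

    h = {s: adhoc_bandwidth(x, y) for s, (x, y) in by_sex.items()}
    all_x = positions["x"].to_numpy()
    all_y = positions["y"].to_numpy()
    grid = _grid_from_bbox(all_x, all_y, 3.0 * max(h.values()), cfg.cell_m)
    uds = {
        s: estimate_ud(x, y, cell=cfg.cell_m, bandwidth=h[s], mask=mask,
                       grid=grid, projection=proj)
        for s, (x, y) in by_sex.items()
    }
    isopleths = {
        (s, lev): isopleth(uds[s], lev)
        for s in uds
        for lev in cfg.isopleth_levels
    }
    overlap = udoi(uds["M"], uds["F"], level=max(cfg.isopleth_levels))
    max_range_km = {
        s: float(np.hypot(x, y).max() / 1e3) for s, (x, y) in by_sex.items()
    }
    return {
        "removal_log": removal_log,
        "positions": positions,
        "uds": uds,
        "isopleths": isopleths,
        "udoi": overlap,
        "bandwidth_m": h,
        "max_range_km": max_range_km,
    }


def _sex_mean(summary: pd.DataFrame, col: str, sex: str) -> float:
    return float(summary.loc[summary["sex"] == sex, col].mean())


def run_synthetic_study(seed: int = 0, truth: SyntheticTruth | None = None,
                        n_replicates: int = 10_000, include_spatial: bool = True,
                        track_days: int = 35, config: StudyConfig | None = None):
    """Full analysis of one synthetic study; returns a flat numeric report.

    The report's keys mirror the study's headline quantities: whisker growth
    rates and cycle counts by sex, WIC/TNW decompositions (with Monte Carlo
    p), Welch blood contrasts (females − males), δ13C/δ15N range means, the
    sex-effect mixed-model F statistics, and the 95% UDOI between sex-pooled
    UDs (in percent).
    """
    truth = truth or SyntheticTruth(rng_seed=seed)
    cfg = config or StudyConfig(rng_seed=seed, track_days=track_days)
    pop = generate_population(truth)
    results, summary, window = run_chronology(
        whiskers=pop.whiskers, days_per_year=truth.days_per_year,
        window_years=cfg.window_years, seed=seed)
    stats = run_niche(pop.blood, window, n_replicates=n_replicates, seed=seed)

    report = {
        "growth_rate_male_mm_per_day": _sex_mean(summary, "growth_rate_mm_per_day", "M"),
        "growth_rate_female_mm_per_day": _sex_mean(summary, "growth_rate_mm_per_day", "F"),
        "mean_cycles_male": _sex_mean(summary, "n_cycles", "M"),
        "mean_cycles_female": _sex_mean(summary, "n_cycles", "F"),
        "whisker_d13c_mean_male": float(
            window[window.sex == "M"].groupby("individual")["d13c"].mean().mean()),
        "whisker_d13c_mean_female": float(
            window[window.sex == "F"].groupby("individual")["d13c"].mean().mean()),
        "whisker_d15n_mean_male": float(
            window[window.sex == "M"].groupby("individual")["d15n"].mean().mean()),
        "whisker_d15n_mean_female": float(
            window[window.sex == "F"].groupby("individual")["d15n"].mean().mean()),
    }
    for (tissue, iso), t in stats["blood_tests"].items():
        report[f"{tissue}_{iso}_t"] = t.t
        report[f"{tissue}_{iso}_p"] = t.p
    ranges = stats["ranges"]
    for iso in ("d13c", "d15n"):
        for sex in ("M", "F"):
            label = "male" if sex == "M" else "female"
            report[f"range_{iso}_{label}"] = float(
                ranges.loc[ranges.sex == sex, f"range_{iso}"].mean())
    for (sex, iso), dec in stats["decompositions"].items():
        label = "male" if sex == "M" else "female"
        report[f"wic_tnw_{iso}_{label}"] = dec.ratio
        report[f"wic_tnw_{iso}_{label}_p"] = dec.p_value
    for iso, lmm in stats["lmm"].items():
        report[f"lmm_{iso}_F"] = lmm.f_statistic
        report[f"lmm_{iso}_p"] = lmm.p_value

    n_sizes = {
        "n_individuals": len(pop.individuals),
        "n_window_sections": int(len(window)),
        "n_mc_replicates": int(n_replicates),
    }

    spatial = None
    if include_spatial:
        mask = make_bathymetry(truth, cell_m=cfg.cell_m)
        gps = generate_tracks(truth, individuals=pop.individuals, n_days=track_days,
                              mask=mask)
        spatial = run_overlap(gps.drop(columns=["is_outlier"]), mask=mask, config=cfg)
        report["udoi_95_percent"] = spatial["udoi"].udoi * 100.0
        report["home_range_male_km2"] = spatial["udoi"].area_1_km2
        report["home_range_female_km2"] = spatial["udoi"].area_2_km2
        report["max_range_male_km"] = spatial["max_range_km"]["M"]
        report["max_range_female_km"] = spatial["max_range_km"]["F"]
        n_sizes["n_positions"] = int(len(spatial["positions"]))

    return {
        "report": report,
        "sizes": n_sizes,
        "summary": summary,
        "window": window,
        "stats": stats,
        "spatial": spatial,
        "population": pop,
    }
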