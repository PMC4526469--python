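"""Synthetic fur-seal datasets with known ground truth.

Every downstream stage (chronology, niche statistics, spatial overlap) is
exercised here on generated data that mimics the statistical structure of the
study system: 6 adult males and 6 lactating females from a single breeding
colony, each contributing

* a whisker — 3-mm serial sections carrying a sinusoidal annual isotope cycle
  on top of an individual mean offset, with within-individual noise, a
  sex-specific growth rate (≈0.17 vs ≈0.09 mm/d for males vs females) and an
  unobserved under-skin time offset;
* plasma and red-cell isotope values drawn from sex-level distributions;
* a central-place GPS track at 10-min fixes (females: short ≈5-d trips;
  males: ≈3-week trips, half not returning within the window) with a small
  fraction of speed outliers whose ground-truth flags are retained.

Group-level draws (individual whisker means, growth rates, whisker ages and
blood values) are affinely standardized so the realized group moments equal
the stated ones; the stated between-individual variance therefore *is* the
true BIC of the generated population, and the true WIC/TNW ratio is available
in closed form (:meth:`SyntheticTruth.true_ratio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chronology import WhiskerSeries, SECTION_MM, DAYS_PER_YEAR
from .geo import DEFAULT_COLONY, LocalProjection

__all__ = [
    "SexParams",
    "SyntheticTruth",
    "IndividualTruth",
    "PopulationData",
    "male_defaults",
    "female_defaults",
    "default_truth",
    "generate_whisker",
    "generate_population",
    "generate_tracks",
    "grouped_niche_samples",
    "make_bathymetry",
]


@dataclass
class SexParams:
    """Generating parameters for one sex."""

    sex: str
    # whisker growth and age
    growth_rate_mean: float  # mm/day
    growth_rate_sd: float
    n_years_mean: float  # whisker record length, years
    n_years_sd: float
    # whisker isotope signal (per-mil)
    mean_d13c: float
    mean_d15n: float
    between_sd_d13c: float  # sd of individual mean offsets -> sqrt(true BIC)
    between_sd_d15n: float
    amplitude_d13c: float  # annual-cycle amplitude
    amplitude_d15n: float
    within_sd_d13c: float  # section-level noise -> contributes to true WIC
    within_sd_d15n: float
    # blood (tissue -> isotope -> (mean, sd))
    blood: dict = field(default_factory=dict)
    # movement
    trip_duration_mean_d: float = 5.0
    trip_duration_sd_d: float = 5.0
    haulout_mean_d: float = 1.6
    haulout_sd_d: float = 0.5
    transit_speed_ms: float = 1.4
    loiter_speed_ms: float = 0.35
    range_km: tuple = (40.0, 120.0)

    def validate(self):
        for name in ("growth_rate_sd", "n_years_sd", "between_sd_d13c",
                     "between_sd_d15n", "within_sd_d13c", "within_sd_d15n",
                     "trip_duration_sd_d", "haulout_sd_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.growth_rate_mean <= 0:
            raise ValueError("growth_rate_mean must be positive")
        if self.amplitude_d13c < 0 or self.amplitude_d15n < 0:
            raise ValueError("cycle amplitudes must be >= 0")


def male_defaults() -> SexParams:
    """Adult males: fast whisker growth, ≈3.5 annual cycles, wide δ13C cycle."""
    return SexParams(
        sex="M",
        growth_rate_mean=0.17, growth_rate_sd=0.04,
        n_years_mean=3.5, n_years_sd=0.6,
        mean_d13c=-16.8, mean_d15n=16.8,
        between_sd_d13c=0.10, between_sd_d15n=0.30,
        amplitude_d13c=0.48, amplitude_d15n=0.45,
        within_sd_d13c=0.10, within_sd_d15n=0.10,
        blood={
            "plasma": {"d13c": (-19.4, 0.2), "d15n": (16.1, 0.4)},
            "red_cells": {"d13c": (-19.0, 0.2), "d15n": (15.9, 0.2)},
        },
        trip_duration_mean_d=22.5, trip_duration_sd_d=6.2,
        haulout_mean_d=2.0, haulout_sd_d=0.8,
        transit_speed_ms=1.4, loiter_speed_ms=0.35,
        range_km=(60.0, 200.0),
    )


def female_defaults() -> SexParams:
    """Lactating females: slow growth, ≈5.5 cycles, short central-place trips."""
    return SexParams(
        sex="F",
        growth_rate_mean=0.09, growth_rate_sd=0.03,
        n_years_mean=5.5, n_years_sd=1.5,
        mean_d13c=-17.1, mean_d15n=16.3,
        between_sd_d13c=0.20, between_sd_d15n=0.40,
        amplitude_d13c=0.22, amplitude_d15n=0.68,
        within_sd_d13c=0.06, within_sd_d15n=0.10,
        blood={
            "plasma": {"d13c": (-19.4, 0.1), "d15n": (15.6, 0.3)},
            "red_cells": {"d13c": (-18.9, 0.3), "d15n": (15.5, 0.3)},
        },
        trip_duration_mean_d=5.2, trip_duration_sd_d=6.5,
        haulout_mean_d=1.6, haulout_sd_d=0.5,
        transit_speed_ms=1.4, loiter_speed_ms=0.35,
        range_km=(40.0, 120.0),
    )


@dataclass
class SyntheticTruth:
    """Full generating configuration plus closed-form niche truths."""

    males: SexParams = field(default_factory=male_defaults)
    females: SexParams = field(default_factory=female_defaults)
    phase_offset_max_days: float = 60.0  # under-skin lag, uniform on [0, max]
    fix_interval_s: float = 600.0
    outlier_rate: float = 0.02
    outlier_displacement_km: float = 15.0
    gps_noise_m: float = 30.0
    colony_lon: float = DEFAULT_COLONY[0]
    colony_lat: float = DEFAULT_COLONY[1]
    coast_north_km: float = 30.0  # synthetic coastline north of the colony
    days_per_year: float = DAYS_PER_YEAR
    section_mm: float = SECTION_MM
    track_start: str = "2013-06-04"
    rng_seed: int = 0

    def __post_init__(self):
        self.males.validate()
        self.females.validate()
        if not (0.0 <= self.outlier_rate < 1.0):
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.fix_interval_s <= 0:
            raise ValueError("fix_interval_s must be positive")
        if self.phase_offset_max_days < 0:
            raise ValueError("phase_offset_max_days must be >= 0")

    def params(self, sex: str) -> SexParams:
        if sex in ("M", "male", "males"):
            return self.males
        if sex in ("F", "female", "females"):
            return self.females
        raise ValueError(f"unknown sex {sex!r}")

    def true_ratio(self, sex: str, isotope: str) -> float:
        """Closed-form WIC/TNW of the generating process.

        Within-individual variance of a sinusoid of amplitude A plus noise of
        sd σ is A²/2 + σ²; between-individual variance is the stated offset
        variance τ², so WIC/TNW = (A²/2 + σ²) / (A²/2 + σ² + τ²).
        """
        p = self.params(sex)
        suff = isotope.removeprefix("d")
        a = getattr(p, f"amplitude_d{suff}")
        s = getattr(p, f"within_sd_d{suff}")
        tau = getattr(p, f"between_sd_d{suff}")
        wic = a * a / 2.0 + s * s
        return wic / (wic + tau * tau)

    def to_dict(self) -> dict:
        return asdict(self)


def default_truth(seed: int = 0) -> SyntheticTruth:
    return SyntheticTruth(rng_seed=seed)


@dataclass
class IndividualTruth:
    """Realized per-individual generating values (ground truth for recovery)."""

    individual: str
    sex: str
    growth_rate: float
    n_years: float
    mean_d13c: float
    mean_d15n: float
    phase_offset_days: float


@dataclass
class PopulationData:
    """Generated whiskers + blood table + the truth that produced them."""

    whiskers: list
    blood: pd.DataFrame
    individuals: list
    truth: SyntheticTruth

    def individual_truth(self, individual: str) -> IndividualTruth:
        for ind in self.individuals:
            if ind.individual == individual:
                return ind
        raise KeyError(individual)


def _standardized(rng, n, mean, sd, ddof=0):
    """n normal draws affinely standardized to the exact target moments."""
    if n == 1 or sd == 0:
        return np.full(n, float(mean))
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=ddof)
    return mean + sd * z


def generate_whisker(
    truth: SyntheticTruth,
    ind: IndividualTruth,
    n_years: float | None = None,
    rng: np.random.Generator | None = None,
) -> WhiskerSeries:
    """One whisker: individual mean + annual sine + section noise.

    The analysed length is ``n_years * days_per_year * growth_rate`` rounded
    down to whole sections; section i (proximal first) has midpoint distance
    ``section_mm * (i + 0.5)`` and value
    ``mean + A sin(2π (t_i - phase_offset) / days_per_year) + ε`` with
    ``t_i = midpoint / growth_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(truth.rng_seed)
    n_years = ind.n_years if n_years is None else float(n_years)
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if ind.growth_rate <= 0:
        raise ValueError("growth rate must be positive")
    p = truth.params(ind.sex)
    length = n_years * truth.days_per_year * ind.growth_rate
    n_sections = int(np.floor(length / truth.section_mm))
    mid = truth.section_mm * (np.arange(n_sections) + 0.5)
    t = mid / ind.growth_rate
    phase = 2.0 * np.pi * (t - ind.phase_offset_days) / truth.days_per_year
    out = {}
    for iso, mean in (("d13c", ind.mean_d13c), ("d15n", ind.mean_d15n)):
        amp = getattr(p, f"amplitude_{iso}")
        noise = getattr(p, f"within_sd_{iso}")
        if amp < 0:
            raise ValueError("amplitude must be >= 0")
        out[iso] = mean + amp * np.sin(phase) + noise * rng.standard_normal(n_sections)
    return WhiskerSeries(
        individual=ind.individual,
        sex=ind.sex,
        d13c=out["d13c"],
        d15n=out["d15n"],
        section_mm=truth.section_mm,
        total_length_mm=n_sections * truth.section_mm,
    )


def _draw_individuals(truth, n_males, n_females, rng):
    inds = []
    for p, n, prefix in ((truth.males, n_males, "M"), (truth.females, n_females, "F")):
        growth = np.clip(
            _standardized(rng, n, p.growth_rate_mean, p.growth_rate_sd), 0.01, None
        )
        # whisker must span the common window plus the largest possible lag
        min_years = 2.5 + truth.phase_offset_max_days / truth.days_per_year + 0.1
        years = np.clip(_standardized(rng, n, p.n_years_mean, p.n_years_sd),
                        min_years, None)
        m13 = _standardized(rng, n, p.mean_d13c, p.between_sd_d13c)
        m15 = _standardized(rng, n, p.mean_d15n, p.between_sd_d15n)
        offs = rng.uniform(0.0, truth.phase_offset_max_days, size=n)
        for i in range(n):
            inds.append(
                IndividualTruth(
                    individual=f"{prefix}{i + 1}",
                    sex=p.sex,
                    growth_rate=float(growth[i]),
                    n_years=float(years[i]),
                    mean_d13c=float(m13[i]),
                    mean_d15n=float(m15[i]),
                    phase_offset_days=float(offs[i]),
                )
            )
    return inds


def generate_population(
    truth: SyntheticTruth, n_males: int = 6, n_females: int = 6
) -> PopulationData:
    """Whiskers and blood values for a population; seed-deterministic."""
    if n_males < 2 or n_females < 2:
        raise ValueError("need at least 2 individuals per sex for variance estimation")
    rng = np.random.default_rng(truth.rng_seed)
    individuals = _draw_individuals(truth, n_males, n_females, rng)
    whiskers = [generate_whisker(truth, ind, rng=rng) for ind in individuals]

    rows = []
    for p, n in ((truth.males, n_males), (truth.females, n_females)):
        ids = [i.individual for i in individuals if i.sex == p.sex]
        for tissue, per_iso in p.blood.items():
            vals = {
                iso: _standardized(rng, n, mean, sd, ddof=1)
                for iso, (mean, sd) in per_iso.items()
            }
            for k, ind_id in enumerate(ids):
                rows.append(
                    {
                        "individual": ind_id,
                        "sex": p.sex,
                        "tissue": tissue,
                        "d13c": float(vals["d13c"][k]),
                        "d15n": float(vals["d15n"][k]),
                    }
                )
    blood = pd.DataFrame(rows)
    return PopulationData(whiskers=whiskers, blood=blood, individuals=individuals,
                          truth=truth)


def grouped_niche_samples(
    ratio: float,
    n_individuals: int = 12,
    n_obs: int = 50,
    tnw: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Plain grouped Gaussian data with an exact WIC/TNW generating ratio.

    Individual means are standardized draws with population variance
    ``(1 - ratio) * tnw``; observations add N(0, ratio * tnw) noise.  Returns
    the long table and the true ratio (exact by construction of the means).
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    tau = np.sqrt((1.0 - ratio) * tnw)
    sigma = np.sqrt(ratio * tnw)
    means = _standardized(rng, n_individuals, 0.0, tau)
    rows = []
    for i in range(n_individuals):
        vals = means[i] + sigma * rng.standard_normal(n_obs)
        rows.append(pd.DataFrame({"individual": f"I{i + 1}", "value": vals}))
    return pd.concat(rows, ignore_index=True), float(ratio)


# ---------------------------------------------------------------------------
# GPS tracks
# ---------------------------------------------------------------------------


def _unit(v):
    n = float(np.hypot(*v))
    return v / n if n > 0 else np.array([1.0, 0.0])


def _rot(v, angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _simulate_xy(rng, p: SexParams, n_fix, dt, y_cap_m):
    """Central-place out-and-back walk in local metres; colony at the origin."""
    pos = np.zeros((n_fix, 2))
    xy = np.zeros(2)
    step_max = p.transit_speed_ms * dt
    mode = "haulout"
    remaining = max(1, int(rng.uniform(0.1, 1.0) * p.haulout_mean_d * 86400 / dt))
    target = np.zeros(2)
    trip_left = 0
    for i in range(n_fix):
        pos[i] = xy
        if mode == "haulout":
            remaining -= 1
            if remaining <= 0:
                # schedule a trip
                if p.trip_duration_sd_d > 0 and p.trip_duration_mean_d > p.trip_duration_sd_d:
                    dur_d = max(0.5, rng.normal(p.trip_duration_mean_d, p.trip_duration_sd_d))
                else:  # heavy-tailed short trips
                    shape = max(0.3, (p.trip_duration_mean_d / max(p.trip_duration_sd_d, 1e-6)) ** 2)
                    dur_d = max(0.3, rng.gamma(shape, p.trip_duration_mean_d / shape))
                trip_left = max(4, int(dur_d * 86400 / dt))
                r = rng.uniform(*p.range_km) * 1000.0
                bearing = rng.uniform(np.radians(100.0), np.radians(260.0))
                target = np.array([r * np.sin(bearing), r * np.cos(bearing)])
                target[1] = min(target[1], y_cap_m)
                mode = "out"
        elif mode in ("out", "loiter", "back"):
            trip_left -= 1
            home = np.hypot(*xy)
            steps_home = home / step_max
            if mode != "back" and trip_left <= steps_home + 2:
                mode = "back"
            if mode == "out":
                to_t = target - xy
                if np.hypot(*to_t) <= step_max:
                    xy = target.copy()
                    mode = "loiter"
                else:
                    xy = xy + step_max * _rot(_unit(to_t), rng.normal(0.0, 0.25))
            elif mode == "loiter":
                drift = 0.15 * _unit(target - xy) if np.hypot(*(target - xy)) > 5000 else 0.0
                head = _rot(np.array([1.0, 0.0]), rng.uniform(0, 2 * np.pi))
                xy = xy + p.loiter_speed_ms * dt * (head + drift)
            else:  # back
                if home <= step_max:
                    xy = np.zeros(2)
                    mode = "haulout"
                    remaining = max(
                        1, int(max(0.2, rng.normal(p.haulout_mean_d, p.haulout_sd_d))
                               * 86400 / dt))
                else:
                    xy = xy + step_max * _rot(_unit(-xy), rng.normal(0.0, 0.1))
            xy[1] = min(xy[1], y_cap_m)
    return pos


def generate_tracks(
    truth: SyntheticTruth,
    individuals: list | None = None,
    n_days: int = 35,
    mask=None,
) -> pd.DataFrame:
    """GPS fix table for all individuals over ``n_days`` at the fix interval.

    Fixes start at ``truth.track_start`` and run inclusive of both endpoints
    (``n_days * 86400 / interval + 1`` fixes per individual).  A fraction
    ``outlier_rate`` of interior, non-adjacent fixes is displaced by
    ``outlier_displacement_km`` so their implied speed far exceeds the 8 m/s
    filter threshold; ground truth is kept in the ``is_outlier`` column.

    ``mask`` may be a :class:`sealniche.spatial.Raster`; the colony must then
    fall on a sea cell.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    proj = LocalProjection(truth.colony_lon, truth.colony_lat)
    if mask is not None:
        if not mask.is_sea(0.0, 0.0):
            raise ValueError("colony lies outside the sea region of the mask")
    rng = np.random.default_rng(np.random.SeedSequence([truth.rng_seed, 7]))
    if individuals is None:
        individuals = _draw_individuals(truth, 6, 6, rng)
    dt = truth.fix_interval_s
    n_fix = int(round(n_days * 86400 / dt)) + 1
    t0 = pd.Timestamp(truth.track_start)
    times = t0 + pd.to_timedelta(np.arange(n_fix) * dt, unit="s")
    y_cap = (truth.coast_north_km - 2.0) * 1000.0

    frames = []
    for ind in individuals:
        p = truth.params(ind.sex)
        xy = _simulate_xy(rng, p, n_fix, dt, y_cap)
        xy = xy + truth.gps_noise_m * rng.standard_normal(xy.shape)
        flags = np.zeros(n_fix, dtype=bool)
        n_out = int(round(truth.outlier_rate * n_fix))
        if n_out > 0:
            candidates = rng.permutation(np.arange(1, n_fix - 1))
            chosen = []
            for c in candidates:
                if len(chosen) == n_out:
                    break
                if all(abs(c - k) > 1 for k in chosen):
                    chosen.append(int(c))
            for c in chosen:
                b = rng.uniform(0, 2 * np.pi)
                xy[c] += truth.outlier_displacement_km * 1000.0 * np.array(
                    [np.sin(b), np.cos(b)]
                )
                flags[c] = True
        lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
        frames.append(
            pd.DataFrame(
                {
                    "individual": ind.individual,
                    "sex": ind.sex,
                    "timestamp": times,
                    "lon": lon,
                    "lat": lat,
                    "is_outlier": flags,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def make_bathymetry(
    truth: SyntheticTruth | None = None,
    cell_m: float = 2000.0,
    extent_km: tuple = (-260.0, 260.0, -260.0, 60.0),
    sea_depth_m: float = -86.0,
    land_elevation_m: float = 10.0,
):
    """Synthetic bathymetry raster: flat shelf with a coastline to the north.

    Cells with value >= 0 are land.  Geometry is in local projected metres
    around the colony, matching :func:`generate_tracks`.
    """
    from .spatial import Raster

    truth = truth or SyntheticTruth()
    x0, x1, y0, y1 = (v * 1000.0 for v in extent_km)
    nx = int(np.ceil((x1 - x0) / cell_m))
    ny = int(np.ceil((y1 - y0) / cell_m))
    yc = y0 + cell_m * (np.arange(ny) + 0.5)
    values = np.full((ny, nx), sea_depth_m, dtype=float)
    values[yc >= truth.coast_north_km * 1000.0, :] = land_elevation_m
    return Raster(values=values, x0=x0, y0=y0, cell=cell_m)
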