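"""Isotopic niche statistics.

Group comparisons (Welch t-tests on blood values and per-individual ranges),
Roughgarden's variance decomposition of niche width for continuous data, and
its Monte Carlo significance test.

The decomposition treats the population variance as the Total Niche Width and
splits it by the law of total variance:

    TNW = WIC + BIC
    WIC = Σ_i (n_i / N) Var(values of individual i)      (within)
    BIC = Σ_i (n_i / N) (mean_i − grand mean)²           (between)

with population (divide-by-n) variances so the identity is exact.  WIC/TNW
near 1 means individuals each use the full population niche (generalists);
near 0 means individuals occupy distinct sub-niches (specialists).  The null
distribution of the ratio is obtained by resampling every individual's
observations with replacement from the pooled sample — the "all individuals
are generalists" hypothesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "welch_t_test",
    "individual_ranges",
    "NicheDecomposition",
    "NicheDecompositionResult",
    "monte_carlo_null",
    "wic_tnw",
    "ZeroNicheWidthError",
]


class ZeroNicheWidthError(ZeroDivisionError):
    """TNW is zero: the WIC/TNW ratio is undefined."""


@dataclass
class GroupComparison:
    """Welch two-sample comparison; ``t`` has the sign of (a − b)."""

    label_a: str
    label_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                f"mean_{self.label_a}": self.mean_a,
                f"sd_{self.label_a}": self.sd_a,
                f"mean_{self.label_b}": self.mean_b,
                f"sd_{self.label_b}": self.sd_b,
                "t": self.t,
                "df": self.df,
                "p": self.p,
            }
        )


def welch_t_test(a, b, label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Welch unequal-variance t-test with Satterthwaite df.

    The statistic is oriented as (a − b).  When reproducing the study's
    summary table, pass females as ``a`` and males as ``b``: the printed
    plasma δ15N contrast (males higher) is then negative, matching the table.
    Degenerate zero-variance input with equal means yields t = 0 with the
    pooled df n_a + n_b − 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        df = float(a.size + b.size - 2)
        t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if t == 0.0 else 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return GroupComparison(
        label_a, label_b,
        float(a.mean()), float(a.std(ddof=1)), int(a.size),
        float(b.mean()), float(b.std(ddof=1)), int(b.size),
        t, df, p,
    )


def individual_ranges(
    df: pd.DataFrame,
    value_cols=("d13c", "d15n"),
    individual_col: str = "individual",
) -> pd.DataFrame:
    """Per-individual max − min of each isotope (niche range, per-mil).

    Input is the long windowed whisker table; individuals with fewer than
    two sections are rejected.
    """
    counts = df.groupby(individual_col).size()
    if (counts < 2).any():
        bad = counts.index[counts < 2].tolist()
        raise ValueError(f"individuals with < 2 sections: {bad}")
    agg = {c: lambda s: s.max() - s.min() for c in value_cols}
    keep = [individual_col] + (["sex"] if "sex" in df.columns else [])
    out = df.groupby(keep, as_index=False).agg(
        **{f"range_{c}": (c, lambda s: s.max() - s.min()) for c in value_cols}
    )
    return out


def wic_tnw(values, individuals) -> tuple[float, float, float]:
    """(TNW, WIC, BIC) with population variances; TNW = WIC + BIC exactly."""
    values = np.asarray(values, dtype=float)
    codes, _ = pd.factorize(np.asarray(individuals))
    n = values.size
    if n == 0:
        raise ValueError("no observations")
    grand = values.mean()
    tnw = float(values.var())
    wic = 0.0
    bic = 0.0
    for g in range(codes.max() + 1):
        v = values[codes == g]
        w = v.size / n
        wic += w * float(v.var())
        bic += w * float((v.mean() - grand) ** 2)
    return tnw, wic, bic


@dataclass
class NicheDecompositionResult:
    """WIC/BIC/TNW decomposition with Monte Carlo significance."""

    tnw: float
    wic: float
    bic: float
    ratio: float
    p_value: float | None
    n_replicates: int
    rng_seed: int | None
    n_observations: int
    n_individuals: int

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "TNW": self.tnw,
                "WIC": self.wic,
                "BIC": self.bic,
                "WIC/TNW": self.ratio,
                "p_value": self.p_value,
                "n_replicates": self.n_replicates,
                "n_observations": self.n_observations,
                "n_individuals": self.n_individuals,
            }
        )

    def __repr__(self):
        p = "n/a" if self.p_value is None else f"{self.p_value:.4g}"
        return (
            f"<NicheDecompositionResult WIC/TNW={self.ratio:.3f} "
            f"TNW={self.tnw:.4f} p={p}>"
        )


class NicheDecomposition:
    """Model object for the WIC/BIC/TNW split of one group of individuals.

    Parameters
    ----------
    values, individuals : array-like
        Long-format observations (one row per whisker section) and their
        individual labels.  Needs >= 2 individuals with >= 2 observations
        each.
    estimator : {"population", "sample"}
        ``population`` (default) uses divide-by-n variances so the identity
        TNW = WIC + BIC is exact; ``sample`` uses ddof=1 variances for
        cross-checking against software that reports sample variances (the
        identity then holds only approximately).
    """

    def __init__(self, values, individuals, estimator: str = "population"):
        if estimator not in ("population", "sample"):
            raise ValueError("estimator must be 'population' or 'sample'")
        self.values = np.asarray(values, dtype=float)
        self.individuals = np.asarray(individuals)
        if self.values.size != self.individuals.size:
            raise ValueError("values and individuals must have equal length")
        counts = pd.Series(self.individuals).value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError("need >= 2 individuals with >= 2 observations each")
        self.estimator = estimator

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str,
                       individual_col: str = "individual", **kw):
        sub = df[[individual_col, value_col]].dropna()
        return cls(sub[value_col].to_numpy(), sub[individual_col].to_numpy(), **kw)

    def decompose(self) -> tuple[float, float, float]:
        if self.estimator == "population":
            return wic_tnw(self.values, self.individuals)
        # sample-variance variant
        s = pd.Series(self.values, index=pd.Index(self.individuals, name="id"))
        n = s.size
        tnw = float(s.var(ddof=1))
        grp = s.groupby(level=0)
        w = grp.size() / n
        wic = float((w * grp.var(ddof=1)).sum())
        bic = float((w * (grp.mean() - s.mean()) ** 2).sum())
        return tnw, wic, bic

    def fit(self, n_replicates: int = 10_000, seed: int = 0) -> NicheDecompositionResult:
        """Decompose and attach the Monte Carlo p-value.

        Pass ``n_replicates=0`` to skip the null model (p_value None).
        """
        tnw, wic, bic = self.decompose()
        if tnw <= 0.0:
            raise ZeroNicheWidthError("TNW is zero; WIC/TNW undefined")
        ratio = wic / tnw
        p = None
        if n_replicates:
            p = monte_carlo_null(self.values, self.individuals, ratio,
                                 n_replicates=n_replicates, seed=seed)
        return NicheDecompositionResult(
            tnw=tnw, wic=wic, bic=bic, ratio=ratio, p_value=p,
            n_replicates=int(n_replicates), rng_seed=seed,
            n_observations=int(self.values.size),
            n_individuals=int(pd.unique(self.individuals).size),
        )


def monte_carlo_null(
    values,
    individuals,
    observed_ratio: float,
    n_replicates: int = 10_000,
    seed: int = 0,
    chunk: int = 2000,
) -> float:
    """P-value of WIC/TNW under the all-generalists null.

    Each replicate redraws, for every individual, its n_i observations with
    replacement from the pooled N observations, then recomputes the ratio.
    Low observed ratios (specialisation) are extreme, so
    ``p = (1 + #{replicate ratio <= observed}) / (1 + n_replicates)`` —
    the add-one rule keeps p > 0 at finite replicates.
    """
    if n_replicates < 100:
        warnings.warn("fewer than 100 Monte Carlo replicates; p-value is crude")
    values = np.asarray(values, dtype=float)
    codes, _ = pd.factorize(np.asarray(individuals))
    order = np.argsort(codes, kind="stable")
    v = values[order]
    codes = codes[order]
    n = v.size
    starts = np.flatnonzero(np.r_[1, np.diff(codes)])
    sizes = np.diff(np.r_[starts, n]).astype(float)
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < n_replicates:
        m = min(chunk, n_replicates - done)
        draw = v[rng.integers(0, n, size=(m, n))]
        sums = np.add.reduceat(draw, starts, axis=1)
        sqs = np.add.reduceat(draw * draw, starts, axis=1)
        means = sums / sizes
        wic = ((sqs / sizes - means**2) * (sizes / n)).sum(axis=1)
        tot = draw.sum(axis=1) / n
        tnw = (draw * draw).sum(axis=1) / n - tot**2
        ratio = np.where(tnw > 0, wic / np.where(tnw > 0, tnw, 1.0), 1.0)
        count += int(np.sum(ratio <= observed_ratio + 1e-12))
        done += m
    return (1 + count) / (1 + n_replicates)
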