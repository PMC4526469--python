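"""Linear mixed model for the sex effect on whisker isotope values.

The repeated sections of one whisker are neither independent of each other
nor of the animal they came from, so the sex contrast is fitted as

    y_ij = β0 + β1 · male_i + b_i + e_ij ,   b_i ~ N(0, τ²),
    Corr(e_ij, e_ik) = ρ^{|j − k|}          (AR(1) along section order),

i.e. a random intercept per individual with AR(1)-correlated residuals
within each whisker, estimated by restricted maximum likelihood.  The scale
is profiled out: with V_i = σ²(θ 11ᵀ + R_i(ρ)) and θ = τ²/σ², the REML
criterion reduces to a 2-parameter optimisation over (log θ, atanh ρ).

The sex effect is tested with a Wald F (numerator df 1).  Sex is a
between-individual contrast, so the denominator df follows the containment
rule: number of individuals minus the two sex-level coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = ["SexEffectMixedModel", "MixedModelResult", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class MixedModelResult:
    """REML fit of the random-intercept + AR(1) sex-contrast model.

    ``sex_effect`` is the fixed-effect contrast (males − females), per-mil.
    """

    sex_effect: float
    sex_se: float
    intercept: float
    var_individual: float
    var_residual: float
    rho: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    n_observations: int
    n_individuals: int
    reml_criterion: float
    converged: bool

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "sex_effect_male_minus_female": self.sex_effect,
                "se": self.sex_se,
                "var_individual": self.var_individual,
                "var_residual": self.var_residual,
                "ar1_rho": self.rho,
                "F": self.f_statistic,
                "df_num": self.df_num,
                "df_den": self.df_den,
                "p": self.p_value,
                "n_obs": self.n_observations,
                "n_individuals": self.n_individuals,
            }
        )


class SexEffectMixedModel:
    """Model container; build with arrays or :meth:`from_dataframe`, then ``fit``."""

    def __init__(self, values, sex, individuals, order=None):
        self.y = np.asarray(values, dtype=float)
        sex = np.asarray(sex)
        individuals = np.asarray(individuals)
        if not (self.y.size == sex.size == individuals.size):
            raise ValueError("values, sex and individuals must have equal length")
        self._groups = []
        self._ind_sex = {}
        order = np.arange(self.y.size) if order is None else np.asarray(order)
        for ind in pd.unique(individuals):
            sel = np.flatnonzero(individuals == ind)
            sel = sel[np.argsort(order[sel], kind="stable")]
            sexes = set(sex[sel].tolist())
            if len(sexes) != 1:
                raise ValueError(f"individual {ind!r} has inconsistent sex labels")
            self._ind_sex[ind] = sexes.pop()
            self._groups.append((ind, sel))
        levels = sorted(set(self._ind_sex.values()))
        if len(levels) != 2:
            raise ValueError("exactly two sex levels are required")
        for lev in levels:
            if sum(s == lev for s in self._ind_sex.values()) < 2:
                raise ValueError("need >= 2 individuals per sex")
        # male-minus-female coding when labels are F/M (sorted), else second level
        self._levels = levels
        self.sex_indicator = {ind: float(s == levels[1]) for ind, s in self._ind_sex.items()}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str, sex_col: str = "sex",
                       individual_col: str = "individual", order_col: str | None = "time_days"):
        order = df[order_col].to_numpy() if order_col and order_col in df else None
        return cls(df[value_col].to_numpy(), df[sex_col].to_numpy(),
                   df[individual_col].to_numpy(), order=order)

    # -- internals ---------------------------------------------------------

    def _design(self):
        X = np.empty((self.y.size, 2))
        X[:, 0] = 1.0
        for ind, sel in self._groups:
            X[sel, 1] = self.sex_indicator[ind]
        return X

    def _profiled(self, theta: float, rho: float):
        """GLS pieces for W_i = theta 11' + AR1(rho); returns criterion parts."""
        X = self._design()
        p = X.shape[1]
        n = self.y.size
        logdet = 0.0
        xtwx = np.zeros((p, p))
        xtwy = np.zeros(p)
        ytwy = 0.0
        for _, sel in self._groups:
            ni = sel.size
            yi = self.y[sel]
            Xi = X[sel]
            idx = np.arange(ni)
            W = theta + rho ** np.abs(idx[:, None] - idx[None, :])
            try:
                c, low = linalg.cho_factor(W, lower=True)
            except linalg.LinAlgError as exc:  # pragma: no cover
                raise ConvergenceError("covariance not positive definite",
                                       {"theta": theta, "rho": rho}) from exc
            logdet += 2.0 * float(np.log(np.diag(c)).sum())
            Wy = linalg.cho_solve((c, low), yi)
            WX = linalg.cho_solve((c, low), Xi)
            xtwx += Xi.T @ WX
            xtwy += Xi.T @ Wy
            ytwy += float(yi @ Wy)
        beta = np.linalg.solve(xtwx, xtwy)
        rss = max(ytwy - float(beta @ xtwy), 1e-300)
        sign, logdet_x = np.linalg.slogdet(xtwx)
        crit = logdet + logdet_x + (n - p) * np.log(rss)
        return crit, beta, rss, xtwx

    # -- fitting -----------------------------------------------------------

    def fit(self, rho: float | None = None, start=(0.0, 0.3),
            maxiter: int = 2000) -> MixedModelResult:
        """REML fit; pass ``rho`` to hold the AR(1) parameter fixed."""
        n = self.y.size
        p = 2

        if rho is None:
            def objective(x):
                th = np.exp(np.clip(x[0], -30.0, 30.0))
                r = np.tanh(x[1])
                return self._profiled(th, r)[0]

            x0 = np.array([np.log(max(start[0], 1e-6)) if start[0] > 0 else 0.0,
                           np.arctanh(np.clip(start[1], -0.99, 0.99))])
            opts = {"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-10}
            res = optimize.minimize(objective, x0, method="Nelder-Mead", options=opts)
            if not res.success:  # restart once from the best point found
                res = optimize.minimize(objective, res.x, method="Nelder-Mead",
                                        options=opts)
            if not res.success:
                raise ConvergenceError("REML optimization did not converge", res)
            theta = float(np.exp(np.clip(res.x[0], -30.0, 30.0)))
            rho_hat = float(np.tanh(res.x[1]))
            converged = bool(res.success)
        else:
            def objective(x):
                return self._profiled(np.exp(np.clip(x[0], -30.0, 30.0)), rho)[0]

            res = optimize.minimize_scalar(
                lambda t: self._profiled(np.exp(np.clip(t, -30, 30)), rho)[0],
                bounds=(-15.0, 15.0), method="bounded")
            theta = float(np.exp(np.clip(res.x, -30.0, 30.0)))
            rho_hat = float(rho)
            converged = True

        if abs(rho_hat) > 0.99:
            warnings.warn("AR(1) parameter at the boundary (|rho| -> 1)")

        crit, beta, rss, xtwx = self._profiled(theta, rho_hat)
        sigma2 = rss / (n - p)
        cov_beta = sigma2 * np.linalg.inv(xtwx)
        se = float(np.sqrt(cov_beta[1, 1]))
        f = float((beta[1] / se) ** 2)
        m = len(self._groups)
        df_den = m - 2
        p_value = float(stats.f.sf(f, 1, df_den))
        return MixedModelResult(
            sex_effect=float(beta[1]),
            sex_se=se,
            intercept=float(beta[0]),
            var_individual=float(theta * sigma2),
            var_residual=float(sigma2),
            rho=rho_hat,
            f_statistic=f,
            df_num=1,
            df_den=df_den,
            p_value=p_value,
            n_observations=int(n),
            n_individuals=int(m),
            reml_criterion=float(crit),
            converged=converged,
        )
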