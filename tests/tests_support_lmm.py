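"""Shared simulator for mixed-model calibration tests."""

import numpy as np
import pandas as pd


def simulate_lmm(seed, n_per_sex=6, n_obs=20, effect=0.5, rho=0.5,
                 tau=0.15, sigma=0.2):
    """Balanced two-sex design with random intercepts and AR(1) residuals."""
    rng = np.random.default_rng(seed)
    rows = []
    for s, base in (("F", 0.0), ("M", effect)):
        for i in range(n_per_sex):
            b = rng.normal(0.0, tau)
            e = np.empty(n_obs)
            e[0] = rng.normal(0.0, sigma)
            for t in range(1, n_obs):
                e[t] = rho * e[t - 1] + rng.normal(0.0, sigma * np.sqrt(1 - rho**2))
            rows.append(pd.DataFrame({
                "individual": f"{s}{i}", "sex": s,
                "time_days": np.arange(n_obs, dtype=float),
                "value": base + b + e,
            }))
    return pd.concat(rows, ignore_index=True)
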