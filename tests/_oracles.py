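"""Independent brute-force oracles shared across test modules."""

import numpy as np
import pandas as pd


def brute_force_logpl(df: pd.DataFrame, covs, beta, ties="efron") -> float:
    """Log partial likelihood by explicit risk-set scan over all intervals.

    Intentionally naive — O(events * rows) — and structurally independent of
    the package's difference-array implementation.
    """
    beta = np.asarray(beta, dtype=float)
    X = df[list(covs)].to_numpy(dtype=float)
    eta = X @ beta
    w = np.exp(eta)
    start = df["start"].to_numpy(float)
    stop = df["stop"].to_numpy(float)
    status = df["status"].to_numpy(int)
    ll = 0.0
    for t in np.unique(stop[status == 1]):
        dead = (status == 1) & (stop == t)
        risk = (start < t) & (t <= stop)
        m = int(dead.sum())
        ll += eta[dead].sum()
        s_all = w[risk].sum()
        s_dead = w[dead].sum()
        for r in range(m):
            frac = r / m if ties == "efron" else 0.0
            ll -= np.log(s_all - frac * s_dead)
    return float(ll)
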