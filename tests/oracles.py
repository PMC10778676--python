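"""Independent brute-force / closed-form oracles used by the test suite.

These deliberately avoid the code paths they check: grid-search
minimisation instead of derivative-based least squares, adaptive quadrature
instead of the closed-form AUC, and a hand-rolled studentized-range
computation instead of the packaged Tukey routine.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.stats import studentized_range


def grid_fit_hydrolysis(t, c, cinf_grid=None, k_grid=None):
    """Brute-force least-squares over a (C_inf, k) grid."""
    if cinf_grid is None:
        cinf_grid = np.linspace(40.0, 120.0, 161)
    if k_grid is None:
        k_grid = np.geomspace(0.001, 0.2, 241)
    cc, kk = np.meshgrid(cinf_grid, k_grid, indexing="ij")
    pred = cc[..., None] * (1.0 - np.exp(-kk[..., None] * t))
    rss = np.sum((pred - c) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    return float(cinf_grid[i]), float(k_grid[j])


def grid_fit_digestogram(t, v, mu0_grid=None, muinf_grid=None, k_grid=None):
    """Brute-force least-squares over a (mu0, mu_inf, k) grid."""
    if mu0_grid is None:
        mu0_grid = np.linspace(1500.0, 2500.0, 51)
    if muinf_grid is None:
        muinf_grid = np.linspace(0.0, 500.0, 51)
    if k_grid is None:
        k_grid = np.geomspace(0.5, 8.0, 121)
    best = (np.inf, None)
    decay = np.exp(-k_grid[:, None] * t)  # (k, t)
    for mu0, mu_inf in itertools.product(mu0_grid, muinf_grid):
        pred = mu_inf + (mu0 - mu_inf) * decay
        rss = np.sum((pred - v) ** 2, axis=-1)
        j = int(np.argmin(rss))
        if rss[j] < best[0]:
            best = (rss[j], (float(mu0), float(mu_inf), float(k_grid[j])))
    return best[1]


def quadrature_auc(cinf, k, t0=0.0, tf=240.0):
    """Adaptive quadrature of the first-order hydrolysis model."""
    val, _ = quad(lambda t: cinf * (1.0 - np.exp(-k * t)), t0, tf,
                  limit=200, epsabs=1e-12, epsrel=1e-12)
    return val


def tukey_kramer_pvalues(samples: list[np.ndarray]) -> np.ndarray:
    """Pairwise Tukey–Kramer p-values from the studentized-range distribution."""
    k = len(samples)
    ns = np.array([len(s) for s in samples])
    means = np.array([s.mean() for s in samples])
    df = int(ns.sum() - k)
    s2 = sum(((s - s.mean()) ** 2).sum() for s in samples) / df
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(s2 / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            p[i, j] = p[j, i] = studentized_range.sf(q, k, df)
    return p
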