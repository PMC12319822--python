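"""Independent reference implementations used only by the tests.

Each oracle re-derives its quantity from first principles (brute-force
search, direct quadrature, textbook critical-value formulas) without
touching the package's own code paths, so agreement is evidence of
correctness rather than of shared bugs.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special, stats


def gesd_oracle(values, alpha=0.05, max_outlier_fraction=0.2):
    """Brute-force sequential ESD: evaluate every prefix removal.

    Removes the extreme point one step at a time, recording the test
    statistic of each step, then independently computes every critical
    value and returns the removed indices of the largest passing
    prefix.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    k_max = min(int(np.ceil(max_outlier_fraction * n)), n - 2)
    order = []
    stats_r = []
    remaining = list(range(n))
    for _ in range(k_max):
        xi = x[remaining]
        mu = xi.mean()
        sd = xi.std(ddof=1)
        if sd == 0:
            break
        devs = np.abs(xi - mu)
        j = int(np.argmax(devs))
        stats_r.append(devs[j] / sd)
        order.append(remaining.pop(j))
    best = 0
    for i, r in enumerate(stats_r, start=1):
        m = n - i + 1
        p = 1 - alpha / (2 * m)
        t = stats.t.ppf(p, m - 2)
        lam = (m - 1) * t / np.sqrt(m * (m - 2 + t * t))
        if r > lam:
            best = i
    return set(order[:best])


def grubbs_critical_oracle(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value straight from the t distribution."""
    t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
    return (n - 1) * np.sqrt(t2 / (n * (n - 2 + t2)))


def correlation_density(r: float, rho: float, n: int) -> float:
    """Hotelling's exact sampling density of the Pearson correlation."""
    c = (
        (n - 2)
        * special.gamma(n - 1)
        / (np.sqrt(2 * np.pi) * special.gamma(n - 0.5))
    )
    return (
        c
        * (1 - rho**2) ** ((n - 1) / 2)
        * (1 - r**2) ** ((n - 4) / 2)
        * (1 - rho * r) ** (1.5 - n)
        * special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r) / 2)
    )


def bf10_quad_oracle(r: float, n: int, kappa: float = 1.0) -> float:
    """Adaptive quadrature of the likelihood over the stretched-beta prior."""
    a = 1.0 / kappa
    norm = 2 ** (2 * a - 1) * special.beta(a, a)

    def integrand(rho):
        return correlation_density(r, rho, n) * (1 - rho**2) ** (a - 1) / norm

    num, _ = integrate.quad(integrand, -1, 1, limit=400)
    return num / correlation_density(r, 0.0, n)
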