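"""Independent brute-force oracles used by the test suite.

Deliberately written with different numerical machinery than the package
(explicit Bonnet recursion instead of polynomial evaluation helpers,
plain sums-of-squares instead of library ANOVA) so that agreement is a
genuine cross-check of two routes.
"""

import numpy as np


def legendre_recursion(x, n_max):
    """P_1..P_n_max at x via the Bonnet three-term recursion."""
    P = [np.ones_like(x), np.asarray(x, float)]
    for n in range(2, n_max + 1):
        P.append(((2 * n - 1) * x * P[-1] - (n - 1) * P[-2]) / n)
    return P[1:]


def spline_laplacian_direct(v, positions, m=4, lam=1e-5, n_terms=50):
    """Perrin spherical-spline surface Laplacian of one potential vector,
    by direct Legendre-series summation at each electrode (unit sphere)."""
    n_ch = len(positions)
    x = np.clip(positions @ positions.T, -1.0, 1.0)
    P = legendre_recursion(x, n_terms)
    G = np.zeros_like(x)
    H = np.zeros_like(x)
    for n in range(1, n_terms + 1):
        c = (2 * n + 1) / (4 * np.pi)
        G += c / (n * (n + 1)) ** m * P[n - 1]
        H += c / (n * (n + 1)) ** (m - 1) * P[n - 1]
    A = np.zeros((n_ch + 1, n_ch + 1))
    A[:n_ch, :n_ch] = G + lam * np.eye(n_ch)
    A[:n_ch, -1] = 1.0
    A[-1, :n_ch] = 1.0
    sol, *_ = np.linalg.lstsq(A, np.concatenate([v, [0.0]]), rcond=None)
    return H @ sol[:n_ch]


def rm_anova_f_bruteforce(x):
    """One-way repeated-measures F by explicit sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_treat = n * ((x.mean(axis=0) - grand) ** 2).sum()
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand
    ss_err = (resid**2).sum()
    ms_treat = ss_treat / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_treat / ms_err
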