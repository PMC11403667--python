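"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own quadrature/estimation code
paths: Boltzmann statistics come from dense midpoint sums, the KS distance
is computed directly from the weighted empirical CDF, and convergence
statistics are recomputed from raw grids with plain loops.
"""

from __future__ import annotations

import numpy as np

KB = 0.0083144626


def boltzmann_cdf_factory(potential, temperature=300.0, n=20001):
    """CDF of exp(-f0(z)/kT)/Z on the potential's z range, by midpoint sums."""
    lo, hi = potential.z_range
    edges = np.linspace(lo, hi, n + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    p = np.exp(-(potential.evaluate(mid) - potential.evaluate(mid).min()) / (KB * temperature))
    cum = np.concatenate([[0.0], np.cumsum(p)])
    cum /= cum[-1]

    def cdf(v):
        return np.interp(v, edges, cum)

    return cdf


def boltzmann_moment(potential, power, temperature=300.0, n=200001):
    """<z^power> under exp(-f0/kT)/Z by dense midpoint quadrature."""
    lo, hi = potential.z_range
    edges = np.linspace(lo, hi, n + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    p = np.exp(-(potential.evaluate(mid) - potential.evaluate(mid).min()) / (KB * temperature))
    p /= p.sum()
    return float(np.sum(p * mid**power))


def weighted_ks(values, weights, cdf) -> float:
    """Kolmogorov-Smirnov distance of a weighted sample against a CDF."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    ecdf = np.cumsum(w)
    ecdf /= ecdf[-1]
    target = cdf(v)
    return float(
        max(np.max(np.abs(ecdf - target)), np.max(np.abs(ecdf - w / w.sum() - target)))
    )


def ks_uniform(values, weights, lo, hi) -> float:
    return weighted_ks(values, weights, lambda v: np.clip((v - lo) / (hi - lo), 0, 1))


def riemann_delta_g(potential, temperature=300.0, boundary=3.0, n=100000) -> float:
    """Partition free energy by an n-node midpoint Riemann sum."""
    lo, hi = potential.z_range
    edges = np.linspace(lo, hi, n + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    dz = edges[1] - edges[0]
    f = potential.evaluate(mid)
    w = np.exp(-(f - f.min()) / (KB * temperature))
    inside = np.abs(mid) < boundary
    i_b = w[inside].sum() * dz
    i_w = w[~inside].sum() * dz
    v_b = 2 * boundary
    v_w = (hi - lo) - v_b
    return float(-KB * temperature * np.log((i_b / i_w) * (v_w / v_b)))


def convergence_stats_bruteforce(f_end, f_prev, grid_z, water_cut=3.0):
    """The three convergence statistics recomputed with explicit loops."""
    f_end = np.asarray(f_end, float).copy()
    f_prev = np.asarray(f_prev, float).copy()
    for f in (f_end, f_prev):
        water = [fi for zi, fi in zip(grid_z, f) if abs(zi) >= water_cut]
        f -= sum(water) / len(water)
    n = len(grid_z)
    max_asym = 0.0
    sq_half = 0.0
    sq_diff = 0.0
    for i in range(n):
        j = n - 1 - i  # grid symmetric about 0: z[j] == -z[i]
        d = f_end[i] - f_end[j]
        max_asym = max(max_asym, abs(d))
        sq_half += (0.5 * d) ** 2
        sq_diff += (f_end[i] - f_prev[i]) ** 2
    return max_asym, (sq_half / n) ** 0.5, (sq_diff / n) ** 0.5
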