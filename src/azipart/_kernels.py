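"""Inner integration loop for the overdamped Langevin propagator.

The step kernel is compiled with numba when available; the pure-Python
fallback is identical code (same floating-point operations in the same
order), so trajectories are bit-identical either way.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def _step_chunk(
    z0,
    noise,
    mob_dt,
    centers,
    amplitudes,
    inv_w2,
    z_min,
    z_max,
    fbias,
    inv_dz,
    out,
):
    """Advance ``noise.size`` overdamped Euler-Maruyama steps from ``z0``.

    ``mob_dt`` = dt/friction.  ``fbias`` is the bias force (-dV/dz) sampled
    on the uniform grid [z_min, z_max]; linear interpolation in between.
    Positions are written into ``out`` (one per step, post-update) and the
    final position is returned.  Reflecting walls at the range edges.
    Returns the maximum absolute single-step displacement for the caller's
    stability check.
    """
    z = z0
    span = z_max - z_min
    max_dz = 0.0
    n_grid = fbias.shape[0]
    for i in range(noise.shape[0]):
        # model force: -d/dz sum a_k exp(-(z-c_k)^2/(2 w_k^2))
        force = 0.0
        for k in range(centers.shape[0]):
            d = z - centers[k]
            force += amplitudes[k] * np.exp(-0.5 * d * d * inv_w2[k]) * d * inv_w2[k]
        # bias force by linear interpolation
        if fbias.shape[0] > 1:
            x = (z - z_min) * inv_dz
            j = int(x)
            if j < 0:
                j = 0
            elif j > n_grid - 2:
                j = n_grid - 2
            frac = x - j
            force += fbias[j] * (1.0 - frac) + fbias[j + 1] * frac
        dz = mob_dt * force + noise[i]
        if abs(dz) > max_dz:
            max_dz = abs(dz)
        z = z + dz
        # reflecting boundaries
        while z < z_min or z > z_max:
            if z < z_min:
                z = 2.0 * z_min - z
            else:
                z = 2.0 * z_max - z
        out[i] = z
    return max_dz


_EMPTY_GRID = np.zeros(1)


def step_chunk(z0, noise, mob_dt, potential_arrays, z_min, z_max, fbias, inv_dz, out):
    """Python-facing wrapper; ``potential_arrays`` = (centers, amplitudes, inv_w2)."""
    centers, amplitudes, inv_w2 = potential_arrays
    if fbias is None:
        fbias, inv_dz = _EMPTY_GRID, 0.0
    return _step_chunk(
        z0, noise, mob_dt, centers, amplitudes, inv_w2,
        z_min, z_max, fbias, inv_dz, out,
    )
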