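"""Compiled numerical kernels.

The overdamped Langevin integrator lives here so the tight per-step loop can
be JIT-compiled; everything user-facing wraps it from :mod:`surfprop.synthetic`.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def langevin_trajectory(
    seed,
    n_steps,
    n_equil,
    stride,
    dt,
    diffusion,
    kT,
    lo,
    hi,
    r0,
    depth,
    center,
    width,
    wall_pos,
    wall_scale,
    k_bias,
    r_bias,
):
    """Euler-Maruyama overdamped Langevin on the slab landscape plus harmonic bias.

    Reflecting boundaries at ``lo``/``hi``; returns every ``stride``-th
    post-equilibration coordinate. Seeding ``np.random`` inside the jitted
    function gives a private, reproducible stream.
    """
    np.random.seed(seed)
    step_sd = np.sqrt(2.0 * diffusion * dt)
    mobility = diffusion / kT
    inv_w2 = 1.0 / (width * width)
    r = r0
    n_out = n_steps // stride
    out = np.empty(n_out)
    iout = 0
    for step in range(n_equil + n_steps):
        dr = r - center
        grad = depth * dr * inv_w2 * np.exp(-0.5 * dr * dr * inv_w2)
        grad += np.exp((r - wall_pos) / wall_scale) / wall_scale
        grad += k_bias * (r - r_bias)
        r = r - mobility * grad * dt + step_sd * np.random.normal()
        while r < lo or r > hi:
            if r < lo:
                r = 2.0 * lo - r
            else:
                r = 2.0 * hi - r
        if step >= n_equil and (step - n_equil + 1) % stride == 0:
            out[iout] = r
            iout += 1
    return out
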