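"""Numba inner loop for the per-step network update.

One fused kernel advances the whole network by a block of steps: sparse
E->E summation, inhibitory-partner pooling, leaky membrane integration,
adaptation, piecewise-linear output, slow global inhibition, and (during
learning) the two-threshold LTP/LTD weight update.  All randomness enters
through the pre-generated ``noise`` array, so results are exactly
reproducible from the caller's NumPy generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_steps(indptr, indices, wdata,
              V_e, V_i, omega, O, G,
              stim, noise,
              side, n_areas,
              tau_e, tau_i, tau_adapt, tau_global,
              k_input, k_noise, k_global, inhib_gain,
              thresh, alpha_adapt, inhib_radius,
              plast_on, theta_pre, theta_plus, theta_minus, dw, w_max,
              check_baseline, watch_a, watch_b, g_thresh):
    """Advance the network by up to ``noise.shape[0]`` steps in place.

    Returns the number of steps actually taken (early exit when
    ``check_baseline`` and the global-inhibition levels of both watch
    areas fall below ``g_thresh``).
    """
    n_e = V_e.shape[0]
    cpa = side * side
    n_steps = noise.shape[0]
    E_in = np.empty(n_e)
    pool = np.empty(n_e)
    O_new = np.empty(n_e)

    for t in range(n_steps):
        # excitatory input: sparse matrix-vector product over old outputs
        for i in range(n_e):
            acc = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                acc += wdata[k] * O[indices[k]]
            E_in[i] = acc

        # each inhibitory partner pools e-output over its neighbourhood
        for a in range(n_areas):
            base = a * cpa
            for r in range(side):
                r0 = r - inhib_radius
                if r0 < 0:
                    r0 = 0
                r1 = r + inhib_radius + 1
                if r1 > side:
                    r1 = side
                for c in range(side):
                    c0 = c - inhib_radius
                    if c0 < 0:
                        c0 = 0
                    c1 = c + inhib_radius + 1
                    if c1 > side:
                        c1 = side
                    s = 0.0
                    for rr in range(r0, r1):
                        row = base + rr * side
                        for cc in range(c0, c1):
                            s += O[row + cc]
                    pool[base + r * side + c] = s

        # membrane integration (leaky, Euler, dt = 1 step)
        for i in range(n_e):
            V_i[i] += (pool[i] - V_i[i]) / tau_i
        for a in range(n_areas):
            g_fb = k_global * G[a]
            base = a * cpa
            for ii in range(cpa):
                i = base + ii
                i_out = V_i[i] if V_i[i] > 0.0 else 0.0
                target = (k_input * (E_in[i] - inhib_gain * i_out - g_fb + stim[i])
                          + k_noise * noise[t, i])
                V_e[i] += (target - V_e[i]) / tau_e

        # adaptation tracks the cell's own output; output is a clipped
        # linear function of potential minus (threshold + adaptation)
        for i in range(n_e):
            omega[i] += (O[i] - omega[i]) / tau_adapt
            x = V_e[i] - thresh - alpha_adapt * omega[i]
            O_new[i] = 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)

        # LTP/LTD: presynaptic = outputs that produced this step's input,
        # postsynaptic = the freshly updated membrane potential
        if plast_on:
            for i in range(n_e):
                v_post = V_e[i]
                if v_post >= theta_plus:
                    for k in range(indptr[i], indptr[i + 1]):
                        if O[indices[k]] >= theta_pre:
                            w = wdata[k] + dw       # LTP
                            wdata[k] = w if w < w_max else w_max
                        else:
                            w = wdata[k] - dw       # heterosynaptic LTD
                            wdata[k] = w if w > 0.0 else 0.0
                elif v_post >= theta_minus:
                    for k in range(indptr[i], indptr[i + 1]):
                        if O[indices[k]] >= theta_pre:
                            w = wdata[k] - dw       # homosynaptic LTD
                            wdata[k] = w if w > 0.0 else 0.0

        for i in range(n_e):
            O[i] = O_new[i]

        # slow area-level regulation tracks total excitatory output
        for a in range(n_areas):
            s = 0.0
            base = a * cpa
            for ii in range(cpa):
                s += O[base + ii]
            G[a] += (s - G[a]) / tau_global

        if check_baseline and G[watch_a] < g_thresh and G[watch_b] < g_thresh:
            return t + 1
    return n_steps
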