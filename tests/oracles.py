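"""Independent brute-force reference implementations used as test oracles.

Everything here is written directly from the documented update equations,
with dense arrays and explicit Python loops, deliberately sharing no code
with the package's fused simulation kernel.
"""

import numpy as np


def scalar_plasticity(w, pre, post, p):
    """Per-synapse three-branch LTP/LTD truth table."""
    active = pre >= p.theta_pre
    if active and post >= p.theta_plus:
        w = w + p.delta_w
    elif active and p.theta_minus <= post < p.theta_plus:
        w = w - p.delta_w
    elif not active and post >= p.theta_plus:
        w = w - p.delta_w
    return min(max(w, 0.0), p.w_max)


def dense_reference_run(network, state, stim_vec, noise, dyn, plast=None):
    """Dense, loop-based re-implementation of the per-step network update.

    Mutates ``state`` (same contract as the package) and returns the dense
    weight matrix after the run.  ``noise`` is (n_steps, n_e).
    """
    side = network.side
    cpa = side * side
    n_areas = network.n_areas
    W = network.weights.toarray()
    exists = network.weights.toarray() > 0  # pattern incl. zero-weight? no:
    # the sparsity pattern must come from the structure, not the values
    exists = np.zeros_like(W, dtype=bool)
    rows, cols = network.weights.nonzero()
    exists[rows, cols] = True
    # explicit zeros in the CSR are still synapses
    coo = network.weights.tocoo()
    exists[coo.row, coo.col] = True

    V_e, V_i, omega, O, G = (state.V_e, state.V_i, state.omega, state.O,
                             state.G)
    radius = (network.kernel.inhib_extent - 1) // 2
    for t in range(noise.shape[0]):
        E_in = W @ O
        pool = np.empty_like(V_e)
        for a in range(n_areas):
            grid = O[a * cpa:(a + 1) * cpa].reshape(side, side)
            for r in range(side):
                for c in range(side):
                    r0, r1 = max(0, r - radius), min(side, r + radius + 1)
                    c0, c1 = max(0, c - radius), min(side, c + radius + 1)
                    pool[a * cpa + r * side + c] = grid[r0:r1, c0:c1].sum()
        V_i += (pool - V_i) / dyn.tau_i
        i_out = np.maximum(V_i, 0.0)
        area_of = np.repeat(np.arange(n_areas), cpa)
        target = (dyn.k_input * (E_in - network.kernel.inhib_gain * i_out
                                 - dyn.k_global * G[area_of] + stim_vec)
                  + dyn.k_noise * noise[t])
        V_e += (target - V_e) / dyn.tau_e
        omega += (O - omega) / dyn.tau_adapt
        O_new = np.clip(V_e - dyn.output_threshold - dyn.alpha_adapt * omega,
                        0.0, 1.0)
        if plast is not None and plast.enabled:
            rr, cc = np.nonzero(exists)
            for r, c in zip(rr, cc):
                W[r, c] = scalar_plasticity(W[r, c], O[c], V_e[r], plast)
        O[:] = O_new
        for a in range(n_areas):
            G[a] += (O[a * cpa:(a + 1) * cpa].sum() - G[a]) / dyn.tau_global
    return W


def ca_members_bruteforce(response, gamma, n_areas, cpa):
    """Exhaustive evaluation of the theta-rule over every cell."""
    members = {}
    for a in range(n_areas):
        block = response[a * cpa:(a + 1) * cpa]
        peak = max(block) if len(block) else 0.0
        sel = []
        if peak > 0:
            for i, v in enumerate(block):
                if v >= gamma * peak:
                    sel.append(i)
        members[a] = sel
    return members
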