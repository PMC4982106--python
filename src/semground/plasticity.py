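"""Hebbian long-term potentiation / depression of E->E synapses.

The rule is a discrete two-threshold (Artola/Singer-type) truth table
evaluated per existing synapse once per simulation step:

========================  =========================  ================
presynaptic output        postsynaptic potential     weight change
========================  =========================  ================
>= theta_pre (active)     >= theta_plus              +delta_w (LTP)
>= theta_pre              [theta_minus, theta_plus)  -delta_w (homosynaptic LTD)
<  theta_pre (inactive)   >= theta_plus              -delta_w (heterosynaptic LTD)
otherwise                                            unchanged
========================  =========================  ================

Weights are clipped to [0, w_max]; synapses are never created or removed.
Because uncorrelated background noise visits the LTD bands far more often
than the coincidence branch, its net effect is to weaken weights, which
counteracts unbounded assembly growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


@dataclass(frozen=True)
class PlasticityParams:
    theta_pre: float = 0.05
    theta_plus: float = 0.30
    theta_minus: float = 0.28
    delta_w: float = 0.008
    w_max: float = 1.2
    enabled: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.theta_minus <= self.theta_plus:
            raise ValueError("need 0 <= theta_minus <= theta_plus")
        if self.delta_w <= 0 or self.w_max <= 0:
            raise ValueError("delta_w and w_max must be positive")


def hebbian_update(weights: sp.csr_matrix, pre_outputs: np.ndarray,
                   post_potentials: np.ndarray,
                   params: PlasticityParams) -> sp.csr_matrix:
    """Apply one LTP/LTD step to every existing synapse (vectorised).

    ``weights`` rows index postsynaptic cells, columns presynaptic cells.
    Returns a new CSR matrix with the same sparsity pattern; explicit
    zeros are kept (a synapse at weight 0 still exists and may recover).
    """
    params.validate()
    if pre_outputs.shape[0] != weights.shape[1] or \
            post_potentials.shape[0] != weights.shape[0]:
        raise ValueError("pre/post arrays misaligned with weight matrix")
    if not params.enabled:
        return weights.copy()

    row_of = np.repeat(np.arange(weights.shape[0]), np.diff(weights.indptr))
    pre_active = pre_outputs[weights.indices] >= params.theta_pre
    post = post_potentials[row_of]
    ltp = pre_active & (post >= params.theta_plus)
    homo_ltd = pre_active & (post >= params.theta_minus) & (post < params.theta_plus)
    hetero_ltd = ~pre_active & (post >= params.theta_plus)

    data = weights.data.copy()
    data[ltp] += params.delta_w
    data[homo_ltd | hetero_ltd] -= params.delta_w
    np.clip(data, 0.0, params.w_max, out=data)
    return sp.csr_matrix((data, weights.indices.copy(), weights.indptr.copy()),
                         shape=weights.shape)
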