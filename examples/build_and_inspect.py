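"""Build the 12-area network and inspect its architecture.

The model covers six perisylvian (spoken word-form) and six extrasylvian
(semantic) areas; adjacent areas within each sensorimotor stream are
linked, and the four multimodal hubs are linked pairwise across systems.
"""

import numpy as np

import semground as sg
from semground.areas import Area, level_of, system_of

net = sg.build_network(seed=42)

print(f"excitatory cells : {net.n_excitatory}  "
      f"(12 areas x {net.side}x{net.side})")
print(f"inhibitory cells : {net.n_inhibitory}  (one partner per e-cell)")
print(f"E->E synapses    : {net.weights.nnz}")
print(f"mean weight      : {net.mean_weight():.3f} "
      f"(uniform in (0, {net.w_init_max}])")
print()
print(f"{'area':6s} {'system':14s} {'level':10s} degree  neighbours")
for area in Area:
    nbrs = ", ".join(sorted(n.name for n in net.graph.neighbours(area)))
    print(f"{area.name:6s} {system_of(area):14s} {level_of(area):10s} "
          f"{net.graph.degree(area):^6d}  {nbrs}")

# Degree tracks the processing level: primary areas have one neighbour,
# secondary two, multimodal hubs three - the structural root of the
# higher assembly-cell density that hubs develop during learning.
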