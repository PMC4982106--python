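# semground

A neurocomputational model of word learning and semantic grounding in
action and perception. `semground` simulates how distributed
lexico-semantic circuits — Hebbian cell assemblies (CAs) — emerge in a
network of 12 interconnected cortical areas when spoken word forms are
repeatedly experienced together with their visual referents (object
words) or with self-performed actions (action words), and provides the
statistics used to quantify the resulting circuit topographies.

It is aimed at computational neuroscientists and psycholinguists studying
the two-sided evidence on cortical semantics: category-*specific*
activation of modality-preferential (visual vs motor) areas versus
category-*general* activation of multimodal "semantic hub" areas. In the
model both behaviours arise from one mechanism — correlation-driven
Hebbian learning inside a realistic between-area connectivity graph.

## The model

Twelve 25×25 sheets of graded-response cells represent a perisylvian
word-form system (auditory A1–AB–PB, articulatory M1_i–PM_i–PF_i) and an
extrasylvian semantic system (visual V1–TO–AT, dorsal motor
M1_L–PM_L–PF_L). Next-neighbour links connect adjacent areas in each
stream; four long-distance links connect the multimodal hubs (PB, PF_i,
AT, PF_L) pairwise across systems. Connectivity is sparse, patchy and
topographic: a synapse between cells at grid distance *d* exists with
probability *A*·exp(−d²/2σ²) inside a 19×19 neighbourhood.

Cells are leaky integrators with piecewise-linear output in [0, 1],
adaptation, local lateral inhibition (one inhibitory partner per cell,
pooling a 5×5 neighbourhood) and slow area-level global inhibition, with
uniform noise everywhere at all times. All E→E synapses follow a discrete
two-threshold LTP/LTD rule: coincident strong pre- and post-activity
potentiates; presynaptic activity against weakly depolarised post, or
strong post without presynaptic support, depresses.

A learning trial stimulates 19-cell patterns (~3 % of an area) in A1 and
M1_i plus V1 (object words) or M1_L (action words) for 16 steps
(~300 ms), while the non-partaking primary area receives a fresh random
mask; the next trial starts once the global-inhibition levels of PF_i and
PB fall below 0.65. After training, each word's CA is extracted by a
word-form-only probe: cell *x* in area *A* belongs to the CA of word *w*
iff its time-averaged response over 15 steps reaches
θ_A(w) = γ·max over A of the response, with γ = 0.5. Count tables feed
within-subject (instance) repeated-measures ANOVAs and
Bonferroni-corrected paired comparisons.

See `docs/methods.md` for equations, parameter rationale and limitations.

## Worked example

```bash
python examples/word_learning.py
```

trains one instance at 60 presentations per word (about a minute) and
prints the per-area mean assembly sizes:

```
trained: 144 (word x area) assembly entries, mean weight now 0.089

mean assembly-cell counts per area (object vs action words):
category  object  action
A1          19.0    19.3
AB           5.5     7.3
PB           5.3     6.3
PF_i         6.8     5.8
PM_i         8.7     8.3
M1_i        19.2    19.2
V1           0.0     0.0
TO           0.2     0.3
AT           2.0     2.7
PF_L         2.0     3.0
PM_L         0.2     0.3
M1_L         0.0     0.0
```

The stimulated word-form primaries (A1, M1_i) carry their 19-cell
patterns; after only 60 presentations distributed circuits are already
spreading through the secondary areas into the four multimodal hubs,
which end up with the densest assemblies relative to their input — the
hub signature. Longer training (the full protocol is 3000 presentations
per word) deepens the category-specific reach into the semantic streams.

Other examples: `examples/build_and_inspect.py` (architecture),
`examples/ignition.py` (recognition as assembly ignition),
`examples/topography_statistics.py` (ANOVA + planned comparisons).
A thin CLI mirrors the library: `semground build|train|probe|stats|experiment`.

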