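# Model and methods

## The model in one paragraph

`semground` simulates word learning and semantic grounding in a network of
12 interconnected cortical areas: an auditory stream (A1–AB–PB) and an
articulatory-motor stream (M1_i–PM_i–PF_i) form the perisylvian
(word-form) system; a ventral visual stream (V1–TO–AT) and a dorsolateral
motor stream (M1_L–PM_L–PF_L) form the extrasylvian (semantic) system.
Adjacent areas within a stream are reciprocally linked, and the four
multimodal hubs (PB, PF_i, AT, PF_L) are linked pairwise across systems,
so area degree rises from 1 (primary) through 2 (secondary) to 3
(multimodal). Each area is a 25×25 sheet of graded-response excitatory
cells, each with one inhibitory partner. Words are learnt by repeatedly
co-stimulating three primary areas — A1 + M1_i (the spoken word form)
plus V1 for object words or M1_L for action words — while Hebbian LTP/LTD
shapes the sparse, patchy, topographic synaptic matrix. The emerging
"cell assemblies" (CAs) are measured by probing the frozen network with
word-form input and thresholding each cell's time-averaged response at a
fraction γ = 0.5 of its area's maximum.

## Dynamics

Per simulation step (~18.75 ms; a 16-step learning trial ≈ 300 ms), the
membrane potential of excitatory cell *x* relaxes with time constant
`tau_e` toward

```
k_input·( E_in(x) − inhib_gain·[V_i(x)]₊ − k_global·G(area) + stim(x) )
+ k_noise·η,   η ~ U(−noise_amplitude, +noise_amplitude)
```

where `E_in` is the weighted sum of presynaptic outputs, `V_i` the
inhibitory partner (a leaky integrator of the excitatory output pooled
over a 5×5 neighbourhood, unit gain), and `G` a slow per-area integral of
total excitatory output fed back subtractively to every cell of the area.
Output is a piecewise-linear sigmoid, `O = clip(V − φ − α·ω, 0, 1)`, with
adaptation `ω` tracking the cell's own output with time constant
`tau_adapt`. Uniform noise is present in every cell at every step —
training, inter-trial intervals and probes alike.

A trial ends when the global-inhibition levels of both PF_i and PB drop
below 0.65 (interpreted on G's own scale); relaxation beyond 500 steps
raises an error, which is how runaway excitation surfaces.

## Plasticity

All E→E synapses follow a discrete two-threshold rule, applied once per
step during learning (stimulation **and** inter-trial relaxation; frozen
during probes): with presynaptic output ≥ `theta_pre` and postsynaptic
potential ≥ `theta_plus`, +`delta_w` (LTP); with active pre and post in
[`theta_minus`, `theta_plus`), −`delta_w` (homosynaptic LTD); with
inactive pre and post ≥ `theta_plus`, −`delta_w` (heterosynaptic LTD).
Weights are clipped to [0, `w_max`]; no synapses are created or removed.
The postsynaptic variable is the membrane potential, which allows
sub-threshold depression bands.

## Parameter reconstruction and what anchored it

The source model's exact constants were not available, so every constant
here is a reconstruction, exposed in `ExperimentConfig`/YAML. The
calibration was anchored to explicit behavioural requirements: a 19-cell
pattern ignites its area; activity returns below the 0.65 criterion
within a few hundred steps after every trial; assemblies form within
50–100 presentations and span multiple areas; circuits do not grow
without bound. Within those anchors the decisive, deliberately chosen
features are:

- **Dense within-area, sparse between-area kernels** (`amplitude` 0.30 vs
  `between_amplitude` 0.10, Gaussian σ = 3.7 cells, 19×19 support).
  The recurrent within-area web lets a handful of consistently co-driven
  relay cells amplify one another into a coherent area-level assembly,
  while sparse between-area convergence keeps one-off random patterns
  (the noise masks) poor recruiters.
- **Synaptic ceiling above unity** (`w_max` = 1.2): a single saturated
  synapse can relay ignition across areas, which sparse between-area
  connectivity requires; reverberation is still bounded because the
  sustained-firing condition κ·w_max > 1 + α + inhib_gain is met only for
  cells with several saturated in-assembly synapses, and those are
  quenched by adaptation (α = 2.0, `tau_adapt` 15) plus the slow global
  feedback (`k_global` 0.05, `tau_global` 8).
- **Slow learning with a narrow depression band** (`delta_w` 0.008,
  band [0.28, 0.30)): recruitment is then governed by repetition
  statistics rather than single-trial luck. A wide band below the LTP
  threshold erases the sub-threshold bootstrap tail and stalls assembly
  growth entirely; no band at all lets rare coincidences with the
  fresh-random mask patterns ratchet circuits into the wrong
  sensorimotor stream. The narrow band is the compromise that keeps
  growth alive while still decaying rarely-reinforced pathways.
- **Noise amplitude 0.30** (membrane-potential s.d. ≈ 0.09): large enough
  to let consistently but sub-threshold-driven cells cross the LTP
  threshold occasionally (noise-assisted recruitment), small enough that
  the LTP threshold sits ≈ 3–4 s.d. above baseline so spontaneous
  crossings — and the heterosynaptic pruning they trigger — stay rare.
- **Stimulus drive 4.0**: holds driven pattern cells near saturation for
  the whole 16-step trial despite adaptation, so the word-form input
  stays the strongest, longest presynaptic signal in the network.

## Probing and CA extraction

Identification probes stimulate the A1 + M1_i components, recognition
probes A1 only; no semantic input is ever given at probe time. The probe
stimulus stays on for the full 15-step averaging window (a brief 2-step
presentation under-drives the 3–4 synaptic hops to the far pole of a
circuit at this scale); the window starts at stimulus onset. Membership
follows the per-area, per-word threshold θ = γ·max with ties included and
γ = 0.5; an all-zero area yields an empty set. Because noise runs during
probes, areas without genuine circuit parts still show a noise floor, and
the relative θ-rule can admit a handful of noise cells there; counts in
silent areas should be read as a floor of a few cells, not exact zeros.
One probe per word is the default (`n_probes` averages more).

## The synthetic-data generator (stimuli)

Word patterns are 19 cells per primary area (~3 % of 625), drawn uniformly
without replacement, independent across words and areas — so pattern
overlap is incidental (expected 0.58 cells) and semantic relatedness
between words is absent by design. The non-partaking primary area receives
a fresh random 19-cell mask every trial; semantic deprivation replaces a
word's semantic component with a single static random pattern on every
k-th presentation of that word (k = 4, 3, 2 → semantic fractions 75 %,
66.7 %, 50 %), with the order of all trials globally shuffled. What this
emulates: consistent word-form/referent co-occurrence against a backdrop
of uncorrelated sensorimotor activity. What it does not emulate: graded
prototype variability, correlated features across words, or natural
phonological structure — passing tests therefore speak to the
correlational learning mechanism, not to realistic language input.

## Study design, scaling, and reproducibility

The full protocol is 13 instances × 12 words × 3000 randomly ordered
trials per condition. Desk-scale runs use the `scaled()` profile — 6
instances × 200 trials per word for the main condition, 3 × 100 for the
deprivation and mask-off controls — chosen because assemblies are in
place after 50–100 presentations and the topography statistics stabilise
well before 200. All randomness derives from one run seed through named
substreams (network build, patterns, schedule, training noise, probe
noise) per instance and condition, so identical configurations reproduce
bit-identical weight matrices and count tables.

## Statistics

Balanced fully-within repeated-measures ANOVA by the standard
sums-of-squares decomposition (each effect tested against its interaction
with network instances); no sphericity correction by default
(Greenhouse–Geisser is not applied, matching the uncorrected degrees of
freedom convention). Planned object-vs-action comparisons are two-sided
paired t-tests on per-instance category means, with Bonferroni-corrected
thresholds (α/m at four decimals: 0.0042 for 12 comparisons, 0.0028
for 18).

## Known limitations

- At desk scale the **category dissociation in modality-preferential
  areas is weak**: the semantic primaries (V1, M1_L) are reached by the
  probe only through 3–4 relay hops and their re-activation is marginal,
  and the secondary-area assemblies are capped by the sparse between-area
  convergence pool (~15 candidate cells per word). Hub generality, the
  multimodal-over-secondary density gradient, the perisylvian null and
  multi-area ignition are the robust emergent signatures; the
  dissociation's direction is correct on average but per-instance hub
  competition ("tipping" toward one category) adds large variance.
- Perisylvian primary areas retain their full driven patterns under the
  θ-rule (the 15-step probe saturates them), so primary-area counts are
  not below secondary ones on the word-form side at this scale.
- One excitatory layer per area; no conduction delays; no parietal
  areas; torus-free truncated kernels (edge cells have fewer synapses).
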