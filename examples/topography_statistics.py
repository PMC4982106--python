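"""Repeated-measures analysis of assembly topographies.

Trains a small fleet of independent network instances, tabulates per-area
assembly counts for object vs action words, and runs the within-subject
ANOVAs (factors: peri/extrasylvian, frontal/temporal, modality level,
word type) plus Bonferroni-corrected planned comparisons.
Runs in a few minutes.
"""

from fractions import Fraction

import semground as sg
from semground.experiment import Condition, condition_stats, run_condition

cfg = sg.ExperimentConfig(seed=11).scaled(n_instances=3, reps_per_word=100)
fleet = run_condition(cfg, Condition(Fraction(1), True), progress=True)

stats = condition_stats(fleet)
print("\nfour-way ANOVA (all 12 areas):")
for effect in ("ModSpecificity", "WordType",
               "ExtraPeri:FrontoTemp:ModSpecificity:WordType"):
    e = stats["anova_all12"][effect]
    print(f"  {effect:45s} F({e['df1']},{e['df2']}) = {e['F']:8.2f}  "
          f"p = {e['p']:.4f}")
print(f"\nplanned comparisons (object vs action, "
      f"Bonferroni threshold {stats['bonferroni_12']}):")
for row in stats["planned_comparisons"]:
    print(f"  {row['area']:5s} t({row['df']}) = {row['t']:6.2f}  "
          f"p = {row['p']:.4f}")

# A strong ModSpecificity main effect (multimodal > secondary > primary
# density) is the robust signature at this scale; word-type effects in the
# modality-preferential areas need larger fleets and longer training.
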