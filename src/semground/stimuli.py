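"""Sensorimotor word patterns and the training schedule.

A "word" is a triplet of random cell patterns: an acoustic pattern in A1
and an articulatory pattern in M1_i (the spoken word form), plus a
semantic-grounding pattern in V1 for object-related words or in M1_L for
action-related words.  Each component drives ``cells_per_area`` cells
(default 19, ~3% of a 25 x 25 area).

During training the "non-partaking" primary area (M1_L for object words,
V1 for action words) is masked with a *fresh* random pattern on every
trial, emulating the low correlation between, e.g., ongoing motor activity
and an object word's referent; this decorrelating mask is what keeps
object circuits out of motor cortex and vice versa.  Semantic deprivation
replaces a word's semantic component with a single *static* random
pattern on every k-th presentation of that word (k = 4, 3, 2 for semantic
fractions 75%, 66.7%, 50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .areas import Area
from .dynamics import StimulusFrame

OBJECT, ACTION = "object", "action"

#: Areas stimulated for each category (word form + semantic grounding).
COMPONENT_AREAS = {
    OBJECT: (Area.A1, Area.M1_i, Area.V1),
    ACTION: (Area.A1, Area.M1_i, Area.M1_L),
}
SEMANTIC_AREA = {OBJECT: Area.V1, ACTION: Area.M1_L}
#: The non-partaking primary area that receives the noise mask.
MASK_AREA = {OBJECT: Area.M1_L, ACTION: Area.V1}

SUPPORTED_FRACTIONS = (Fraction(1), Fraction(3, 4), Fraction(2, 3),
                       Fraction(1, 2))


@dataclass(frozen=True)
class WordPattern:
    word_id: int                    # 1..12
    category: str                   # "object" | "action"
    components: dict[Area, np.ndarray]   # area -> sorted cell indices

    @property
    def n_cells(self) -> int:
        return sum(len(c) for c in self.components.values())

    @property
    def semantic_area(self) -> Area:
        return SEMANTIC_AREA[self.category]


@dataclass(frozen=True)
class Trial:
    """One learning trial: the final per-area stimulus composition."""

    word_id: int
    category: str
    semantic_present: bool
    stimulus: dict[Area, np.ndarray]    # all driven cells, mask included
    mask_area: Area | None

    def to_frame(self, drive: float = 2.0) -> StimulusFrame:
        return StimulusFrame(driven=dict(self.stimulus), drive=drive)


@dataclass(frozen=True)
class TrainingSchedule:
    trials: tuple[Trial, ...]
    reps_per_word: int
    semantic_fraction: Fraction
    mask_enabled: bool

    def __len__(self) -> int:
        return len(self.trials)


def _sample_pattern(rng: np.random.Generator, cells_per_area: int,
                    n_cells: int) -> np.ndarray:
    return np.sort(rng.choice(n_cells, size=cells_per_area, replace=False))


def make_word_patterns(n_object: int = 6, n_action: int = 6,
                       cells_per_area: int = 19, side: int = 25,
                       rng: np.random.Generator | None = None
                       ) -> list[WordPattern]:
    """Draw the full word set (default 6 object + 6 action words).

    Component cells are sampled uniformly without replacement per area,
    independently across words and areas.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = side * side
    if cells_per_area > n:
        raise ValueError("cells_per_area exceeds area size")
    patterns = []
    categories = [OBJECT] * n_object + [ACTION] * n_action
    for i, cat in enumerate(categories, start=1):
        comps = {a: _sample_pattern(rng, cells_per_area, n)
                 for a in COMPONENT_AREAS[cat]}
        patterns.append(WordPattern(word_id=i, category=cat, components=comps))
    return patterns


def make_schedule(patterns: list[WordPattern], reps_per_word: int = 3000,
                  semantic_fraction: Fraction | float = 1,
                  rng: np.random.Generator | None = None, *,
                  mask_enabled: bool = True, side: int = 25,
                  cells_per_area: int = 19) -> TrainingSchedule:
    """Build the randomly ordered training schedule.

    Deprivation is counted per word: with semantic fraction (k-1)/k, every
    k-th presentation of a word replaces its semantic component with that
    word's static random pattern.  Deprived trials still receive the fresh
    mask in the non-partaking area (both non-word-form areas then carry
    uninformative input).
    """
    rng = rng if rng is not None else np.random.default_rng()
    frac = Fraction(semantic_fraction).limit_denominator(1000)
    if frac not in SUPPORTED_FRACTIONS:
        raise ValueError(f"unsupported semantic fraction {semantic_fraction!r}")
    n = side * side
    period = None if frac == 1 else int((1 / (1 - frac)))

    # one static replacement pattern per word, fixed for the whole run
    static_sem = {p.word_id: _sample_pattern(rng, cells_per_area, n)
                  for p in patterns}

    trials: list[Trial] = []
    for p in patterns:
        for rep in range(reps_per_word):
            deprived = period is not None and (rep + 1) % period == 0
            stim = {a: c.copy() for a, c in p.components.items()}
            if deprived:
                stim[p.semantic_area] = static_sem[p.word_id].copy()
            mask_area = None
            if mask_enabled:
                mask_area = MASK_AREA[p.category]
                stim[mask_area] = _sample_pattern(rng, cells_per_area, n)
            trials.append(Trial(word_id=p.word_id, category=p.category,
                                semantic_present=not deprived,
                                stimulus=stim, mask_area=mask_area))
    order = rng.permutation(len(trials))
    return TrainingSchedule(trials=tuple(trials[i] for i in order),
                            reps_per_word=reps_per_word,
                            semantic_fraction=frac,
                            mask_enabled=mask_enabled)
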