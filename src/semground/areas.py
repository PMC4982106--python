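"""The twelve modelled cortical areas and their between-area connectivity.

The model covers two six-area systems: a perisylvian (spoken word-form)
system with an auditory stream (A1 - AB - PB) and an articulatory-motor
stream (M1_i - PM_i - PF_i), and an extrasylvian (semantic) system with a
ventral visual "what" stream (V1 - TO - AT) and a dorsolateral hand/arm
motor stream (M1_L - PM_L - PF_L).  Within each stream adjacent areas are
linked by next-neighbour connections; in addition the four multimodal
"hub" areas (PB, PF_i, AT, PF_L) are linked pairwise across systems by
four long-distance connections, so that area degree grows from 1 (primary)
through 2 (secondary) to 3 (multimodal).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Area(enum.IntEnum):
    """Identifiers of the 12 modelled areas (values index array blocks)."""

    A1 = 0    # primary auditory
    AB = 1    # auditory belt
    PB = 2    # auditory parabelt (multimodal hub)
    PF_i = 3  # inferior prefrontal (multimodal hub)
    PM_i = 4  # inferior premotor
    M1_i = 5  # inferior (articulatory) primary motor
    V1 = 6    # primary visual
    TO = 7    # temporo-occipital visual
    AT = 8    # anterior temporal (multimodal hub)
    PF_L = 9  # dorsolateral prefrontal (multimodal hub)
    PM_L = 10  # dorsolateral premotor
    M1_L = 11  # dorsolateral (hand/arm) primary motor


PERISYLVIAN = frozenset({Area.A1, Area.AB, Area.PB, Area.M1_i, Area.PM_i, Area.PF_i})
EXTRASYLVIAN = frozenset({Area.V1, Area.TO, Area.AT, Area.M1_L, Area.PM_L, Area.PF_L})

FRONTAL = frozenset({Area.M1_L, Area.PM_L, Area.PF_L, Area.M1_i, Area.PM_i, Area.PF_i})
TEMPORAL = frozenset({Area.A1, Area.AB, Area.PB, Area.V1, Area.TO, Area.AT})

PRIMARY = frozenset({Area.A1, Area.V1, Area.M1_L, Area.M1_i})
SECONDARY = frozenset({Area.TO, Area.AB, Area.PM_L, Area.PM_i})
MULTIMODAL = frozenset({Area.PB, Area.AT, Area.PF_L, Area.PF_i})

#: The four hub areas double as the semantic/lexical "convergence zones".
HUBS = MULTIMODAL


def system_of(area: Area) -> str:
    return "perisylvian" if area in PERISYLVIAN else "extrasylvian"


def stream_of(area: Area) -> str:
    return "frontal" if area in FRONTAL else "temporal"


def level_of(area: Area) -> str:
    if area in PRIMARY:
        return "primary"
    if area in SECONDARY:
        return "secondary"
    return "multimodal"


#: Next-neighbour links within each of the four three-area streams.
_NEXT_NEIGHBOUR = (
    (Area.A1, Area.AB), (Area.AB, Area.PB),
    (Area.M1_i, Area.PM_i), (Area.PM_i, Area.PF_i),
    (Area.V1, Area.TO), (Area.TO, Area.AT),
    (Area.M1_L, Area.PM_L), (Area.PM_L, Area.PF_L),
)

#: Long-distance cortico-cortical links between the four multimodal hubs
#: (arcuate/uncinate fascicles and extreme capsule analogues).
_LONG_DISTANCE = (
    (Area.PF_i, Area.PB), (Area.PF_i, Area.AT),
    (Area.PF_L, Area.PB), (Area.PF_L, Area.AT),
)


@dataclass(frozen=True)
class ConnectivityGraph:
    """Undirected between-area graph; every link is realised as two
    reciprocal directed projections, and every area also projects to itself."""

    links: frozenset[frozenset[Area]] = field(
        default_factory=lambda: frozenset(
            frozenset(pair) for pair in _NEXT_NEIGHBOUR + _LONG_DISTANCE
        )
    )

    def neighbours(self, area: Area) -> frozenset[Area]:
        out = set()
        for link in self.links:
            if area in link:
                (other,) = link - {area}
                out.add(other)
        return frozenset(out)

    def degree(self, area: Area) -> int:
        return len(self.neighbours(area))

    def has_link(self, a: Area, b: Area) -> bool:
        """True for between-area links and for within-area (self) projections."""
        return a == b or frozenset((a, b)) in self.links

    def projections(self) -> list[tuple[Area, Area]]:
        """All directed projections (source, target), self-projections included,
        in a deterministic order."""
        pairs = [(a, a) for a in Area]
        for link in sorted(self.links, key=lambda l: tuple(sorted(l))):
            a, b = sorted(link)
            pairs.append((Area(a), Area(b)))
            pairs.append((Area(b), Area(a)))
        return pairs


def build_area_graph() -> ConnectivityGraph:
    """Construct the fixed 12-area graph (8 next-neighbour + 4 long-distance
    reciprocal links; degree sequence 1/2/3 for primary/secondary/multimodal)."""
    return ConnectivityGraph()
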