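"""Cell-assembly (CA) extraction from trained networks.

After training, each word's distributed circuit is measured by probing the
frozen network with the word-form components only (no semantic input) and
recording every excitatory cell's time-averaged output over a 15-step
window from stimulus onset.  A cell belongs to the CA of word ``w`` in
area ``A`` iff its time-averaged response reaches the area- and word-
specific threshold

    theta_A(w) = gamma * max over cells of A of the time-averaged response,

with gamma = 0.50 by default.  Only excitatory cells are considered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .areas import Area, level_of, system_of
from .connectivity import Network
from .dynamics import (DynamicsParams, StimulusFrame, run, zero_state)
from .stimuli import WordPattern

__all__ = ["CAParams", "TimeAveragedResponse", "CATable", "probe_word",
           "ca_members", "ca_count_table", "category_means", "ignited_areas"]

IDENTIFICATION = "identification"   # A1 + M1_i word-form components
RECOGNITION = "recognition"         # A1 (acoustic) component only


@dataclass(frozen=True)
class CAParams:
    """CA-membership threshold fraction gamma in [0, 1] (default 0.50)."""

    gamma: float = 0.50

    def validate(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")


@dataclass(frozen=True)
class TimeAveragedResponse:
    """Per-cell mean output over the probe window."""

    response: np.ndarray        # (n_e,) mean rates in [0, 1]
    probe_mode: str
    window: int
    word_id: int


@dataclass
class CATable:
    """Per (word x area) CA membership and counts, with provenance."""

    counts: pd.DataFrame        # columns: word_id, category, area, n_cells
    members: dict[tuple[int, Area], np.ndarray]
    gamma: float
    probe_mode: str
    network_seed: int

    def count(self, word_id: int, area: Area) -> int:
        df = self.counts
        row = df[(df.word_id == word_id) & (df.area == area.name)]
        return int(row.n_cells.iloc[0])


def probe_word(network: Network, pattern: WordPattern, mode: str,
               dyn: DynamicsParams, rng: np.random.Generator, *,
               window: int = 15, stim_steps: int = 15, drive: float = 4.0,
               settle_steps: int = 30, n_probes: int = 1
               ) -> TimeAveragedResponse:
    """Probe the (frozen) network with a word's form components.

    The network state is relaxed under noise for ``settle_steps`` first;
    the stimulus (identification: A1 + M1_i; recognition: A1 only) is then
    applied for ``stim_steps`` steps, and the per-cell output is averaged
    over ``window`` steps starting at stimulus onset.  Weights are never
    modified.  ``n_probes > 1`` averages several independent probes.
    """
    if mode == IDENTIFICATION:
        stim_areas = (Area.A1, Area.M1_i)
    elif mode == RECOGNITION:
        stim_areas = (Area.A1,)
    else:
        raise ValueError(f"unknown probe mode {mode!r}")
    driven = {a: pattern.components[a] for a in stim_areas}
    frame = StimulusFrame(driven=driven, drive=drive)

    acc = np.zeros(network.n_excitatory)
    for _ in range(max(1, n_probes)):
        state = zero_state(network)
        run(network, state, None, settle_steps, dyn, rng)
        mean_out = np.zeros(network.n_excitatory)
        for t in range(window):
            stim = frame if t < stim_steps else None
            run(network, state, stim, 1, dyn, rng)
            mean_out += state.O
        acc += mean_out / window
    return TimeAveragedResponse(response=acc / max(1, n_probes),
                                probe_mode=mode, window=window,
                                word_id=pattern.word_id)


def ca_members(response: TimeAveragedResponse | np.ndarray,
               params: CAParams, *, cells_per_area: int | None = None
               ) -> dict[Area, np.ndarray]:
    """Apply the theta-rule per area: members respond at >= gamma * area max.

    An all-zero area yields an empty member set (otherwise theta = 0 would
    admit every cell).
    """
    params.validate()
    resp = response.response if isinstance(response, TimeAveragedResponse) \
        else np.asarray(response, dtype=float)
    cpa = cells_per_area if cells_per_area is not None \
        else resp.shape[0] // len(Area)
    out: dict[Area, np.ndarray] = {}
    for area in Area:
        block = resp[int(area) * cpa:(int(area) + 1) * cpa]
        peak = block.max() if block.size else 0.0
        if peak <= 0.0:
            out[area] = np.empty(0, dtype=np.int64)
        else:
            out[area] = np.flatnonzero(block >= params.gamma * peak)
    return out


def ca_count_table(network: Network, patterns: list[WordPattern],
                   dyn: DynamicsParams, rng: np.random.Generator, *,
                   params: CAParams | None = None, mode: str = IDENTIFICATION,
                   window: int = 15, stim_steps: int = 15, drive: float = 4.0,
                   n_probes: int = 1) -> CATable:
    """Probe every word and tabulate CA counts for all 12 areas."""
    params = params if params is not None else CAParams()
    rows = []
    members: dict[tuple[int, Area], np.ndarray] = {}
    for pattern in patterns:
        resp = probe_word(network, pattern, mode, dyn, rng, window=window,
                          stim_steps=stim_steps, drive=drive,
                          n_probes=n_probes)
        mem = ca_members(resp, params, cells_per_area=network.cells_per_area)
        for area in Area:
            members[(pattern.word_id, area)] = mem[area]
            rows.append({"word_id": pattern.word_id,
                         "category": pattern.category,
                         "area": area.name,
                         "system": system_of(area),
                         "level": level_of(area),
                         "n_cells": int(mem[area].size)})
    counts = pd.DataFrame(rows)
    return CATable(counts=counts, members=members, gamma=params.gamma,
                   probe_mode=mode, network_seed=network.seed)


def category_means(table: CATable | pd.DataFrame) -> pd.DataFrame:
    """Mean CA-cell counts per area for object vs action words.

    Returns a DataFrame indexed by area name with columns
    ``object`` / ``action``.
    """
    df = table.counts if isinstance(table, CATable) else table
    words = df.groupby("category").word_id.nunique()
    if set(words.index) != {"object", "action"}:
        raise ValueError("table must contain both object and action words")
    wide = (df.groupby(["area", "category"]).n_cells.mean()
              .unstack("category"))
    return wide.reindex([a.name for a in Area])[["object", "action"]]


def ignited_areas(recognition: TimeAveragedResponse,
                  ca: dict[Area, np.ndarray], params: CAParams, *,
                  cells_per_area: int, floor: float = 0.1,
                  exclude: tuple[Area, ...] = (Area.A1,)) -> list[Area]:
    """Areas whose CA part is reactivated by an A1-only probe ("ignition").

    An unstimulated area counts as ignited if at least one of the word's
    CA members there reaches the theta-rule threshold of the recognition
    response and the area's peak time-averaged response exceeds an
    absolute floor (guarding against noise-only areas).
    """
    resp = recognition.response
    ignited = []
    for area in Area:
        if area in exclude or ca[area].size == 0:
            continue
        block = resp[int(area) * cells_per_area:(int(area) + 1) * cells_per_area]
        peak = block.max()
        if peak < floor:
            continue
        if np.any(block[ca[area]] >= params.gamma * peak):
            ignited.append(area)
    return ignited
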