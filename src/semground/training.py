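"""The learning protocol: stimulate, learn, relax to baseline, repeat.

Each learning trial applies the trial's composite stimulus for 16 steps
(~300 ms) with Hebbian plasticity active, then lets the network relax
under noise alone — plasticity still on, as learning is a continuous
background process — until the global-inhibition levels of both PF_i and
PB fall below the 0.65 criterion, at which point the next trial starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .areas import Area
from .connectivity import Network
from .dynamics import (DynamicsParams, NetworkState, NonConvergenceError,
                       run, run_until_baseline, zero_state)
from .plasticity import PlasticityParams
from .stimuli import Trial, TrainingSchedule

__all__ = ["TrialLog", "TrainingLog", "run_learning_trial", "train"]


@dataclass(frozen=True)
class TrialLog:
    word_id: int
    semantic_present: bool
    relax_steps: int
    peak_area_output: np.ndarray    # (n_areas,) max of summed output per area


@dataclass
class TrainingLog:
    trials: list[TrialLog] = field(default_factory=list)
    checkpoints: list[str] = field(default_factory=list)

    def relax_steps(self) -> np.ndarray:
        return np.array([t.relax_steps for t in self.trials], dtype=int)


def run_learning_trial(network: Network, state: NetworkState, trial: Trial,
                       dyn: DynamicsParams, plast: PlasticityParams,
                       rng: np.random.Generator, *, steps: int = 16,
                       drive: float = 4.0) -> TrialLog:
    """Run one trial in place: ``steps`` stimulated learning steps, then
    noise-only relaxation to the baseline criterion (PF_i and PB)."""
    frame = trial.to_frame(drive=drive)
    peak = np.zeros(network.n_areas)
    cpa = network.cells_per_area
    for _ in range(steps):
        run(network, state, frame, 1, dyn, rng, plasticity=plast)
        sums = state.O.reshape(network.n_areas, cpa).sum(axis=1)
        np.maximum(peak, sums, out=peak)
    _, relax_steps = run_until_baseline(network, state, dyn, rng,
                                        plasticity=plast)
    return TrialLog(word_id=trial.word_id,
                    semantic_present=trial.semantic_present,
                    relax_steps=relax_steps, peak_area_output=peak)


def train(network: Network, schedule: TrainingSchedule,
          dyn: DynamicsParams | None = None,
          plast: PlasticityParams | None = None,
          rng: np.random.Generator | None = None, *,
          state: NetworkState | None = None, steps_per_trial: int = 16,
          drive: float = 4.0, checkpoint_every: int | None = None,
          checkpoint_dir=None, progress_every: int | None = None,
          log_peaks: bool = False) -> tuple[NetworkState, TrainingLog]:
    """Execute the whole schedule on ``network`` (weights updated in place).

    ``checkpoint_every`` (trials) writes portable network snapshots into
    ``checkpoint_dir``.  Identical network, schedule, parameters and RNG
    seed reproduce bit-identical final weights.
    """
    dyn = dyn if dyn is not None else DynamicsParams()
    plast = plast if plast is not None else PlasticityParams()
    rng = rng if rng is not None else np.random.default_rng()
    state = state if state is not None else zero_state(network)
    log = TrainingLog()
    for idx, trial in enumerate(schedule.trials):
        try:
            tlog = _run_trial(network, state, trial, dyn, plast, rng,
                              steps_per_trial, drive, log_peaks)
        except NonConvergenceError as err:
            raise NonConvergenceError(
                f"trial {idx} (word {trial.word_id}): {err}") from err
        log.trials.append(tlog)
        if checkpoint_every and checkpoint_dir is not None \
                and (idx + 1) % checkpoint_every == 0:
            from .io import save_network
            path = f"{checkpoint_dir}/checkpoint_{idx + 1:06d}.npz"
            save_network(path, network, state=state)
            log.checkpoints.append(path)
        if progress_every and (idx + 1) % progress_every == 0:
            mean_w = network.mean_weight()
            print(f"trial {idx + 1}/{len(schedule.trials)} "
                  f"word={trial.word_id} relax={tlog.relax_steps} "
                  f"mean_w={mean_w:.4f}", flush=True)
    return state, log


def _run_trial(network, state, trial, dyn, plast, rng, steps, drive,
               log_peaks):
    if log_peaks:
        return run_learning_trial(network, state, trial, dyn, plast, rng,
                                  steps=steps, drive=drive)
    # fast path: single fused call for the stimulated steps
    frame = trial.to_frame(drive=drive)
    run(network, state, frame, steps, dyn, rng, plasticity=plast)
    _, relax_steps = run_until_baseline(network, state, dyn, rng,
                                        plasticity=plast)
    return TrialLog(word_id=trial.word_id,
                    semantic_present=trial.semantic_present,
                    relax_steps=relax_steps,
                    peak_area_output=np.zeros(network.n_areas))
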