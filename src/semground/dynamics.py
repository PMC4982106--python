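"""Graded-response cell dynamics: integration, output, inhibition, noise.

Each excitatory cell is a leaky integrator (discrete Euler update, one
step ~ 18.75 ms so that a 16-step trial spans roughly 300 ms).  Its
membrane potential relaxes with time constant ``tau_e`` toward

    k_input * (E_in - inhib_gain * [V_i]+ - k_global * G_area + stimulus)
    + k_noise * eta,     eta ~ U(-noise_amplitude, +noise_amplitude)

where ``E_in`` is the weighted sum of presynaptic outputs, ``V_i`` the
cell's inhibitory partner (itself a leaky integrator of the local
excitatory output pool) and ``G_area`` a slow per-area integral of total
excitatory output fed back subtractively to every cell of the area
("global inhibition").  Output is a piecewise-linear sigmoid of potential
minus threshold minus adaptation; adaptation slowly tracks the cell's own
output, producing habituation under sustained drive.

Noise is present in every cell at every step, probes included: it stands
in for spontaneous baseline firing and for trial-to-trial variability of
the sensorimotor input.

All default constants here are this package's own calibration, anchored to
two behavioural requirements: a 19-cell pattern must ignite its area, and
post-stimulus activity must fall back below the 0.65 global-inhibition
criterion within a few hundred steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import run_steps
from .areas import Area
from .connectivity import Network
from .plasticity import PlasticityParams

__all__ = ["DynamicsParams", "NetworkState", "StimulusFrame", "zero_state",
           "output_of", "step", "run", "run_until_baseline",
           "NonConvergenceError"]


@dataclass(frozen=True)
class DynamicsParams:
    """Cell and area dynamics constants (model units; time in steps)."""

    tau_e: float = 2.5          # e-cell membrane time constant
    tau_i: float = 2.0          # i-cell membrane time constant
    tau_adapt: float = 15.0     # adaptation time constant
    tau_global: float = 8.0     # global-inhibition time constant
    k_input: float = 1.0        # input gain
    k_noise: float = 1.0        # noise gain
    noise_amplitude: float = 0.30   # half-width of the uniform noise
    alpha_adapt: float = 2.0    # adaptation strength
    k_global: float = 0.05      # global-inhibition feedback gain
    output_threshold: float = 0.3   # potential offset of the output sigmoid
    baseline_threshold: float = 0.65   # inter-trial criterion on G
    max_relax_steps: int = 500

    def validate(self) -> None:
        for name in ("tau_e", "tau_i", "tau_adapt", "tau_global"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1 step")
        for name in ("k_input", "k_noise", "k_global", "noise_amplitude",
                     "alpha_adapt"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")


class NonConvergenceError(RuntimeError):
    """Activity failed to return below the baseline criterion (runaway
    excitation or ill-chosen parameters)."""


@dataclass
class NetworkState:
    """Mutable per-cell and per-area state of a running network."""

    V_e: np.ndarray     # (n_e,) excitatory membrane potentials
    V_i: np.ndarray     # (n_e,) inhibitory-partner potentials
    omega: np.ndarray   # (n_e,) adaptation
    O: np.ndarray       # (n_e,) outputs in [0, 1]
    G: np.ndarray       # (n_areas,) global-inhibition levels

    def copy(self) -> "NetworkState":
        return NetworkState(self.V_e.copy(), self.V_i.copy(),
                            self.omega.copy(), self.O.copy(), self.G.copy())


def zero_state(network: Network) -> NetworkState:
    n = network.n_excitatory
    return NetworkState(np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n),
                        np.zeros(network.n_areas))


@dataclass(frozen=True)
class StimulusFrame:
    """Per-area sets of driven excitatory cells with a common drive strength."""

    driven: dict[Area, np.ndarray] = field(default_factory=dict)
    drive: float = 4.0

    def to_vector(self, network: Network) -> np.ndarray:
        out = np.zeros(network.n_excitatory)
        cpa = network.cells_per_area
        for area, cells in self.driven.items():
            idx = np.asarray(cells, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= cpa):
                raise ValueError(f"driven cell index out of range in {area.name}")
            out[int(area) * cpa + idx] = self.drive
        return out


def output_of(V: np.ndarray | float, omega: np.ndarray | float,
              params: DynamicsParams) -> np.ndarray:
    """Piecewise-linear sigmoid rate in [0, 1]."""
    x = np.asarray(V, dtype=float) - params.output_threshold \
        - params.alpha_adapt * np.asarray(omega, dtype=float)
    return np.clip(x, 0.0, 1.0)


def _stim_vector(network: Network, stim) -> np.ndarray:
    if stim is None:
        return np.zeros(network.n_excitatory)
    if isinstance(stim, StimulusFrame):
        return stim.to_vector(network)
    vec = np.asarray(stim, dtype=float)
    if vec.shape != (network.n_excitatory,):
        raise ValueError("stimulus vector has wrong shape")
    return vec


def run(network: Network, state: NetworkState, stim, n_steps: int,
        params: DynamicsParams, rng: np.random.Generator,
        plasticity: PlasticityParams | None = None) -> NetworkState:
    """Advance ``state`` by ``n_steps`` under a constant stimulus (in place).

    If ``plasticity`` is given and enabled, the network's weights are
    updated by the LTP/LTD rule at every step.
    """
    params.validate()
    if state.V_e.shape[0] != network.n_excitatory:
        raise ValueError("state shape does not match network")
    stim_vec = _stim_vector(network, stim)
    noise = rng.uniform(-params.noise_amplitude, params.noise_amplitude,
                        size=(n_steps, network.n_excitatory))
    plast_on = plasticity is not None and plasticity.enabled
    if plast_on:
        plasticity.validate()
    p = plasticity if plast_on else PlasticityParams(enabled=False)
    run_steps(network.weights.indptr, network.weights.indices,
              network.weights.data,
              state.V_e, state.V_i, state.omega, state.O, state.G,
              stim_vec, noise,
              network.side, network.n_areas,
              params.tau_e, params.tau_i, params.tau_adapt, params.tau_global,
              params.k_input, params.k_noise, params.k_global,
              network.kernel.inhib_gain,
              params.output_threshold, params.alpha_adapt,
              (network.kernel.inhib_extent - 1) // 2,
              plast_on, p.theta_pre, p.theta_plus, p.theta_minus,
              p.delta_w, p.w_max,
              False, 0, 0, 0.0)
    return state


def step(network: Network, state: NetworkState, stim,
         params: DynamicsParams, rng: np.random.Generator,
         plasticity: PlasticityParams | None = None) -> NetworkState:
    """Advance the network by exactly one simulation step (in place)."""
    return run(network, state, stim, 1, params, rng, plasticity)


def run_until_baseline(network: Network, state: NetworkState,
                       params: DynamicsParams, rng: np.random.Generator,
                       threshold: float | None = None,
                       watch_areas: tuple[Area, Area] = (Area.PF_i, Area.PB),
                       max_steps: int | None = None,
                       plasticity: PlasticityParams | None = None,
                       chunk: int = 32) -> tuple[NetworkState, int]:
    """Run stimulus-free (noise-only) steps until the global-inhibition
    levels of both watch areas drop below the criterion.

    Returns ``(state, steps_taken)``; raises :class:`NonConvergenceError`
    after ``max_steps``.
    """
    params.validate()
    thr = params.baseline_threshold if threshold is None else threshold
    if thr <= 0:
        raise ValueError("baseline threshold must be positive")
    limit = params.max_relax_steps if max_steps is None else max_steps
    wa, wb = int(watch_areas[0]), int(watch_areas[1])
    if state.G[wa] < thr and state.G[wb] < thr:
        return state, 0

    stim_vec = np.zeros(network.n_excitatory)
    plast_on = plasticity is not None and plasticity.enabled
    p = plasticity if plast_on else PlasticityParams(enabled=False)
    taken = 0
    while taken < limit:
        n = min(chunk, limit - taken)
        noise = rng.uniform(-params.noise_amplitude, params.noise_amplitude,
                            size=(n, network.n_excitatory))
        done = run_steps(network.weights.indptr, network.weights.indices,
                         network.weights.data,
                         state.V_e, state.V_i, state.omega, state.O, state.G,
                         stim_vec, noise,
                         network.side, network.n_areas,
                         params.tau_e, params.tau_i, params.tau_adapt,
                         params.tau_global,
                         params.k_input, params.k_noise, params.k_global,
                         network.kernel.inhib_gain,
                         params.output_threshold, params.alpha_adapt,
                         (network.kernel.inhib_extent - 1) // 2,
                         plast_on, p.theta_pre, p.theta_plus, p.theta_minus,
                         p.delta_w, p.w_max,
                         True, wa, wb, thr)
        taken += done
        if done < n or (state.G[wa] < thr and state.G[wb] < thr):
            return state, taken
    raise NonConvergenceError(
        f"activity did not return below {thr} within {limit} steps "
        f"(G={state.G[wa]:.3f}/{state.G[wb]:.3f} in watch areas)")
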