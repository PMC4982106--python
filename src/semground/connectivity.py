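"""Synaptic connectivity: sparse, patchy, topographic projection sampling.

Every area is a ``side x side`` sheet of excitatory cells, each paired with
one inhibitory partner cell.  Excitatory-to-excitatory links (within-area
and between linked areas) are sampled at random under a topographic kernel:
a synapse between a source cell and a target cell at grid offset (dr, dc)
exists with probability

    p(d) = amplitude * exp(-d**2 / (2 * sigma**2)),   d = sqrt(dr**2 + dc**2)

restricted to a square neighbourhood of odd side ``extent`` (Chebyshev
radius (extent - 1) / 2) centred on the homotopic position in the target
sheet.  Kernels are truncated at sheet borders (no wrap-around).  Initial
efficacies are uniform in (0, w_init_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .areas import Area, ConnectivityGraph, build_area_graph


@dataclass(frozen=True)
class KernelParams:
    """Geometry and statistics of the connectivity kernels.

    Within-area kernels default to a mean in-degree of ~25 synapses
    (dense enough for recurrent assembly webs to amplify consistent
    input); between-area kernels are sparser (~8 synapses, about 2% of
    the 19 x 19 kernel support), which keeps assembly growth across areas
    convergence-limited and makes one-off random patterns poor recruiters.  ``inhib_extent`` is the neighbourhood over
    which each inhibitory partner cell pools excitatory output (unit gain);
    ``inhib_gain`` is the single scalar i->e feedback gain.
    """

    within_extent: int = 19
    between_extent: int = 19
    inhib_extent: int = 5
    amplitude: float = 0.30
    between_amplitude: float | None = 0.10
    sigma: float = 3.7
    inhib_gain: float = 0.6

    @property
    def amplitude_between(self) -> float:
        return self.amplitude if self.between_amplitude is None \
            else self.between_amplitude

    def validate(self, side: int) -> None:
        for name in ("within_extent", "between_extent", "inhib_extent"):
            v = getattr(self, name)
            if v % 2 != 1 or v < 1 or v > side:
                raise ValueError(f"{name}={v} must be odd and in [1, side={side}]")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must be a probability")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def kernel_probabilities(extent: int, amplitude: float, sigma: float) -> np.ndarray:
    """(extent x extent) matrix of link probabilities by grid offset."""
    radius = (extent - 1) // 2
    dr, dc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = (dr**2 + dc**2).astype(float)
    return np.clip(amplitude * np.exp(-d2 / (2.0 * sigma**2)), 0.0, 1.0)


def expected_projection_links(side: int, extent: int, amplitude: float,
                              sigma: float, exclude_self: bool) -> float:
    """Exact expected synapse count of one projection (border-truncated)."""
    probs = kernel_probabilities(extent, amplitude, sigma)
    radius = (extent - 1) // 2
    total = 0.0
    for i, dr in enumerate(range(-radius, radius + 1)):
        valid_r = side - abs(dr)
        for j, dc in enumerate(range(-radius, radius + 1)):
            if exclude_self and dr == 0 and dc == 0:
                continue
            total += probs[i, j] * valid_r * (side - abs(dc))
    return total


def sample_projection(source: Area, target: Area, kernel: KernelParams,
                      rng: np.random.Generator, *, side: int = 25,
                      graph: ConnectivityGraph | None = None,
                      w_init_max: float = 0.3) -> sp.csr_matrix:
    """Sample one directed projection as a (side^2 x side^2) sparse matrix.

    Rows index postsynaptic (target) cells, columns presynaptic (source)
    cells, both in row-major sheet order.  For self-projections the
    synapse of a cell onto itself is excluded.

    Raises ``ValueError`` if (source, target) is not an implemented link.
    """
    if graph is not None and not graph.has_link(source, target):
        raise ValueError(f"no anatomical link {source.name} -> {target.name}")
    kernel.validate(side)
    within = source == target
    extent = kernel.within_extent if within else kernel.between_extent
    amp = kernel.amplitude if within else kernel.amplitude_between
    probs = kernel_probabilities(extent, amp, kernel.sigma)
    radius = (extent - 1) // 2

    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    r_idx, c_idx = np.mgrid[0:side, 0:side]
    for i, dr in enumerate(range(-radius, radius + 1)):
        for j, dc in enumerate(range(-radius, radius + 1)):
            if source == target and dr == 0 and dc == 0:
                continue
            p = probs[i, j]
            if p <= 0.0:
                continue
            # source cell (r, c) -> target cell (r + dr, c + dc), in bounds
            valid = ((r_idx + dr >= 0) & (r_idx + dr < side)
                     & (c_idx + dc >= 0) & (c_idx + dc < side))
            draws = rng.random((side, side)) < p
            hit = valid & draws
            src = (r_idx[hit] * side + c_idx[hit]).astype(np.int64)
            tgt = ((r_idx[hit] + dr) * side + (c_idx[hit] + dc)).astype(np.int64)
            rows_out.append(tgt)
            cols_out.append(src)

    n = side * side
    rows = np.concatenate(rows_out) if rows_out else np.empty(0, np.int64)
    cols = np.concatenate(cols_out) if cols_out else np.empty(0, np.int64)
    # weights uniform in (0, w_init_max]
    data = (1.0 - rng.random(rows.size)) * w_init_max
    mat = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return mat


@dataclass
class Network:
    """A built network: global E->E weight matrix plus fixed inhibition.

    ``weights`` is a CSR matrix over all excitatory cells (12 * side^2 rows),
    rows = postsynaptic cell, ordered by area block.  Inhibition is not
    stored as a matrix: each excitatory cell has one inhibitory partner that
    pools excitatory output over ``kernel.inhib_extent`` with unit gain and
    feeds back with the scalar gain ``kernel.inhib_gain``.
    """

    side: int
    kernel: KernelParams
    w_max: float
    w_init_max: float
    seed: int
    graph: ConnectivityGraph
    weights: sp.csr_matrix

    @property
    def n_areas(self) -> int:
        return len(Area)

    @property
    def cells_per_area(self) -> int:
        return self.side * self.side

    @property
    def n_excitatory(self) -> int:
        return self.n_areas * self.cells_per_area

    @property
    def n_inhibitory(self) -> int:
        # one inhibitory partner cell per excitatory cell
        return self.n_excitatory

    def area_slice(self, area: Area) -> slice:
        n = self.cells_per_area
        return slice(int(area) * n, (int(area) + 1) * n)

    def projection(self, source: Area, target: Area) -> sp.csr_matrix:
        """Extract one projection block (target rows x source cols)."""
        return self.weights[self.area_slice(target), self.area_slice(source)].tocsr()

    def mean_weight(self) -> float:
        return float(self.weights.data.mean()) if self.weights.nnz else 0.0


def build_network(graph: ConnectivityGraph | None = None,
                  kernel: KernelParams | None = None, *, side: int = 25,
                  w_init_max: float = 0.3, w_max: float = 1.2,
                  seed: int = 0) -> Network:
    """Sample the full network (all self- and between-area projections).

    The same seed always yields a bit-identical network; each directed
    projection is drawn from its own child RNG stream so reciprocal
    projections are sampled independently.
    """
    graph = graph if graph is not None else build_area_graph()
    kernel = kernel if kernel is not None else KernelParams()
    kernel.validate(side)
    if not (0 < w_init_max <= w_max):
        raise ValueError("need 0 < w_init_max <= w_max")

    streams = np.random.SeedSequence(seed).spawn(len(graph.projections()))
    n = side * side
    blocks: list[list[sp.csr_matrix | None]] = [
        [None] * len(Area) for _ in Area
    ]
    for (src, tgt), ss in zip(graph.projections(), streams):
        rng = np.random.default_rng(ss)
        blocks[int(tgt)][int(src)] = sample_projection(
            src, tgt, kernel, rng, side=side, graph=graph,
            w_init_max=w_init_max)
    weights = sp.bmat(blocks, format="csr", dtype=np.float64)
    weights.sort_indices()
    return Network(side=side, kernel=kernel, w_max=w_max,
                   w_init_max=w_init_max, seed=seed, graph=graph,
                   weights=weights)
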