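"""Spatially embedded weighted digraphs and the atomic rewiring move.

The evolving state of the simulator is a :class:`SpatialDigraph`: a directed
graph on ``n`` nodes embedded in the unit square, with strictly positive edge
weights stored in an ``n x n`` adjacency matrix ``A`` under the convention

    ``A[i, j] = w_ij > 0``  iff the directed edge ``j -> i`` exists.

Rows of ``A`` therefore collect a node's *incoming* weights and columns its
*outgoing* weights.  The topological length of an edge is the reciprocal of
its weight (strong synapse = short path); spatial distances come from the
fixed 2-D node positions and never change during a run.

All randomness flows through an explicit :class:`numpy.random.Generator` so
that every construction is bit-reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "ConfigurationError",
    "GraphConsistencyError",
    "RewiringConfig",
    "SpatialDigraph",
    "init_random_digraph",
    "replace_edge",
    "sample_weights",
]

#: Mean and standard deviation of the initial weight distribution N(1, 0.25^2).
WEIGHT_MEAN = 1.0
WEIGHT_SD = 0.25
#: Replacement value for negative weight draws.
WEIGHT_FLOOR = 0.05


class ConfigurationError(ValueError):
    """Raised for invalid model parameters."""


class GraphConsistencyError(RuntimeError):
    """Raised when an edge operation would violate a graph invariant."""


@dataclass(frozen=True)
class RewiringConfig:
    """All parameters of a single evolution run.

    Parameters
    ----------
    n, m
        Number of nodes and of directed edges.  Both are conserved by every
        rewiring move.
    M
        Total number of rewirings (iterations) to perform.
    p_in
        Probability that an iteration rewires an in-link of the selected
        node rather than an out-link.
    p_adaptive, p_wave, p_proximity
        Probabilities of selecting each rewiring rule at every iteration;
        they must sum to one.
    tau
        Diffusion time at which the consensus/advection kernels are
        evaluated between consecutive rewirings.
    B
        Additive boost applied to the out-link weights of every wave
        initiator while the wave rule is in effect.
    hub_threshold
        Degree threshold for convergent/divergent hub classification
        (strict exceedance).
    initiators
        Indices of wave-initiator nodes ("retinal ganglion cells").
        ``None`` means: draw one node uniformly at the start of the run.
    seed
        Seed for the run's random stream.
    weight_policy
        ``"inherit"``: a new edge takes over the weight of the edge it
        replaces (keeps the weight multiset invariant); ``"resample"``:
        the new edge draws a fresh N(1, 0.25^2) weight.
    """

    n: int = 100
    m: int = 1000
    M: int = 4000
    p_in: float = 0.5
    p_adaptive: float = 1.0
    p_wave: float = 0.0
    p_proximity: float = 0.0
    tau: float = 1.0
    B: float = 1.0
    hub_threshold: int = 15
    initiators: tuple[int, ...] | None = None
    seed: int = 0
    weight_policy: str = "inherit"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError(f"need at least 2 nodes, got n={self.n}")
        if not (1 <= self.m <= self.n * (self.n - 1)):
            raise ConfigurationError(
                f"m={self.m} outside [1, n(n-1)]={self.n * (self.n - 1)}"
            )
        if self.M < 0:
            raise ConfigurationError(f"M must be >= 0, got {self.M}")
        probs = (self.p_adaptive, self.p_wave, self.p_proximity)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError(f"rule probabilities outside [0,1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ConfigurationError(
                f"rule probabilities must sum to 1, got {sum(probs)!r}"
            )
        if not (0.0 <= self.p_in <= 1.0):
            raise ConfigurationError(f"p_in outside [0,1]: {self.p_in}")
        if self.tau <= 0:
            raise ConfigurationError(f"tau must be > 0, got {self.tau}")
        if self.B < 0:
            raise ConfigurationError(f"B must be >= 0, got {self.B}")
        if self.hub_threshold < 1:
            raise ConfigurationError(
                f"hub_threshold must be >= 1, got {self.hub_threshold}"
            )
        if self.initiators is not None:
            inits = tuple(sorted(set(int(i) for i in self.initiators)))
            if inits and (inits[0] < 0 or inits[-1] >= self.n):
                raise ConfigurationError(f"initiators out of range: {inits}")
            object.__setattr__(self, "initiators", inits)
        if self.weight_policy not in ("inherit", "resample"):
            raise ConfigurationError(
                f"weight_policy must be 'inherit' or 'resample', "
                f"got {self.weight_policy!r}"
            )

    def rng(self) -> np.random.Generator:
        """Fresh generator seeded with this configuration's seed."""
        return np.random.default_rng(self.seed)

    def resolve_initiators(self) -> tuple[int, ...]:
        """Return the initiator set, drawing one node uniformly if unset.

        The draw comes from a dedicated stream derived from ``seed`` (not
        from the run's main stream), so a configuration with its initiator
        made explicit reproduces the exact same trajectory.
        """
        if self.initiators is not None:
            return self.initiators
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(101,))
        )
        return (int(rng.integers(self.n)),)

    def with_initiators(self, initiators: Iterable[int]) -> "RewiringConfig":
        return replace(self, initiators=tuple(initiators))


@dataclass
class SpatialDigraph:
    """Weighted digraph with fixed 2-D node coordinates.

    ``weights[i, j] > 0`` encodes the edge ``j -> i`` of weight ``w_ij``;
    ``positions[i]`` is node ``i``'s coordinate, immutable over a run.
    """

    weights: np.ndarray
    positions: np.ndarray
    _dist: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise GraphConsistencyError("weights must be a square matrix")
        if self.positions.shape != (self.weights.shape[0], 2):
            raise GraphConsistencyError(
                f"positions must be (n, 2), got {self.positions.shape}"
            )
        self.validate()

    # -- basic structure ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def m(self) -> int:
        """Number of directed edges (strictly positive entries of A)."""
        return int(np.count_nonzero(self.weights > 0))

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def in_degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)

    def out_degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=0)

    def in_strengths(self) -> np.ndarray:
        """Row sums of A: total incoming weight per node."""
        return self.weights.sum(axis=1)

    def out_strengths(self) -> np.ndarray:
        """Column sums of A: total outgoing weight per node."""
        return self.weights.sum(axis=0)

    def in_neighbors(self, v: int) -> np.ndarray:
        """Tails u of edges u -> v, in ascending node order."""
        return np.flatnonzero(self.weights[v] > 0)

    def out_neighbors(self, v: int) -> np.ndarray:
        """Heads u of edges v -> u, in ascending node order."""
        return np.flatnonzero(self.weights[:, v] > 0)

    def has_edge(self, source: int, target: int) -> bool:
        return bool(self.weights[target, source] > 0)

    def edge_weight(self, source: int, target: int) -> float:
        return float(self.weights[target, source])

    def edges(self) -> list[tuple[int, int, float]]:
        """All edges as (source, target, weight), lexicographic order."""
        tgt, src = np.nonzero(self.weights > 0)
        order = np.lexsort((tgt, src))
        return [
            (int(src[k]), int(tgt[k]), float(self.weights[tgt[k], src[k]]))
            for k in order
        ]

    def weight_multiset(self) -> np.ndarray:
        """Sorted array of all edge weights (a conserved quantity)."""
        return np.sort(self.weights[self.weights > 0])

    # -- geometry ----------------------------------------------------------

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix of the node positions (cached)."""
        if self._dist is None:
            diff = self.positions[:, None, :] - self.positions[None, :, :]
            self._dist = np.linalg.norm(diff, axis=-1)
        return self._dist

    def total_edge_length(self) -> float:
        """Sum of spatial lengths of all edges."""
        tgt, src = np.nonzero(self.weights > 0)
        return float(self.distances()[tgt, src].sum())

    # -- lifecycle ---------------------------------------------------------

    def copy(self) -> "SpatialDigraph":
        return SpatialDigraph(self.weights.copy(), self.positions.copy())

    def validate(self) -> None:
        """Check structural invariants; raise GraphConsistencyError on failure."""
        if np.any(np.diagonal(self.weights) != 0):
            raise GraphConsistencyError("self-loops are forbidden")
        if np.any(self.weights < 0):
            raise GraphConsistencyError("negative weights are forbidden")
        if not np.all(np.isfinite(self.weights)):
            raise GraphConsistencyError("non-finite weights")


def sample_weights(m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``m`` edge weights from N(1, 0.25^2), clamping negatives to 0.05.

    Negative draws have probability Phi(-4) ~ 3.17e-5; each is replaced by
    the floor value 0.05 so that every stored weight is strictly positive.
    """
    w = rng.normal(WEIGHT_MEAN, WEIGHT_SD, size=m)
    w[w < 0] = WEIGHT_FLOOR
    return w


def init_random_digraph(
    config: RewiringConfig, rng: np.random.Generator | None = None
) -> SpatialDigraph:
    """Build the initial random digraph of an evolution run.

    Exactly ``config.m`` ordered node pairs (no self-pairs) are chosen
    uniformly without replacement from all ``n(n-1)`` candidates and given
    independent N(1, 0.25^2) weights (negatives clamped to 0.05).  Node
    positions are i.i.d. uniform on the unit square.
    """
    if rng is None:
        rng = config.rng()
    n, m = config.n, config.m
    # Sample m off-diagonal cells of A uniformly without replacement.
    flat = rng.choice(n * (n - 1), size=m, replace=False)
    row = flat // (n - 1)
    col = flat % (n - 1)
    col = col + (col >= row)  # skip the diagonal
    A = np.zeros((n, n))
    A[row, col] = sample_weights(m, rng)
    positions = rng.uniform(0.0, 1.0, size=(n, 2))
    return SpatialDigraph(A, positions)


def replace_edge(
    G: SpatialDigraph,
    remove: tuple[int, int],
    add: tuple[int, int],
    new_weight: float | None = None,
) -> SpatialDigraph:
    """Atomically swap one directed edge for another, in place.

    ``remove`` and ``add`` are ``(source, target)`` pairs.  The new edge
    inherits the removed edge's weight unless ``new_weight`` is given.
    Mutates ``G`` and returns it.  Edge count is conserved by construction.
    """
    rs, rt = remove
    as_, at = add
    if as_ == at:
        raise GraphConsistencyError(f"cannot add self-loop {add}")
    if G.weights[rt, rs] <= 0:
        raise GraphConsistencyError(f"edge {remove} does not exist")
    if G.weights[at, as_] > 0:
        raise GraphConsistencyError(f"edge {add} already exists")
    w = G.weights[rt, rs] if new_weight is None else float(new_weight)
    if w <= 0:
        raise GraphConsistencyError(f"new weight must be positive, got {w}")
    G.weights[rt, rs] = 0.0
    G.weights[at, as_] = w
    return G
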