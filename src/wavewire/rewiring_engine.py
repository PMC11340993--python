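"""The three rewiring rules and the master evolution loop.

Each iteration of :func:`evolve` rewires exactly one edge of one node ``v``:

1. draw the direction — an in-link with probability ``p_in``, else an
   out-link;
2. choose ``v`` uniformly among nodes whose degree in that direction lies in
   ``[1, n-2]`` (so that both a removable edge and a legal new partner
   exist);
3. draw one of three rules with probabilities ``(p_adaptive, p_wave,
   p_proximity)`` and apply it;
4. repeat until ``M`` edges have been rewired.

*Adaptive rewiring* removes the link of ``v`` with the weakest diffusion
communication and reconnects ``v`` to the unconnected node with the
strongest one, read off the consensus kernel (in-links) or advection kernel
(out-links) at diffusion time ``tau``.

*The retinal wave rule* is adaptive rewiring evaluated on a temporarily
modified weight matrix: every out-link weight of every wave-initiator node
is boosted by ``B`` and the whole matrix renormalised to unit grand sum,
emulating a calcium wave emanating from designated ganglion cells.  The
topology change is permanent; all weights revert afterwards.

*Proximity rewiring* removes the spatially longest link of ``v`` and adds
the spatially shortest feasible one, using the fixed 2-D embedding.

Ties in any argmin/argmax are broken toward the lowest node index, making
every trajectory a deterministic function of the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .diffusion_kernels import advection_kernel, consensus_kernel
from .graph_core import RewiringConfig, SpatialDigraph, replace_edge, sample_weights

__all__ = [
    "EvolutionError",
    "RewiringEvent",
    "eligible_nodes",
    "select_rewiring_target",
    "adaptive_rewire",
    "boosted_matrix",
    "wave_rewire",
    "proximity_rewire",
    "evolve",
]

logger = logging.getLogger(__name__)

IN, OUT = "in", "out"


class EvolutionError(RuntimeError):
    """Raised when an iteration cannot proceed (e.g. no eligible node)."""


@dataclass(frozen=True)
class RewiringEvent:
    """Audit record of one rewiring: who moved, under which rule, which edge."""

    iteration: int
    node: int
    direction: str  # "in" | "out"
    rule: str  # "adaptive" | "wave" | "proximity"
    removed: tuple[int, int]  # (source, target)
    added: tuple[int, int]


def eligible_nodes(G: SpatialDigraph, direction: str) -> np.ndarray:
    """Nodes whose degree in ``direction`` is in [1, n-2]."""
    deg = G.in_degrees() if direction == IN else G.out_degrees()
    return np.flatnonzero((deg >= 1) & (deg <= G.n - 2))


def select_rewiring_target(
    G: SpatialDigraph, direction: str, rng: np.random.Generator
) -> int:
    """Uniformly choose a node eligible for rewiring in ``direction``."""
    pool = eligible_nodes(G, direction)
    if pool.size == 0:
        raise EvolutionError(
            f"no node with {direction}-degree in [1, n-2] is available"
        )
    return int(pool[rng.integers(pool.size)])


def _candidate_partners(G: SpatialDigraph, v: int, neighbors: np.ndarray) -> np.ndarray:
    """Nodes not currently linked to v in the given direction, excluding v."""
    mask = np.ones(G.n, dtype=bool)
    mask[neighbors] = False
    mask[v] = False
    return np.flatnonzero(mask)


def _adaptive_choice(
    G: SpatialDigraph, v: int, direction: str, kernel: np.ndarray
) -> tuple[tuple[int, int], tuple[int, int]]:
    """(removed, added) edge pair under the adaptive criterion.

    In-direction: drop the in-neighbour ``k`` minimising ``c[v, k]``, link
    from the non-neighbour ``l`` maximising ``c[v, l]``.  Out-direction:
    drop the out-neighbour ``k`` minimising ``a[k, v]``, link to the
    non-neighbour ``l`` maximising ``a[l, v]``.  First (lowest) index wins
    ties because candidate arrays are in ascending node order.
    """
    if direction == IN:
        nbrs = G.in_neighbors(v)
        cands = _candidate_partners(G, v, nbrs)
        k = int(nbrs[np.argmin(kernel[v, nbrs])])
        l = int(cands[np.argmax(kernel[v, cands])])
        return (k, v), (l, v)
    nbrs = G.out_neighbors(v)
    cands = _candidate_partners(G, v, nbrs)
    k = int(nbrs[np.argmin(kernel[nbrs, v])])
    l = int(cands[np.argmax(kernel[cands, v])])
    return (v, k), (v, l)


def _apply(
    G: SpatialDigraph,
    removed: tuple[int, int],
    added: tuple[int, int],
    config: RewiringConfig | None,
    rng: np.random.Generator | None,
) -> None:
    new_w = None
    if config is not None and config.weight_policy == "resample":
        if rng is None:
            raise EvolutionError("weight_policy='resample' requires an rng")
        new_w = float(sample_weights(1, rng)[0])
    replace_edge(G, removed, added, new_weight=new_w)


def adaptive_rewire(
    G: SpatialDigraph,
    v: int,
    direction: str,
    kernel: np.ndarray,
    config: RewiringConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Apply one adaptive rewiring of ``v``; returns (removed, added).

    ``kernel`` is the consensus matrix for in-link moves and the advection
    matrix for out-link moves, computed on the matrix the rule should see
    (the current weights, or the boosted ones for the wave rule).  Mutates
    ``G`` in place; the degree of ``v`` in ``direction`` is unchanged.
    """
    removed, added = _adaptive_choice(G, v, direction, kernel)
    _apply(G, removed, added, config, rng)
    return removed, added


def boosted_matrix(
    G: SpatialDigraph, initiators: tuple[int, ...], B: float
) -> np.ndarray:
    """Wave-perturbed weight matrix: +B on initiator out-links, unit grand sum.

    Each *existing* out-link weight of every initiator gains ``B``
    simultaneously; the whole matrix is then divided by its total so that
    the temporary weights sum to one.  Initiators without out-links
    contribute no boost (logged as a warning).
    """
    W = G.weights.copy()
    for c in initiators:
        col = W[:, c]
        hit = col > 0
        if not hit.any():
            logger.warning("wave initiator %d has no out-links; boost is void", c)
            continue
        col[hit] += B
    total = W.sum()
    return W / total


def wave_rewire(
    G: SpatialDigraph,
    v: int,
    direction: str,
    initiators: tuple[int, ...],
    B: float,
    t: float,
    config: RewiringConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Adaptive rewiring of ``v`` driven by the wave-boosted kernel.

    Kernels are computed on :func:`boosted_matrix`; the resulting edge swap
    is applied to ``G`` with its *pre-boost* weights (the boost is a
    transient perturbation, never stored).  Returns (removed, added).
    """
    if not initiators:
        raise EvolutionError("wave rule requires a non-empty initiator set")
    W = boosted_matrix(G, initiators, B)
    kernel = consensus_kernel(W, t) if direction == IN else advection_kernel(W, t)
    removed, added = _adaptive_choice(G, v, direction, kernel)
    _apply(G, removed, added, config, rng)
    return removed, added


def proximity_rewire(
    G: SpatialDigraph,
    v: int,
    direction: str,
    config: RewiringConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Swap the spatially longest link of ``v`` for the shortest feasible one.

    Distances are Euclidean in the fixed embedding; positions are untouched.
    Returns (removed, added); mutates ``G`` in place.
    """
    d = G.distances()
    if direction == IN:
        nbrs = G.in_neighbors(v)
        cands = _candidate_partners(G, v, nbrs)
        k = int(nbrs[np.argmax(d[nbrs, v])])
        l = int(cands[np.argmin(d[cands, v])])
        removed, added = (k, v), (l, v)
    else:
        nbrs = G.out_neighbors(v)
        cands = _candidate_partners(G, v, nbrs)
        k = int(nbrs[np.argmax(d[v, nbrs])])
        l = int(cands[np.argmin(d[v, cands])])
        removed, added = (v, k), (v, l)
    _apply(G, removed, added, config, rng)
    return removed, added


def evolve(
    G: SpatialDigraph,
    config: RewiringConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SpatialDigraph, list[RewiringEvent]]:
    """Run the full rewiring loop for ``config.M`` iterations.

    Mutates and returns ``G`` together with the complete event log.  Node
    count, edge count and (under the default ``inherit`` weight policy) the
    weight multiset are conserved.  With the same seed the trajectory is
    bit-identical.  If ``config.initiators`` is ``None`` and waves are
    possible, one initiator is drawn uniformly before the first iteration.
    """
    if rng is None:
        rng = config.rng()
    if G.n != config.n or G.m != config.m:
        raise EvolutionError(
            f"graph (n={G.n}, m={G.m}) does not match config "
            f"(n={config.n}, m={config.m})"
        )
    initiators = config.resolve_initiators()
    p_a, p_w = config.p_adaptive, config.p_wave
    events: list[RewiringEvent] = []
    for it in range(config.M):
        direction = IN if rng.random() < config.p_in else OUT
        try:
            v = select_rewiring_target(G, direction, rng)
        except EvolutionError as exc:
            raise EvolutionError(f"iteration {it}: {exc}") from exc
        u = rng.random()
        if u < p_a:
            rule = "adaptive"
            kernel = (
                consensus_kernel(G.weights, config.tau)
                if direction == IN
                else advection_kernel(G.weights, config.tau)
            )
            removed, added = adaptive_rewire(G, v, direction, kernel, config, rng)
        elif u < p_a + p_w:
            rule = "wave"
            removed, added = wave_rewire(
                G, v, direction, initiators, config.B, config.tau, config, rng
            )
        else:
            rule = "proximity"
            removed, added = proximity_rewire(G, v, direction, config, rng)
        events.append(RewiringEvent(it, v, direction, rule, removed, added))
        if (it + 1) % 500 == 0:
            logger.info("rewiring iteration %d/%d", it + 1, config.M)
    return G, events
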