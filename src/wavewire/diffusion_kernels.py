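"""Consensus and advection diffusion kernels on a weighted digraph.

Network communication intensity between node pairs is measured by matrix
exponentials of graph Laplacians:

* consensus kernel ``c(t) = exp(-L_in t)`` with ``L_in = D_in - A`` where
  ``D_in`` is the diagonal of in-strengths (row sums of A).  Rows of ``L_in``
  sum to zero, so every row of ``c(t)`` sums to one: each node averages
  opinions over its in-neighbourhood.
* advection kernel ``a(t) = exp(-L_out t)`` with ``L_out = D_out - A`` where
  ``D_out`` holds out-strengths (column sums).  Columns of ``L_out`` sum to
  zero, so columns of ``a(t)`` sum to one: mass leaving a node is conserved.

Under the adjacency convention ``A[i, j] > 0`` iff ``j -> i``, these are the
unique Laplacian orientations for which both stochasticity properties hold.
``-L t`` is a Metzler matrix, hence both kernels are entrywise non-negative
for every ``t >= 0``, and the entries live in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .graph_core import SpatialDigraph

__all__ = [
    "DiffusionKernels",
    "laplacian_matrices",
    "laplacians",
    "consensus_kernel",
    "advection_kernel",
    "compute_kernels",
]


def laplacian_matrices(
    W: np.ndarray, normalized: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """In- and out-Laplacians of a raw weight matrix.

    ``normalized=True`` divides each Laplacian by the corresponding strength
    (random-walk normalisation); zero-strength nodes keep unnormalised rows
    or columns.  The unnormalised convention is the model default.
    """
    W = np.asarray(W, dtype=float)
    d_in = W.sum(axis=1)
    d_out = W.sum(axis=0)
    L_in = np.diag(d_in) - W
    L_out = np.diag(d_out) - W
    if normalized:
        s_in = np.where(d_in > 0, d_in, 1.0)
        s_out = np.where(d_out > 0, d_out, 1.0)
        L_in = L_in / s_in[:, None]
        L_out = L_out / s_out[None, :]
    return L_in, L_out


def laplacians(
    G: SpatialDigraph, normalized: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """(L_in, L_out) of a graph; row sums of L_in and column sums of L_out are 0."""
    return laplacian_matrices(G.weights, normalized=normalized)


def _check_time(t: float) -> float:
    t = float(t)
    if t < 0:
        raise ValueError(f"diffusion time must be >= 0, got {t}")
    return t


def _exp_of(L: np.ndarray, t: float) -> np.ndarray:
    K = expm(-L * t)
    if not np.all(np.isfinite(K)):
        raise FloatingPointError("non-finite entries in diffusion kernel")
    return K


def consensus_kernel(W: np.ndarray, t: float) -> np.ndarray:
    """``exp(-L_in t)`` of a weight matrix; rows sum to one."""
    L_in, _ = laplacian_matrices(W)
    return _exp_of(L_in, _check_time(t))


def advection_kernel(W: np.ndarray, t: float) -> np.ndarray:
    """``exp(-L_out t)`` of a weight matrix; columns sum to one."""
    _, L_out = laplacian_matrices(W)
    return _exp_of(L_out, _check_time(t))


@dataclass(frozen=True)
class DiffusionKernels:
    """Both kernels of a graph at diffusion time ``t``.

    ``c[v, u]`` scores in-link rewiring of ``v`` against candidate tail
    ``u``; ``a[u, v]`` scores out-link rewiring of ``v`` against candidate
    head ``u``.
    """

    t: float
    L_in: np.ndarray
    L_out: np.ndarray
    c: np.ndarray
    a: np.ndarray


def compute_kernels(G: SpatialDigraph, t: float) -> DiffusionKernels:
    """Exact consensus and advection kernels of ``G`` at time ``t``.

    Kernels are recomputed from scratch; at ``t = 0`` both are the identity.
    """
    t = _check_time(t)
    L_in, L_out = laplacians(G)
    return DiffusionKernels(
        t=t, L_in=L_in, L_out=L_out, c=_exp_of(L_in, t), a=_exp_of(L_out, t)
    )
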