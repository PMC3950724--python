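"""Markov clustering (MCL) of MI-weighted networks.

Alternates random-walk expansion (matrix power) with inflation
(entrywise power + column renormalization) on a column-stochastic matrix
until a fixed point; clusters are read from the attractor structure of
the limit matrix.  Dense implementation — intended for networks up to a
few thousand nodes, which covers subnetwork-discovery use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ganet.network_builder import Network

__all__ = ["MCLConfig", "Partition", "MCLConvergenceWarning", "mcl_cluster", "partition_sizes"]


class MCLConvergenceWarning(UserWarning):
    """Iteration cap reached; clusters read from the current matrix."""


@dataclass
class MCLConfig:
    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-8
    add_self_loops: bool = True
    use_weights: bool = True

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if int(self.expansion) != self.expansion or self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")
        if not 0 <= self.prune_threshold < 1:
            raise ValueError("prune_threshold must be in [0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class Partition:
    """Hard cluster assignment; cluster indices contiguous from 1, ordered
    by descending size (ties broken by smallest member identifier)."""

    assignment: dict[str, int]
    converged: bool = True

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignment.values()))
        if labels and labels != list(range(1, len(labels) + 1)):
            raise ValueError("cluster indices must be contiguous from 1")

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster: int) -> list[str]:
        return sorted(g for g, c in self.assignment.items() if c == cluster)


def _column_normalize(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=0)
    dead = sums == 0
    if np.any(dead):
        # a fully pruned column restarts as a self-loop
        M[np.flatnonzero(dead), np.flatnonzero(dead)] = 1.0
        sums = M.sum(axis=0)
    return M / sums


def mcl_cluster(network: Network, config: MCLConfig | None = None) -> Partition:
    """Partition ``network`` into subnetworks by Markov clustering.

    The transition matrix is built from MI weights (or unit weights with
    ``use_weights=False``); self-loops default to each node's maximum
    incident weight, which damps oscillation.  Deterministic for a fixed
    config.  Nodes in different connected components are never merged.
    """
    config = config or MCLConfig()
    nodes = list(network.nodes)
    if not nodes:
        raise ValueError("empty network")
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for e in network.edges:
        w = e.mi if config.use_weights else 1.0
        if w < 0:
            raise ValueError(f"negative weight on {e.pair}")
        M[index[e.gene_a], index[e.gene_b]] = w
        M[index[e.gene_b], index[e.gene_a]] = w
    if config.add_self_loops:
        loop = M.max(axis=0)
        loop[loop == 0] = 1.0  # isolated nodes
        np.fill_diagonal(M, loop)
    else:
        np.fill_diagonal(M, np.where(M.max(axis=0) == 0, 1.0, np.diagonal(M)))
    M = _column_normalize(M)

    converged = False
    for _ in range(config.max_iterations):
        prev = M
        M = np.linalg.matrix_power(M, config.expansion)
        M = np.power(M, config.inflation)
        M[M < config.prune_threshold] = 0.0
        M = _column_normalize(M)
        if M.shape == prev.shape and np.max(np.abs(M - prev)) < config.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {config.max_iterations} iterations; "
            "returning interpretation of current matrix",
            MCLConvergenceWarning,
            stacklevel=2,
        )

    # attractor systems = connected components of the limit matrix support
    support = csr_matrix((M + M.T) > config.convergence_tol)
    _, labels = connected_components(support, directed=False)

    groups: dict[int, list[str]] = {}
    for g, lab in zip(nodes, labels):
        groups.setdefault(int(lab), []).append(g)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    assignment = {g: ci for ci, ms in enumerate(ordered, start=1) for g in ms}
    return Partition(assignment=assignment, converged=converged)


def partition_sizes(partition: Partition) -> list[int]:
    """Descending cluster sizes; sums to the number of assigned nodes."""
    counts: dict[int, int] = {}
    for c in partition.assignment.values():
        counts[c] = counts.get(c, 0) + 1
    return [counts[c] for c in sorted(counts)]
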