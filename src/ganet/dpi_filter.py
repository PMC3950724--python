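"""Indirect-edge removal via the data processing inequality (DPI).

For each closed triangle, the weakest edge is the candidate indirect
interaction: edge (i, j) is removed when some common neighbour k makes it
strictly weaker than ``(1 - tolerance)`` times *both* alternative edges.
All removals are marked first and swept simultaneously, so the result is
independent of edge/triangle enumeration order and of parallel schedule.
A tolerance of 1.0 disables removal entirely (the coarse-pass setting);
tolerance 0 is the strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ganet.mi_engine import EdgeSet

__all__ = ["DPIConfig", "apply_dpi", "dpi_removal_count"]


@dataclass
class DPIConfig:
    """DPI tolerance in [0, 1]; 1.0 keeps every edge."""

    tolerance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tolerance <= 1.0:
            raise ValueError("tolerance must be in [0, 1]")


def apply_dpi(edges: EdgeSet, config: DPIConfig) -> EdgeSet:
    """Return ``edges`` with DPI-marked edges removed (mark-then-sweep).

    Removal condition for edge (i, j) with weight w_ij: there exists k
    adjacent to both i and j with

        w_ij < (1 - tolerance) * w_ik  AND  w_ij < (1 - tolerance) * w_jk.

    Ties (exact equality) are kept.  Single pass; the output may still
    contain triangles whose weakest edge only became weakest relative to
    surviving edges — matching standard relevance-network practice.
    """
    factor = 1.0 - config.tolerance
    edge_list = edges.sorted_edges()
    if factor <= 0.0 or not edge_list:
        return EdgeSet(edge_list)

    nodes = edges.nodes()
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    A = np.zeros((n, n), dtype=bool)
    for e in edge_list:
        i, j = index[e.gene_a], index[e.gene_b]
        W[i, j] = W[j, i] = e.mi
        A[i, j] = A[j, i] = True

    kept = []
    for e in edge_list:
        i, j = index[e.gene_a], index[e.gene_b]
        common = A[i] & A[j]
        if common.any():
            bound = e.mi  # strict inequality: ties survive
            marked = np.any((bound < factor * W[i, common]) & (bound < factor * W[j, common]))
            if marked:
                continue
        kept.append(e)
    return EdgeSet(kept)


def dpi_removal_count(edges_before: EdgeSet, edges_after: EdgeSet) -> int:
    """Number of edges removed; errors unless ``edges_after`` is a subset."""
    extra = edges_after.pairs() - edges_before.pairs()
    if extra:
        raise ValueError(f"edges_after is not a subset of edges_before: {sorted(extra)[:3]}")
    return len(edges_before) - len(edges_after)
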