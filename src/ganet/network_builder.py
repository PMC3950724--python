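"""Network assembly (threshold + DPI), coarse-to-fine refinement, and
degree/power-law topology statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ganet.dpi_filter import DPIConfig, apply_dpi
from ganet.expression_io import ExpressionMatrix
from ganet.mi_engine import EdgeSet, ThresholdConfig, pairwise_mi, select_threshold

__all__ = [
    "Network",
    "DegreeFit",
    "build_network",
    "refine",
    "degree_distribution",
    "fit_powerlaw",
]


@dataclass
class Network:
    """Undirected MI-weighted graph plus the settings that produced it.

    ``source_edges`` is the thresholded, pre-DPI edge set the network was
    derived from; :func:`refine` re-applies DPI on a re-thresholded subset
    of it so refinement chains are path-independent.
    """

    nodes: list[str]
    edges: EdgeSet
    threshold: float | None = None
    dpi_tolerance: float | None = None
    source_edges: EdgeSet | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        for e in self.edges:
            if e.gene_a not in node_set or e.gene_b not in node_set:
                raise ValueError(f"edge endpoint not in nodes: {e.pair}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self.nodes}
        for e in self.edges:
            deg[e.gene_a] += 1
            deg[e.gene_b] += 1
        return deg


@dataclass
class DegreeFit:
    """Power-law fit of a degree distribution, ``count(k) ~ C * k**(-exponent)``."""

    exponent: float
    intercept: float
    r_squared: float


def build_network(
    matrix: ExpressionMatrix,
    threshold: ThresholdConfig | None = None,
    dpi: DPIConfig | None = None,
    workers: int = 1,
    *,
    drop_isolated: bool = True,
) -> Network:
    """Full pipeline: pairwise MI -> top-fraction threshold -> DPI.

    Deterministic given (matrix, configs); at keep-all settings
    (fraction 1.0, tolerance 1.0) the result is the complete relevance
    network on non-constant genes.  Nodes left isolated by filtering are
    dropped from the reported network unless ``drop_isolated=False``.
    """
    threshold = threshold or ThresholdConfig()
    dpi = dpi or DPIConfig()
    all_edges = pairwise_mi(matrix, workers=workers)
    thr = select_threshold(all_edges.mi_values(), threshold)
    kept = all_edges.subset(lambda e: e.mi >= thr)
    final = apply_dpi(kept, dpi)
    if drop_isolated:
        nodes = final.nodes()
    else:
        usable = ~np.all(matrix.values == matrix.values[:, :1], axis=1)
        nodes = [g for g, u in zip(matrix.gene_ids, usable) if u]
    return Network(
        nodes=nodes,
        edges=final,
        threshold=thr,
        dpi_tolerance=dpi.tolerance,
        source_edges=kept,
    )


def refine(network: Network, new_threshold: float, new_dpi: DPIConfig) -> Network:
    """Tighten a network's threshold/tolerance without rescoring the matrix.

    Both parameters must be non-loosening.  The new edge set is obtained by
    re-thresholding ``source_edges`` and recomputing DPI on that subgraph,
    so chained refinements equal a direct build at the final settings.
    """
    if network.threshold is not None and new_threshold < network.threshold:
        raise ValueError(
            f"new threshold {new_threshold} is looser than {network.threshold}; "
            "rebuild from the expression matrix instead"
        )
    if network.dpi_tolerance is not None and new_dpi.tolerance > network.dpi_tolerance:
        raise ValueError(
            f"new DPI tolerance {new_dpi.tolerance} is looser than "
            f"{network.dpi_tolerance}; rebuild from the expression matrix instead"
        )
    base = network.source_edges if network.source_edges is not None else network.edges
    kept = base.subset(lambda e: e.mi >= new_threshold)
    final = apply_dpi(kept, new_dpi)
    return Network(
        nodes=final.nodes(),
        edges=final,
        threshold=new_threshold,
        dpi_tolerance=new_dpi.tolerance,
        source_edges=kept,
    )


def degree_distribution(network: Network) -> dict[int, int]:
    """Map degree -> node count; counts sum to the number of nodes."""
    if not network.nodes:
        raise ValueError("empty network")
    counts: dict[int, int] = {}
    for d in network.degrees().values():
        counts[d] = counts.get(d, 0) + 1
    return dict(sorted(counts.items()))


def fit_powerlaw(dist: dict[int, int], method: str = "ols") -> DegreeFit:
    """Fit ``count(k) = C * k**(-gamma)`` over degrees >= 1.

    ``method="ols"``: ordinary least squares on (log k, log count) — the
    straight line of a log-log degree plot; exponent = -slope.
    ``method="mle"``: discrete maximum-likelihood estimate from the degree
    sample — minimizes ``gamma * sum(log k) + n * log(zeta(gamma))`` with
    ``k_min = 1`` (intercept/r_squared still reported from the OLS line).
    Preferred for sampled data, where the log-log regression is biased by
    the noisy tail.
    """
    pts = [(k, c) for k, c in dist.items() if k >= 1 and c > 0]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 distinct degrees >= 1, got {len(pts)}")
    logk = np.log([k for k, _ in pts])
    logc = np.log([c for _, c in pts])
    slope, intercept = np.polyfit(logk, logc, 1)
    pred = slope * logk + intercept
    ss_res = float(np.sum((logc - pred) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if method == "ols":
        exponent = -float(slope)
    elif method == "mle":
        from scipy.optimize import minimize_scalar
        from scipy.special import zeta

        n = sum(c for _, c in pts)
        s = sum(c * math.log(k) for k, c in pts)
        res = minimize_scalar(
            lambda g: g * s + n * math.log(zeta(g, 1)),
            bounds=(1.01, 8.0),
            method="bounded",
        )
        exponent = float(res.x)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DegreeFit(exponent=exponent, intercept=float(intercept), r_squared=r2)
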