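"""Leave-one-chip-out ("condition-removing") annotation of network edges.

For each edge, the pair's rank-transform MI is recomputed with each chip
removed in turn.  Chips whose removal sharply reduces MI are the
conditions under which the association operates: the leave-one-out MI
family is treated as approximately normal and each chip receives a
one-sided lower-tail z-test p-value.
"""

from __future__ import annotations

import math
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ganet.expression_io import ExpressionMatrix
from ganet.mi_engine import EdgeSet, mi_from_correlation

__all__ = [
    "ConditionTestConfig",
    "DegenerateLOOWarning",
    "leave_one_out_mi",
    "condition_ztest",
    "significant_conditions",
]


class DegenerateLOOWarning(UserWarning):
    """The leave-one-out MI family has zero variance; p-values defaulted."""


@dataclass
class ConditionTestConfig:
    """Significance cutoff and reporting limits for the per-chip test.

    ``min_samples`` reflects the accuracy caveat that leave-one-out MI is
    only well estimated on compendia of >100 chips; smaller inputs warn
    rather than fail.  ``studentized=True`` excludes the tested chip from
    the mean/sd of its own z-score (off by default).
    """

    alpha: float = 1e-4
    top_k: int = 10
    min_samples: int = 100
    studentized: bool = False
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def _pair_mi(x: np.ndarray, y: np.ndarray) -> float:
    rx = rankdata(x)
    ry = rankdata(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    nx = math.sqrt(float(dx @ dx))
    ny = math.sqrt(float(dy @ dy))
    if nx == 0.0 or ny == 0.0:
        return math.nan
    rho = min(1.0, max(-1.0, float(dx @ dy) / (nx * ny)))
    return mi_from_correlation(rho)


def leave_one_out_mi(
    edge: tuple[str, str],
    matrix: ExpressionMatrix,
) -> np.ndarray:
    """MI of ``edge`` recomputed with each chip removed in turn.

    Entry ``c`` is the rank-transform MI of the pair on the ``m - 1``
    chips excluding chip ``c`` (ranks fully recomputed on the reduced
    sample); ordering matches ``matrix.sample_ids``.  Removals that leave
    a gene constant yield ``nan`` and are excluded from the z-test.
    """
    gene_a, gene_b = edge
    x = matrix.row(gene_a)
    y = matrix.row(gene_b)
    m = matrix.m
    if m < 4:
        raise ValueError("need at least 4 chips for leave-one-out MI")
    out = np.empty(m)
    keep = np.ones(m, dtype=bool)
    for c in range(m):
        keep[c] = False
        out[c] = _pair_mi(x[keep], y[keep])
        keep[c] = True
    return out


def condition_ztest(loo_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-chip (z, p) from the leave-one-out MI family.

    ``z_c = (mi_c - mean) / sd`` over all defined entries (mean and sd
    include chip c); ``p_c = Phi(z_c)`` — a strong MI drop gives a very
    negative z and a small p.  Zero variance is flagged and all p default
    to 0.5.  NaN entries propagate.
    """
    loo = np.asarray(loo_values, dtype=float)
    defined = np.isfinite(loo)
    if defined.sum() < 4:
        raise ValueError("need >= 4 defined leave-one-out values")
    vals = loo[defined]
    mean = vals.mean()
    sd = vals.std(ddof=1)
    z = np.full(loo.shape, np.nan)
    p = np.full(loo.shape, np.nan)
    # relative guard: a family of identical values can carry sd ~ 1e-16
    # from summation rounding alone
    if sd <= 1e-12 * max(1.0, abs(mean)):
        warnings.warn(
            "zero-variance leave-one-out family; p defaulted to 0.5",
            DegenerateLOOWarning,
            stacklevel=2,
        )
        z[defined] = 0.0
        p[defined] = 0.5
        return z, p
    z[defined] = (vals - mean) / sd
    p[defined] = norm.cdf(z[defined])
    return z, p


def _studentized_ztest(loo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    defined = np.isfinite(loo)
    vals = loo[defined]
    k = vals.size
    z = np.full(loo.shape, np.nan)
    for i, v in enumerate(np.flatnonzero(defined)):
        others = np.delete(vals, i)
        sd = others.std(ddof=1)
        z[v] = 0.0 if sd == 0 else (loo[v] - others.mean()) / sd
    p = np.where(np.isfinite(z), norm.cdf(z), np.nan)
    return z, p


def significant_conditions(
    edges: EdgeSet,
    matrix: ExpressionMatrix,
    config: ConditionTestConfig | None = None,
    workers: int = 1,
) -> pd.DataFrame:
    """Condition-removal table for every edge.

    Returns a DataFrame with columns ``gene_a, gene_b, sample_id, mi_full,
    mi_loo, z, p`` holding, per edge, the chips with ``p <= alpha`` capped
    at ``top_k`` ordered by ascending p; rows sorted by (edge, p).
    Deterministic and independent of ``workers``.
    """
    config = config or ConditionTestConfig()
    known = set(matrix.gene_ids)
    for e in edges:
        for g in (e.gene_a, e.gene_b):
            if g not in known:
                raise KeyError(f"edge references unknown gene {g!r}")
    if matrix.m < config.min_samples:
        warnings.warn(
            f"only {matrix.m} chips (< {config.min_samples}); leave-one-out MI "
            "estimates may be unstable",
            UserWarning,
            stacklevel=2,
        )
    alpha = config.alpha
    if config.bonferroni:
        alpha = alpha / matrix.m

    edge_list = edges.sorted_edges()

    def one_edge(e):
        mi_full = _pair_mi(matrix.row(e.gene_a), matrix.row(e.gene_b))
        loo = leave_one_out_mi(e.pair, matrix)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateLOOWarning)
            if config.studentized:
                z, p = _studentized_ztest(loo)
            else:
                z, p = condition_ztest(loo)
        rows = []
        order = np.argsort(p, kind="stable")
        for c in order:
            if not np.isfinite(p[c]) or p[c] > alpha:
                continue
            rows.append(
                (e.gene_a, e.gene_b, matrix.sample_ids[c], mi_full, loo[c], z[c], p[c])
            )
            if len(rows) >= config.top_k:
                break
        return rows

    if workers == 1:
        all_rows = [one_edge(e) for e in edge_list]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            all_rows = list(pool.map(one_edge, edge_list))

    flat = [r for rows in all_rows for r in rows]
    return pd.DataFrame(
        flat,
        columns=["gene_a", "gene_b", "sample_id", "mi_full", "mi_loo", "z", "p"],
    )
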