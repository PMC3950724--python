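"""Pairwise mutual information via the rank-correlation transform.

The default estimator converts each gene's expression profile to ranks,
computes the Pearson correlation of the rank vectors (the Spearman
coefficient, exact under ties), and maps it to mutual information through
the closed form for a standardized bivariate normal,

    I(rho) = -1/2 * ln(1 - rho**2)   [nats].

Because ranks are invariant under strictly increasing transforms, so is
the resulting MI.  A Gaussian-kernel density estimator is provided as a
slower baseline compatible with kernel-based network inference tools.
"""

from __future__ import annotations

import math
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from ganet.expression_io import ExpressionMatrix

__all__ = [
    "MIEdge",
    "EdgeSet",
    "ThresholdConfig",
    "ConstantGeneWarning",
    "rank_transform",
    "spearman_correlation",
    "mi_from_correlation",
    "pairwise_mi",
    "gaussian_kernel_mi",
    "pairwise_gaussian_mi",
    "permutation_pvalue",
    "select_threshold",
]

#: |rho| is clamped to 1 - RHO_CLAMP before the log so MI stays finite and
#: totally ordered for thresholding and DPI.
RHO_CLAMP = 1e-12


class ConstantGeneWarning(UserWarning):
    """A gene with constant expression was excluded from pair scoring."""


@dataclass(frozen=True)
class MIEdge:
    """Unordered gene pair with its rank correlation and MI weight.

    ``gene_a < gene_b`` lexicographically (canonical order); construct
    through :meth:`make` to get the ordering and the rho/MI consistency
    for free.
    """

    gene_a: str
    gene_b: str
    rho: float
    mi: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a!r}")
        if self.mi < 0:
            raise ValueError(f"negative MI {self.mi} for ({self.gene_a}, {self.gene_b})")

    @classmethod
    def make(cls, gene_a: str, gene_b: str, rho: float, mi: float | None = None) -> "MIEdge":
        if gene_b < gene_a:
            gene_a, gene_b = gene_b, gene_a
        if mi is None:
            mi = mi_from_correlation(rho)
        return cls(gene_a, gene_b, float(rho), float(mi))

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


class EdgeSet:
    """Collection of :class:`MIEdge` keyed by canonical gene pair."""

    def __init__(self, edges=()):
        self._edges: dict[tuple[str, str], MIEdge] = {}
        for e in edges:
            self.add(e)

    def add(self, edge: MIEdge) -> None:
        if edge.pair in self._edges:
            raise ValueError(f"duplicate edge {edge.pair}")
        self._edges[edge.pair] = edge

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self):
        return iter(self._edges.values())

    def __contains__(self, pair) -> bool:
        a, b = pair
        if b < a:
            a, b = b, a
        return (a, b) in self._edges

    def __getitem__(self, pair) -> MIEdge:
        a, b = pair
        if b < a:
            a, b = b, a
        return self._edges[(a, b)]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EdgeSet):
            return NotImplemented
        return self._edges == other._edges

    def pairs(self) -> set[tuple[str, str]]:
        return set(self._edges)

    def nodes(self) -> list[str]:
        """Endpoint identifiers, sorted."""
        out: set[str] = set()
        for a, b in self._edges:
            out.add(a)
            out.add(b)
        return sorted(out)

    def mi_values(self) -> np.ndarray:
        return np.array([e.mi for e in self.sorted_edges()])

    def sorted_edges(self) -> list[MIEdge]:
        """Edges in canonical (gene_a, gene_b) order — the serialization order."""
        return [self._edges[k] for k in sorted(self._edges)]

    def subset(self, predicate) -> "EdgeSet":
        return EdgeSet(e for e in self.sorted_edges() if predicate(e))

    def write(self, path, *, header_lines=()) -> None:
        """Three-column ``geneA<TAB>geneB<TAB>MI`` text, Cytoscape-importable."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            for e in self.sorted_edges():
                fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.mi:.6f}\n")

    @classmethod
    def read(cls, path) -> "EdgeSet":
        """Read a 2- or 3-column edge list; missing weights default to 0."""
        edges = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\r\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) not in (2, 3):
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 or 3 tab-separated fields"
                    )
                mi = float(fields[2]) if len(fields) == 3 else 0.0
                edges.add(MIEdge.make(fields[0], fields[1], rho=math.nan, mi=mi))
        return edges


@dataclass
class ThresholdConfig:
    """MI-threshold selection and permutation-null settings.

    ``keep_top_fraction`` follows the coarse-pass default of retaining the
    strongest tenth of all pairs.
    """

    keep_top_fraction: float = 0.10
    n_permutations: int = 1000
    permutation_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.keep_top_fraction <= 1:
            raise ValueError("keep_top_fraction must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def rank_transform(matrix: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Per-gene ranks across samples, ties receiving average (fractional) ranks.

    Every row of the result sums to ``m * (m + 1) / 2``.  Constant rows are
    rank-transformable but have zero variance; they are flagged with a
    :class:`ConstantGeneWarning` because downstream correlations for them
    are undefined.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    constant = np.all(values == values[:, :1], axis=1)
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant gene row(s); their pairs will be skipped",
            ConstantGeneWarning,
            stacklevel=2,
        )
    return rankdata(values, axis=1, method="average")


def spearman_correlation(ranks_a: np.ndarray, ranks_b: np.ndarray) -> float:
    """Pearson product-moment correlation of two rank vectors (exact under ties)."""
    ra = np.asarray(ranks_a, dtype=float)
    rb = np.asarray(ranks_b, dtype=float)
    if ra.shape != rb.shape or ra.ndim != 1:
        raise ValueError("rank vectors must be 1-D with equal length")
    if ra.size < 3:
        raise ValueError("need at least 3 observations")
    da = ra - ra.mean()
    db = rb - rb.mean()
    na = math.sqrt(float(da @ da))
    nb = math.sqrt(float(db @ db))
    if na == 0.0 or nb == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    rho = float(da @ db) / (na * nb)
    return min(1.0, max(-1.0, rho))


def mi_from_correlation(rho) -> float | np.ndarray:
    """Closed-form bivariate-normal MI, ``-0.5 * ln(1 - rho**2)`` nats.

    Symmetric in the sign of ``rho`` and monotone in ``|rho|``; ``|rho|``
    within ``1e-12`` of 1 is clamped so the output stays finite.
    """
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-9):
        raise ValueError("|rho| > 1")
    r = np.clip(np.abs(r), 0.0, 1.0 - RHO_CLAMP)
    out = -0.5 * np.log1p(-(r * r))
    return float(out) if out.ndim == 0 else out


def _standardize_ranks(ranks: np.ndarray) -> np.ndarray:
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    return centered / norms[:, None]


def pairwise_mi(
    matrix: ExpressionMatrix,
    workers: int = 1,
    *,
    copula_adjust: bool = False,
) -> EdgeSet:
    """Score every gene pair with rank-transform MI.

    Genes with constant expression are dropped (with a warning) rather than
    failing the run.  The result is bitwise identical for any ``workers``
    value and any pair-evaluation order: each correlation row is an
    independent vector product against the full standardized rank matrix.

    ``copula_adjust`` applies the Gaussian-copula correction
    ``rho = 2 * sin(pi * rho_s / 6)`` before the MI map (off by default).
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConstantGeneWarning)
        ranks = rank_transform(matrix)
    usable = ~np.all(matrix.values == matrix.values[:, :1], axis=1)
    if not np.all(usable):
        dropped = [g for g, u in zip(matrix.gene_ids, usable) if not u]
        warnings.warn(
            f"dropping constant gene(s): {', '.join(dropped)}",
            ConstantGeneWarning,
            stacklevel=2,
        )
    idx = np.flatnonzero(usable)
    if idx.size < 2:
        raise ValueError(f"need at least 2 non-constant genes, got {idx.size}")
    gene_ids = [matrix.gene_ids[i] for i in idx]
    Z = _standardize_ranks(ranks[idx])

    def row_corr(i: int) -> np.ndarray:
        # one matrix-vector product per row: identical arithmetic for any
        # scheduling, which is what makes worker count irrelevant bitwise
        return Z[i + 1 :] @ Z[i]

    n = len(gene_ids)
    if workers == 1:
        rows = [row_corr(i) for i in range(n - 1)]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            rows = list(pool.map(row_corr, range(n - 1)))

    edges = EdgeSet()
    for i, r in enumerate(rows):
        r = np.clip(r, -1.0, 1.0)
        rho_eff = 2.0 * np.sin(np.pi * r / 6.0) if copula_adjust else r
        mis = mi_from_correlation(rho_eff)
        mis = np.atleast_1d(mis)
        for off, (rho, mi) in enumerate(zip(np.atleast_1d(rho_eff), mis)):
            edges.add(MIEdge.make(gene_ids[i], gene_ids[i + 1 + off], float(rho), float(mi)))
    return edges


def _silverman_bandwidth(v: np.ndarray) -> float:
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise ValueError("constant vector: bandwidth undefined")
    return 1.06 * sd * v.size ** (-0.2)


def _kernel_matrix(v: np.ndarray, h: float) -> np.ndarray:
    d = (v[:, None] - v[None, :]) / h
    return np.exp(-0.5 * d * d) / (h * math.sqrt(2.0 * math.pi))


def gaussian_kernel_mi(x, y, bandwidth="auto", *, copula: bool = False) -> float:
    """Kernel-density MI estimate in nats (leave-one-out, product kernel).

    ``bandwidth="auto"`` uses the rule-of-thumb ``1.06 * sigma * m**(-1/5)``
    per dimension.  With ``copula=True`` both vectors are mapped to normal
    scores first.  The estimate is truncated at 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    m = x.size
    if m < 4:
        raise ValueError("need at least 4 observations")
    if copula:
        from scipy.stats import norm

        x = norm.ppf((rankdata(x) - 0.5) / m)
        y = norm.ppf((rankdata(y) - 0.5) / m)
    if bandwidth == "auto":
        hx = _silverman_bandwidth(x)
        hy = _silverman_bandwidth(y)
    else:
        hx = hy = float(bandwidth)
        if hx <= 0:
            raise ValueError("bandwidth must be positive")
        if np.all(x == x[0]) or np.all(y == y[0]):
            raise ValueError("constant vector")
    Kx = _kernel_matrix(x, hx)
    Ky = _kernel_matrix(y, hy)
    return _loo_kde_mi(Kx, Ky)


def _loo_kde_mi(Kx: np.ndarray, Ky: np.ndarray) -> float:
    """MI from precomputed per-dimension kernel matrices (leave-one-out)."""
    m = Kx.shape[0]
    dx = np.diagonal(Kx)
    dy = np.diagonal(Ky)
    fx = (Kx.sum(axis=1) - dx) / (m - 1)
    fy = (Ky.sum(axis=1) - dy) / (m - 1)
    fxy = (np.einsum("ij,ij->i", Kx, Ky) - dx * dy) / (m - 1)
    mi = float(np.mean(np.log(fxy) - np.log(fx) - np.log(fy)))
    return max(mi, 0.0)


def pairwise_gaussian_mi(
    matrix: ExpressionMatrix | np.ndarray,
    bandwidth="auto",
    *,
    copula: bool = False,
) -> np.ndarray:
    """All-pairs Gaussian-kernel MI as a condensed upper-triangle matrix.

    Returns an ``(n, n)`` symmetric array (diagonal 0).  Kernel matrices
    are cached per gene, so memory grows as ``n * m**2`` — intended for
    benchmark-scale inputs, not compendium-scale ones.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, dtype=float)
    n, m = values.shape
    if copula:
        from scipy.stats import norm

        values = norm.ppf((rankdata(values, axis=1) - 0.5) / m)
    kernels = []
    for i in range(n):
        h = _silverman_bandwidth(values[i]) if bandwidth == "auto" else float(bandwidth)
        kernels.append(_kernel_matrix(values[i], h))
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _loo_kde_mi(kernels[i], kernels[j])
    return out


def permutation_pvalue(
    x,
    y,
    observed_mi: float,
    config: ThresholdConfig,
) -> float:
    """Add-one permutation p-value for one pair's MI.

    One vector is independently shuffled across samples ``n_permutations``
    times; ``p = (1 + #{MI_perm >= MI_obs}) / (1 + n_permutations)``, which
    never returns 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = rankdata(x)
    ry = rankdata(y)
    zx = rx - rx.mean()
    zy = ry - ry.mean()
    nx = math.sqrt(float(zx @ zx))
    ny = math.sqrt(float(zy @ zy))
    if nx == 0 or ny == 0:
        raise ValueError("constant vector")
    zx /= nx
    zy /= ny
    rng = np.random.default_rng(config.permutation_seed)
    count = 0
    for _ in range(config.n_permutations):
        rho = float(zx @ rng.permutation(zy))
        if mi_from_correlation(rho) >= observed_mi:
            count += 1
    return (1 + count) / (1 + config.n_permutations)


def select_threshold(mi_values, config: ThresholdConfig) -> float:
    """MI value at rank ``ceil(keep_top_fraction * N)`` in descending order.

    Keeping edges with ``MI >= threshold`` then retains the top fraction
    (plus any exact ties at the threshold).
    """
    arr = np.sort(np.asarray(list(mi_values), dtype=float))[::-1]
    if arr.size == 0:
        raise ValueError("empty MI collection")
    k = math.ceil(config.keep_top_fraction * arr.size)
    return float(arr[k - 1])
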