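"""PageRank and CheiRank computation with global and subset rank indices.

PageRank P solves G P = P (unit eigenvalue of the damped column-stochastic
matrix) and is computed by power iteration.  CheiRank P* is the PageRank of
the link-inverted network: high P measures influence (many/strong in-links),
high P* measures diffusivity (many/strong out-links).  Rank indices K are
1-based: K = 1 is the node with maximal probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph_core import (
    DEFAULT_ALPHA,
    DirectedNetwork,
    GoogleMatrix,
    build_google_matrix,
    invert_network,
)

__all__ = [
    "RankVector",
    "LocalRanking",
    "ConvergenceError",
    "pagerank",
    "cheirank",
    "rank_indices",
    "local_ranking",
    "write_rank_table",
]

DEFAULT_TOL = 1e-12
DEFAULT_MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the requested tolerance."""


def rank_indices(probabilities: np.ndarray) -> np.ndarray:
    """Permutation of node indices sorted by decreasing probability.

    ``order[0]`` is the node at rank K = 1.  Ties are broken by ascending
    node index so the permutation is deterministic.
    """
    p = np.asarray(probabilities, dtype=float)
    # lexsort: last key is primary -> sort by -p, then by node index
    return np.lexsort((np.arange(p.size), -p))


@dataclass
class RankVector:
    """Stationary probabilities of a Google matrix plus rank bookkeeping."""

    probabilities: np.ndarray
    node_ids: list[str]
    kind: str  # "pagerank" | "cheirank"
    alpha: float
    tol: float
    iterations: int
    order: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.order = rank_indices(self.probabilities)
        self._index = {n: i for i, n in enumerate(self.node_ids)}
        self._rank = np.empty(self.probabilities.size, dtype=np.int64)
        self._rank[self.order] = np.arange(1, self.probabilities.size + 1)

    @property
    def N(self) -> int:
        return self.probabilities.size

    def probability(self, node: str) -> float:
        return float(self.probabilities[self._index[node]])

    def rank_of(self, node: str) -> int:
        """1-based rank index K of a node (K = 1 for the top node)."""
        return int(self._rank[self._index[node]])

    def top(self, k: int) -> list[str]:
        return [self.node_ids[i] for i in self.order[:k]]


def _power_iteration(
    matvec, n: int, tol: float, max_iter: int
) -> tuple[np.ndarray, int]:
    """Iterate v <- M v from the uniform vector until the L1 change < tol."""
    v = np.full(n, 1.0 / n)
    residual = np.inf
    for it in range(1, max_iter + 1):
        w = matvec(v)
        w_sum = w.sum()
        if w_sum <= 0:
            raise ConvergenceError("iteration produced a non-positive vector sum")
        w = w / w_sum
        residual = float(np.abs(w - v).sum())
        v = w
        if residual < tol:
            return v, it
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(last L1 residual {residual:.3e})"
    )


def pagerank(
    G: GoogleMatrix,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RankVector:
    """PageRank of a Google matrix by power iteration.

    Starts from the uniform vector and stops when the L1 change of the
    probability vector falls below ``tol``; the result is normalized to sum
    one and is a fixed point of G to within a small multiple of ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    v, iters = _power_iteration(G.matvec, G.N, tol, max_iter)
    return RankVector(
        probabilities=v,
        node_ids=list(G.node_ids),
        kind="pagerank",
        alpha=G.alpha,
        tol=tol,
        iterations=iters,
    )


def cheirank(
    net: DirectedNetwork,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RankVector:
    """CheiRank: the PageRank of the link-inverted network."""
    rv = pagerank(build_google_matrix(invert_network(net), alpha=alpha), tol, max_iter)
    rv.kind = "cheirank"
    return rv


@dataclass
class LocalRanking:
    """Restriction of a global ranking to a node subset.

    ``local_index`` maps each subset node to K_r in 1..N_r preserving the
    global order; ``category_index`` additionally ranks nodes within their
    category (e.g. the cancers-only or drugs-only sub-order of a mixed
    subset ranking).
    """

    subset: list[str]  # ordered by local rank: subset[0] has K_r = 1
    local_index: dict[str, int]
    categories: dict[str, str]
    category_index: dict[str, int]

    @property
    def N_r(self) -> int:
        return len(self.subset)

    def of_category(self, category: str) -> list[str]:
        """Subset nodes of one category, in local-rank order."""
        return [n for n in self.subset if self.categories.get(n) == category]


def local_ranking(
    rv: RankVector,
    subset: list[str],
    categories: dict[str, str] | None = None,
) -> LocalRanking:
    """Assign local rank indices K_r = 1..N_r to a subset of nodes.

    The local order is the restriction of the global rank order to the
    subset, so a subset equal to all nodes reproduces K itself.
    """
    categories = categories or {}
    for n in subset:
        if n not in rv._index:
            raise KeyError(f"node not in ranking: {n!r}")
    ordered = sorted(subset, key=rv.rank_of)
    local_index = {n: i + 1 for i, n in enumerate(ordered)}
    category_index: dict[str, int] = {}
    counters: dict[str, int] = {}
    for n in ordered:
        cat = categories.get(n)
        if cat is not None:
            counters[cat] = counters.get(cat, 0) + 1
            category_index[n] = counters[cat]
    return LocalRanking(
        subset=ordered,
        local_index=local_index,
        categories={n: categories[n] for n in subset if n in categories},
        category_index=category_index,
    )


def write_rank_table(
    rv: RankVector,
    path: str | Path,
    labels: dict[str, str] | None = None,
    categories: dict[str, str] | None = None,
) -> None:
    """Write ``rank<TAB>id<TAB>label<TAB>probability<TAB>category`` rows."""
    labels = labels or {}
    categories = categories or {}
    lines = ["rank\tid\tlabel\tprobability\tcategory"]
    for rank, i in enumerate(rv.order, start=1):
        node = rv.node_ids[i]
        lines.append(
            f"{rank}\t{node}\t{labels.get(node, node)}\t"
            f"{rv.probabilities[i]:.17g}\t{categories.get(node, '')}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
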