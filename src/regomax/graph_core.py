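"""Directed-network data model, edge-list I/O and Google matrix construction.

The adjacency convention follows the Google-matrix literature: ``A[i, j] = 1``
when node *j* cites node *i*, i.e. columns index link sources.  Edge-list files
use the intuitive "source<TAB>target" line order; the transposition happens at
matrix-construction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedNetwork",
    "GoogleMatrix",
    "ParseError",
    "load_edge_list",
    "load_label_table",
    "save_edge_list",
    "save_label_table",
    "build_google_matrix",
    "invert_network",
    "DEFAULT_ALPHA",
]

#: Standard damping factor of the random-surfer model.
DEFAULT_ALPHA = 0.85


class ParseError(ValueError):
    """Raised when an edge-list or label-table file is malformed."""


@dataclass
class DirectedNetwork:
    """A directed network of string-identified nodes with unweighted links.

    Parameters
    ----------
    node_ids
        Node identifiers in a stable order; this order defines the integer
        indexing used by all matrix operations.
    links
        Set of ``(source, target)`` pairs, meaning "source cites target".
        Self-loops are forbidden.
    labels
        Optional id -> display-name map.
    categories
        Optional id -> category tag map (e.g. ``cancer``/``drug``/``country``).
    """

    node_ids: list[str]
    links: set[tuple[str, str]] = field(default_factory=set)
    labels: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValueError("duplicate node identifiers")
        for s, t in self.links:
            if s == t:
                raise ValueError(f"self-loop on node {s!r}")
            if s not in self._index or t not in self._index:
                raise ValueError(f"link endpoint not a known node: ({s!r}, {t!r})")

    # -- basic queries ----------------------------------------------------

    @property
    def N(self) -> int:
        """Number of nodes."""
        return len(self.node_ids)

    @property
    def N_l(self) -> int:
        """Number of directed links."""
        return len(self.links)

    def index_of(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown node: {node!r}") from None

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def label_of(self, node: str) -> str:
        return self.labels.get(node, node)

    def out_degree(self, node: str) -> int:
        """Number of outgoing links of ``node`` (its k_out)."""
        self.index_of(node)
        return sum(1 for s, _ in self.links if s == node)

    def in_degree(self, node: str) -> int:
        self.index_of(node)
        return sum(1 for _, t in self.links if t == node)

    def adjacency(self) -> sp.csc_matrix:
        """Sparse adjacency with ``A[i, j] = 1`` iff j -> i (column = source)."""
        if not self.links:
            return sp.csc_matrix((self.N, self.N))
        src = np.fromiter((self._index[s] for s, _ in self.links), dtype=np.int64)
        dst = np.fromiter((self._index[t] for _, t in self.links), dtype=np.int64)
        data = np.ones(len(src))
        return sp.csc_matrix((data, (dst, src)), shape=(self.N, self.N))


def out_degree(net: DirectedNetwork, node: str) -> int:
    return net.out_degree(node)


def invert_network(net: DirectedNetwork) -> DirectedNetwork:
    """Reverse every link; the node set and order are unchanged.

    The Google matrix of the inverted network is the G* operator whose
    PageRank is the CheiRank of the original network.
    """
    return DirectedNetwork(
        node_ids=list(net.node_ids),
        links={(t, s) for s, t in net.links},
        labels=dict(net.labels),
        categories=dict(net.categories),
    )


# -- file I/O -------------------------------------------------------------


def _parse_fields(line: str) -> list[str]:
    # tab-separated canonically; fall back to any whitespace for hand-written files
    fields = line.split("\t") if "\t" in line else line.split()
    return [f.strip() for f in fields]


def load_label_table(path: str | Path) -> tuple[list[str], dict[str, str], dict[str, str]]:
    """Read a label table: ``id<TAB>display name[<TAB>category]`` per line.

    Returns (ordered ids, labels map, categories map).
    """
    ids: list[str] = []
    labels: dict[str, str] = {}
    categories: dict[str, str] = {}
    path = Path(path)
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = _parse_fields(line)
        if len(fields) not in (2, 3) or not fields[0]:
            raise ParseError(f"{path}:{lineno}: expected 'id<TAB>name[<TAB>category]', got {raw!r}")
        node = fields[0]
        if node not in labels:
            ids.append(node)
        labels[node] = fields[1]
        if len(fields) == 3 and fields[2]:
            categories[node] = fields[2]
    return ids, labels, categories


def load_edge_list(path: str | Path, labels_path: str | Path | None = None) -> DirectedNetwork:
    """Read a directed network from a two-column edge-list text file.

    Each non-comment line is ``source<TAB>target`` meaning source cites
    target.  Duplicate links collapse to a single link (the adjacency is
    binary) and self-loops are dropped with a logged count.  The node set is
    the union of all link endpoints plus any nodes that appear only in the
    optional label table.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    links: set[tuple[str, str]] = set()
    seen: list[str] = []
    seen_set: set[str] = set()
    dropped_self = 0
    any_content = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            any_content = any_content or line.startswith("#")
            continue
        any_content = True
        fields = _parse_fields(line)
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}:{lineno}: expected 'source<TAB>target', got {raw!r}")
        s, t = fields
        for n in (s, t):
            if n not in seen_set:
                seen_set.add(n)
                seen.append(n)
        if s == t:
            dropped_self += 1
            continue
        links.add((s, t))
    if not any_content:
        raise ParseError(f"{path}: empty edge-list file")
    if dropped_self:
        logger.info("dropped %d self-loop(s) while reading %s", dropped_self, path)

    labels: dict[str, str] = {}
    categories: dict[str, str] = {}
    if labels_path is not None:
        extra_ids, labels, categories = load_label_table(labels_path)
        for n in extra_ids:
            if n not in seen_set:
                seen_set.add(n)
                seen.append(n)
    return DirectedNetwork(node_ids=seen, links=links, labels=labels, categories=categories)


def save_edge_list(net: DirectedNetwork, path: str | Path) -> None:
    """Write the edge list byte-stably: one 'source<TAB>target' per line,
    sorted by source then target."""
    lines = [f"{s}\t{t}" for s, t in sorted(net.links)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def save_label_table(net: DirectedNetwork, path: str | Path) -> None:
    lines = []
    for n in net.node_ids:
        cat = net.categories.get(n, "")
        lines.append(f"{n}\t{net.label_of(n)}\t{cat}".rstrip("\t"))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# -- Google matrix --------------------------------------------------------


class GoogleMatrix:
    """Column-stochastic Google matrix G = alpha*S + (1-alpha)/N.

    The stochastic matrix S follows the standard construction:
    ``S[i, j] = A[i, j] / k_out(j)`` for a non-dangling column j, and a
    uniform ``1/N`` column for dangling nodes (k_out = 0).

    The uniform teleport term and the dangling-column rank-one part are held
    implicitly (sparse-plus-rank-one representation); :meth:`dense` and
    :meth:`matvec` behave exactly as if the dense G existed.
    """

    def __init__(self, net: DirectedNetwork, alpha: float = DEFAULT_ALPHA):
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"damping factor alpha must be in (0, 1), got {alpha}")
        if net.N < 1:
            raise ValueError("network must have at least one node")
        self.alpha = float(alpha)
        self.N = net.N
        self.node_ids = list(net.node_ids)
        self._index = {n: i for i, n in enumerate(self.node_ids)}
        A = net.adjacency()
        self.adjacency = A
        k_out = np.asarray(A.sum(axis=0)).ravel()
        self.dangling = k_out == 0
        inv = np.zeros(self.N)
        nz = ~self.dangling
        inv[nz] = 1.0 / k_out[nz]
        # S restricted to non-dangling columns; dangling columns handled as rank-one
        self._S_links = (A @ sp.diags(inv)).tocsc()

    @property
    def dangling_nodes(self) -> set[int]:
        return set(np.flatnonzero(self.dangling))

    def index_of(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown node: {node!r}") from None

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """Compute G @ v without materializing the dense matrix."""
        v = np.asarray(v, dtype=float)
        total = v.sum()
        dangling_mass = v[self.dangling].sum()
        out = self.alpha * (self._S_links @ v)
        out += (self.alpha * dangling_mass / self.N) + ((1.0 - self.alpha) * total / self.N)
        return out

    def dense(self) -> np.ndarray:
        """Materialize the full dense G (use only at desk scale)."""
        G = self.alpha * self._S_links.toarray()
        G[:, self.dangling] += self.alpha / self.N
        G += (1.0 - self.alpha) / self.N
        return G

    def dense_blocks(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Dense sub-block G[rows][:, cols] without building the full matrix."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        block = self.alpha * self._S_links[rows][:, cols].toarray()
        block[:, self.dangling[cols]] += self.alpha / self.N
        block += (1.0 - self.alpha) / self.N
        return block


def build_google_matrix(net: DirectedNetwork, alpha: float = DEFAULT_ALPHA) -> GoogleMatrix:
    """Build the damped column-stochastic Google matrix of a network."""
    return GoogleMatrix(net, alpha=alpha)
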