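"""Iterative "friend network" construction and top-k partner tables.

From a reduced Google matrix, the score of a candidate link j -> i is the
(G_rr + G_qrnd)[i, j] element: direct plus off-diagonal indirect weight.
Starting from seed nodes, each node's strongest same-category partners
("friends") are attached and the newly added nodes are expanded in turn
until no new node appears; finally every primary node receives its
strongest partners from the attached categories (countries, drugs), with
no further expansion from those.  Each edge is classified direct (present
in the restricted adjacency) or hidden (absent from the adjacency, carried
purely by indirect pathways).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .reduced_matrix import ReducedGoogleMatrix

__all__ = [
    "FriendNode",
    "FriendEdge",
    "FriendNetwork",
    "PartnerTable",
    "friend_scores",
    "build_friend_network",
    "top_partners",
    "export_graph",
    "import_edge_tsv",
]

SCORE_MATRICES = ("rr_plus_qrnd", "rr_plus_qr")


def _score_matrix(rgm: ReducedGoogleMatrix, score: str) -> np.ndarray:
    if score == "rr_plus_qrnd":
        return rgm.G_rr + rgm.G_qrnd
    if score == "rr_plus_qr":
        return rgm.G_rr + rgm.G_qr
    raise ValueError(f"unknown score matrix: {score!r} (expected one of {SCORE_MATRICES})")


def _edge_kind(rgm: ReducedGoogleMatrix, src_idx: int, dst_idx: int) -> str:
    """direct if the adjacency (restricted to the subset) has the link,
    hidden otherwise."""
    return "direct" if rgm.restricted_adjacency[dst_idx, src_idx] else "hidden"


def friend_scores(
    rgm: ReducedGoogleMatrix,
    from_node: str,
    candidate_set: list[str],
    score: str = "rr_plus_qrnd",
) -> list[tuple[str, float]]:
    """Candidates ordered by decreasing link strength from ``from_node``.

    The score of a candidate is the chosen matrix element
    [candidate, from_node] (columns index link sources); ties are broken by
    ascending local PageRank index.
    """
    M = _score_matrix(rgm, score)
    j = rgm.index_of(from_node)
    local_k = rgm.local_pagerank_index()
    scored = []
    for cand in candidate_set:
        if cand == from_node:
            raise ValueError("candidate set must not contain the from_node itself")
        scored.append((cand, float(M[rgm.index_of(cand), j])))
    scored.sort(key=lambda cs: (-cs[1], local_k[cs[0]]))
    return scored


@dataclass
class FriendNode:
    id: str
    category: str
    role: str  # "seed" | "expanded" | "attached"
    iteration_added: int


@dataclass
class FriendEdge:
    source: str
    target: str
    weight: float
    iteration: int
    kind: str  # "direct" | "hidden"


@dataclass
class FriendNetwork:
    nodes: list[FriendNode]
    edges: list[FriendEdge]
    seeds: list[str]
    params: dict = field(default_factory=dict)

    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def primary_nodes(self) -> list[str]:
        return [n.id for n in self.nodes if n.role in ("seed", "expanded")]


def build_friend_network(
    rgm: ReducedGoogleMatrix,
    seeds: list[str],
    categories: dict[str, str],
    primary_category: str,
    attach_categories: list[str] | None = None,
    n_friends: int = 2,
    n_attach: int = 2,
    max_iter: int | None = None,
    score: str = "rr_plus_qrnd",
) -> FriendNetwork:
    """Grow the friend network from seed nodes to fixpoint.

    Iteration 1 expands the seeds; each later iteration expands only the
    nodes newly added in the previous one (breadth-first), stopping when an
    iteration adds no new primary-category node (or at ``max_iter``, a
    safety valve).  Afterwards every primary node present receives its
    ``n_attach`` strongest partners in each attach category; no expansion
    happens from attached nodes.
    """
    if categories is None:
        raise ValueError("a category map is required")
    attach_categories = attach_categories or []
    for s in seeds:
        if s not in rgm.subset:
            raise ValueError(f"seed not in reduced subset: {s!r}")
        if categories.get(s) != primary_category:
            raise ValueError(f"seed {s!r} is not of category {primary_category!r}")

    primary_pool = [n for n in rgm.subset if categories.get(n) == primary_category]
    nodes: dict[str, FriendNode] = {
        s: FriendNode(id=s, category=primary_category, role="seed", iteration_added=0)
        for s in seeds
    }
    edges: list[FriendEdge] = []

    frontier = list(seeds)
    iteration = 0
    while frontier and n_friends > 0:
        iteration += 1
        if max_iter is not None and iteration > max_iter:
            break
        newly_added: list[str] = []
        for node in frontier:
            candidates = [c for c in primary_pool if c != node]
            for friend, weight in friend_scores(rgm, node, candidates, score)[:n_friends]:
                edges.append(
                    FriendEdge(
                        source=node,
                        target=friend,
                        weight=weight,
                        iteration=iteration,
                        kind=_edge_kind(rgm, rgm.index_of(node), rgm.index_of(friend)),
                    )
                )
                if friend not in nodes:
                    nodes[friend] = FriendNode(
                        id=friend,
                        category=primary_category,
                        role="expanded",
                        iteration_added=iteration,
                    )
                    newly_added.append(friend)
        frontier = newly_added

    # satellite attachment: strongest partners per attach category, no expansion
    for node in list(nodes):
        if nodes[node].role == "attached":
            continue
        for cat in attach_categories:
            pool = [c for c in rgm.subset if categories.get(c) == cat and c != node]
            if not pool:
                continue
            for partner, weight in friend_scores(rgm, node, pool, score)[:n_attach]:
                it = nodes[node].iteration_added + 1
                edges.append(
                    FriendEdge(
                        source=node,
                        target=partner,
                        weight=weight,
                        iteration=it,
                        kind=_edge_kind(rgm, rgm.index_of(node), rgm.index_of(partner)),
                    )
                )
                if partner not in nodes:
                    nodes[partner] = FriendNode(
                        id=partner,
                        category=cat,
                        role="attached",
                        iteration_added=it,
                    )

    return FriendNetwork(
        nodes=list(nodes.values()),
        edges=edges,
        seeds=list(seeds),
        params={
            "n_friends": n_friends,
            "n_attach": n_attach,
            "score": score,
            "primary_category": primary_category,
            "attach_categories": list(attach_categories),
        },
    )


@dataclass
class PartnerTable:
    """Per row node, the k strongest partners with scores and link kinds."""

    rows: dict[str, list[tuple[str, float, str]]]
    k: int
    score: str
    short_rows: list[str] = field(default_factory=list)  # rows with fewer than k partners


def top_partners(
    rgm: ReducedGoogleMatrix,
    rows: list[str],
    cols: list[str],
    k: int = 3,
    score: str = "rr_plus_qrnd",
) -> PartnerTable:
    """For each row node, its k strongest partners among ``cols``.

    The strength of partner c for row node r is the chosen score matrix
    element [c, r] (the link points from r to c).  Rows and cols must be
    disjoint; if k exceeds the candidate count the full sorted column is
    returned and the row is flagged short.
    """
    overlap = set(rows) & set(cols)
    if overlap:
        raise ValueError(f"rows and cols must be disjoint; both contain {sorted(overlap)}")
    table: dict[str, list[tuple[str, float, str]]] = {}
    short: list[str] = []
    for r in rows:
        ranked = friend_scores(rgm, r, list(cols), score)[:k]
        if len(ranked) < k:
            short.append(r)
        table[r] = [
            (c, s, _edge_kind(rgm, rgm.index_of(r), rgm.index_of(c))) for c, s in ranked
        ]
    return PartnerTable(rows=table, k=k, score=score, short_rows=short)


# -- export ---------------------------------------------------------------


def _export_edge_tsv(fn: FriendNetwork, path: Path) -> None:
    lines = ["record\tid\tcategory_or_target\trole_or_weight\titeration\tkind"]
    for n in fn.nodes:
        lines.append(f"node\t{n.id}\t{n.category}\t{n.role}\t{n.iteration_added}\t")
    for e in fn.edges:
        lines.append(
            f"edge\t{e.source}\t{e.target}\t{e.weight!r}\t{e.iteration}\t{e.kind}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def import_edge_tsv(path: str | Path) -> FriendNetwork:
    """Read back a friend network written in the edge-tsv dialect."""
    nodes: list[FriendNode] = []
    edges: list[FriendEdge] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for raw in lines[1:]:
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if fields[0] == "node":
            nodes.append(
                FriendNode(
                    id=fields[1],
                    category=fields[2],
                    role=fields[3],
                    iteration_added=int(fields[4]),
                )
            )
        elif fields[0] == "edge":
            edges.append(
                FriendEdge(
                    source=fields[1],
                    target=fields[2],
                    weight=float(fields[3]),
                    iteration=int(fields[4]),
                    kind=fields[5],
                )
            )
    seeds = [n.id for n in nodes if n.role == "seed"]
    return FriendNetwork(nodes=nodes, edges=edges, seeds=seeds)


def _export_graphml(fn: FriendNetwork, path: Path) -> None:
    g = nx.MultiDiGraph()
    for n in fn.nodes:
        g.add_node(n.id, category=n.category, role=n.role, iteration=n.iteration_added)
    for e in fn.edges:
        g.add_edge(e.source, e.target, weight=e.weight, iteration=e.iteration, kind=e.kind)
    nx.write_graphml(g, path)


def _export_dot(fn: FriendNetwork, path: Path) -> None:
    def q(s: str) -> str:
        return '"' + s.replace('"', '\\"') + '"'

    lines = ["digraph friend {"]
    for n in fn.nodes:
        lines.append(
            f"  {q(n.id)} [category={q(n.category)}, role={q(n.role)}, iteration={n.iteration_added}];"
        )
    for e in fn.edges:
        style = "solid" if e.kind == "direct" else "dashed"
        lines.append(
            f"  {q(e.source)} -> {q(e.target)} "
            f"[weight={e.weight:.6g}, iteration={e.iteration}, kind={q(e.kind)}, style={style}];"
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_graph(fn: FriendNetwork, path: str | Path, format: str = "edge-tsv") -> None:
    """Write a friend network to ``edge-tsv`` (lossless), ``graphml`` or ``dot``."""
    path = Path(path)
    if format == "edge-tsv":
        _export_edge_tsv(fn, path)
    elif format == "graphml":
        _export_graphml(fn, path)
    elif format == "dot":
        _export_dot(fn, path)
    else:
        raise ValueError(f"unknown export format: {format!r}")
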