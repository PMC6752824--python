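"""PageRank sensitivity of reduced-network nodes to link perturbations.

A link b -> a of the reduced Google matrix is boosted by multiplying the
element (G_R)_{a,b} by (1 + delta) and renormalizing column b to unit sum.
The sensitivity of an observed node c is the logarithmic derivative of its
reduced PageRank, D = d ln P(c) / d delta, evaluated by finite differences
(central by default, delta = 1e-4).  Diagonal sensitivity observes one of
the perturbed link's endpoints; nondiagonal sensitivity observes a third
node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reduced_matrix import ReducedGoogleMatrix, _stationary

__all__ = [
    "SensitivityMatrix",
    "perturb_column",
    "perturbed_matrix",
    "sensitivity",
    "sensitivity_matrix",
]

DEFAULT_DELTA = 1e-4
DEFAULT_SCHEME = "central"


def perturb_column(matrix: np.ndarray, a: int, b: int, delta: float) -> np.ndarray:
    """Multiply element (a, b) by (1 + delta) and renormalize column b.

    All other columns are untouched; the result is column-stochastic.
    Perturbing a structural zero is undefined and raises ``ValueError``.
    """
    M = np.asarray(matrix, dtype=float)
    if delta <= -1:
        raise ValueError("delta must be > -1")
    if M[a, b] <= 0:
        raise ValueError(
            f"element ({a}, {b}) is not positive; perturbing a structural zero is undefined"
        )
    out = M.copy()
    out[a, b] *= 1.0 + delta
    out[:, b] /= out[:, b].sum()
    return out


def perturbed_matrix(
    rgm: ReducedGoogleMatrix, source: str, target: str, delta: float
) -> np.ndarray:
    """Boost the reduced-matrix link source -> target and renormalize.

    ``source`` names the column (link origin b) and ``target`` the row
    (link destination a)."""
    a = rgm.index_of(target)
    b = rgm.index_of(source)
    return perturb_column(rgm.G_R, a, b, delta)


def _log_p(M: np.ndarray, c: int, tol: float, max_iter: int) -> float:
    p = _stationary(M, tol=tol, max_iter=max_iter)
    pc = p[c]
    if pc <= 0:
        raise RuntimeError("observed PageRank probability is not positive")
    return float(np.log(pc))


def sensitivity(
    rgm: ReducedGoogleMatrix,
    source: str,
    target: str,
    observed: str | None = None,
    delta: float = DEFAULT_DELTA,
    scheme: str = DEFAULT_SCHEME,
    tol: float = 1e-14,
    max_iter: int = 200_000,
) -> float:
    """Logarithmic PageRank derivative D = d ln P(observed) / d delta.

    The link ``source -> target`` of G_R is boosted by (1 + delta) with
    column renormalization, the reduced PageRank is recomputed, and the
    derivative is formed by finite differences:

    - ``scheme="central"`` (default): [ln P_{+d}(c) - ln P_{-d}(c)] / (2 d)
    - ``scheme="forward"``: [ln P_{+d}(c) - ln P_0(c)] / d

    ``observed`` defaults to ``target`` (diagonal sensitivity of the link's
    destination).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if scheme not in ("central", "forward"):
        raise ValueError(f"unknown scheme: {scheme!r}")
    if observed is None:
        observed = target
    c = rgm.index_of(observed)
    if scheme == "central":
        lp_plus = _log_p(perturbed_matrix(rgm, source, target, +delta), c, tol, max_iter)
        lp_minus = _log_p(perturbed_matrix(rgm, source, target, -delta), c, tol, max_iter)
        return (lp_plus - lp_minus) / (2.0 * delta)
    lp_plus = _log_p(perturbed_matrix(rgm, source, target, +delta), c, tol, max_iter)
    lp_zero = float(np.log(rgm.pagerank(tol=tol, max_iter=max_iter)[c]))
    return (lp_plus - lp_zero) / delta


@dataclass
class SensitivityMatrix:
    """Grid of sensitivities D for perturbed links (source, target) pairs.

    ``values[i, j]`` is the sensitivity for the link ``sources[j] ->
    targets[i]``; entries are NaN where the reduced matrix has no positive
    element to perturb (absent link, not zero sensitivity).
    """

    sources: list[str]
    targets: list[str]
    values: np.ndarray
    observe: str
    delta: float
    scheme: str

    def value(self, source: str, target: str) -> float:
        return float(
            self.values[self.targets.index(target), self.sources.index(source)]
        )

    def to_tsv(self, path) -> None:
        """Long-format heat table: row label, column label, value."""
        lines = ["target\tsource\tD"]
        for i, t in enumerate(self.targets):
            for j, s in enumerate(self.sources):
                v = self.values[i, j]
                lines.append(f"{t}\t{s}\t{'NA' if np.isnan(v) else format(v, '.17g')}")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def sensitivity_matrix(
    rgm: ReducedGoogleMatrix,
    sources: list[str],
    targets: list[str],
    observe: str = "target",
    observed_node: str | None = None,
    delta: float = DEFAULT_DELTA,
    scheme: str = DEFAULT_SCHEME,
) -> SensitivityMatrix:
    """Sensitivities for every perturbable link sources x targets.

    ``observe`` selects the observed node per entry: ``"target"`` reports
    D(src -> tgt, tgt) (e.g. how a country responds to a cancer -> country
    link), ``"source"`` reports D(src -> tgt, src) (e.g. how a cancer
    responds to its own cancer -> drug link), and ``"fixed"`` observes the
    single node ``observed_node`` for every entry.  Structurally absent
    links yield NaN.
    """
    if observe not in ("target", "source", "fixed"):
        raise ValueError(f"unknown observe mode: {observe!r}")
    if observe == "fixed" and observed_node is None:
        raise ValueError("observe='fixed' requires observed_node")
    values = np.full((len(targets), len(sources)), np.nan)
    for j, s in enumerate(sources):
        b = rgm.index_of(s)
        for i, t in enumerate(targets):
            a = rgm.index_of(t)
            if rgm.G_R[a, b] <= 0:
                continue  # absent link: flagged NaN
            obs = {"target": t, "source": s, "fixed": observed_node}[observe]
            values[i, j] = sensitivity(
                rgm, source=s, target=t, observed=obs, delta=delta, scheme=scheme
            )
    return SensitivityMatrix(
        sources=list(sources),
        targets=list(targets),
        values=values,
        observe=observe,
        delta=delta,
        scheme=scheme,
    )
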