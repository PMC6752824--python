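"""Reduced Google matrix (REGOMAX) with direct/indirect decomposition.

Given the global Google matrix G partitioned over a subset r of N_r nodes of
interest and its complement s (the "scattering" bulk),

    G = [[G_rr, G_rs],
         [G_sr, G_ss]],

the reduced Google matrix is the effective stochastic operator on the subset
that accounts for every pathway through the bulk:

    G_R = G_rr + G_rs (1 - G_ss)^(-1) G_sr.

Its defining property is PageRank conservation: the leading eigenvector of
G_R equals the global PageRank restricted to the subset and renormalized.

Splitting the bulk resolvent over the leading eigenspace of G_ss (leading
eigenvalue lambda_c, right/left eigenvectors psi_R/psi_L with
psi_L . psi_R = 1, projector P_c = psi_R psi_L^T, Q_c = 1 - P_c,
Gbar_ss = Q_c G_ss Q_c) gives the three-component decomposition

    G_R = G_rr + G_pr + G_qr,
    G_pr = G_rs [P_c / (1 - lambda_c)] G_sr,
    G_qr = G_rs Q_c (1 - Gbar_ss)^(-1) Q_c G_sr,

where G_rr carries the direct links, G_pr is a rank-one-dominated term that
essentially re-encodes the global PageRank, and G_qr carries the indirect
pathways.  The off-diagonal part G_qrnd of G_qr is the hidden-link signal: a
pair with zero direct adjacency but positive G_qrnd interacts purely through
the bulk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .graph_core import GoogleMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ReducedGoogleMatrix",
    "DegenerateSpectrumError",
    "reduce",
    "component_weights",
    "direct_link_mask",
    "hidden_link_mask",
]

#: Slack added to the (1-alpha)/N "numerical zero" threshold of G_rr entries.
ZERO_SLACK = 1e-15

#: Refuse the spectral split when |lambda_1| - |lambda_2| of G_ss is below this.
EIGENGAP_MIN = 1e-8

#: Complement size up to which the full spectrum is computed densely.
_DENSE_EIG_LIMIT = 1500


class DegenerateSpectrumError(RuntimeError):
    """The leading eigenvalue of the complement block is (nearly) degenerate,
    so the G_pr / G_qr split is ill-defined."""


@dataclass
class ReducedGoogleMatrix:
    """The reduced Google matrix of a node subset and its decomposition.

    All matrices are dense N_r x N_r with the convention that columns index
    link sources (entry [i, j] is the effective transition j -> i).
    ``restricted_adjacency`` is the boolean global adjacency restricted to
    the subset, used to tell direct from hidden links.
    """

    subset: list[str]
    G_R: np.ndarray
    G_rr: np.ndarray
    G_pr: np.ndarray
    G_qr: np.ndarray
    lambda_c: float | None
    alpha: float
    N_global: int
    method: str
    restricted_adjacency: np.ndarray
    series_depth: int | None = None
    _pagerank: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.subset)}

    @property
    def N_r(self) -> int:
        return len(self.subset)

    @property
    def G_qrd(self) -> np.ndarray:
        """Diagonal part of G_qr."""
        return np.diag(np.diag(self.G_qr))

    @property
    def G_qrnd(self) -> np.ndarray:
        """Off-diagonal (hidden-link) part of G_qr."""
        out = self.G_qr.copy()
        np.fill_diagonal(out, 0.0)
        return out

    @property
    def weights(self) -> dict[str, float]:
        return component_weights(self)

    def index_of(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"node not in subset: {node!r}") from None

    def pagerank(self, tol: float = 1e-14, max_iter: int = 200_000) -> np.ndarray:
        """Stationary probability vector of G_R (normalized to sum one).

        By construction it equals the global PageRank restricted to the
        subset up to the renormalization constant.
        """
        if self._pagerank is None:
            self._pagerank = _stationary(self.G_R, tol=tol, max_iter=max_iter)
        return self._pagerank

    def local_pagerank_index(self) -> dict[str, int]:
        """1-based rank of each subset node by the reduced PageRank."""
        p = self.pagerank()
        order = np.lexsort((np.arange(p.size), -p))
        return {self.subset[j]: r + 1 for r, j in enumerate(order)}


def _stationary(M: np.ndarray, tol: float = 1e-14, max_iter: int = 200_000) -> np.ndarray:
    """Leading (unit-eigenvalue) eigenvector of a column-stochastic matrix
    by power iteration, normalized to sum one."""
    n = M.shape[0]
    v = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        w = M @ v
        w = w / w.sum()
        if np.abs(w - v).sum() < tol:
            return w
        v = w
    raise RuntimeError(f"stationary vector did not converge (tol={tol})")


def _leading_eigenpair(G_ss: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Leading eigenvalue of G_ss with right and left eigenvectors.

    psi_R is scaled to sum one and psi_L so that psi_L . psi_R = 1, making
    P_c = psi_R psi_L^T a proper spectral projector.  Raises
    :class:`DegenerateSpectrumError` when the modulus gap to the second
    eigenvalue is below ``EIGENGAP_MIN``.
    """
    n = G_ss.shape[0]
    if n == 1:
        lam = float(G_ss[0, 0])
        return lam, np.ones(1), np.ones(1)
    if n <= _DENSE_EIG_LIMIT:
        w, vl, vr = scipy.linalg.eig(G_ss, left=True, right=True)
        mods = np.abs(w)
        order = np.argsort(-mods)
        gap = mods[order[0]] - mods[order[1]]
        if gap < EIGENGAP_MIN:
            raise DegenerateSpectrumError(
                f"leading eigenvalue of the complement block is degenerate "
                f"(modulus gap {gap:.3e} < {EIGENGAP_MIN})"
            )
        k = order[0]
        lam = w[k]
        psi_r = vr[:, k]
        # scipy returns vl with vl.conj().T @ A = w * vl.conj().T
        psi_l = vl[:, k].conj()
    else:
        w, vr = scipy.sparse.linalg.eigs(G_ss, k=2, which="LM")
        wl, vl = scipy.sparse.linalg.eigs(G_ss.T, k=2, which="LM")
        mods = np.abs(w)
        order = np.argsort(-mods)
        gap = mods[order[0]] - mods[order[1]]
        if gap < EIGENGAP_MIN:
            raise DegenerateSpectrumError(
                f"leading eigenvalue of the complement block is degenerate "
                f"(modulus gap {gap:.3e} < {EIGENGAP_MIN})"
            )
        lam = w[order[0]]
        psi_r = vr[:, order[0]]
        psi_l = vl[:, np.argsort(-np.abs(wl))[0]]
    # Perron eigenvector of a (sub)stochastic nonnegative block: real, one-signed
    if abs(np.imag(lam)) > 1e-12:
        raise DegenerateSpectrumError("leading eigenvalue is not real")
    lam = float(np.real(lam))
    psi_r = np.real(psi_r)
    psi_l = np.real(psi_l)
    s = psi_r.sum()
    if abs(s) < 1e-300:
        raise DegenerateSpectrumError("right eigenvector sums to zero")
    psi_r = psi_r / s
    dot = psi_l @ psi_r
    if abs(dot) < 1e-14:
        raise DegenerateSpectrumError("left/right eigenvectors are near-orthogonal")
    psi_l = psi_l / dot
    return lam, psi_r, psi_l


def _qr_series(Gbar_ss: np.ndarray, X0: np.ndarray, tol: float) -> tuple[np.ndarray, int]:
    """Evaluate (1 - Gbar_ss)^(-1) X0 by the geometric series with a
    tail bound below ``tol``.  Returns (sum, truncation depth)."""
    total = X0.copy()
    term = X0.copy()
    prev_norm = np.abs(term).sum()
    depth = 0
    for depth in range(1, 100_000):
        term = Gbar_ss @ term
        total += term
        norm = np.abs(term).sum()
        if norm == 0.0:
            break
        ratio = norm / prev_norm if prev_norm > 0 else 0.0
        prev_norm = norm
        if ratio < 1.0 and norm * ratio / (1.0 - ratio) < tol:
            break
    else:
        raise RuntimeError("truncated series for (1 - Gbar_ss)^(-1) did not converge")
    logger.debug("series evaluation truncated at depth %d", depth)
    return total, depth


def reduce(
    G: GoogleMatrix,
    subset: list[str],
    method: str = "direct",
    qr_eval: str = "solve",
    series_tol: float = 1e-12,
) -> ReducedGoogleMatrix:
    """Compute the reduced Google matrix of a node subset.

    Parameters
    ----------
    G
        Global Google matrix.
    subset
        Node identifiers of interest (order defines the matrix axes).
    method
        ``"direct"``: G_R from one linear solve on the complement block,
        then split off G_pr (leading-eigenspace term) and obtain G_qr by
        subtraction.  ``"spectral"``: build G_pr and G_qr from the projector
        formulas and sum them; both methods agree to solver precision.
    qr_eval
        For ``method="spectral"``, evaluate the bulk resolvent by a linear
        ``"solve"`` or by the truncated geometric ``"series"`` (tail bound
        below ``series_tol``).
    """
    if method not in ("direct", "spectral"):
        raise ValueError(f"unknown method: {method!r}")
    if qr_eval not in ("solve", "series"):
        raise ValueError(f"unknown qr_eval: {qr_eval!r}")
    if not subset:
        raise ValueError("subset must contain at least one node")
    if len(set(subset)) != len(subset):
        raise ValueError("subset contains duplicate nodes")

    idx_r = np.array([G.index_of(n) for n in subset], dtype=np.int64)
    in_subset = np.zeros(G.N, dtype=bool)
    in_subset[idx_r] = True
    idx_s = np.flatnonzero(~in_subset)

    A = G.adjacency
    A_rr = np.asarray(A[idx_r][:, idx_r].toarray() > 0)

    if idx_s.size == 0:
        # degenerate N_r = N case: nothing to integrate out
        G_full = G.dense()
        zeros = np.zeros_like(G_full)
        return ReducedGoogleMatrix(
            subset=list(subset),
            G_R=G_full,
            G_rr=G_full.copy(),
            G_pr=zeros,
            G_qr=zeros.copy(),
            lambda_c=None,
            alpha=G.alpha,
            N_global=G.N,
            method=method,
            restricted_adjacency=A_rr,
        )

    G_rr = G.dense_blocks(idx_r, idx_r)
    G_rs = G.dense_blocks(idx_r, idx_s)
    G_sr = G.dense_blocks(idx_s, idx_r)
    G_ss = G.dense_blocks(idx_s, idx_s)

    n_s = idx_s.size
    lam, psi_r, psi_l = _leading_eigenpair(G_ss)
    if not 0.0 < lam < 1.0:
        raise RuntimeError(
            f"leading eigenvalue of the complement block is {lam}; expected a "
            "damped sub-stochastic block with 0 < lambda_c < 1"
        )
    # P_c applied to G_sr: psi_r (psi_l . columns)
    proj_sr = np.outer(psi_r, psi_l @ G_sr)
    G_pr = (G_rs @ proj_sr) / (1.0 - lam)

    depth: int | None = None
    if method == "direct":
        X = scipy.linalg.solve(np.eye(n_s) - G_ss, G_sr)
        G_R = G_rr + G_rs @ X
        G_qr = G_R - G_rr - G_pr
    else:
        Qc_G_sr = G_sr - proj_sr
        # Gbar_ss = Q_c G_ss Q_c with the numerical projector
        tmp = G_ss - np.outer(psi_r, psi_l @ G_ss)
        Gbar = tmp - np.outer(tmp @ psi_r, psi_l)
        if qr_eval == "solve":
            Y = scipy.linalg.solve(np.eye(n_s) - Gbar, Qc_G_sr)
        else:
            Y, depth = _qr_series(Gbar, Qc_G_sr, series_tol)
        # re-apply Q_c on the left to stay in the complement of the leading mode
        Y = Y - np.outer(psi_r, psi_l @ Y)
        G_qr = G_rs @ Y
        G_R = G_rr + G_pr + G_qr

    return ReducedGoogleMatrix(
        subset=list(subset),
        G_R=G_R,
        G_rr=G_rr,
        G_pr=G_pr,
        G_qr=G_qr,
        lambda_c=lam,
        alpha=G.alpha,
        N_global=G.N,
        method=method,
        restricted_adjacency=A_rr,
        series_depth=depth,
    )


def component_weights(rgm: ReducedGoogleMatrix) -> dict[str, float]:
    """Component weights W_X = sum of elements of X divided by N_r.

    W_R = 1 by column stochasticity and W_rr + W_pr + W_qr = 1 by the
    decomposition identity.
    """
    n = rgm.N_r
    return {
        "W_R": float(rgm.G_R.sum() / n),
        "W_rr": float(rgm.G_rr.sum() / n),
        "W_pr": float(rgm.G_pr.sum() / n),
        "W_qr": float(rgm.G_qr.sum() / n),
        "W_qrnd": float(rgm.G_qrnd.sum() / n),
    }


def direct_link_mask(rgm: ReducedGoogleMatrix) -> np.ndarray:
    """Boolean mask of direct links: entries of G_rr above the teleport floor.

    An entry is a numerical zero when it does not exceed (1 - alpha)/N of the
    parent matrix; above that it corresponds one-to-one to an adjacency link
    restricted to the subset.
    """
    threshold = (1.0 - rgm.alpha) / rgm.N_global + ZERO_SLACK
    return rgm.G_rr > threshold


def hidden_link_mask(rgm: ReducedGoogleMatrix, threshold: float = 0.0) -> np.ndarray:
    """Boolean mask of hidden links: positive off-diagonal indirect weight
    (G_qrnd > ``threshold``) where no direct link exists."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (rgm.G_qrnd > threshold) & ~direct_link_mask(rgm)
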