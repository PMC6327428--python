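"""Label propagation on the lncRNA side of the bipartite network.

Starting from the known association matrix M (n lncRNAs x m proteins),
scores diffuse over the lncRNA-lncRNA similarity graph W:

    P^t = rho * W @ P^{t-1} + (1 - rho) * M,     P^0 = M.

Each node absorbs its neighbors' labels with probability ``rho`` and
retains its initial labels with probability ``1 - rho``.  Because W is
row-stochastic and ``rho < 1``, the iteration is a contraction with
factor rho and converges geometrically to the unique fixed point

    P* = (1 - rho) (I - rho W)^{-1} M,

which :func:`closed_form` computes directly via a linear solve and
serves as an exact oracle for the iterative route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix

__all__ = ["PropagationParams", "ScoreMatrix", "propagate", "closed_form"]


@dataclass
class PropagationParams:
    """Absorption probability, convergence tolerance and iteration cap."""

    rho: float = 0.6
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")


@dataclass
class ScoreMatrix:
    """Real-valued predicted interaction scores with provenance metadata."""

    values: np.ndarray
    lncrna_ids: list[str] | None = None
    protein_ids: list[str] | None = None
    n_iter: int | None = None
    converged: bool | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("score matrix must be 2-d")
        if not np.isfinite(v).all():
            raise ValueError("score entries must be finite")
        self.values = v

    def to_csv(self, path) -> None:
        import pandas as pd

        n, m = self.values.shape
        idx = self.lncrna_ids or [f"L{i}" for i in range(n)]
        cols = self.protein_ids or [f"P{j}" for j in range(m)]
        pd.DataFrame(self.values, index=idx, columns=cols).to_csv(path)

    def ranked_pairs(self, known=None, exclude_known: bool = True):
        """DataFrame of (lncrna, protein, score, rank), best first.

        ``known`` is a binary matrix of training edges; when
        ``exclude_known`` those pairs are omitted, leaving only novel
        candidate interactions.
        """
        import pandas as pd

        n, m = self.values.shape
        idx = self.lncrna_ids or [f"L{i}" for i in range(n)]
        cols = self.protein_ids or [f"P{j}" for j in range(m)]
        mask = np.ones((n, m), dtype=bool)
        if known is not None and exclude_known:
            mask &= np.asarray(known) == 0
        rows, cs = np.where(mask)
        df = pd.DataFrame(
            {
                "lncrna": [idx[i] for i in rows],
                "protein": [cols[j] for j in cs],
                "score": self.values[rows, cs],
            }
        )
        df = df.sort_values(
            ["score", "lncrna", "protein"], ascending=[False, True, True]
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df


def _as_W(W) -> np.ndarray:
    if isinstance(W, SimilarityMatrix):
        return W.values
    return np.asarray(W, dtype=float)


def _as_M(M) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    # accept an InteractionNetwork without importing it (duck typing)
    if hasattr(M, "adjacency"):
        return (
            np.asarray(M.adjacency, dtype=float),
            list(M.lncrna_ids),
            list(M.protein_ids),
        )
    return np.asarray(M, dtype=float), None, None


def _check_row_stochastic(W: np.ndarray) -> None:
    sums = W.sum(axis=1)
    bad = (sums > 1e-6) & (np.abs(sums - 1.0) > 1e-6)
    if bad.any():
        raise ValueError(
            f"W rows {np.where(bad)[0].tolist()} are not row-stochastic"
        )


def propagate(W, M, params: PropagationParams | None = None) -> ScoreMatrix:
    """Iterate ``P^t = rho W P^{t-1} + (1-rho) M`` from ``P^0 = M``.

    Stops when the max-abs elementwise change drops below ``tol`` or at
    ``max_iter`` (with a warning; the partial result is returned).
    """
    if params is None:
        params = PropagationParams()
    Wv = _as_W(W)
    Mv, lnc, prot = _as_M(M)
    if Wv.shape[0] != Wv.shape[1] or Wv.shape[0] != Mv.shape[0]:
        raise ValueError("W must be n x n and M n x m")
    _check_row_stochastic(Wv)

    P = Mv.copy()
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        P_next = params.rho * (Wv @ P) + (1.0 - params.rho) * Mv
        if np.abs(P_next - P).max() < params.tol:
            P = P_next
            converged = True
            break
        P = P_next
    if not converged:
        warnings.warn(
            f"propagation did not converge in {params.max_iter} iterations"
        )
    return ScoreMatrix(P, lnc, prot, n_iter=it, converged=converged)


def closed_form(W, M, rho: float = 0.6) -> ScoreMatrix:
    """Exact fixed point ``P* = (1-rho) (I - rho W)^{-1} M`` by linear solve."""
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    Wv = _as_W(W)
    Mv, lnc, prot = _as_M(M)
    n = Wv.shape[0]
    A = np.eye(n) - rho * Wv
    P = np.linalg.solve(A, (1.0 - rho) * Mv)
    return ScoreMatrix(P, lnc, prot, n_iter=0, converged=True)
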