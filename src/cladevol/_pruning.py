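"""Felsenstein pruning over array-form trees, with branch-length gradients.

State-count agnostic: the same engine serves the 61-state codon models, the
4-state nucleotide models and the 20-state amino-acid profile models.  Sites
are compressed to unique patterns with multiplicities; gap/ambiguous states
are missing data (all-ones tip partials).  Per-node rescaling guards against
underflow; rescaling factors cancel in the gradient ratios, so gradients are
computed scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .trees import TreeArrays

__all__ = ["ReversibleEigen", "PruningModel", "compress_patterns"]

MISSING = -1


def compress_patterns(site_states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical columns.

    Parameters
    ----------
    site_states:
        ``(n_taxa, n_sites)`` integer matrix, ``MISSING`` (−1) for gaps.

    Returns
    -------
    patterns : ``(n_taxa, n_patterns)``, weights : ``(n_patterns,)``.
    """
    cols, inverse, counts = np.unique(
        site_states.T, axis=0, return_inverse=True, return_counts=True
    )
    return cols.T.copy(), counts.astype(float)


@dataclass
class ReversibleEigen:
    """Eigendecomposition of a reversible generator Q with stationary π.

    ``S = diag(√π) Q diag(1/√π)`` is symmetric; with ``S = U Λ Uᵀ``,
    ``P(t) = diag(1/√π) U e^{Λt} Uᵀ diag(√π)`` and
    ``Q·P(t)`` replaces ``e^{Λt}`` with ``Λ e^{Λt}``.
    """

    lam: np.ndarray
    left: np.ndarray   # diag(1/√π) U
    right: np.ndarray  # Uᵀ diag(√π)

    @classmethod
    def from_q(cls, Q: np.ndarray, pi: np.ndarray) -> "ReversibleEigen":
        if not np.all(np.isfinite(Q)):
            raise ValueError("non-finite generator matrix")
        sqrt_pi = np.sqrt(pi)
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        S = (S + S.T) / 2.0
        lam, U = eigh(S)
        return cls(lam=lam, left=U / sqrt_pi[:, None], right=U.T * sqrt_pi[None, :])

    def transition(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.lam * t)) @ self.right
        return np.clip(P, 0.0, None)

    def qp(self, t: float) -> np.ndarray:
        """d/dt P(t) = Q P(t)."""
        return (self.left * (self.lam * np.exp(self.lam * t))) @ self.right


class PruningModel:
    """Pruning likelihood for one alignment on one tree.

    Parameters
    ----------
    arrays:
        Postorder array view of the tree.
    patterns:
        ``(n_taxa, n_patterns)`` integer states, −1 missing.
    weights:
        Pattern multiplicities.
    n_states:
        Size of the state space.
    """

    def __init__(
        self,
        arrays: TreeArrays,
        patterns: np.ndarray,
        weights: np.ndarray,
        n_states: int,
    ):
        self.arrays = arrays
        self.weights = np.asarray(weights, dtype=float)
        self.n_states = n_states
        self.n_patterns = patterns.shape[1]
        # Precompute tip partials: (node, pattern, state)
        self._tip_partials: dict[int, np.ndarray] = {}
        for node in range(arrays.n_nodes):
            li = arrays.leaf_index[node]
            if li < 0:
                continue
            states = patterns[li]
            part = np.zeros((self.n_patterns, n_states))
            obs = states >= 0
            part[obs, states[obs]] = 1.0
            part[~obs, :] = 1.0
            self._tip_partials[node] = part

    # ---------------------------------------------------------------- core

    def _postorder(self, P: dict[int, np.ndarray]):
        """Scaled below-partials C and per-node log-scalers."""
        a = self.arrays
        C: dict[int, np.ndarray] = {}
        logscale: dict[int, np.ndarray] = {}
        for node in a.postorder:
            kids = a.children[node]
            if not kids:
                C[node] = self._tip_partials[node]
                logscale[node] = np.zeros(self.n_patterns)
                continue
            part = np.ones((self.n_patterns, self.n_states))
            scale = np.zeros(self.n_patterns)
            for k in kids:
                part = part * (C[k] @ P[k].T)
                scale = scale + logscale[k]
            m = part.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            C[node] = part / m[:, None]
            logscale[node] = scale + np.log(m)
        return C, logscale

    def loglik(self, P: dict[int, np.ndarray], root_freq: np.ndarray) -> float:
        C, logscale = self._postorder(P)
        root = self.arrays.root
        site_l = C[root] @ root_freq
        if np.any(site_l <= 0):
            return -np.inf
        return float(np.sum(self.weights * (np.log(site_l) + logscale[root])))

    def loglik_and_branch_grad(
        self,
        P: dict[int, np.ndarray],
        QP: dict[int, np.ndarray],
        root_freq: np.ndarray,
    ) -> tuple[float, np.ndarray]:
        """lnL and d lnL / d t_e for every edge (indexed by child node id).

        Uses one postorder and one preorder sweep.  For edge e = (u, v):
        site L ∝ (A_u ∘ Π_{s≠v} P_s C_s) · (P_e C_v); the derivative replaces
        P_e by Q P_e, and the shared (unknown) scale cancels in the ratio.
        """
        a = self.arrays
        C, logscale = self._postorder(P)
        root = a.root
        site_l = C[root] @ root_freq
        if np.any(site_l <= 0):
            return -np.inf, np.zeros(a.n_nodes)
        lnl = float(np.sum(self.weights * (np.log(site_l) + logscale[root])))

        # Preorder "above" partials A, scaled arbitrarily (ratios cancel).
        A: dict[int, np.ndarray] = {root: np.tile(root_freq, (self.n_patterns, 1))}
        grad = np.zeros(a.n_nodes)
        down: dict[int, np.ndarray] = {}  # P_k C_k per child k
        for node in a.postorder[::-1]:
            kids = a.children[node]
            if not kids:
                continue
            for k in kids:
                down[k] = C[k] @ P[k].T
            for k in kids:
                rest = A[node]
                for s in kids:
                    if s != k:
                        rest = rest * down[s]
                denom = np.sum(rest * down[k], axis=1)
                numer = np.sum(rest * (C[k] @ QP[k].T), axis=1)
                ok = denom > 0
                grad[k] = float(np.sum(self.weights[ok] * numer[ok] / denom[ok]))
                # Above partial for k, rescaled for stability.
                Ak = rest @ P[k]
                m = Ak.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                A[k] = Ak / m[:, None]
        return lnl, grad

    # ------------------------------------------------------------- oracle

    def loglik_bruteforce(
        self, P: dict[int, np.ndarray], root_freq: np.ndarray
    ) -> float:
        """Exhaustive sum over all interior-node state assignments.

        Independent oracle for the pruning recursion; exponential in the
        number of interior nodes, so only usable on tiny fixtures.
        """
        import itertools

        a = self.arrays
        interior = [n for n in a.postorder if a.children[n]]
        total = np.zeros(self.n_patterns)
        for assign in itertools.product(range(self.n_states), repeat=len(interior)):
            state_of = dict(zip(interior, assign))
            lik = np.full(self.n_patterns, root_freq[state_of[a.root]])
            for node in a.postorder:
                if node == a.root:
                    continue
                ps = state_of[a.parent[node]]
                if a.children[node]:
                    lik = lik * P[node][ps, state_of[node]]
                else:
                    lik = lik * (self._tip_partials[node] @ P[node][ps, :])
            total += lik
        return float(np.sum(self.weights * np.log(total)))
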