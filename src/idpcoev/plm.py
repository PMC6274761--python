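"""Pseudolikelihood fit of a pairwise Potts (Markov random field) model to a
weighted paired alignment.

The model assigns each alignment row x a probability proportional to
exp(sum_i h_i(x_i) + sum_{i<j} e_ij(x_i, x_j)) over the 21-state alphabet
(20 amino acids + gap). Fitting the full likelihood is intractable, so the
standard pseudolikelihood surrogate is minimised instead: the weighted sum
over rows and columns of -log P(x_i | x_{-i}), which is convex and known to
recover contact structure well. L2 regularisation keeps couplings near zero
wherever the data impose no constraint, so conserved or uninformative column
pairs score ~0. Coupling strength between columns i and j is summarised as
the Frobenius norm of the 20x20 amino-acid block of e_ij (gap state
excluded), which downstream code corrects with APC.

Parameters are zero-initialised and optimised with L-BFGS; the procedure is
deterministic (no randomness anywhere in the fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .alignment import PairedAlignment
from .alphabet import Q

DEFAULT_LAMBDA_H = 0.01
DEFAULT_LAMBDA_E_PER_COL = 0.2  # lambda_e = 0.2 * (L - 1)


@dataclass
class MRFModel:
    """Fitted Potts model: fields h (L, q) and couplings e (L, L, q, q) with
    e[i, j] = e[j, i].T and zero diagonal blocks."""

    h: np.ndarray
    e: np.ndarray
    lambda_h: float
    lambda_e: float
    converged: bool
    objective: float
    n_iter: int

    @property
    def n_cols(self) -> int:
        return self.h.shape[0]


def _unpack(theta: np.ndarray, L: int, q: int, iu: tuple[np.ndarray, np.ndarray]):
    nh = L * q
    h = theta[:nh].reshape(L, q)
    eu = theta[nh:].reshape(-1, q, q)  # upper-triangle pair blocks, i < j
    return h, eu


def _full_coupling_matrix(eu: np.ndarray, L: int, q: int,
                          iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Symmetric (L*q, L*q) block matrix E with E[(i,a),(j,b)] = e_ij(a,b)."""
    E = np.zeros((L, q, L, q))
    E[iu[0], :, iu[1], :] = eu
    E[iu[1], :, iu[0], :] = np.transpose(eu, (0, 2, 1))
    return E.reshape(L * q, L * q)


def make_objective(X: np.ndarray, weights: np.ndarray,
                   lambda_h: float, lambda_e: float):
    """Build the value-and-gradient closure of the regularised negative
    log-pseudolikelihood for encoded rows ``X`` (N, L). The data term is the
    weight-averaged pseudolikelihood, so regularisation strength is relative
    to the effective sample size. Exposed separately so tests can probe the
    exact function the optimiser sees."""
    X = np.asarray(X, dtype=np.int64)
    N, L = X.shape
    q = Q
    wn = (weights / weights.sum()).astype(np.float64)

    iu = np.triu_indices(L, k=1)

    # one-hot encoding, (N, L*q)
    Xoh = np.zeros((N, L * q))
    flat_idx = np.arange(L) * q + X
    Xoh[np.arange(N)[:, None], flat_idx] = 1.0

    rows = np.arange(N)[:, None]
    cols = np.arange(L)[None, :]

    def objective(theta: np.ndarray):
        h, eu = _unpack(theta, L, q, iu)
        E = _full_coupling_matrix(eu, L, q, iu)
        logits = (Xoh @ E).reshape(N, L, q) + h[None, :, :]
        m = logits.max(axis=2, keepdims=True)
        z = np.exp(logits - m)
        zsum = z.sum(axis=2)
        logZ = np.log(zsum) + m[:, :, 0]
        ll = logits[rows, cols, X] - logZ  # (N, L) conditional log-probs
        nll = -float((wn[:, None] * ll).sum())
        reg = lambda_h * float((h ** 2).sum()) + lambda_e * float((eu ** 2).sum())
        f = nll + reg
        if not np.isfinite(f):
            raise FloatingPointError("non-finite pseudolikelihood objective")

        # gradient
        p = z / zsum[:, :, None]  # softmax probabilities (N, L, q)
        d = p.copy()
        d[rows, cols, X] -= 1.0  # dNLL/dlogits per row, before weighting
        grad_h = (wn[:, None, None] * d).sum(axis=0) + 2.0 * lambda_h * h
        dflat = (d * wn[:, None, None]).reshape(N, L * q)
        A = Xoh.T @ dflat  # (L*q, L*q): dNLL/dE[(j,b),(i,a)] contributions
        A4 = A.reshape(L, q, L, q)
        # E[(i,a),(j,b)] appears via rows (j,b) acting on logits (i,a) and,
        # by symmetry of the parameterisation, rows (i,a) on logits (j,b)
        grad_eu = (np.transpose(A4[iu[1], :, iu[0], :], (0, 2, 1))
                   + A4[iu[0], :, iu[1], :])
        grad_eu = grad_eu + 2.0 * lambda_e * eu
        g = np.concatenate([grad_h.ravel(), grad_eu.ravel()])
        return f, g

    n_params = L * q + len(iu[0]) * q * q
    return objective, n_params, iu


def fit_mrf(
    aln: PairedAlignment,
    lambda_h: float = DEFAULT_LAMBDA_H,
    lambda_e: float | None = None,
    max_iter: int = 500,
    grad_tol: float = 1e-5,
) -> MRFModel:
    """Minimise the weighted, L2-regularised negative log-pseudolikelihood
    with L-BFGS from zero-initialised parameters (deterministic).

    ``lambda_e`` defaults to 0.2 * (L - 1). Raises on a non-finite
    objective; returns a partial model flagged ``converged=False`` when the
    iteration cap is hit before the gradient tolerance.
    """
    X = aln.matrix.astype(np.int64)
    N, L = X.shape
    q = Q
    w = aln.weights if aln.weights is not None else np.ones(N)
    if N < 2 or np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 non-identical rows to fit")
    if lambda_e is None:
        lambda_e = DEFAULT_LAMBDA_E_PER_COL * (L - 1)

    objective, n_params, iu = make_objective(X, w, lambda_h, lambda_e)
    theta0 = np.zeros(n_params)
    res = minimize(
        objective, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                 "ftol": 1e-12, "gtol": grad_tol, "maxcor": 10},
    )
    h, eu = _unpack(res.x, L, q, iu)
    e = np.zeros((L, L, q, q))
    e[iu[0], iu[1]] = eu
    e[iu[1], iu[0]] = np.transpose(eu, (0, 2, 1))
    converged = bool(res.success) or res.status == 0
    return MRFModel(h=h, e=e, lambda_h=lambda_h, lambda_e=float(lambda_e),
                    converged=converged, objective=float(res.fun),
                    n_iter=int(res.nit))


def coupling_matrix(model: MRFModel) -> np.ndarray:
    """Frobenius norms of the amino-acid sub-blocks of the couplings.

    S[i, j] = ||e_ij[:20, :20]||_F, symmetric with zero diagonal; the gap
    state does not contribute.
    """
    sub = model.e[:, :, : Q - 1, : Q - 1]
    S = np.sqrt((sub ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(S, 0.0)
    return S
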