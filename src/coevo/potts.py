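"""Potts model inference from weighted alignments.

The generative model assigns a sequence :math:`X = (X_1,\\dots,X_L)` the
probability

.. math::

    P(X) = \\frac{1}{Z} \\exp\\Big[\\sum_i h_i(X_i)
            + \\sum_{i<j} J_{ij}(X_i, X_j)\\Big]

with per-position fields ``h`` and per-pair coupling matrices ``J`` over
q = 21 states (20 amino acids + gap).  Two inference routes are
provided:

* :func:`fit_plm` — asymmetric pseudo-likelihood maximization: each
  position's conditional distribution is fit independently as an
  L2-regularized multinomial logistic regression, and the two directed
  coupling estimates are averaged.  This is the high-accuracy route used
  for contact prediction.
* :func:`fit_mean_field` — mean-field inversion of the pseudocount-
  regularized connected-correlation matrix.  Much faster and used inside
  the iterative paralog-matching loop, where the model is refit many
  times on small matched alignments.

Both the fields and couplings are over-parameterized (gauge freedom);
:func:`zero_sum_gauge` maps a model to the canonical zero-sum
representative without changing sequence probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alignment import Alignment, GAP, Q, SequenceWeights, compute_weights

__all__ = [
    "PottsModel",
    "FitConfig",
    "ConvergenceError",
    "site_conditional_logprob",
    "fit_plm",
    "fit_mean_field",
    "zero_sum_gauge",
]


class ConvergenceError(RuntimeError):
    """Optimization failed to reach the requested gradient tolerance."""


@dataclass
class PottsModel:
    """Fields ``h`` (L x q) and couplings ``J`` (L x L x q x q).

    Invariants: ``J[i, j] == J[j, i].T``, ``J[i, i] == 0``, all finite.
    """

    h: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError("J must have shape (L, L, q, q)")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("model parameters must be finite")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def validate(self, atol: float = 1e-10) -> None:
        """Check coupling symmetry and zero diagonal blocks."""
        if not np.allclose(self.J, np.transpose(self.J, (1, 0, 3, 2)), atol=atol):
            raise ValueError("J[i,j] must equal J[j,i]^T")
        for i in range(self.L):
            if not np.allclose(self.J[i, i], 0.0, atol=atol):
                raise ValueError("J[i,i] must be zero")

    def energy(self, sequence: np.ndarray) -> float:
        """Unnormalized log-probability of one sequence."""
        x = np.asarray(sequence)
        e = float(self.h[np.arange(self.L), x].sum())
        for i in range(self.L):
            for j in range(i + 1, self.L):
                e += self.J[i, j, x[i], x[j]]
        return e


@dataclass
class FitConfig:
    """Hyper-parameters of the pseudo-likelihood fit.

    ``lambda_h`` / ``lambda_J`` are L2 weights on the weighted-mean
    log-likelihood scale (default 0.01 each, the standard plmDCA value).
    """

    lambda_h: float = 0.01
    lambda_J: float = 0.01
    gradient_tolerance: float = 1e-5
    max_iterations: int = 2000
    identity_threshold: float = 0.90

    def __post_init__(self) -> None:
        if self.lambda_h < 0 or self.lambda_J < 0:
            raise ValueError("regularization weights must be non-negative")
        if self.gradient_tolerance <= 0:
            raise ValueError("gradient_tolerance must be positive")


def site_conditional_logprob(
    model: PottsModel, sequence: np.ndarray, position: int
) -> np.ndarray:
    """log P(X_i = a | X_{-i}) for all q states at 0-based ``position``."""
    x = np.asarray(sequence)
    L = model.L
    if not 0 <= position < L:
        raise IndexError(f"position {position} outside [0, {L})")
    logits = model.h[position].copy()
    for j in range(L):
        if j != position:
            logits += model.J[position, j, :, x[j]]
    return logits - logsumexp(logits)


class _SiteProblem:
    """Regularized weighted pseudo-likelihood for one position.

    Parameter vector: fields h_i (q entries) followed by the directed
    coupling blocks J_ij for j != i, stored as (L-1, q, q) with axis
    order (state at i, state at j).
    """

    def __init__(
        self,
        matrix: np.ndarray,
        weights: np.ndarray,
        site: int,
        lambda_h: float,
        lambda_J: float,
        q: int = Q,
    ) -> None:
        self.q = q
        self.site = site
        M, L = matrix.shape
        self.L = L
        self.others = np.array([j for j in range(L) if j != site])
        self.w = np.asarray(weights, dtype=float)
        self.n_eff = float(self.w.sum())
        self.lambda_h = lambda_h
        self.lambda_J = lambda_J
        self.xi = matrix[:, site].astype(np.int64)
        # dense one-hot of the conditioning columns, (M, (L-1)*q)
        codes = matrix[:, self.others].astype(np.int64)
        D = np.zeros((M, (L - 1) * q))
        rows = np.repeat(np.arange(M), L - 1)
        cols = (np.arange(L - 1)[None, :] * q + codes).ravel()
        D[rows, cols] = 1.0
        self.D = D
        self.n_params = q + (L - 1) * q * q

    def split(self, theta: np.ndarray):
        q = self.q
        h = theta[:q]
        Jdir = theta[q:].reshape(self.L - 1, q, q)
        return h, Jdir

    def value_and_grad(self, theta: np.ndarray):
        q = self.q
        h, Jdir = self.split(theta)
        # energies[s, a] = h[a] + sum_j Jdir[j, a, x_sj]
        W = np.transpose(Jdir, (0, 2, 1)).reshape((self.L - 1) * q, q)
        E = self.D @ W + h[None, :]
        mx = E.max(axis=1, keepdims=True)
        expE = np.exp(E - mx)
        Zs = expE.sum(axis=1)
        logZ = np.log(Zs) + mx[:, 0]
        M = E.shape[0]
        ll = float((self.w * (E[np.arange(M), self.xi] - logZ)).sum())
        p = expE / Zs[:, None]
        R = p
        R[np.arange(M), self.xi] -= 1.0
        R *= (self.w / self.n_eff)[:, None]
        grad_h = R.sum(axis=0) + 2.0 * self.lambda_h * h
        grad_W = self.D.T @ R + 2.0 * self.lambda_J * W
        grad_J = np.transpose(grad_W.reshape(self.L - 1, q, q), (0, 2, 1))
        f = (
            -ll / self.n_eff
            + self.lambda_h * float(h @ h)
            + self.lambda_J * float((Jdir * Jdir).sum())
        )
        grad = np.concatenate([grad_h, grad_J.ravel()])
        return f, grad

    def solve(self, gtol: float, maxiter: int):
        res = minimize(
            self.value_and_grad,
            np.zeros(self.n_params),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14},
        )
        gnorm = float(np.abs(res.jac).max())
        if gnorm > gtol:
            raise ConvergenceError(
                f"site {self.site}: pseudo-likelihood fit stopped with "
                f"gradient norm {gnorm:.3e} > {gtol:.1e} "
                f"({res.nit} iterations; {res.message})"
            )
        return res.x


def fit_plm(
    aln: Alignment,
    weights: SequenceWeights | None = None,
    config: FitConfig | None = None,
) -> PottsModel:
    """Asymmetric pseudo-likelihood fit of the Potts model.

    Each position is fit independently by quasi-Newton minimization of
    its regularized conditional negative log-likelihood (convex), from a
    zero initialization; the two directed estimates of every J_ij are
    then averaged, which restores coupling symmetry.
    """
    if aln.M < 2:
        raise ValueError("pseudo-likelihood fit needs at least 2 sequences")
    config = config or FitConfig()
    if weights is None:
        weights = compute_weights(aln, config.identity_threshold)
    L, q = aln.L, Q
    h = np.zeros((L, q))
    J = np.zeros((L, L, q, q))
    for i in range(L):
        prob = _SiteProblem(
            aln.matrix, weights.w, i, config.lambda_h, config.lambda_J, q
        )
        theta = prob.solve(config.gradient_tolerance, config.max_iterations)
        hi, Jdir = prob.split(theta)
        h[i] = hi
        for jj, j in enumerate(prob.others):
            J[i, j] += 0.5 * Jdir[jj]
            J[j, i] += 0.5 * Jdir[jj].T
    return PottsModel(h, J)


def zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Canonical zero-sum (Ising) gauge representative of a model.

    Every coupling block is double-centered so its rows and columns
    average to zero; the removed row means are folded into the fields.
    Sequence probabilities are unchanged (the leftover constant is
    absorbed by the partition function).
    """
    L, q = model.L, model.q
    h = model.h.copy()
    J = np.zeros_like(model.J)
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            K = model.J[i, j]
            row = K.mean(axis=1, keepdims=True)
            col = K.mean(axis=0, keepdims=True)
            tot = K.mean()
            J[i, j] = K - row - col + tot
            if i < j:
                h[i] += row[:, 0] - tot
                h[j] += col[0, :] - tot
            else:
                # the i<j pass already credited both sides of this block's
                # transpose; skip to avoid double counting
                pass
    return PottsModel(h, J)


def _weighted_frequencies(
    aln: Alignment, weights: SequenceWeights, pseudocount: float
):
    """Pseudocount-regularized weighted single and pair frequencies."""
    L, q = aln.L, Q
    w = weights.w / weights.n_eff
    M = aln.M
    oh = np.zeros((M, L, q))
    oh[np.arange(M)[:, None], np.arange(L)[None, :], aln.matrix.astype(int)] = 1.0
    fi = np.einsum("s,slq->lq", w, oh)
    flat = (oh * np.sqrt(w)[:, None, None]).reshape(M, L * q)
    fij = (flat.T @ flat).reshape(L, q, L, q).transpose(0, 2, 1, 3)
    lam = pseudocount
    fi = (1 - lam) * fi + lam / q
    fij = (1 - lam) * fij + lam / q**2
    # diagonal blocks must stay consistent with single-site frequencies
    for i in range(L):
        fij[i, i] = np.diag(fi[i])
    return fi, fij


def fit_mean_field(
    aln: Alignment,
    weights: SequenceWeights | None = None,
    pseudocount: float = 0.5,
) -> PottsModel:
    """Mean-field (naive inverse-covariance) Potts inference.

    Builds the connected-correlation matrix C_ij(a,b) = f_ij(a,b) -
    f_i(a) f_j(b) over q-1 states per position (the gap state is the
    gauge reference) and returns couplings J = -C^{-1}, with fields from
    the independent-site relation.
    """
    if aln.M < 2:
        raise ValueError("mean-field fit needs at least 2 sequences")
    if not 0.0 <= pseudocount <= 1.0:
        raise ValueError("pseudocount must lie in [0, 1]")
    if weights is None:
        weights = compute_weights(aln)
    fi, fij = _weighted_frequencies(aln, weights, pseudocount)
    L, q = aln.L, Q
    qr = q - 1  # reduced states, gap = gauge reference
    C = (
        fij[:, :, :qr, :qr]
        - fi[:, None, :qr, None] * fi[None, :, None, :qr]
    )
    Cmat = C.transpose(0, 2, 1, 3).reshape(L * qr, L * qr)
    try:
        Jmat = -np.linalg.inv(Cmat)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; increase the pseudocount"
        ) from exc
    Jred = Jmat.reshape(L, qr, L, qr).transpose(0, 2, 1, 3)
    J = np.zeros((L, L, q, q))
    J[:, :, :qr, :qr] = Jred
    for i in range(L):
        J[i, i] = 0.0
    J = 0.5 * (J + J.transpose(1, 0, 3, 2))
    h = np.zeros((L, q))
    h[:, :qr] = np.log(fi[:, :qr] / fi[:, qr:])
    h[:, :qr] -= np.einsum("ijab,jb->ia", J[:, :, :qr, :], fi)
    return PottsModel(h, J)
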