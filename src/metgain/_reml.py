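"""Restricted-likelihood machinery shared by the single-site and MET models.

The restricted log-likelihood is defined on an orthonormal basis of error
contrasts: for a marginal model y ~ N(Xb, V) with X of full column rank p,

    l_R = -1/2 [ (n-p) log 2*pi + log|V| + log|X'V^-1 X| - log|X'X| + y'Py ],

which equals the log-density of K'y for any column-orthonormal K spanning the
null space of X'.  The value therefore does not depend on the choice of
contrast basis, and different evaluation strategies (dense, Woodbury,
balanced factorisation) agree exactly.

Evaluation uses the Woodbury identity on V = sigma2_e I + Z D Z', so the cost
is governed by the number of random-effect columns q, not by n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve

LOG2PI = math.log(2.0 * math.pi)

#: value returned when V(theta) is numerically indefinite; keeps optimizers
#: inside the feasible region without raising.
PENALIZED_LOGLIK = -1.0e12


@dataclass
class BlockSpec:
    """Covariance of one random-effect block.

    kind "diag": D = diag(values) with ``values`` of length n_cols.
    kind "kron": D = I_copies (x) Sigma, columns ordered copy-major
    (all columns of copy 0 first).  Sigma must be symmetric positive definite.
    """

    kind: str
    values: np.ndarray | None = None
    sigma: np.ndarray | None = None
    copies: int = 1

    @property
    def n_cols(self) -> int:
        if self.kind == "diag":
            return len(self.values)
        return self.copies * self.sigma.shape[0]

    def inv_dense(self) -> np.ndarray:
        if self.kind == "diag":
            return np.diag(1.0 / self.values)
        m = self.sigma.shape[0]
        c, low = cho_factor(self.sigma)
        sig_inv = cho_solve((c, low), np.eye(m))
        out = np.zeros((self.copies * m, self.copies * m))
        for i in range(self.copies):
            out[i * m : (i + 1) * m, i * m : (i + 1) * m] = sig_inv
        return out

    def logdet(self) -> float:
        if self.kind == "diag":
            return float(np.sum(np.log(self.values)))
        sign, ld = np.linalg.slogdet(self.sigma)
        if sign <= 0:
            raise np.linalg.LinAlgError("block covariance not positive definite")
        return self.copies * float(ld)

    def matvec(self, u: np.ndarray) -> np.ndarray:
        """D @ u for a vector of length n_cols."""
        if self.kind == "diag":
            return self.values * u
        m = self.sigma.shape[0]
        return (u.reshape(self.copies, m) @ self.sigma).ravel()


class MarginalModel:
    """y = X b + sum_k Z_k u_k + e with e ~ N(0, sigma2_e W).

    Holds the data and incidence structure; variance parameters are supplied
    per evaluation, so one instance serves a whole optimization.
    ``resid_weights`` (optional, length n) gives W's diagonal for
    heterogeneous residual variance; default is W = I.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Z_blocks: list[sp.spmatrix]):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("fixed-effect design matrix is rank deficient")
        self.block_slices: list[slice] = []
        start = 0
        for Zb in Z_blocks:
            self.block_slices.append(slice(start, start + Zb.shape[1]))
            start += Zb.shape[1]
        self.q = start
        self.Z = sp.hstack([sp.csr_matrix(Zb) for Zb in Z_blocks], format="csr") if Z_blocks else None
        # unweighted cross-products, reused when W = I
        if self.Z is not None:
            self.ZtZ = np.asarray((self.Z.T @ self.Z).todense())
            self.ZtX = np.asarray(self.Z.T @ self.X)
            self.Zty = np.asarray(self.Z.T @ self.y)
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        sign, self.logdet_XtX = np.linalg.slogdet(self.XtX)

    # -- internals -----------------------------------------------------
    def _cross_products(self, resid_weights):
        has_z = self.Z is not None
        if resid_weights is None:
            return (
                self.ZtZ if has_z else None,
                self.ZtX if has_z else None,
                self.Zty if has_z else None,
                self.XtX,
                self.Xty,
                self.yty,
                0.0,
            )
        w = np.asarray(resid_weights, dtype=float)
        Xw = self.X / w[:, None]
        yw = self.y / w
        logdet_w = float(np.sum(np.log(w)))
        XtWX = self.X.T @ Xw
        XtWy = self.X.T @ yw
        ytWy = float(self.y @ yw)
        if not has_z:
            return None, None, None, XtWX, XtWy, ytWy, logdet_w
        Zw = self.Z.multiply((1.0 / w)[:, None]).tocsr()
        ZtWZ = np.asarray((self.Z.T @ Zw).todense())
        ZtWX = np.asarray(Zw.T @ self.X)
        ZtWy = np.asarray(Zw.T @ self.y)
        return ZtWZ, ZtWX, ZtWy, XtWX, XtWy, ytWy, logdet_w

    def _assemble(self, blocks: list[BlockSpec], sigma2_e: float, resid_weights=None):
        ZtWZ, ZtWX, ZtWy, XtWX, XtWy, ytWy, logdet_w = self._cross_products(resid_weights)
        if self.Z is None or not blocks:
            XtVinvX = XtWX / sigma2_e
            XtVinvy = XtWy / sigma2_e
            ytVinvy = ytWy / sigma2_e
            logdetV = self.n * math.log(sigma2_e) + logdet_w
            return XtVinvX, XtVinvy, ytVinvy, logdetV, None, (ZtWy, None)
        Dinv = np.zeros((self.q, self.q))
        logdetD = 0.0
        for spec, sl in zip(blocks, self.block_slices):
            Dinv[sl, sl] = spec.inv_dense()
            logdetD += spec.logdet()
        M = Dinv + ZtWZ / sigma2_e
        cM = cho_factor(M)
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(cM[0]))))
        a_X = ZtWX / sigma2_e
        a_y = ZtWy / sigma2_e
        MinvX = cho_solve(cM, a_X)
        Minvy = cho_solve(cM, a_y)
        XtVinvX = XtWX / sigma2_e - a_X.T @ MinvX
        XtVinvy = XtWy / sigma2_e - a_X.T @ Minvy
        ytVinvy = ytWy / sigma2_e - a_y @ Minvy
        logdetV = logdet_M + logdetD + self.n * math.log(sigma2_e) + logdet_w
        return XtVinvX, XtVinvy, ytVinvy, logdetV, cM, (ZtWy, ZtWX)

    # -- public --------------------------------------------------------
    def reml_loglik(self, blocks: list[BlockSpec], sigma2_e: float, resid_weights=None) -> float:
        """Restricted log-likelihood; PENALIZED_LOGLIK on numerical failure."""
        try:
            XtVinvX, XtVinvy, ytVinvy, logdetV, _, _ = self._assemble(blocks, sigma2_e, resid_weights)
            cXVX = cho_factor(XtVinvX)
            beta = cho_solve(cXVX, XtVinvy)
            yPy = ytVinvy - XtVinvy @ beta
            logdet_XVX = 2.0 * float(np.sum(np.log(np.diag(cXVX[0]))))
            val = -0.5 * (
                (self.n - self.p) * LOG2PI + logdetV + logdet_XVX - self.logdet_XtX + yPy
            )
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return PENALIZED_LOGLIK
        if not np.isfinite(val):
            return PENALIZED_LOGLIK
        return float(val)

    def solve(self, blocks: list[BlockSpec], sigma2_e: float, resid_weights=None):
        """GLS fixed effects and BLUPs at the given variance parameters.

        Returns (beta, blups: list per block, loglik).
        """
        XtVinvX, XtVinvy, ytVinvy, logdetV, cM, (ZtWy, ZtWX) = self._assemble(
            blocks, sigma2_e, resid_weights
        )
        cXVX = cho_factor(XtVinvX)
        beta = cho_solve(cXVX, XtVinvy)
        yPy = ytVinvy - XtVinvy @ beta
        logdet_XVX = 2.0 * float(np.sum(np.log(np.diag(cXVX[0]))))
        loglik = -0.5 * (
            (self.n - self.p) * LOG2PI + logdetV + logdet_XVX - self.logdet_XtX + yPy
        )
        blups: list[np.ndarray] = []
        if self.Z is not None and blocks:
            # u_hat = D Z' V^-1 (y - X beta) = M^-1 Z' W^-1 (y - X beta) / sigma2_e
            resid_cross = (ZtWy - ZtWX @ beta) / sigma2_e
            u = cho_solve(cM, resid_cross)
            blups = [u[sl] for sl in self.block_slices]
        return beta, blups, float(loglik)


def indicator_matrix(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    """Sparse 0/1 incidence matrix from integer level codes."""
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), np.asarray(codes))), shape=(n, n_levels)
    )
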