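"""L1-regularized non-negative matrix factorization.

The model approximates the feature matrix ``X`` (features x voxels) by
``W H`` with both factors elementwise non-negative: columns of ``W`` are
tissue signatures, rows of ``H`` are spatial abundance maps.  The
objective is

    f(W, H) = 1/2 ( ||X - W H||_F^2 + lambda * ||(L + I) H||_1 )

where ``L`` is an in-plane 4-neighbour Laplacian acting on each abundance
map.  ``L H`` penalises spatial roughness (piecewise smoothness with
sharp tissue boundaries preserved by the L1 norm) while the identity
part penalises ``H`` directly (sparseness).  Ablation modes drop the
identity (``spatial``) or the whole term (``no_reg``).

Non-negativity is enforced by the change of variables ``W = A * A``,
``H = B * B`` (elementwise squares), turning the problem unconstrained;
the smoothed objective is minimised by a Gauss-Newton model inside a
Steihaug-Toint conjugate-gradient trust region, so accepted steps never
increase the objective.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)

MODES = ("no_reg", "spatial", "spatial_sparse")


def build_laplacian(voxel_index: np.ndarray, shape: Sequence[int]) -> sparse.csr_matrix:
    """Sparse ``n x n`` in-plane 4-neighbour Laplacian over the voxel set.

    Row ``v`` has the number of in-plane neighbours of ``v`` that are
    themselves columns of ``X`` at the centre and -1 at each such
    neighbour, so constant vectors are annihilated (``L 1 = 0``).
    Adjacent slices are never coupled.
    """
    voxel_index = np.asarray(voxel_index)
    n = voxel_index.shape[0]
    nx, ny, nz = shape
    flat = np.full(nx * ny * nz, -1, dtype=np.int64)
    lin = np.ravel_multi_index((voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]), shape)
    flat[lin] = np.arange(n)

    rows, cols, vals = [], [], []
    deg = np.zeros(n, dtype=np.int64)
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        x = voxel_index[:, 0] + dx
        y = voxel_index[:, 1] + dy
        ok = (x >= 0) & (x < nx) & (y >= 0) & (y < ny)
        nb = np.full(n, -1, dtype=np.int64)
        nb[ok] = flat[np.ravel_multi_index((x[ok], y[ok], voxel_index[ok, 2]), shape)]
        present = nb >= 0
        deg += present
        rows.append(np.nonzero(present)[0])
        cols.append(nb[present])
        vals.append(np.full(int(present.sum()), -1.0))
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(deg.astype(float))
    L = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return L


def _reg_operator(lap: sparse.spmatrix, mode: str) -> Optional[sparse.csr_matrix]:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "no_reg":
        return None
    if mode == "spatial":
        return lap.tocsr()
    return (lap + sparse.eye(lap.shape[0], format="csr")).tocsr()


def objective(
    X: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    lap: Optional[sparse.spmatrix],
    lam: float = 0.1,
    mode: str = "spatial_sparse",
    eps: float = 0.0,
) -> float:
    """Evaluate the regularized NMF objective.

    The operator ``(L + I)`` (or ``L`` in ``spatial`` mode) acts on each
    source's abundance map, i.e. on the columns of ``H^T``; the L1 norm
    is the entrywise sum of absolute values.  ``eps > 0`` replaces
    ``|u|`` with ``sqrt(u^2 + eps^2)`` (the solver's smoothing).
    """
    if X.shape != (W.shape[0], H.shape[1]) or W.shape[1] != H.shape[0]:
        raise ValueError(
            f"shape mismatch: X {X.shape}, W {W.shape}, H {H.shape}"
        )
    R = X - W @ H
    f = 0.5 * float(np.sum(R * R))
    M = _reg_operator(lap, mode) if mode != "no_reg" else None
    if M is not None and lam > 0:
        U = M @ H.T
        if eps > 0:
            f += 0.5 * lam * float(np.sum(np.sqrt(U * U + eps * eps)))
        else:
            f += 0.5 * lam * float(np.abs(U).sum())
    return f


class RegularizedNMF(BaseEstimator):
    """Spatially regularized NMF solved in squared variables.

    Parameters
    ----------
    n_components : int
        Rank ``r`` of the factorization.
    alpha : float, default 0.1
        Regularization weight ``lambda``.
    mode : {"no_reg", "spatial", "spatial_sparse"}
        Which regularizer to use (see module docstring).
    max_iter : int, default 500
        Maximum outer trust-region iterations.
    tol : float, default 1e-6
        Stop when the relative objective change between two accepted
        iterates falls below this.
    smooth_eps : float, default 1e-9
        Smoothing constant for the absolute value (data is [0, 1] scaled).
    cg_max_iter : int, default 60
        Cap on inner conjugate-gradient iterations per outer step.
    random_state : int, default 0
        Seed for the fallback random initialization when no ``W0/H0`` is
        supplied.

    Attributes
    ----------
    W_ : ndarray (m, r)
        Non-negative source matrix.
    H_ : ndarray (r, n)
        Non-negative abundance matrix.
    objective_trace_ : ndarray
        Objective value at the initial point and after each accepted
        step; non-increasing by construction.
    n_iter_ : int
        Outer iterations performed.
    converged_ : bool
        Whether the relative-change criterion fired before ``max_iter``.
    """

    def __init__(
        self,
        n_components: int = 11,
        alpha: float = 0.1,
        mode: str = "spatial_sparse",
        max_iter: int = 500,
        tol: float = 1e-6,
        smooth_eps: float = 1e-9,
        cg_max_iter: int = 60,
        random_state: int = 0,
    ) -> None:
        self.n_components = n_components
        self.alpha = alpha
        self.mode = mode
        self.max_iter = max_iter
        self.tol = tol
        self.smooth_eps = smooth_eps
        self.cg_max_iter = cg_max_iter
        self.random_state = random_state

    # -- objective / derivatives in the squared variables ---------------

    def _value_grad(self, A, B, X, M, lam, eps):
        W = A * A
        H = B * B
        R = X - W @ H
        f = 0.5 * float(np.sum(R * R))
        gW = -(R @ H.T)
        gH = -(W.T @ R)
        cache = {"A": A, "B": B, "W": W, "H": H}
        if M is not None and lam > 0:
            U = M @ H.T  # (n, r)
            phi = np.sqrt(U * U + eps * eps)
            f += 0.5 * lam * float(phi.sum())
            gH = gH + 0.5 * lam * (M.T @ (U / phi)).T
            cache["irls_w"] = 1.0 / phi
        gA = 2.0 * A * gW
        gB = 2.0 * B * gH
        return f, gA, gB, cache

    def _hessp(self, dA, dB, X, M, lam, cache):
        """Gauss-Newton model Hessian-vector product (PSD)."""
        A, B, W, H = cache["A"], cache["B"], cache["W"], cache["H"]
        dW = 2.0 * A * dA
        dH = 2.0 * B * dB
        P = dW @ H + W @ dH
        HA = 2.0 * A * (P @ H.T)
        hH = W.T @ P
        if M is not None and lam > 0:
            # IRLS majorizer curvature of the smoothed L1 term
            hH = hH + 0.5 * lam * (M.T @ (cache["irls_w"] * (M @ dH.T))).T
        HB = 2.0 * B * hH
        return HA, HB

    # -- Steihaug-Toint CG trust-region subproblem ----------------------

    @staticmethod
    def _to_boundary(z, d, delta):
        zz = float(np.dot(z, z))
        dd = float(np.dot(d, d))
        zd = float(np.dot(z, d))
        disc = zd * zd + dd * (delta * delta - zz)
        tau = (-zd + np.sqrt(max(disc, 0.0))) / dd
        return z + tau * d

    def _steihaug(self, g, hessp, delta):
        n = g.size
        z = np.zeros(n)
        r = g.copy()
        d = -g
        gnorm = float(np.linalg.norm(g))
        if gnorm == 0.0:
            return z
        cg_tol = min(0.5, np.sqrt(gnorm)) * gnorm
        for _ in range(self.cg_max_iter):
            Hd = hessp(d)
            dHd = float(np.dot(d, Hd))
            if dHd <= 0:
                return self._to_boundary(z, d, delta)
            rr = float(np.dot(r, r))
            alpha = rr / dHd
            z_next = z + alpha * d
            if np.linalg.norm(z_next) >= delta:
                return self._to_boundary(z, d, delta)
            r = r + alpha * Hd
            if np.linalg.norm(r) < cg_tol:
                return z_next
            beta = float(np.dot(r, r)) / rr
            d = -r + beta * d
            z = z_next
        return z

    # -- fit -------------------------------------------------------------

    def fit(self, X, W0=None, H0=None, laplacian=None):
        """Minimise the objective from the given initialization.

        Parameters
        ----------
        X : ndarray (m, n)
            Non-negative feature matrix.
        W0, H0 : ndarray, optional
            Non-negative initial factors; random uniform if omitted.
        laplacian : sparse matrix, optional
            ``n x n`` Laplacian; required unless ``mode == "no_reg"``
            or ``alpha == 0``.
        """
        X = np.asarray(X, dtype=float)
        m, n = X.shape
        r = self.n_components
        if r > m or r > n:
            raise ValueError(f"rank {r} exceeds matrix dimensions {X.shape}")
        rng = np.random.default_rng(self.random_state)
        if W0 is None:
            W0 = rng.uniform(0.1, 1.0, size=(m, r))
        if H0 is None:
            H0 = rng.uniform(0.1, 1.0, size=(r, n))
        W0 = np.asarray(W0, dtype=float)
        H0 = np.asarray(H0, dtype=float)
        if W0.shape != (m, r) or H0.shape != (r, n):
            raise ValueError("W0/H0 shapes do not match X and n_components")
        if (W0 < 0).any() or (H0 < 0).any():
            raise ValueError("W0 and H0 must be non-negative")

        lam = 0.0 if self.mode == "no_reg" else float(self.alpha)
        M = _reg_operator(laplacian, self.mode) if (lam > 0) else None
        if M is None:
            lam = 0.0
        eps = float(self.smooth_eps)

        A = np.sqrt(W0)
        B = np.sqrt(H0)
        na = A.size

        def split(x):
            return x[:na].reshape(A.shape), x[na:].reshape(B.shape)

        f, gA, gB, cache = self._value_grad(A, B, X, M, lam, eps)
        if not np.isfinite(f):
            raise FloatingPointError("non-finite objective at initialization")
        g = np.concatenate([gA.ravel(), gB.ravel()])
        trace = [f]
        delta = max(1.0, 0.1 * float(np.linalg.norm(np.concatenate([A.ravel(), B.ravel()]))))
        converged = False
        n_iter = 0
        gtol = 1e-12 * max(1.0, f)

        for n_iter in range(1, self.max_iter + 1):
            if float(np.linalg.norm(g, np.inf)) <= gtol:
                converged = True
                n_iter -= 1
                break

            def hessp(v, cache=cache):
                dA, dB = split(v)
                HA, HB = self._hessp(dA, dB, X, M, lam, cache)
                return np.concatenate([HA.ravel(), HB.ravel()])

            p = self._steihaug(g, hessp, delta)
            pnorm = float(np.linalg.norm(p))
            if pnorm == 0.0:
                converged = True
                break
            pred = -(float(np.dot(g, p)) + 0.5 * float(np.dot(p, hessp(p))))
            dA, dB = split(p)
            A_new = A + dA
            B_new = B + dB
            f_new, gA_new, gB_new, cache_new = self._value_grad(A_new, B_new, X, M, lam, eps)
            if not np.isfinite(f_new):
                raise FloatingPointError(f"non-finite objective at iteration {n_iter}")
            ared = f - f_new
            rho = ared / pred if pred > 0 else -1.0

            if rho > 1e-4 and ared > 0:
                rel = ared / max(f, 1e-30)
                A, B = A_new, B_new
                f = f_new
                g = np.concatenate([gA_new.ravel(), gB_new.ravel()])
                cache = cache_new
                trace.append(f)
                if rel < self.tol:
                    converged = True
                    break
            if rho < 0.25:
                delta *= 0.25
            elif rho > 0.75 and pnorm >= 0.99 * delta:
                delta = min(2.0 * delta, 1e6)
            if delta < 1e-14:
                log.warning("trust region collapsed at iteration %d", n_iter)
                break

        self.W_ = A * A
        self.H_ = B * B
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def transform(self, X=None):
        """Return the fitted abundance matrix ``H``."""
        if not hasattr(self, "H_"):
            raise AttributeError("RegularizedNMF instance is not fitted yet")
        return self.H_
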