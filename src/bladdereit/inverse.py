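"""Linearized difference-imaging solvers.

One-step regularized Gauss-Newton reconstructions of the conductivity
perturbation delta_x = x_p - x from the measurement difference
dv = F(x_p) - V:

* Tikhonov:  delta_x = (J'J + lambda I)^-1 J' dv
* NOSER:     delta_x = (J'J + eps diag(J'J))^-1 J' dv
* combined:  delta_x = (J'J + lambda I + eps diag(J'J))^-1 J' dv

All three are diagonal-penalty ridge problems.  No explicit inverse is
ever formed: the primal normal matrix is Cholesky-factorized when the
element count does not exceed the measurement count, otherwise the
algebraically identical dual (measurement-space) form

    delta_x = D^-1 J' (I + J D^-1 J')^-1 dv,   D the diagonal penalty,

is factorized instead — the system then has only as many unknowns as
measurements (4032), independent of mesh size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .forward import SensitivityMatrix

logger = logging.getLogger(__name__)

_DENSE_LIMIT = 12_000  # largest n for dense condition-number eigendecomposition


@dataclass
class RegularizationConfig:
    """Method and parameters for the regularized reconstruction."""

    method: str = "combined"  # "tikhonov" | "noser" | "combined"
    lam: float | None = None  # Tikhonov parameter; None = scale-aware default
    epsilon: float = 0.05  # NOSER parameter, in (0, 1)
    l_operator: str = "identity"  # "identity" | "first_difference"

    def validate(self) -> None:
        if self.method not in ("tikhonov", "noser", "combined", "jacobian"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method in ("tikhonov", "combined"):
            if self.lam is not None and self.lam <= 0:
                raise ValueError("lambda must be positive")
        if self.method in ("noser", "combined"):
            if not 0 < self.epsilon < 1:
                raise ValueError("epsilon must lie in (0, 1)")
        if self.l_operator not in ("identity", "first_difference"):
            raise ValueError(f"unknown L operator {self.l_operator!r}")


@dataclass
class ReconstructionResult:
    """Per-element perturbation delta_x = x_p - x plus solve diagnostics.

    A conductive inclusion (x > x_p) appears as *negative* delta_x under
    this sign convention; downstream edge detection and quantification
    operate on |delta_x|.
    """

    delta_x: np.ndarray
    method: str
    params: dict
    residual_norm: float
    condition_number: float | None = None


def default_lambda(j: np.ndarray) -> float:
    """Scale-aware Tikhonov default: 1e-3 * trace(J'J) / n."""
    return 1e-3 * float(np.einsum("me,me->", j, j)) / j.shape[1]


def _entries(j) -> np.ndarray:
    return j.entries if isinstance(j, SensitivityMatrix) else np.asarray(j, float)


def _check_inputs(j: np.ndarray, dv: np.ndarray) -> None:
    if not np.all(np.isfinite(j)):
        raise ValueError("Jacobian contains non-finite entries")
    if not np.all(np.isfinite(dv)):
        raise ValueError("measurement difference contains non-finite entries")
    if dv.shape != (j.shape[0],):
        raise ValueError("dv length must equal the number of Jacobian rows")


def _ridge_solve(j: np.ndarray, dv: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Solve (J'J + diag(d)) x = J' dv by Cholesky, primal or dual form."""
    m, n = j.shape
    if n <= m:
        c = j.T @ j
        c[np.diag_indices_from(c)] += d
        cf = la.cho_factor(c, lower=True)
        return la.cho_solve(cf, j.T @ dv)
    b = j / d[None, :]
    k = b @ j.T
    k[np.diag_indices_from(k)] += 1.0
    cf = la.cho_factor(k, lower=True)
    return (j.T @ la.cho_solve(cf, dv)) / d


def first_difference_operator(mesh) -> sp.csr_matrix:
    """Graph first-difference operator over face-adjacent element pairs."""
    nbr = mesh.tet_neighbors
    a = np.repeat(np.arange(mesh.n_tets), 4)
    b = nbr.ravel()
    keep = (b >= 0) & (a < b)
    a, b = a[keep], b[keep]
    rows = np.arange(len(a))
    data = np.concatenate([np.ones(len(a)), -np.ones(len(a))])
    return sp.coo_matrix(
        (data, (np.concatenate([rows, rows]), np.concatenate([a, b]))),
        shape=(len(a), mesh.n_tets),
    ).tocsr()


def _solve_general_l(j, dv, lam, d_extra, l_mat) -> np.ndarray:
    """Dense path for a non-identity L (small/medium systems only)."""
    n = j.shape[1]
    if n > _DENSE_LIMIT:
        raise ValueError(
            "first-difference regularization supports at most "
            f"{_DENSE_LIMIT} elements; use the identity operator"
        )
    c = j.T @ j + lam * (l_mat.T @ l_mat).toarray()
    if d_extra is not None:
        c[np.diag_indices_from(c)] += d_extra
    return la.solve(c, j.T @ dv, assume_a="pos")


def _result(j, dv, delta_x, method, params) -> ReconstructionResult:
    residual = float(np.linalg.norm(j @ delta_x - dv))
    return ReconstructionResult(
        delta_x=delta_x, method=method, params=params, residual_norm=residual
    )


def solve_tikhonov(
    j, dv: np.ndarray, lam: float | None = None, l_mat: sp.spmatrix | None = None
) -> ReconstructionResult:
    """Standard-form Tikhonov solution (identity L unless l_mat given)."""
    j = _entries(j)
    dv = np.asarray(dv, dtype=float)
    _check_inputs(j, dv)
    if lam is None:
        lam = default_lambda(j)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if l_mat is not None:
        dx = _solve_general_l(j, dv, lam, None, l_mat)
    else:
        dx = _ridge_solve(j, dv, np.full(j.shape[1], lam))
    return _result(j, dv, dx, "tikhonov", {"lambda": lam})


def _noser_diag(j: np.ndarray) -> np.ndarray:
    d = np.einsum("me,me->e", j, j)
    dead = np.flatnonzero(d <= 0)
    if len(dead):
        raise ValueError(
            f"element {dead[0]} has zero sensitivity (diag(J'J) = 0); "
            "mask insensitive elements before solving"
        )
    return d

def solve_noser(j, dv: np.ndarray, epsilon: float = 0.05) -> ReconstructionResult:
    """NOSER solution: diagonal weighting of J'J as the penalty."""
    j = _entries(j)
    dv = np.asarray(dv, dtype=float)
    _check_inputs(j, dv)
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    dx = _ridge_solve(j, dv, epsilon * _noser_diag(j))
    return _result(j, dv, dx, "noser", {"epsilon": epsilon})


def solve_combined(
    j, dv: np.ndarray, lam: float | None = None, epsilon: float = 0.05
) -> ReconstructionResult:
    """Combined Tikhonov + NOSER penalty, the package's default method."""
    j = _entries(j)
    dv = np.asarray(dv, dtype=float)
    _check_inputs(j, dv)
    if lam is None:
        lam = default_lambda(j)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    dx = _ridge_solve(j, dv, lam + epsilon * _noser_diag(j))
    return _result(
        j, dv, dx, "combined", {"lambda": lam, "epsilon": epsilon}
    )


def solve(
    j, dv: np.ndarray, config: RegularizationConfig, mesh=None
) -> ReconstructionResult:
    """Dispatch on the configured method."""
    config.validate()
    l_mat = None
    if config.l_operator == "first_difference":
        if config.method != "tikhonov":
            raise ValueError("first_difference L applies to the Tikhonov method")
        if mesh is None:
            raise ValueError("first_difference L requires the element mesh")
        l_mat = first_difference_operator(mesh)
    if config.method == "tikhonov":
        return solve_tikhonov(j, dv, config.lam, l_mat)
    if config.method == "noser":
        return solve_noser(j, dv, config.epsilon)
    return solve_combined(j, dv, config.lam, config.epsilon)


class RidgeReconstructor:
    """Factorize a diagonal-penalty ridge once, solve many frames.

    The dual-form Gram matrix ``I + J D^-1 J'`` (measurements x
    measurements) is built chunk-wise over elements — peak memory stays
    at one copy of J — and Cholesky-factorized; each subsequent frame
    costs two matrix-vector products.
    """

    def __init__(
        self,
        j,
        method: str = "combined",
        lam: float | None = None,
        epsilon: float = 0.05,
        chunk: int = 8192,
    ):
        self.j = _entries(j)
        self.method = method
        m, n = self.j.shape
        if method == "tikhonov":
            self.lam = lam if lam is not None else default_lambda(self.j)
            self.d = np.full(n, self.lam)
            self.params = {"lambda": self.lam}
        elif method == "noser":
            if not 0 < epsilon < 1:
                raise ValueError("epsilon must lie in (0, 1)")
            self.d = epsilon * _noser_diag(self.j)
            self.params = {"epsilon": epsilon}
        elif method == "combined":
            self.lam = lam if lam is not None else default_lambda(self.j)
            if self.lam <= 0:
                raise ValueError("lambda must be positive")
            if not 0 < epsilon < 1:
                raise ValueError("epsilon must lie in (0, 1)")
            self.d = self.lam + epsilon * _noser_diag(self.j)
            self.params = {"lambda": self.lam, "epsilon": epsilon}
        else:
            raise ValueError(f"unknown method {method!r}")
        k = np.eye(m)
        for s in range(0, n, chunk):
            blk = slice(s, min(s + chunk, n))
            k += (self.j[:, blk] / self.d[blk][None, :]) @ self.j[:, blk].T
        self._cf = la.cho_factor(k, lower=True)

    def solve(self, dv: np.ndarray) -> ReconstructionResult:
        dv = np.asarray(dv, dtype=float)
        _check_inputs(self.j, dv)
        dx = (self.j.T @ la.cho_solve(self._cf, dv)) / self.d
        return _result(self.j, dv, dx, self.method, self.params)


# ----------------------------------------------------------------------
# conditioning diagnostics


def _penalty_diag(j: np.ndarray, config: RegularizationConfig) -> np.ndarray:
    n = j.shape[1]
    lam = config.lam if config.lam is not None else default_lambda(j)
    if config.method == "tikhonov":
        return np.full(n, lam)
    d = np.einsum("me,me->e", j, j)
    if config.method == "noser":
        return config.epsilon * d
    return lam + config.epsilon * d


def condition_number(j, config: RegularizationConfig) -> float:
    """2-norm condition number of the regularized system matrix.

    ``method="jacobian"`` conditions J itself (by singular values); the
    regularization methods condition J'J + penalty.  Small systems use a
    dense eigendecomposition; large ones use Lanczos iteration with an
    exact shift-invert through the dual-form Cholesky factorization, so
    the extreme eigenvalues are computed without ever densifying J'J.
    """
    config.validate()
    j = _entries(j)
    if j.size == 0:
        raise ValueError("empty matrix")
    m, n = j.shape
    if config.method == "jacobian":
        gram = j @ j.T if m <= n else j.T @ j
        ev = la.eigvalsh(gram)
        ev = np.clip(ev, 0.0, None)
        smin = np.sqrt(ev[0]) if ev[0] > 0 else 0.0
        if smin == 0.0:
            return np.inf
        return float(np.sqrt(ev[-1]) / smin)

    if config.method == "tikhonov" and config.l_operator == "identity":
        # lambda I shifts the spectrum of J'J: eigenvalues are s_i^2 +
        # lambda, padded with lambda itself when n > m (the null space
        # of J'J).  Exact, via the smaller Gram matrix.
        lam = config.lam if config.lam is not None else default_lambda(j)
        gram = j @ j.T if m <= n else j.T @ j
        ev = np.clip(la.eigvalsh(gram), 0.0, None)
        low = lam if n > m else ev[0] + lam
        return float((ev[-1] + lam) / low)

    d = _penalty_diag(j, config)
    if (d <= 0).any():
        raise ValueError("penalty diagonal must be positive")
    if n <= 4000:
        c = j.T @ j
        c[np.diag_indices_from(c)] += d
        ev = la.eigvalsh(c)
        return float(ev[-1] / ev[0])

    # Large n: Lanczos extremes with exact shift-invert via the dual
    # Cholesky.  For "combined" the system matrix is the NOSER matrix
    # plus lambda*I — identical eigenvectors, spectrum shifted by
    # lambda — so the extremes are computed on the NOSER matrix (whose
    # inverse has a well-separated top, where Lanczos converges fast)
    # and shifted exactly.
    shift = 0.0
    if config.method == "combined":
        shift = config.lam if config.lam is not None else default_lambda(j)
        d = d - shift  # epsilon * diag(J'J)
    lam_max, lam_min = _lanczos_extremes(j, d)
    return float((lam_max + shift) / (lam_min + shift))


def _lanczos_extremes(j: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Extreme eigenvalues of J'J + diag(d) without densifying it."""
    n = j.shape[1]
    b = j / d[None, :]
    k = b @ j.T
    k[np.diag_indices_from(k)] += 1.0
    cf = la.cho_factor(k, lower=True)

    def mv(x):
        return j.T @ (j @ x) + d * x

    def mvinv(x):
        return (x - j.T @ la.cho_solve(cf, b @ x)) / d

    op = spla.LinearOperator((n, n), matvec=mv)
    opinv = spla.LinearOperator((n, n), matvec=mvinv)
    v0 = np.full(n, 1.0 / np.sqrt(n))
    lam_max = spla.eigsh(
        op, k=1, which="LA", v0=v0, tol=1e-7, return_eigenvectors=False
    )[0]
    inv_max = spla.eigsh(
        opinv, k=1, which="LA", v0=v0, tol=1e-7, return_eigenvectors=False
    )[0]
    return float(lam_max), float(1.0 / inv_max)
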