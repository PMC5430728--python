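"""Constrained nonnegative CP decomposition with supervised and similarity
regularizers.

The observed count tensor O (patients x diagnoses x prescriptions) is
approximated by sum_r lambda_r A_:r o B_:r o C_:r with all factors
nonnegative.  Two penalties shape the solution:

* per patient row, a logistic negative log-likelihood
  ``-omega * log P(y_i | [A_i:, 1] . theta)`` couples the patient's phenotype
  memberships to the binary outcome;
* per code factor (B for diagnoses, C for prescriptions), a symmetric-NMF
  term ``mu * ||S - B B^T||^2`` pulls the factor toward the spectral-cluster
  structure of the contextual similarity matrix S, which keeps phenotypes
  distinct.

All updates are projected, damped Newton steps.  The printed curvature of the
similarity term is exact only at rank 1 (it drops cross-column coupling for
R > 1); backtracking makes the step safe regardless, and a constant-step
gradient fallback handles problems where the JRxJR solve is too large.
Convergence is declared when the fit statistic 1 - ||O - X|| / ||O|| moves by
less than ``tol`` between sweeps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import CooccurrenceTensor, RunConfig
from .errors import (
    DegenerateLabelsError,
    DivergenceError,
    ParameterError,
    PhenotensorError,
    UndefinedFitError,
)
from .similarity import SimilarityMatrix

log = logging.getLogger(__name__)

HESSIAN_RIDGE = 1e-8
MAX_HALVINGS = 20
JR_NEWTON_LIMIT = 2000


# ---------------------------------------------------------------------------
# Multilinear algebra primitives


def khatri_rao(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product: column r is kron(m1[:, r], m2[:, r])."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.ndim != 2 or m2.ndim != 2 or m1.shape[1] != m2.shape[1]:
        raise ParameterError(
            f"khatri_rao needs equal column counts, got {m1.shape} and {m2.shape}"
        )
    n1, r = m1.shape
    n2 = m2.shape[0]
    return (m1[:, None, :] * m2[None, :, :]).reshape(n1 * n2, r)


def _as_dense(t) -> np.ndarray:
    if isinstance(t, CooccurrenceTensor):
        return t.to_dense()
    arr = np.asarray(t, dtype=float)
    if arr.ndim != 3:
        raise ParameterError("expected a third-order tensor")
    return arr


def mode_unfold(t, mode: int) -> np.ndarray:
    """Mode-n unfolding matched to the Khatri-Rao identities
    O_(1) = A (C x B)^T, O_(2) = B (C x A)^T, O_(3) = C (B x A)^T."""
    dense = _as_dense(t)
    if mode == 1:
        return dense.transpose(0, 2, 1).reshape(dense.shape[0], -1)
    if mode == 2:
        return dense.transpose(1, 2, 0).reshape(dense.shape[1], -1)
    if mode == 3:
        return dense.transpose(2, 1, 0).reshape(dense.shape[2], -1)
    raise ParameterError(f"mode must be 1, 2 or 3, got {mode}")


def mode_fold(mat: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`mode_unfold`."""
    i, j, k = shape
    mat = np.asarray(mat, dtype=float)
    if mode == 1:
        return mat.reshape(i, k, j).transpose(0, 2, 1)
    if mode == 2:
        return mat.reshape(j, k, i).transpose(2, 0, 1)
    if mode == 3:
        return mat.reshape(k, j, i).transpose(2, 1, 0)
    raise ParameterError(f"mode must be 1, 2 or 3, got {mode}")


# ---------------------------------------------------------------------------
# Supervised pieces


def _delta(a_row: np.ndarray, theta: np.ndarray) -> float:
    return float(a_row @ theta[:-1] + theta[-1])


def mortality_neg_log_likelihood(a_row: np.ndarray, y: int, theta: np.ndarray) -> float:
    """log(1 + exp(-y * delta)) with delta = [a_row, 1] . theta, overflow-safe."""
    return float(np.logaddexp(0.0, -y * _delta(np.asarray(a_row, float), theta)))


def patient_row_objective(
    a_row: np.ndarray, y: int, theta: np.ndarray, B: np.ndarray, C: np.ndarray,
    o_row: np.ndarray, omega: float,
) -> float:
    """f(A_i:) = ||A_i: (C x B)^T - O_(1)i:||^2 - omega log P(y_i | ...)."""
    kr = khatri_rao(C, B)
    resid = np.asarray(a_row, float) @ kr.T - o_row
    val = float(resid @ resid)
    if omega > 0:
        val += omega * mortality_neg_log_likelihood(a_row, y, theta)
    return val


def _row_grad_hess(a_row, y, theta, gram, m_row, omega):
    """Gradient and Hessian of the row objective; gram = (C x B)^T (C x B),
    m_row = O_(1)i: (C x B).  Only the first R components of theta enter."""
    grad = 2.0 * a_row @ gram - 2.0 * m_row
    hess = 2.0 * gram
    if omega > 0:
        d = _delta(a_row, theta)
        yd = y * d
        grad = grad - omega * y / (1.0 + np.exp(np.clip(yd, -500, 500))) * theta[:-1]
        s = 1.0 / (2.0 + np.exp(np.clip(yd, -500, 500)) + np.exp(np.clip(-yd, -500, 500)))
        hess = hess + omega * s * np.outer(theta[:-1], theta[:-1])
    return grad, hess


def newton_update_patient_row(
    a_row: np.ndarray, y: int, theta: np.ndarray, B: np.ndarray, C: np.ndarray,
    o_row: np.ndarray, omega: float, eta: float = HESSIAN_RIDGE,
) -> np.ndarray:
    """One projected, backtracked Newton step on a single patient row."""
    a_row = np.asarray(a_row, dtype=float)
    kr = khatri_rao(C, B)
    gram = kr.T @ kr
    m_row = o_row @ kr
    grad, hess = _row_grad_hess(a_row, y, theta, gram, m_row, omega)
    if not np.all(np.isfinite(grad)):
        raise PhenotensorError("non-finite gradient in patient-row update")
    step = np.linalg.solve(hess + eta * np.eye(hess.shape[0]), grad)
    f_old = patient_row_objective(a_row, y, theta, B, C, o_row, omega)
    alpha = 1.0
    for _ in range(MAX_HALVINGS + 1):
        cand = np.maximum(0.0, a_row - alpha * step)
        if patient_row_objective(cand, y, theta, B, C, o_row, omega) <= f_old + 1e-12:
            return cand
        alpha *= 0.5
    return a_row


def newton_update_patient_rows(
    A: np.ndarray, y: np.ndarray, theta: np.ndarray, B: np.ndarray, C: np.ndarray,
    O1: np.ndarray, omega: float, train_mask: np.ndarray, eta: float = HESSIAN_RIDGE,
) -> np.ndarray:
    """Vectorized projected Newton sweep over all patient rows.

    Rows with ``train_mask`` False (held-out patients) are updated with
    omega = 0, i.e. plain CP least squares.  The supervised rank-1 Hessian
    correction is folded in with Sherman-Morrison so the whole sweep is a
    single R x R solve plus vector arithmetic.
    """
    A = np.asarray(A, dtype=float)
    kr = khatri_rao(C, B)
    gram = kr.T @ kr
    M = O1 @ kr  # I x R
    r = A.shape[1]
    grad = 2.0 * A @ gram - 2.0 * M
    omega_row = np.where(train_mask, omega, 0.0)

    s_row = np.zeros(A.shape[0])
    if omega > 0 and train_mask.any():
        deltas = A @ theta[:-1] + theta[-1]
        yd = np.clip(y * deltas, -500, 500)
        sig = 1.0 / (1.0 + np.exp(yd))
        grad = grad - (omega_row * y * sig)[:, None] * theta[None, :-1]
        s_row = omega_row / (2.0 + np.exp(yd) + np.exp(-yd))
    if not np.all(np.isfinite(grad)):
        raise PhenotensorError("non-finite gradient in patient-row sweep")

    h0 = 2.0 * gram + eta * np.eye(r)
    base = np.linalg.solve(h0, grad.T).T  # H0^{-1} g per row
    if omega > 0 and train_mask.any():
        h0_theta = np.linalg.solve(h0, theta[:-1])
        denom = 1.0 + s_row * (theta[:-1] @ h0_theta)
        coef = s_row * (base @ theta[:-1]) / denom
        step = base - coef[:, None] * h0_theta[None, :]
    else:
        step = base

    def row_objectives(X: np.ndarray) -> np.ndarray:
        quad = np.einsum("ir,rs,is->i", X, gram, X) - 2.0 * np.einsum("ir,ir->i", X, M)
        if omega > 0 and train_mask.any():
            d = X @ theta[:-1] + theta[-1]
            quad = quad + omega_row * np.logaddexp(0.0, -y * d)
        return quad

    f_old = row_objectives(A)
    alpha = np.ones(A.shape[0])
    new_A = A.copy()
    pending = np.ones(A.shape[0], dtype=bool)
    for _ in range(MAX_HALVINGS + 1):
        cand = np.maximum(0.0, A - alpha[:, None] * step)
        f_cand = row_objectives(cand)
        ok = pending & (f_cand <= f_old + 1e-12)
        new_A[ok] = cand[ok]
        pending &= ~ok
        if not pending.any():
            break
        alpha[pending] *= 0.5
    return new_A


def _penalized_logistic(X: np.ndarray, y: np.ndarray, c: float, tol: float = 1e-6,
                        max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Minimize sum_i log(1+exp(-y_i x_i.theta)) + c ||theta||^2 by damped
    Newton.  Returns (theta, Hessian at the optimum)."""
    n, p = X.shape
    theta = np.zeros(p)

    def nll(th):
        return float(np.sum(np.logaddexp(0.0, -y * (X @ th))) + c * th @ th)

    eye = np.eye(p)
    for _ in range(max_iter):
        z = np.clip(y * (X @ theta), -500, 500)
        sig = 1.0 / (1.0 + np.exp(z))  # P(misclassify)
        grad = -X.T @ (y * sig) + 2.0 * c * theta
        if np.linalg.norm(grad) <= tol:
            break
        w = sig * (1.0 - sig)
        hess = X.T @ (w[:, None] * X) + 2.0 * c * eye
        step = np.linalg.solve(hess + HESSIAN_RIDGE * eye, grad)
        f_old = nll(theta)
        alpha = 1.0
        for _ in range(MAX_HALVINGS + 1):
            cand = theta - alpha * step
            if nll(cand) <= f_old + 1e-12:
                theta = cand
                break
            alpha *= 0.5
        else:  # no improving step left
            break
    z = np.clip(y * (X @ theta), -500, 500)
    sig = 1.0 / (1.0 + np.exp(z))
    w = sig * (1.0 - sig)
    hess = X.T @ (w[:, None] * X) + 2.0 * c * np.eye(p)
    return theta, hess


def fit_theta_ridge(A_L: np.ndarray, y_L: np.ndarray, c: float) -> np.ndarray:
    """Ridge-penalized logistic regression of the outcome on the training
    patients' memberships; returns theta of length R+1 (intercept last)."""
    A_L = np.asarray(A_L, dtype=float)
    y_L = np.asarray(y_L, dtype=float)
    if A_L.shape[0] < 2 or len(np.unique(y_L)) < 2:
        raise DegenerateLabelsError("fit_theta_ridge needs >= 2 patients with both classes")
    design = np.hstack([A_L, np.ones((A_L.shape[0], 1))])
    theta, _ = _penalized_logistic(design, y_L, c)
    return theta


# ---------------------------------------------------------------------------
# Code-mode factor updates


def factor_objective(B: np.ndarray, A: np.ndarray, C: np.ndarray, O2: np.ndarray,
                     S: np.ndarray | None, mu: float) -> float:
    """g(B) = ||B (C x A)^T - O_(2)||^2 + mu ||S - B B^T||^2."""
    kr = khatri_rao(C, A)
    resid = B @ kr.T - O2
    val = float(np.sum(resid * resid))
    if mu > 0:
        diff = S - B @ B.T
        val += mu * float(np.sum(diff * diff))
    return val


def _check_sym(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ParameterError("similarity matrix must be symmetric")
    return S


def factor_gradient(B: np.ndarray, A: np.ndarray, C: np.ndarray, O2: np.ndarray,
                    S: np.ndarray | None, mu: float) -> np.ndarray:
    """Gradient of the code-factor objective:
    2 B (CxA)^T (CxA) - 2 O_(2) (CxA) + 4 mu (B B^T - S) B."""
    B = np.asarray(B, dtype=float)
    gram = (C.T @ C) * (A.T @ A)
    grad = 2.0 * B @ gram - 2.0 * O2 @ khatri_rao(C, A)
    if mu > 0:
        S = _check_sym(S)
        grad = grad + 4.0 * mu * (B @ B.T - S) @ B
    return grad


def _factor_hessian(B: np.ndarray, gram: np.ndarray, S: np.ndarray | None,
                    mu: float) -> np.ndarray:
    """Printed curvature of g at vec(B) (column-major).  Data-fit block
    2 (CxA)^T(CxA) kron I_J; similarity block
    4 mu (2 vv^T + (v^T v) I - I_R kron S).  Exact only at R = 1."""
    j, r = B.shape
    hess = 2.0 * np.kron(gram, np.eye(j))
    if mu > 0:
        v = B.flatten(order="F")
        hess = hess + 4.0 * mu * (
            2.0 * np.outer(v, v) + (v @ v) * np.eye(j * r) - np.kron(np.eye(r), S)
        )
    return hess


def newton_update_factor(
    B: np.ndarray, A: np.ndarray, C: np.ndarray, O2: np.ndarray,
    S: np.ndarray | None, mu: float, solver: str = "auto",
    eta: float = HESSIAN_RIDGE, jr_limit: int = JR_NEWTON_LIMIT,
) -> np.ndarray:
    """One projected step on a code factor: exact JRxJR Newton when the solve
    is affordable, otherwise a backtracked constant-step gradient move.  The
    step size starts at 1 and halves until the objective does not increase."""
    B = np.asarray(B, dtype=float)
    if mu > 0:
        S = _check_sym(S)
    gram = (C.T @ C) * (A.T @ A)
    grad = 2.0 * B @ gram - 2.0 * O2 @ khatri_rao(C, A)
    if mu > 0:
        grad = grad + 4.0 * mu * (B @ B.T - S) @ B

    j, r = B.shape
    use_newton = solver == "newton" or (solver == "auto" and j * r <= jr_limit)
    direction = None
    if use_newton:
        hess = _factor_hessian(B, gram, S, mu) + eta * np.eye(j * r)
        try:
            step_vec = np.linalg.solve(hess, grad.flatten(order="F"))
            direction = step_vec.reshape((j, r), order="F")
        except np.linalg.LinAlgError:
            warnings.warn("singular factor Hessian; falling back to gradient step", stacklevel=2)
    if direction is None:
        direction = grad

    f_old = factor_objective(B, A, C, O2, S, mu)
    alpha = 1.0
    for _ in range(MAX_HALVINGS + 1):
        cand = np.maximum(0.0, B - alpha * direction)
        if factor_objective(cand, A, C, O2, S, mu) <= f_old + 1e-12:
            return cand
        alpha *= 0.5
    return B


# ---------------------------------------------------------------------------
# Fit statistic, normalization, full solver


def compute_fit(O, X) -> float:
    """fit = 1 - ||O - X||_F / ||O||_F."""
    O = _as_dense(O)
    X = _as_dense(X)
    if O.shape != X.shape:
        raise ParameterError(f"shape mismatch {O.shape} vs {X.shape}")
    norm_o = np.linalg.norm(O)
    if norm_o == 0:
        raise UndefinedFitError("fit undefined for an all-zero observed tensor")
    return float(1.0 - np.linalg.norm(O - X) / norm_o)


@dataclass
class TrainingSplit:
    """Patient indices with supervision active (train) and held out (test)."""

    train_idx: np.ndarray
    test_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.train_idx = np.unique(np.asarray(self.train_idx, dtype=int))
        self.test_idx = np.unique(np.asarray(self.test_idx, dtype=int))
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ParameterError("train and test indices overlap")

    def mask(self, n: int) -> np.ndarray:
        if self.train_idx.size and self.train_idx.max() >= n:
            raise ParameterError("train index out of range")
        m = np.zeros(n, dtype=bool)
        m[self.train_idx] = True
        return m


@dataclass
class FactorModel:
    """Fitted nonnegative factors with logistic parameters and normalized,
    thresholded copies.

    A, B, C : raw nonnegative factors (patients/diagnoses/prescriptions x R).
    theta : logistic parameters, length R+1, intercept last.
    lam : per-phenotype magnitudes, lambda_r = ||A_:r|| ||B_:r|| ||C_:r||.
    A_bar, B_bar, C_bar : unit-column-normalized factors with entries below
        the mode threshold zeroed (1e-6 patients, 1e-3 codes by default).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    theta: np.ndarray
    lam: np.ndarray | None = None
    A_bar: np.ndarray | None = None
    B_bar: np.ndarray | None = None
    C_bar: np.ndarray | None = None
    fit_history: list[float] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return self.A.shape[1]

    def reconstruction(self) -> np.ndarray:
        """X = sum_r lambda_r A_bar o B_bar o C_bar (raw factors if not yet
        normalized)."""
        if self.lam is not None:
            return np.einsum("r,ir,jr,kr->ijk", self.lam, self.A_bar, self.B_bar, self.C_bar)
        return np.einsum("ir,jr,kr->ijk", self.A, self.B, self.C)

    def save(self, path) -> None:
        np.savez(
            path, A=self.A, B=self.B, C=self.C, theta=self.theta,
            lam=self.lam if self.lam is not None else np.array([]),
            A_bar=self.A_bar if self.A_bar is not None else np.array([]),
            B_bar=self.B_bar if self.B_bar is not None else np.array([]),
            C_bar=self.C_bar if self.C_bar is not None else np.array([]),
            fit_history=np.array(self.fit_history),
        )

    @classmethod
    def load(cls, path) -> "FactorModel":
        z = np.load(path)
        def opt(k):
            return z[k] if z[k].size else None
        return cls(A=z["A"], B=z["B"], C=z["C"], theta=z["theta"], lam=opt("lam"),
                   A_bar=opt("A_bar"), B_bar=opt("B_bar"), C_bar=opt("C_bar"),
                   fit_history=list(z["fit_history"]))


def normalize_and_threshold(
    model: FactorModel, eps_a: float = 1e-6, eps_bc: float = 1e-3
) -> FactorModel:
    """Column-normalize the factors (lambda_r = product of the three column
    norms; zero columns keep lambda_r = 0), then zero entries below the mode
    threshold.  Columns are not renormalized after thresholding."""
    norms = []
    bars = []
    for mat in (model.A, model.B, model.C):
        n = np.linalg.norm(mat, axis=0)
        safe = np.where(n > 0, n, 1.0)
        bars.append(mat / safe)
        norms.append(n)
    lam = norms[0] * norms[1] * norms[2]
    a_bar, b_bar, c_bar = bars
    a_bar = np.where(a_bar < eps_a, 0.0, a_bar)
    b_bar = np.where(b_bar < eps_bc, 0.0, b_bar)
    c_bar = np.where(c_bar < eps_bc, 0.0, c_bar)
    model.lam = lam
    model.A_bar, model.B_bar, model.C_bar = a_bar, b_bar, c_bar
    return model


def _sim_matrix(S) -> np.ndarray | None:
    if S is None:
        return None
    if isinstance(S, SimilarityMatrix):
        return S.matrix
    return np.asarray(S, dtype=float)


def fit_model(
    O,
    S_B=None,
    S_C=None,
    y: np.ndarray | None = None,
    split: TrainingSplit | None = None,
    cfg: RunConfig | None = None,
) -> FactorModel:
    """Run the full alternating solver.

    Each sweep updates every patient row (with the supervised weight omega for
    training patients, 0 for held-out ones), refreshes theta by ridge
    logistic regression on the training rows, then takes one projected Newton
    step on B (with S_B) and C (with S_C).  Sweeps stop when the fit changes
    by less than ``cfg.tol`` or after ``cfg.max_iter`` sweeps; the returned
    model is normalized and thresholded.
    """
    cfg = cfg or RunConfig()
    dense = _as_dense(O)
    i_dim, j_dim, k_dim = dense.shape
    sb = _sim_matrix(S_B)
    sc = _sim_matrix(S_C)
    if cfg.mu > 0 and (sb is None or sc is None):
        raise ParameterError("mu > 0 requires both similarity matrices")
    if cfg.omega > 0:
        if y is None:
            raise ParameterError("omega > 0 requires outcome labels")
        y = np.asarray(y, dtype=float)
        if y.shape[0] != i_dim:
            raise ParameterError("outcome length must equal patient count")
    else:
        y = np.zeros(i_dim) if y is None else np.asarray(y, dtype=float)
    train_mask = split.mask(i_dim) if split is not None else np.ones(i_dim, dtype=bool)

    rng = np.random.default_rng(cfg.seed)
    r = cfg.rank
    A = rng.random((i_dim, r))
    B = rng.random((j_dim, r))
    C = rng.random((k_dim, r))
    theta = np.zeros(r + 1)

    O1 = mode_unfold(dense, 1)
    O2 = mode_unfold(dense, 2)
    O3 = mode_unfold(dense, 3)
    norm_o = np.linalg.norm(dense)
    if norm_o == 0:
        raise UndefinedFitError("cannot factorize an all-zero tensor")

    def current_fit() -> float:
        gram = (A.T @ A) * (B.T @ B) * (C.T @ C)
        cross = np.einsum("ir,ir->", O1 @ khatri_rao(C, B), A)
        sq = max(norm_o**2 - 2.0 * cross + gram.sum(), 0.0)
        return float(1.0 - np.sqrt(sq) / norm_o)

    def similarity_term() -> float:
        if cfg.mu == 0:
            return 0.0
        return float(np.sum((sb - B @ B.T) ** 2) + np.sum((sc - C @ C.T) ** 2))

    history: list[float] = []
    fit_old = -np.inf
    sim_old = np.inf
    for sweep in range(cfg.max_iter):
        A = newton_update_patient_rows(A, y, theta, B, C, O1, cfg.omega, train_mask)
        if cfg.omega > 0:
            theta = fit_theta_ridge(A[train_mask], y[train_mask], cfg.ridge_c)
        B = newton_update_factor(B, A, C, O2, sb, cfg.mu)
        C = newton_update_factor(C, A, B, O3, sc, cfg.mu)
        fit = current_fit()
        history.append(fit)
        if not np.isfinite(fit) or fit < -10:
            raise DivergenceError(f"factorization diverged at sweep {sweep} (fit={fit})")
        # The fit statistic alone plateaus while a large mu is still reshaping
        # B and C (columns merge or prune with almost no movement in the data
        # term), so for mu > 0 the similarity term must have stabilized too;
        # the test only arms after min_iter sweeps.
        sim_val = similarity_term()
        sim_done = cfg.mu == 0 or abs(sim_old - sim_val) < cfg.tol * max(1.0, sim_val)
        if sweep + 1 >= cfg.min_iter and abs(fit - fit_old) < cfg.tol and sim_done:
            break
        fit_old = fit
        sim_old = sim_val

    model = FactorModel(A=A, B=B, C=C, theta=theta, fit_history=history)
    return normalize_and_threshold(model, cfg.eps_a, cfg.eps_bc)
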