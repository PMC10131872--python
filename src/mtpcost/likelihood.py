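"""Marginalized two-part (MTP) likelihood for semicontinuous cost panels.

Model
-----
For subject ``i`` at month ``j`` with design rows ``x1_ij`` (binary part)
and ``x2_ij`` (overall-mean part), and correlated random intercepts
``(a_i, d_i) ~ N2(0, Sigma)``:

    P(Y_ij > 0 | a_i)      = pi_ij  = logistic(x1_ij' alpha + a_i)
    E(Y_ij | a_i, d_i)     = nu_ij  = exp(x2_ij' beta + d_i)
    E(Y_ij | Y>0, a, d)    = mu_ij  = nu_ij / pi_ij
    Y_ij | Y>0, a, d       ~ Gamma(shape=kappa, mean=mu_ij)

The defining feature of the marginalized parameterization is that ``beta``
acts on the log of the OVERALL mean ``nu`` (zeros included), so
``exp(beta_k)`` is a population-level cost ratio per unit of covariate k.
The conditional positive mean ``mu = nu / pi`` is derived, not modelled.

The subject likelihood integrates the two-part density over the bivariate
random effect.  Integration uses Gauss–Hermite product quadrature, either
plain (nodes scaled by chol(Sigma)) or adaptive (nodes centered at the
per-subject Laplace mode and scaled by the local curvature).  The adaptive
scheme writes the integral in importance form with the node positions and
weights treated as constants, so the resulting objective is analytic in all
parameters — including the random-effect covariance, which enters through
an explicit bivariate-normal prior term — and exact gradients are available
for optimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import digamma, expit, gammaln, logsumexp

from .design import DesignMatrices

#: lower clip for pi when forming mu = nu / pi; guards against unbounded
#: positive means under extreme negative binary-part random effects.
PI_FLOOR = 1e-6
_LOG_PI_FLOOR = np.log(PI_FLOOR)

#: linear predictors beyond this would overflow exp() in float64
_EXP_OVERFLOW = 700.0


class LikelihoodError(ValueError):
    """Raised when the likelihood cannot be evaluated (domain/overflow)."""


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class MTPParams:
    """Full MTP parameter vector.

    ``alpha``/``beta`` follow the design column order; ``kappa`` is the
    gamma shape; (``sigma_a``, ``sigma_d``, ``rho``) parameterize the 2x2
    random-intercept covariance.
    """

    alpha: np.ndarray
    beta: np.ndarray
    kappa: float
    sigma_a: float
    sigma_d: float
    rho: float

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.kappa <= 0:
            raise LikelihoodError("gamma shape kappa must be positive")
        if self.sigma_a < 0 or self.sigma_d < 0:
            raise LikelihoodError("random-effect standard deviations must be >= 0")
        if not -1.0 < self.rho < 1.0:
            raise LikelihoodError("rho must lie strictly inside (-1, 1)")

    def covariance(self) -> np.ndarray:
        """2x2 covariance of (a, d)."""
        c = self.rho * self.sigma_a * self.sigma_d
        return np.array([[self.sigma_a**2, c], [c, self.sigma_d**2]])

    @property
    def has_random_effects(self) -> bool:
        return self.sigma_a > 0 or self.sigma_d > 0

    # unconstrained parameterization used by the optimizer:
    # [alpha, beta, log kappa, log sigma_a, log sigma_d, atanh rho]
    def to_internal(self) -> np.ndarray:
        if self.sigma_a <= 0 or self.sigma_d <= 0:
            raise LikelihoodError("internal parameterization needs sigma > 0")
        return np.concatenate([
            self.alpha, self.beta,
            [np.log(self.kappa), np.log(self.sigma_a),
             np.log(self.sigma_d), np.arctanh(self.rho)],
        ])

    @classmethod
    def from_internal(cls, vec: np.ndarray, p: int) -> "MTPParams":
        vec = np.asarray(vec, dtype=float)
        lk, lsa, lsd, w = vec[2 * p:]
        return cls(alpha=vec[:p].copy(), beta=vec[p:2 * p].copy(),
                   kappa=float(np.exp(lk)), sigma_a=float(np.exp(lsa)),
                   sigma_d=float(np.exp(lsd)), rho=float(np.tanh(w)))

    def to_dict(self, columns: Sequence[str]) -> dict:
        return {
            "binary": dict(zip(columns, map(float, self.alpha))),
            "mean": dict(zip(columns, map(float, self.beta))),
            "kappa": float(self.kappa),
            "sigma_a": float(self.sigma_a),
            "sigma_d": float(self.sigma_d),
            "rho": float(self.rho),
        }

    @classmethod
    def from_dict(cls, d: Mapping, columns: Sequence[str]) -> "MTPParams":
        return cls(
            alpha=np.array([d["binary"][c] for c in columns], dtype=float),
            beta=np.array([d["mean"][c] for c in columns], dtype=float),
            kappa=float(d["kappa"]), sigma_a=float(d["sigma_a"]),
            sigma_d=float(d["sigma_d"]), rho=float(d["rho"]),
        )


@dataclass
class QuadratureSpec:
    """How to integrate over the bivariate random intercept."""

    nodes_per_dim: int = 9
    adaptive: bool = True
    mc_oracle_draws: int = 100_000  # brute-force cross-checks only

    def __post_init__(self) -> None:
        if self.nodes_per_dim < 1:
            raise LikelihoodError("nodes_per_dim must be >= 1")


# ---------------------------------------------------------------------------
# elementary model quantities


def zero_prob(x1_row, alpha, a: float = 0.0) -> float:
    """P(Y > 0 | a): logistic usage probability for one design row."""
    lp = float(np.dot(np.asarray(x1_row, float), np.asarray(alpha, float)) + a)
    return float(expit(lp))


def marginal_mean(x2_row, beta, d: float = 0.0) -> float:
    """Overall mean nu = exp(x2' beta + d), zeros included."""
    lp = float(np.dot(np.asarray(x2_row, float), np.asarray(beta, float)) + d)
    if lp > _EXP_OVERFLOW:
        raise LikelihoodError(f"marginal mean overflows: linear predictor {lp:.1f}")
    return float(np.exp(lp))


def conditional_positive_mean(nu: float, pi: float, pi_floor: float = PI_FLOOR) -> float:
    """Positive-part mean mu = nu / pi (pi clipped below at ``pi_floor``)."""
    if nu <= 0:
        raise LikelihoodError("nu must be positive")
    if not 0 <= pi <= 1:
        raise LikelihoodError("pi must be a probability")
    return nu / max(pi, pi_floor)


def gamma_logpdf(y, kappa: float, mu) -> np.ndarray | float:
    """Log gamma density with shape ``kappa`` and MEAN ``mu`` (scale mu/kappa)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if kappa <= 0:
        raise LikelihoodError("kappa must be positive")
    if np.any(y <= 0):
        raise LikelihoodError("gamma_logpdf needs y > 0 (zeros belong to the binary part)")
    if np.any(mu <= 0):
        raise LikelihoodError("gamma mean must be positive")
    out = (kappa * (np.log(kappa) - np.log(mu)) - gammaln(kappa)
           + (kappa - 1.0) * np.log(y) - kappa * y / mu)
    return out if out.ndim else float(out)


def _log_bvn(a, d, sigma_a, sigma_d, rho):
    """Log bivariate normal density at (a, d), mean zero."""
    u = a / sigma_a
    v = d / sigma_d
    om = 1.0 - rho**2
    q = (u * u - 2.0 * rho * u * v + v * v) / om
    return (-np.log(2 * np.pi) - np.log(sigma_a) - np.log(sigma_d)
            - 0.5 * np.log(om) - 0.5 * q)


# ---------------------------------------------------------------------------
# frozen node sets


@dataclass
class NodeSet:
    """Frozen per-subject quadrature nodes in random-effect space.

    ``a``/``d`` hold node coordinates (n_subjects x Q) and ``log_w`` the
    log importance weights including the Gaussian back-correction and the
    local Jacobian, but NOT the prior density — the bivariate-normal prior
    is evaluated analytically at each likelihood call so the covariance
    parameters keep exact gradients.
    """

    a: np.ndarray
    d: np.ndarray
    log_w: np.ndarray
    modes: np.ndarray = None  # (n_subjects, 2) adaptation centers


def _hermite_grid(k: int):
    z, w = hermegauss(k)
    z1 = np.repeat(z, k)
    z2 = np.tile(z, k)
    lw = np.log(np.repeat(w, k) * np.tile(w, k))
    return z1, z2, lw  # weights integrate against exp(-|z|^2/2)


def _chol2(v11, v12, v22):
    """Cholesky of a 2x2 PSD matrix, elementwise over arrays."""
    c11 = np.sqrt(v11)
    c21 = v12 / c11
    c22 = np.sqrt(np.maximum(v22 - c21**2, 1e-300))
    return c11, c21, c22


def standard_nodes(params: MTPParams, n_subjects: int, k: int) -> NodeSet:
    """Plain (non-adaptive) GH nodes: centered at zero, scaled by chol(Sigma)."""
    z1, z2, lw = _hermite_grid(k)
    sa = max(params.sigma_a, 1e-8)
    sd = max(params.sigma_d, 1e-8)
    c11, c21, c22 = _chol2(sa**2, params.rho * sa * sd, sd**2)
    a = c11 * z1
    d = c21 * z1 + c22 * z2
    # importance form: log w + |z|^2/2 + log det C
    log_w = lw + 0.5 * (z1**2 + z2**2) + np.log(c11) + np.log(c22)
    ones = np.ones((n_subjects, 1))
    return NodeSet(a=ones * a, d=ones * d, log_w=ones * log_w,
                   modes=np.zeros((n_subjects, 2)))


# ---------------------------------------------------------------------------
# vectorized panel evaluator


class PanelEvaluator:
    """Evaluates the integrated MTP log-likelihood and its exact gradient
    over a panel for a frozen node set.

    Rows are grouped by subject; zero-cost and positive-cost rows are
    indexed once so each likelihood pass runs the logistic terms on the
    zero subset and the gamma terms on the positive subset only.
    """

    def __init__(self, design: DesignMatrices):
        self.design = design
        y = np.asarray(design.y, float)
        self.y = y
        pos = y > 0
        self.pos = pos
        self.pos_idx = np.flatnonzero(pos)
        self.zero_idx = np.flatnonzero(~pos)
        self.y_pos = y[self.pos_idx]
        self.logy_pos = np.log(self.y_pos)
        self.starts = design.subject_starts
        self.sidx = design.subject_index
        self.sidx_pos = self.sidx[self.pos_idx]
        self.sidx_zero = self.sidx[self.zero_idx]
        self.n_subjects = design.n_subjects
        self.p = design.n_params
        # node-independent per-subject pieces of the gamma log-density
        self.subj_npos = np.bincount(self.sidx_pos, minlength=self.n_subjects)
        self.subj_sumlogy = np.bincount(self.sidx_pos, weights=self.logy_pos,
                                        minlength=self.n_subjects)

    # -- shared node-wise quantities ----------------------------------------

    def _eta(self, params: MTPParams):
        return self.design.x1 @ params.alpha, self.design.x2 @ params.beta

    def _node_quantities(self, eta1, eta2, nodes: NodeSet, kappa: float):
        """Per-node arrays on the pos/zero row subsets.

        Returns ``(lp1_zero, logpi_pos, logmu_pos, t_pos, clip_pos, data_M)``
        where ``data_M`` is the (S x Q) per-subject sum of the
        kappa-independent part ``logpi - kappa*logmu - kappa*t`` for
        positive rows plus ``log(1-pi)`` for zero rows.
        """
        A, D = nodes.a, nodes.d
        with np.errstate(invalid="ignore", over="ignore"):
            lp1_zero = eta1[self.zero_idx, None] + A[self.sidx_zero, :]
            lp1_pos = eta1[self.pos_idx, None] + A[self.sidx_pos, :]
            logpi_pos = -np.logaddexp(0.0, -lp1_pos)
            clip_pos = logpi_pos < _LOG_PI_FLOOR
            logpi_c = np.maximum(logpi_pos, _LOG_PI_FLOOR)
            logmu_pos = eta2[self.pos_idx, None] + D[self.sidx_pos, :] - logpi_c
            t_pos = self.y_pos[:, None] * np.exp(-logmu_pos)
            ll_zero = -np.logaddexp(0.0, lp1_zero)
            ll_pos = logpi_pos - kappa * (logmu_pos + t_pos)
        Q = A.shape[1]
        full = np.empty((len(self.y), Q))
        full[self.zero_idx] = ll_zero
        full[self.pos_idx] = ll_pos
        data_M = np.add.reduceat(full, self.starts, axis=0)
        return lp1_zero, logpi_pos, logmu_pos, t_pos, clip_pos, data_M

    def _node_matrix(self, params: MTPParams, nodes: NodeSet) -> np.ndarray:
        """(S x Q) log integrand mass: data terms + prior + node weights."""
        eta1, eta2 = self._eta(params)
        kappa = params.kappa
        *_, data_M = self._node_quantities(eta1, eta2, nodes, kappa)
        const = ((kappa - 1.0) * self.subj_sumlogy
                 + self.subj_npos * (kappa * np.log(kappa) - gammaln(kappa)))
        sa = max(params.sigma_a, 1e-8)
        sd = max(params.sigma_d, 1e-8)
        M = (data_M + const[:, None]
             + _log_bvn(nodes.a, nodes.d, sa, sd, params.rho) + nodes.log_w)
        if not np.all(np.isfinite(M)):
            s_bad = int(np.argwhere(~np.isfinite(M))[0, 0])
            raise LikelihoodError(
                f"non-finite integrand for subject {self.design.subject_ids[s_bad]!r}"
            )
        return M

    def loglik(self, params: MTPParams, nodes: NodeSet,
               return_by_subject: bool = False):
        M = self._node_matrix(params, nodes)
        by_subject = logsumexp(M, axis=1)
        total = float(by_subject.sum())
        if return_by_subject:
            return total, by_subject
        return total

    def clip_count(self, params: MTPParams, nodes: NodeSet) -> int:
        """Observation-node pairs where pi hit the floor (diagnostic)."""
        eta1, _ = self._eta(params)
        lp1_pos = eta1[self.pos_idx, None] + nodes.a[self.sidx_pos, :]
        return int(np.sum(lp1_pos < _LOG_PI_FLOOR))

    def loglik_and_grad(self, internal: np.ndarray, nodes: NodeSet):
        """Total log-likelihood and exact gradient (internal scale) of the
        frozen-node objective."""
        p = self.p
        params = MTPParams.from_internal(internal, p)
        x1, x2 = self.design.x1, self.design.x2
        eta1, eta2 = self._eta(params)
        kappa = params.kappa
        lk = np.log(kappa)
        sa, sd, rho = params.sigma_a, params.sigma_d, params.rho

        lp1_zero, logpi_pos, logmu_pos, t_pos, clip_pos, data_M = \
            self._node_quantities(eta1, eta2, nodes, kappa)
        const = ((kappa - 1.0) * self.subj_sumlogy
                 + self.subj_npos * (kappa * lk - gammaln(kappa)))
        M = (data_M + const[:, None]
             + _log_bvn(nodes.a, nodes.d, sa, sd, rho) + nodes.log_w)
        if not np.all(np.isfinite(M)):
            s_bad = int(np.argwhere(~np.isfinite(M))[0, 0])
            raise LikelihoodError(
                f"non-finite integrand for subject {self.design.subject_ids[s_bad]!r}"
            )
        by_subject = logsumexp(M, axis=1)
        total = float(by_subject.sum())
        P = np.exp(M - by_subject[:, None])        # posterior node weights

        P_zero = P[self.sidx_zero, :]
        P_pos = P[self.sidx_pos, :]

        pi_zero = expit(lp1_zero)
        pi_pos = np.exp(logpi_pos)
        one_m_pi = 1.0 - pi_pos
        g1_pos = np.where(clip_pos, one_m_pi,
                          one_m_pi * (1.0 + kappa * (1.0 - t_pos)))
        g2_pos = kappa * (t_pos - 1.0)

        wr1 = np.zeros(len(self.y))
        wr1[self.zero_idx] = -(P_zero * pi_zero).sum(axis=1)
        wr1[self.pos_idx] = (P_pos * g1_pos).sum(axis=1)
        wr2 = np.zeros(len(self.y))
        wr2[self.pos_idx] = (P_pos * g2_pos).sum(axis=1)
        grad_alpha = x1.T @ wr1
        grad_beta = x2.T @ wr2

        # d/d kappa on positive rows: lk + 1 - logmu - digamma + logy - t
        gk = ((lk + 1.0 - digamma(kappa)) * float(P_pos.sum())
              + float((P_pos * (self.logy_pos[:, None] - logmu_pos - t_pos)).sum()))
        grad_log_kappa = kappa * gk

        # prior gradients w.r.t. log sigma_a, log sigma_d, atanh(rho)
        u = nodes.a / sa
        v = nodes.d / sd
        om = 1.0 - rho**2
        uv = u * v
        g_lsa = -1.0 + (u * u - rho * uv) / om
        g_lsd = -1.0 + (v * v - rho * uv) / om
        q_form = u * u - 2.0 * rho * uv + v * v
        g_w = (rho / om + (uv * om - rho * q_form) / om**2) * om
        grad_lsa = float((P * g_lsa).sum())
        grad_lsd = float((P * g_lsd).sum())
        grad_w = float((P * g_w).sum())

        grad = np.concatenate([grad_alpha, grad_beta,
                               [grad_log_kappa, grad_lsa, grad_lsd, grad_w]])
        return total, grad

    def subject_gradients(self, internal: np.ndarray, nodes: NodeSet) -> np.ndarray:
        """Per-subject score vectors (S x n_params, internal scale)."""
        p = self.p
        params = MTPParams.from_internal(internal, p)
        x1, x2 = self.design.x1, self.design.x2
        eta1, eta2 = self._eta(params)
        kappa = params.kappa
        lk = np.log(kappa)
        sa = max(params.sigma_a, 1e-8)
        sd = max(params.sigma_d, 1e-8)
        rho = params.rho

        lp1_zero, logpi_pos, logmu_pos, t_pos, clip_pos, data_M = \
            self._node_quantities(eta1, eta2, nodes, kappa)
        const = ((kappa - 1.0) * self.subj_sumlogy
                 + self.subj_npos * (kappa * lk - gammaln(kappa)))
        M = (data_M + const[:, None]
             + _log_bvn(nodes.a, nodes.d, sa, sd, rho) + nodes.log_w)
        by_subject = logsumexp(M, axis=1)
        P = np.exp(M - by_subject[:, None])

        wr1 = np.zeros(len(self.y))
        wr1[self.zero_idx] = -(P[self.sidx_zero, :] * expit(lp1_zero)).sum(axis=1)
        pi_pos = np.exp(logpi_pos)
        one_m_pi = 1.0 - pi_pos
        g1_pos = np.where(clip_pos, one_m_pi,
                          one_m_pi * (1.0 + kappa * (1.0 - t_pos)))
        P_pos = P[self.sidx_pos, :]
        wr1[self.pos_idx] = (P_pos * g1_pos).sum(axis=1)
        wr2 = np.zeros(len(self.y))
        wr2[self.pos_idx] = (P_pos * (kappa * (t_pos - 1.0))).sum(axis=1)
        gk_rows = np.zeros(len(self.y))
        gk_rows[self.pos_idx] = (P_pos * (
            lk + 1.0 - digamma(kappa) + self.logy_pos[:, None]
            - logmu_pos - t_pos)).sum(axis=1)

        S = self.n_subjects
        G = np.zeros((S, 2 * p + 4))
        for j in range(p):
            G[:, j] = np.bincount(self.sidx, weights=wr1 * x1[:, j], minlength=S)
            G[:, p + j] = np.bincount(self.sidx, weights=wr2 * x2[:, j], minlength=S)
        G[:, 2 * p] = kappa * np.bincount(self.sidx, weights=gk_rows, minlength=S)

        u = nodes.a / sa
        v = nodes.d / sd
        om = 1.0 - rho**2
        uv = u * v
        G[:, 2 * p + 1] = (P * (-1.0 + (u * u - rho * uv) / om)).sum(axis=1)
        G[:, 2 * p + 2] = (P * (-1.0 + (v * v - rho * uv) / om)).sum(axis=1)
        qf = u * u - 2.0 * rho * uv + v * v
        G[:, 2 * p + 3] = (P * ((rho / om + (uv * om - rho * qf) / om**2) * om)).sum(axis=1)
        return G

    # -- adaptive node placement -------------------------------------------

    def laplace_modes(self, params: MTPParams, start: np.ndarray | None = None,
                      max_iter: int = 40, tol: float = 1e-6):
        """Per-subject posterior modes of (a, d) and the local curvature.

        Damped Newton, vectorized across subjects.  Returns
        ``(modes (S,2), H (S,2,2))`` with H the Hessian of the log joint.
        """
        S = self.n_subjects
        eta1, eta2 = self._eta(params)
        eta1_zero = eta1[self.zero_idx]
        eta1_pos = eta1[self.pos_idx]
        eta2_pos = eta2[self.pos_idx]
        kappa = params.kappa
        sa = max(params.sigma_a, 1e-8)
        sd = max(params.sigma_d, 1e-8)
        Sigma = np.array([[sa**2, params.rho * sa * sd],
                          [params.rho * sa * sd, sd**2]])
        Sinv = np.linalg.inv(Sigma)

        b = np.zeros((S, 2)) if start is None else np.array(start, float)

        def joint_and_derivs(b):
            with np.errstate(invalid="ignore", over="ignore"):
                return _joint_and_derivs(b)

        def _joint_and_derivs(b):
            a_z = b[self.sidx_zero, 0]
            a_p = b[self.sidx_pos, 0]
            d_p = b[self.sidx_pos, 1]
            lp1_z = eta1_zero + a_z
            lp1_p = eta1_pos + a_p
            logpi = -np.logaddexp(0.0, -lp1_p)
            clipped = logpi < _LOG_PI_FLOOR
            logpi_c = np.maximum(logpi, _LOG_PI_FLOOR)
            logmu = eta2_pos + d_p - logpi_c
            t = self.y_pos * np.exp(-logmu)
            ll_z = -np.logaddexp(0.0, lp1_z)
            ll_p = logpi - kappa * (logmu + t)
            h = (np.bincount(self.sidx_zero, weights=ll_z, minlength=S)
                 + np.bincount(self.sidx_pos, weights=ll_p, minlength=S))

            pi_z = expit(lp1_z)
            pi_p = np.exp(logpi)
            omp = 1.0 - pi_p
            g1_p = np.where(clipped, omp, omp * (1.0 + kappa * (1.0 - t)))
            g2_p = kappa * (t - 1.0)
            haa_p = np.where(clipped, -pi_p * omp,
                             -pi_p * omp * (1.0 + kappa * (1.0 - t))
                             - kappa * t * omp**2)
            had_p = np.where(clipped, 0.0, kappa * t * omp)
            hdd_p = -kappa * t

            G = np.empty((S, 2))
            G[:, 0] = (np.bincount(self.sidx_zero, weights=-pi_z, minlength=S)
                       + np.bincount(self.sidx_pos, weights=g1_p, minlength=S))
            G[:, 1] = np.bincount(self.sidx_pos, weights=g2_p, minlength=S)
            H = np.empty((S, 2, 2))
            H[:, 0, 0] = (np.bincount(self.sidx_zero, weights=-pi_z * (1 - pi_z),
                                      minlength=S)
                          + np.bincount(self.sidx_pos, weights=haa_p, minlength=S))
            H[:, 0, 1] = H[:, 1, 0] = np.bincount(self.sidx_pos, weights=had_p,
                                                  minlength=S)
            H[:, 1, 1] = np.bincount(self.sidx_pos, weights=hdd_p, minlength=S)
            # prior
            h = h - 0.5 * np.einsum("si,ij,sj->s", b, Sinv, b)
            G = G - b @ Sinv
            H = H - Sinv[None, :, :]
            return h, G, H

        h, G, H = joint_and_derivs(b)
        for _ in range(max_iter):
          with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
            bad = ~(det > 1e-12) | ~(H[:, 0, 0] < 0)   # nan-safe
            Hs = H.copy()
            if bad.any():
                Hs[bad] = -Sinv[None, :, :] - 0.5 * np.eye(2)
                det = Hs[:, 0, 0] * Hs[:, 1, 1] - Hs[:, 0, 1] ** 2
            step = np.empty_like(G)
            step[:, 0] = -(Hs[:, 1, 1] * G[:, 0] - Hs[:, 0, 1] * G[:, 1]) / det
            step[:, 1] = -(Hs[:, 0, 0] * G[:, 1] - Hs[:, 0, 1] * G[:, 0]) / det
            norm = np.max(np.abs(step), axis=1, keepdims=True)
            step *= np.minimum(1.0, 4.0 / np.maximum(norm, 1e-300))
            frac = np.ones((S, 1))
            for _ in range(8):
                h_new, G_new, H_new = joint_and_derivs(b + frac * step)
                worse = h_new < h - 1e-10
                if not worse.any():
                    break
                frac = np.where(worse[:, None], frac * 0.5, frac)
            b = b + frac * step
            h, G, H = h_new, G_new, H_new
            if np.max(np.abs(G)) < tol:
                break
        return b, H

    def adaptive_nodes(self, params: MTPParams, k: int,
                       start: np.ndarray | None = None) -> NodeSet:
        """Laplace-centered Gauss–Hermite node set (importance form)."""
        modes, H = self.laplace_modes(params, start=start)
        V = -H  # negative Hessian of log joint = local precision
        det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] ** 2
        ok = (det > 1e-12) & (V[:, 0, 0] > 0)
        Sigma = params.covariance()
        safe_det = np.where(ok, det, 1.0)
        v11 = np.where(ok, V[:, 1, 1] / safe_det, max(Sigma[0, 0], 1e-16))
        v22 = np.where(ok, V[:, 0, 0] / safe_det, max(Sigma[1, 1], 1e-16))
        v12 = np.where(ok, -V[:, 0, 1] / safe_det, Sigma[0, 1])
        c11, c21, c22 = _chol2(v11, v12, v22)
        z1, z2, lw = _hermite_grid(k)
        a = modes[:, [0]] + c11[:, None] * z1[None, :]
        d = modes[:, [1]] + c21[:, None] * z1[None, :] + c22[:, None] * z2[None, :]
        log_w = (lw + 0.5 * (z1**2 + z2**2))[None, :] \
            + (np.log(c11) + np.log(c22))[:, None]
        return NodeSet(a=a, d=d, log_w=log_w, modes=modes)

    def nodes_for(self, params: MTPParams, quad: QuadratureSpec) -> NodeSet:
        if quad.adaptive and params.has_random_effects:
            return self.adaptive_nodes(params, quad.nodes_per_dim)
        return standard_nodes(params, self.n_subjects, quad.nodes_per_dim)


# ---------------------------------------------------------------------------
# public likelihood API


def _two_part_closed_form(x1, x2, y, params: MTPParams) -> float:
    """Independent two-part log-likelihood (sigma_a = sigma_d = 0)."""
    eta1 = x1 @ params.alpha
    eta2 = x2 @ params.beta
    pos = y > 0
    log_pi = -np.logaddexp(0.0, -eta1)
    log_1mpi = -np.logaddexp(0.0, eta1)
    ll = np.where(pos, 0.0, log_1mpi)
    if pos.any():
        pi_c = np.maximum(np.exp(log_pi[pos]), PI_FLOOR)
        mu = np.exp(eta2[pos]) / pi_c
        ll = ll.copy()
        ll[pos] = log_pi[pos] + gamma_logpdf(y[pos], params.kappa, mu)
    return float(ll.sum())


def _as_design(x1, x2, y) -> DesignMatrices:
    x1 = np.atleast_2d(np.asarray(x1, float))
    x2 = np.atleast_2d(np.asarray(x2, float))
    y = np.asarray(y, float).ravel()
    return DesignMatrices(
        x1=x1, x2=x2, y=y,
        subject_index=np.zeros(len(y), dtype=np.int64),
        subject_ids=np.array([0]),
        columns=tuple(f"c{i}" for i in range(x1.shape[1])),
    )


def subject_loglik(x1, x2, y, params: MTPParams,
                   quad: QuadratureSpec | None = None) -> float:
    """Integrated log-likelihood for one subject's rows.

    With both random-effect SDs zero this reduces exactly to the
    closed-form independent two-part log-likelihood.
    """
    quad = quad or QuadratureSpec()
    x1 = np.atleast_2d(np.asarray(x1, float))
    x2 = np.atleast_2d(np.asarray(x2, float))
    y = np.asarray(y, float).ravel()
    if len(y) == 0:
        raise LikelihoodError("subject has no observations")
    if not params.has_random_effects:
        return _two_part_closed_form(x1, x2, y, params)
    ev = PanelEvaluator(_as_design(x1, x2, y))
    return ev.loglik(params, ev.nodes_for(params, quad))


def total_loglik(design: DesignMatrices, params: MTPParams,
                 quad: QuadratureSpec | None = None) -> float:
    """Sum of subject log-likelihoods over a panel."""
    quad = quad or QuadratureSpec()
    if not params.has_random_effects:
        return _two_part_closed_form(design.x1, design.x2, design.y, params)
    ev = PanelEvaluator(design)
    return ev.loglik(params, ev.nodes_for(params, quad))


def subject_loglik_mc(x1, x2, y, params: MTPParams, n_draws: int = 100_000,
                      rng: np.random.Generator | None = None):
    """Brute-force Monte-Carlo integration of the subject likelihood.

    Independent of the quadrature path (scipy.stats densities, plain MVN
    draws); returns ``(loglik, mc_standard_error_of_loglik)``.  Intended as
    a cross-check oracle, not for fitting.
    """
    from scipy import stats

    rng = rng or np.random.default_rng()
    x1 = np.atleast_2d(np.asarray(x1, float))
    x2 = np.atleast_2d(np.asarray(x2, float))
    y = np.asarray(y, float).ravel()
    b = rng.multivariate_normal(np.zeros(2), params.covariance(), size=n_draws)
    eta1 = x1 @ params.alpha
    eta2 = x2 @ params.beta
    logf = np.zeros(n_draws)
    for j in range(len(y)):
        pi = expit(eta1[j] + b[:, 0])
        if y[j] > 0:
            mu = np.exp(eta2[j] + b[:, 1]) / np.maximum(pi, PI_FLOOR)
            logf += np.log(pi) + stats.gamma.logpdf(y[j], a=params.kappa,
                                                    scale=mu / params.kappa)
        else:
            logf += np.log1p(-pi)
    m = logsumexp(logf) - np.log(n_draws)
    # delta-method SE of the log of the MC mean
    w = np.exp(logf - m - np.log(n_draws))  # normalized weights, sum ~ 1
    se = float(np.sqrt(np.sum((w - 1.0 / n_draws) ** 2)))
    return float(m), se
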