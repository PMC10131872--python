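"""Maximum-likelihood fitting of the MTP model with Wald inference.

Strategy
--------
1. Starting values from two no-random-effect fits: a logistic GLM of the
   usage indicator on the binary-part design, and a log-link Poisson
   quasi-likelihood GLM of the (zero-inclusive) cost on the mean-part
   design — the latter targets the marginal mean directly, which is what
   the MTP ``beta`` parameterizes.  The gamma shape starts at a
   method-of-moments value, the random-effect SDs at a small positive
   constant.
2. Iteratively adapted Gauss–Hermite quadrature: per-subject Laplace
   modes/curvatures are computed, frozen, and the frozen-node likelihood —
   analytic in every parameter — is maximized by L-BFGS-B with exact
   gradients on the unconstrained scale (log kappa, log sigmas, atanh rho).
   Nodes are then re-adapted and the cycle repeats until the likelihood
   stabilizes.
3. The observed information is obtained by central differences of the
   analytic gradient (per-parameter adaptive steps); its inverse is the
   internal-scale covariance, transformed to the natural scale by the
   delta method.  If the information is not positive definite, an
   outer-product-of-gradients covariance is substituted with a warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import STRUCTURAL_COLUMNS, DesignMatrices
from .likelihood import (
    MTPParams,
    NodeSet,
    PanelEvaluator,
    QuadratureSpec,
    standard_nodes,
)

logger = logging.getLogger(__name__)

VARIANCE_NAMES = ("kappa", "sigma_a", "sigma_d", "rho")


class FitError(RuntimeError):
    """Raised for unusable designs (collinearity, no zeros/positives...)."""


def wald_ci(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Symmetric normal-theory interval: estimate +/- z * se."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return (estimate - z * se, estimate + z * se)


def parameter_names(columns) -> list[str]:
    return (["binary:" + c for c in columns]
            + ["mean:" + c for c in columns]
            + list(VARIANCE_NAMES))


@dataclass
class FitOptions:
    max_outer: int = 4
    maxiter: int = 300
    outer_tol: float = 1e-6     # stop re-adapting when loglik moves less than this
    stab_tol: float = 1e-4      # final-round loglik stability required for `converged`
    gtol_rel: float = 1e-5      # relative-gradient convergence criterion
    laplace_warmup: bool = True  # first round on the 1-node (Laplace) objective
    lbfgs_ftol: float = 1e-12
    lbfgs_gtol: float = 1e-4    # on the column-scaled gradient
    compute_se: bool = True
    start: MTPParams | None = None
    sigma_start: float = 0.3


@dataclass
class FitResult:
    """Estimates, covariance and diagnostics of one MTP fit.

    ``estimates`` concatenates the natural-scale parameters in the order
    given by ``names`` (binary coefficients, mean coefficients, kappa,
    sigma_a, sigma_d, rho); ``vcov`` is on the same scale, or None when
    the result was loaded from printed estimates without a covariance.
    """

    params: MTPParams
    columns: tuple
    names: list
    estimates: np.ndarray
    vcov: np.ndarray | None
    loglik: float
    n_subjects: int
    n_obs: int
    converged: bool
    iterations: int
    gradient_norm: float
    rel_gradient: float
    rel_ll_change: float
    n_pi_clipped: int = 0
    message: str = ""
    ci_overrides: dict = field(default_factory=dict)  # printed intervals
    vcov_internal: np.ndarray | None = None

    def se(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        se = self.se()
        rows = []
        for i, name in enumerate(self.names):
            est = float(self.estimates[i])
            if name in self.ci_overrides:
                lo, hi = self.ci_overrides[name]
            elif se is not None:
                lo, hi = wald_ci(est, float(se[i]), level)
            else:
                lo = hi = np.nan
            rows.append((name, est, lo, hi))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "lower", "upper"])

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Reporting table: component, parameter symbol, estimate, CI."""
        ci = self.ci(level)
        n_struct = sum(c in STRUCTURAL_COLUMNS for c in self.columns)
        symbols, components = [], []
        for name in self.names:
            if name.startswith("binary:") or name.startswith("mean:"):
                part, col = name.split(":", 1)
                idx = list(self.columns).index(col)
                if idx < n_struct:
                    sym = ("alpha" if part == "binary" else "beta") + f"_{idx + 1}"
                else:
                    sym = ("gamma" if part == "binary" else "delta") + f"_{idx - n_struct + 1}"
                components.append(part)
            else:
                sym = name
                components.append("dispersion" if name == "kappa" else "random_effects")
            symbols.append(sym)
        out = ci.copy()
        out.insert(0, "component", components)
        out.insert(2, "symbol", symbols)
        return out

    def to_json(self, path=None):
        payload = {
            "columns": list(self.columns),
            "names": list(self.names),
            "params": self.params.to_dict(self.columns),
            "estimates": [float(v) for v in self.estimates],
            "vcov": None if self.vcov is None else np.asarray(self.vcov).tolist(),
            "loglik": float(self.loglik),
            "n_subjects": int(self.n_subjects),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "gradient_norm": float(self.gradient_norm),
            "rel_gradient": float(self.rel_gradient),
            "rel_ll_change": float(self.rel_ll_change),
            "n_pi_clipped": int(self.n_pi_clipped),
            "message": self.message,
            "ci_overrides": {k: list(v) for k, v in self.ci_overrides.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FitResult":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        columns = tuple(payload["columns"])
        params = MTPParams.from_dict(payload["params"], columns)
        vcov = payload["vcov"]
        return cls(
            params=params, columns=columns, names=list(payload["names"]),
            estimates=np.asarray(payload["estimates"], float),
            vcov=None if vcov is None else np.asarray(vcov, float),
            loglik=payload["loglik"], n_subjects=payload["n_subjects"],
            n_obs=payload["n_obs"], converged=payload["converged"],
            iterations=payload["iterations"],
            gradient_norm=payload["gradient_norm"],
            rel_gradient=payload["rel_gradient"],
            rel_ll_change=payload["rel_ll_change"],
            n_pi_clipped=payload.get("n_pi_clipped", 0),
            message=payload.get("message", ""),
            ci_overrides={k: tuple(v) for k, v in payload.get("ci_overrides", {}).items()},
        )

    @classmethod
    def from_estimates(cls, columns, binary: dict, mean: dict,
                       kappa: float = 1.0, sigma_a: float = 0.0,
                       sigma_d: float = 0.0, rho: float = 0.0,
                       ci_overrides: dict | None = None) -> "FitResult":
        """Assemble a coefficient-only result (no covariance), e.g. from a
        printed reporting table, for use with the effects machinery."""
        columns = tuple(columns)
        params = MTPParams(
            alpha=np.array([binary[c] for c in columns], float),
            beta=np.array([mean[c] for c in columns], float),
            kappa=kappa, sigma_a=sigma_a, sigma_d=sigma_d,
            rho=max(min(rho, 0.999999), -0.999999),
        )
        est = np.concatenate([params.alpha, params.beta,
                              [kappa, sigma_a, sigma_d, rho]])
        return cls(
            params=params, columns=columns, names=parameter_names(columns),
            estimates=est, vcov=None, loglik=np.nan,
            n_subjects=0, n_obs=0, converged=True, iterations=0,
            gradient_norm=np.nan, rel_gradient=np.nan, rel_ll_change=np.nan,
            message="loaded from printed estimates",
            ci_overrides=ci_overrides or {},
        )


def _natural_jacobian(params: MTPParams, p: int,
                      col_scale: np.ndarray) -> np.ndarray:
    """Diagonal Jacobian d(natural)/d(internal, column-scaled) at the
    estimate.  Coefficients are optimized against unit-scaled design
    columns, so the natural coefficient is the scaled one divided by the
    column scale."""
    jac = np.ones(2 * p + 4)
    jac[:p] = 1.0 / col_scale
    jac[p:2 * p] = 1.0 / col_scale
    jac[2 * p + 0] = params.kappa
    jac[2 * p + 1] = params.sigma_a
    jac[2 * p + 2] = params.sigma_d
    jac[2 * p + 3] = 1.0 - params.rho**2
    return jac


def starting_values(design: DesignMatrices, options: FitOptions) -> MTPParams:
    """No-random-effect two-part starts (see module docstring)."""
    import statsmodels.api as sm

    y = design.y
    pos = (y > 0).astype(float)
    if pos.min() == 1.0 or pos.max() == 0.0:
        raise FitError("design needs at least one zero and one positive outcome")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        logit = sm.GLM(pos, design.x1, family=sm.families.Binomial()).fit()
        poisson = sm.GLM(y, design.x2, family=sm.families.Poisson()).fit()
    alpha0 = np.asarray(logit.params, float)
    beta0 = np.asarray(poisson.params, float)
    if not (np.all(np.isfinite(alpha0)) and np.all(np.isfinite(beta0))):
        raise FitError("starting GLMs produced non-finite coefficients "
                       "(near-collinear design columns?)")
    # method-of-moments gamma shape from positive-part squared CV
    pi_hat = np.clip(1.0 / (1.0 + np.exp(-(design.x1 @ alpha0))), 1e-6, 1.0)
    mu_hat = np.exp(design.x2 @ beta0) / pi_hat
    posm = y > 0
    cv2 = float(np.mean(((y[posm] - mu_hat[posm]) / mu_hat[posm]) ** 2))
    kappa0 = float(np.clip(1.0 / max(cv2, 1e-3), 0.05, 50.0))

    # moment starts for the random-intercept SDs: between-subject spread of
    # (i) mean log-cost residuals and (ii) usage-rate logit shifts
    S = design.n_subjects
    sidx = design.subject_index
    r = np.log(y[posm]) - (design.x2 @ beta0)[posm]
    n_pos = np.bincount(sidx[posm], minlength=S)
    sum_r = np.bincount(sidx[posm], weights=r, minlength=S)
    enough = n_pos >= 3
    if enough.sum() >= 10:
        sigma_d0 = float(np.clip(np.std(sum_r[enough] / n_pos[enough]), 0.05, 2.0))
    else:
        sigma_d0 = options.sigma_start
    n_i = np.bincount(sidx, minlength=S)
    obs = np.clip(np.bincount(sidx, weights=posm.astype(float), minlength=S) / n_i,
                  0.02, 0.98)
    exp_ = np.clip(np.bincount(sidx, weights=pi_hat, minlength=S) / n_i, 0.02, 0.98)
    shift = np.log(obs / (1 - obs)) - np.log(exp_ / (1 - exp_))
    sigma_a0 = float(np.clip(0.7 * np.std(shift), 0.05, 2.0))
    return MTPParams(alpha=alpha0, beta=beta0, kappa=kappa0,
                     sigma_a=sigma_a0, sigma_d=sigma_d0, rho=0.0)


def _hessian_from_grad(fun_grad, theta: np.ndarray, nodes: NodeSet) -> np.ndarray:
    """Central-difference Hessian of the log-likelihood from its analytic
    gradient, with per-parameter adaptive steps."""
    n = len(theta)
    H = np.empty((n, n))
    for k in range(n):
        h = 1e-5 * max(1.0, abs(theta[k]))
        tp = theta.copy(); tp[k] += h
        tm = theta.copy(); tm[k] -= h
        _, gp = fun_grad(tp, nodes)
        _, gm = fun_grad(tm, nodes)
        H[:, k] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _opg_vcov(ev: PanelEvaluator, theta: np.ndarray, nodes: NodeSet) -> np.ndarray:
    """Outer-product-of-gradients covariance (fallback)."""
    G = ev.subject_gradients(theta, nodes)
    info = G.T @ G
    return np.linalg.pinv(info)


def fit(design: DesignMatrices, quad: QuadratureSpec | None = None,
        options: FitOptions | None = None) -> FitResult:
    """Maximize the integrated MTP likelihood on a cost panel.

    Deterministic given the design and options (single-start L-BFGS-B from
    GLM starting values).  Non-convergence is reported through the
    ``converged`` flag and diagnostics, never as a silent success.
    """
    quad = quad or QuadratureSpec()
    options = options or FitOptions()
    if design.n_subjects < 2:
        raise FitError("need at least 2 subjects")

    # collinearity guard on the shared column set
    svals = np.linalg.svd(design.x1, compute_uv=False)
    if svals[-1] < 1e-10 * svals[0]:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(design.x1, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise FitError(
            "singular design: columns "
            f"{design.columns[i]!r} and {design.columns[j]!r} are near-collinear")

    # optimize against unit-scaled columns for L-BFGS conditioning
    p = design.n_params
    col_scale = np.maximum(np.max(np.abs(design.x1), axis=0), 1e-12)
    scaled = DesignMatrices(
        x1=design.x1 / col_scale, x2=design.x2 / col_scale, y=design.y,
        subject_index=design.subject_index, subject_ids=design.subject_ids,
        columns=design.columns, subject_starts=design.subject_starts,
    )
    ev = PanelEvaluator(scaled)
    start = options.start or starting_values(design, options)
    start_scaled = MTPParams(
        alpha=start.alpha * col_scale, beta=start.beta * col_scale,
        kappa=start.kappa, sigma_a=start.sigma_a,
        sigma_d=start.sigma_d, rho=start.rho,
    )
    theta = start_scaled.to_internal()

    # node schedule: an optional cheap Laplace (1-node) round brings the
    # parameters close before the full-node rounds polish
    ks = [quad.nodes_per_dim] * options.max_outer
    if options.laplace_warmup and quad.adaptive and quad.nodes_per_dim > 1:
        ks = [1] + ks

    total_iter = 0
    prev_ll = -np.inf
    rel_change = np.inf
    nodes = None
    modes = None
    for outer, k_round in enumerate(ks):
        params = MTPParams.from_internal(theta, p)
        if quad.adaptive:
            nodes = ev.adaptive_nodes(params, k_round, start=modes)
            modes = nodes.modes
        else:
            nodes = standard_nodes(params, ev.n_subjects, k_round)

        def negobj(th):
            ll, g = ev.loglik_and_grad(th, nodes)
            return -ll, -g

        res = optimize.minimize(
            negobj, theta, jac=True, method="L-BFGS-B",
            options={"maxiter": options.maxiter, "ftol": options.lbfgs_ftol,
                     "gtol": options.lbfgs_gtol},
        )
        theta = res.x
        ll = -res.fun
        total_iter += res.nit
        rel_change = abs(ll - prev_ll) / max(1.0, abs(ll))
        logger.info("outer %d: loglik %.6f (rel change %.3g, %d iters)",
                    outer + 1, ll, rel_change, res.nit)
        prev_ll = ll
        if k_round == ks[-1] and outer > 0 and rel_change < options.outer_tol:
            break

    params = MTPParams.from_internal(theta, p)
    ll, grad = ev.loglik_and_grad(theta, nodes)
    gradient_norm = float(np.max(np.abs(grad)))
    rel_grad = float(np.max(np.abs(grad) * np.maximum(np.abs(theta), 1.0))
                     / max(abs(ll), 1.0))
    converged = (rel_change < options.stab_tol) and (rel_grad < options.gtol_rel)
    message = "converged" if converged else (
        f"not converged: rel gradient {rel_grad:.2e}, rel loglik change {rel_change:.2e}")
    if not converged:
        logger.warning(message)

    vcov_nat = None
    vcov_int = None
    if options.compute_se:
        H = _hessian_from_grad(ev.loglik_and_grad, theta, nodes)
        info = -H
        try:
            np.linalg.cholesky(info + 0.0 * np.eye(len(theta)))
            vcov_int = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            logger.warning("observed information not positive definite; "
                           "falling back to outer-product-of-gradients covariance")
            vcov_int = _opg_vcov(ev, theta, nodes)
        jac = _natural_jacobian(params, p, col_scale)
        vcov_nat = vcov_int * np.outer(jac, jac)

    params_nat = MTPParams(
        alpha=params.alpha / col_scale, beta=params.beta / col_scale,
        kappa=params.kappa, sigma_a=params.sigma_a,
        sigma_d=params.sigma_d, rho=params.rho,
    )
    estimates = np.concatenate([params_nat.alpha, params_nat.beta,
                                [params.kappa, params.sigma_a,
                                 params.sigma_d, params.rho]])
    return FitResult(
        params=params_nat, columns=design.columns,
        names=parameter_names(design.columns),
        estimates=estimates, vcov=vcov_nat, vcov_internal=vcov_int,
        loglik=float(ll), n_subjects=design.n_subjects, n_obs=design.n_obs,
        converged=bool(converged), iterations=int(total_iter),
        gradient_norm=gradient_norm, rel_gradient=rel_grad,
        rel_ll_change=float(rel_change),
        n_pi_clipped=ev.clip_count(params, nodes),
        message=message,
    )
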