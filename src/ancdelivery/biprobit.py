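"""Recursive bivariate probit with an instrumental variable.

The system is

    O* = delta*E + X @ beta1  + eps,      O = 1{O* > 0}
    E* = gamma*Z + X @ beta1' + eps',     E = 1{E* > 0}

with (eps, eps') standard bivariate normal with correlation rho and the
instrument Z excluded from the outcome equation.  Despite the recursive
structure, the likelihood coincides with that of an ordinary bivariate
probit treating E as a regressor in the outcome equation (the endogenous
dummy needs no Jacobian term), so each row contributes

    log Phi2( q_O * w_O, q_E * w_E, q_O * q_E * rho ),   q = 2*indicator - 1.

rho is parameterized as atanh(rho) for unconstrained optimization; the Wald
test of exogeneity is the squared z-statistic of atanh(rho) against zero,
chi-square(1) under rho = 0.  A significantly negative rho means the
unobservables that raise ANC uptake depress facility delivery, so the naive
probit understates the exposure effect — the pattern the corrected
estimator is there to undo.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr, ndtr, owens_t
from scipy.stats import chi2, norm

from .design import DesignMatrix
from .exceptions import (
    ConvergenceError,
    DataError,
    ExclusionRestrictionError,
    InferenceError,
)
from .probit import fit_probit, significance_stars

logger = logging.getLogger("ancdelivery")

ATANH_RHO_BOUND = 12.0
_TINY = 1e-300


def bvn_cdf(x, y, rho):
    """Standard bivariate normal CDF P(U <= x, V <= y) with correlation rho.

    Evaluated through Owen's T function (Owen 1956):

        Phi2(h, k, r) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - c,
        a_h = (k - r*h) / (h*sqrt(1-r^2)),  a_k symmetric,
        c = 1/2 when h*k < 0, else 0,

    with closed forms on the h=0 / k=0 axes and at |rho| = 1.  Inputs
    broadcast; accuracy is limited only by scipy's owens_t (~1e-14).
    """
    x, y, rho = np.broadcast_arrays(*(np.asarray(v, dtype=float) for v in (x, y, rho)))
    if np.any(np.abs(rho) > 1):
        raise ValueError("|rho| must be <= 1")
    out = np.empty(x.shape, dtype=float)

    pos_inf_x, neg_inf_x = np.isposinf(x), np.isneginf(x)
    pos_inf_y, neg_inf_y = np.isposinf(y), np.isneginf(y)
    rho_hi = rho >= 1.0 - 1e-15
    rho_lo = rho <= -1.0 + 1e-15
    finite = ~(pos_inf_x | neg_inf_x | pos_inf_y | neg_inf_y)
    general = finite & ~rho_hi & ~rho_lo

    with np.errstate(divide="ignore", invalid="ignore"):
        h, k, r = x[general], y[general], rho[general]
        s = np.sqrt(1.0 - r * r)
        both_zero = (h == 0) & (k == 0)
        h_zero = (h == 0) & ~both_zero
        k_zero = (k == 0) & ~both_zero
        gen = ~(both_zero | h_zero | k_zero)

        res = np.empty(h.shape, dtype=float)
        res[both_zero] = 0.25 + np.arcsin(r[both_zero]) / (2.0 * np.pi)
        # one argument on the axis: Phi2(0, k, r) = Phi(k)/2 + T(k, r/s)
        res[h_zero] = ndtr(k[h_zero]) / 2.0 + owens_t(k[h_zero], r[h_zero] / s[h_zero])
        res[k_zero] = ndtr(h[k_zero]) / 2.0 + owens_t(h[k_zero], r[k_zero] / s[k_zero])

        hg, kg, rg, sg = h[gen], k[gen], r[gen], s[gen]
        a1 = (kg - rg * hg) / (hg * sg)
        a2 = (hg - rg * kg) / (kg * sg)
        # sign-based quadrant correction (h*k can underflow to +-0)
        c = np.where(np.sign(hg) * np.sign(kg) < 0, 0.5, 0.0)
        res[gen] = (0.5 * (ndtr(hg) + ndtr(kg))
                    - owens_t(hg, a1) - owens_t(kg, a2) - c)
        out[general] = res

    # comonotone / countermonotone limits
    lim_hi = finite & rho_hi
    out[lim_hi] = ndtr(np.minimum(x[lim_hi], y[lim_hi]))
    lim_lo = finite & rho_lo
    out[lim_lo] = np.maximum(0.0, ndtr(x[lim_lo]) + ndtr(y[lim_lo]) - 1.0)

    # infinite arguments
    out[neg_inf_x | neg_inf_y] = 0.0
    only_x_inf = pos_inf_x & ~neg_inf_y
    out[only_x_inf] = ndtr(y[only_x_inf])
    only_y_inf = pos_inf_y & ~neg_inf_x & ~pos_inf_x
    out[only_y_inf] = ndtr(x[only_y_inf])
    out[pos_inf_x & pos_inf_y] = 1.0

    np.clip(out, 0.0, 1.0, out=out)
    return out if out.ndim else float(out)


@dataclass
class BiprobitFit:
    """Joint MLE of the recursive bivariate probit system."""

    params: np.ndarray          # (delta, beta1..., gamma, beta1'..., atanh rho)
    outcome_names: list[str]    # names for (dimension, X columns)
    treatment_names: list[str]  # names for (instrument, X columns)
    cov: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    identified: bool
    weak_instrument: bool
    n: int
    dimension_col: str
    instrument_col: str

    @property
    def k(self) -> int:
        return len(self.outcome_names) - 1  # X columns (dimension excluded)

    @property
    def delta(self) -> float:
        return float(self.params[0])

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.params[1:1 + self.k]

    @property
    def gamma(self) -> float:
        return float(self.params[1 + self.k])

    @property
    def beta_treatment(self) -> np.ndarray:
        return self.params[2 + self.k:2 + 2 * self.k]

    @property
    def atanh_rho(self) -> float:
        return float(self.params[-1])

    @property
    def rho(self) -> float:
        return float(np.tanh(self.atanh_rho))

    @property
    def se_atanh_rho(self) -> float:
        return float(self.se[-1])

    @property
    def se_rho(self) -> float:
        """Delta-method SE of rho from the atanh scale."""
        return (1.0 - self.rho**2) * self.se_atanh_rho

    @property
    def wald_stat(self) -> float:
        return (self.atanh_rho / self.se_atanh_rho) ** 2

    @property
    def wald_p(self) -> float:
        return float(chi2.sf(self.wald_stat, df=1))

    def se_delta(self) -> float:
        return float(self.se[0])

    def to_dict(self) -> dict:
        names = (["delta:" + self.dimension_col]
                 + ["outcome:" + nm for nm in self.outcome_names[1:]]
                 + ["gamma:" + self.instrument_col]
                 + ["treatment:" + nm for nm in self.treatment_names[1:]]
                 + ["atanh_rho"])
        pvals = 2.0 * norm.sf(np.abs(self.params / self.se))
        return {
            "coefficients": [
                {"term": nm, "coef": float(b), "se": float(s), "p": float(p),
                 "stars": significance_stars(float(p))}
                for nm, b, s, p in zip(names, self.params, self.se, pvals)
            ],
            "rho": self.rho,
            "atanh_rho": self.atanh_rho,
            "se_rho": self.se_rho,
            "se_atanh_rho": self.se_atanh_rho,
            "wald_stat": self.wald_stat,
            "wald_p": self.wald_p,
            "loglik": self.loglik,
            "n": self.n,
            "converged": self.converged,
            "identified": self.identified,
            "weak_instrument": self.weak_instrument,
        }


def _as_arrays(O, E, X, Z):
    Xv = X.values if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    Ov = np.asarray(O, dtype=float)
    Ev = np.asarray(E, dtype=float)
    Zv = np.asarray(Z, dtype=float)
    if not (np.isin(Ov, (0.0, 1.0)).all() and np.isin(Ev, (0.0, 1.0)).all()):
        raise DataError("outcome and exposure must be coded 0/1")
    for j in range(Xv.shape[1] if np.ptp(Zv) > 0 else 0):
        if np.array_equal(Xv[:, j], Zv):
            name = X.names[j] if isinstance(X, DesignMatrix) else f"column {j}"
            raise ExclusionRestrictionError(
                f"instrument also appears in the outcome design ({name}); "
                "the exclusion restriction requires it only in the exposure equation"
            )
    return Ov, Ev, Xv, Zv


def _unpack(params: np.ndarray, k: int):
    delta = params[0]
    beta1 = params[1:1 + k]
    gamma = params[1 + k]
    beta2 = params[2 + k:2 + 2 * k]
    theta = params[-1]
    return delta, beta1, gamma, beta2, theta


def _indices(params, E, X, Z, k):
    delta, beta1, gamma, beta2, theta = _unpack(params, k)
    w1 = delta * E + X @ beta1
    w2 = gamma * Z + X @ beta2
    return w1, w2, np.tanh(theta)


def biprobit_loglik(params, O, E, X, Z) -> float:
    """Joint log-likelihood of the recursive bivariate probit.

    ``params`` packs (delta, beta1, gamma, beta1', atanh rho); X is the
    covariate design (intercept included, instrument and exposure excluded).
    """
    Ov, Ev, Xv, Zv = _as_arrays(O, E, X, Z)
    k = Xv.shape[1]
    w1, w2, rho = _indices(np.asarray(params, dtype=float), Ev, Xv, Zv, k)
    q1 = 2.0 * Ov - 1.0
    q2 = 2.0 * Ev - 1.0
    p = bvn_cdf(q1 * w1, q2 * w2, q1 * q2 * rho)
    return float(np.sum(np.log(np.maximum(p, _TINY))))


def _biprobit_grad(params, Ov, Ev, Xv, Zv) -> np.ndarray:
    """Analytic score of the log-likelihood (stable log-space ratios)."""
    k = Xv.shape[1]
    w1, w2, rho = _indices(params, Ev, Xv, Zv, k)
    theta = params[-1]
    q1 = 2.0 * Ov - 1.0
    q2 = 2.0 * Ev - 1.0
    a = q1 * w1
    b = q2 * w2
    r = q1 * q2 * rho
    s2 = 1.0 - r * r
    s = np.sqrt(s2)
    p = np.maximum(bvn_cdf(a, b, r), _TINY)
    logp = np.log(p)
    # dPhi2/da = phi(a) * Phi((b - r a)/s); computed as exp(log terms - log p)
    ga = np.exp(norm.logpdf(a) + log_ndtr((b - r * a) / s) - logp)
    gb = np.exp(norm.logpdf(b) + log_ndtr((a - r * b) / s) - logp)
    # dPhi2/dr = phi2(a, b, r)
    quad = (a * a - 2.0 * r * a * b + b * b) / (2.0 * s2)
    gr = np.exp(-quad - logp) / (2.0 * np.pi * s)

    grad = np.empty(params.size)
    grad[0] = np.sum(q1 * ga * Ev)                      # delta
    grad[1:1 + k] = Xv.T @ (q1 * ga)                    # beta1
    grad[1 + k] = np.sum(q2 * gb * Zv)                  # gamma
    grad[2 + k:2 + 2 * k] = Xv.T @ (q2 * gb)            # beta1'
    grad[-1] = np.sum(gr * q1 * q2) * (1.0 - np.tanh(theta) ** 2)  # atanh rho
    return grad


def _numerical_hessian(grad_fn, params: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of the analytic gradient, symmetrized."""
    p = params.size
    H = np.empty((p, p))
    for j in range(p):
        h = step * max(1.0, abs(params[j]))
        up, dn = params.copy(), params.copy()
        up[j] += h
        dn[j] -= h
        H[:, j] = (grad_fn(up) - grad_fn(dn)) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_biprobit(
    O,
    E,
    X: DesignMatrix,
    Z,
    fix_rho: float | None = None,
    dimension_name: str = "exposure",
    instrument_name: str = "instrument",
) -> BiprobitFit:
    """Joint MLE of (delta, beta1, gamma, beta1', atanh rho).

    Starts from the two single-equation probits with atanh(rho) = 0 and
    optimizes by quasi-Newton (L-BFGS-B) with the analytic score.  Standard
    errors come from the inverse observed information (finite differences of
    the analytic score).  ``fix_rho`` pins rho (used by the reduction check
    that the system collapses to two independent probits at rho = 0).
    """
    Ov, Ev, Xv, Zv = _as_arrays(O, E, X, Z)
    if np.ptp(Zv) == 0:
        raise DataError("instrument has no variation")
    n, k = Xv.shape
    names_x = list(X.names) if isinstance(X, DesignMatrix) else [f"x{j}" for j in range(k)]

    # start values: independent probits
    dm_out = DesignMatrix(values=np.column_stack([Xv, Ev]),
                          names=names_x + [dimension_name],
                          dimension_col=dimension_name)
    dm_trt = DesignMatrix(values=np.column_stack([Xv, Zv]),
                          names=names_x + [instrument_name],
                          dimension_col=instrument_name)
    probit_out = fit_probit(Ov, dm_out)
    probit_trt = fit_probit(Ev, dm_trt)

    start = np.concatenate([
        [probit_out.params[-1]], probit_out.params[:-1],
        [probit_trt.params[-1]], probit_trt.params[:-1],
        [0.0 if fix_rho is None else np.arctanh(fix_rho)],
    ])

    free = np.ones(start.size, dtype=bool)
    if fix_rho is not None:
        free[-1] = False
    full = start.copy()

    def expand(x):
        full[free] = x
        return full

    def negll(x):
        return -biprobit_loglik(expand(x), Ov, Ev, Xv, Zv)

    def neggrad(x):
        return -_biprobit_grad(expand(x), Ov, Ev, Xv, Zv)[free]

    bounds = [(None, None)] * start.size
    bounds[-1] = (-ATANH_RHO_BOUND, ATANH_RHO_BOUND)
    bounds = [bd for bd, f in zip(bounds, free) if f]

    res = optimize.minimize(negll, start[free], jac=neggrad, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
    params = expand(res.x).copy()
    gnorm = float(np.max(np.abs(_biprobit_grad(params, Ov, Ev, Xv, Zv)[free])))
    if not res.success and gnorm > 1e-5 * max(1.0, n):
        raise ConvergenceError(
            f"biprobit failed to converge: {res.message} "
            f"(iterations {res.nit}, grad norm {gnorm:.3e})"
        )
    identified = abs(params[-1]) < ATANH_RHO_BOUND - 0.5
    if not identified:
        warnings.warn("atanh(rho) at its bound: rho is not identified by these data",
                      stacklevel=2)

    def grad_fn(p):
        return _biprobit_grad(p, Ov, Ev, Xv, Zv)

    H = _numerical_hessian(grad_fn, params)
    info = -H
    if fix_rho is not None:
        info = info[np.ix_(free, free)]
    try:
        cov_free = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise InferenceError("singular observed information") from exc
    diag = np.diag(cov_free)
    if np.any(diag <= 0):
        raise InferenceError("observed information not positive definite at optimum")
    cov = np.zeros((params.size, params.size))
    cov[np.ix_(free, free)] = cov_free
    se = np.full(params.size, np.nan)
    se[free] = np.sqrt(diag)

    gamma_z = params[1 + k] / se[1 + k]
    weak = abs(gamma_z) < 2.0
    if weak:
        warnings.warn(
            f"weak instrument: exposure-equation IV z-statistic {gamma_z:.2f} < 2",
            stacklevel=2,
        )
    fit = BiprobitFit(
        params=params,
        outcome_names=[dimension_name] + names_x,
        treatment_names=[instrument_name] + names_x,
        cov=cov,
        se=se,
        loglik=float(-res.fun),
        converged=True,
        identified=identified,
        weak_instrument=weak,
        n=n,
        dimension_col=dimension_name,
        instrument_col=instrument_name,
    )
    logger.info("biprobit fit: n=%d k=%d loglik=%.4f rho=%.4f iter=%d grad=%.2e",
                n, k, fit.loglik, fit.rho, res.nit, gnorm)
    return fit


def wald_exogeneity_test(fit: BiprobitFit, alpha: float = 0.05) -> tuple[float, float, str]:
    """Wald chi-square(1) test of atanh(rho) = 0 and the rho-behaviour label."""
    if not fit.converged:
        raise ConvergenceError("Wald test requires a converged fit")
    if not np.isfinite(fit.se_atanh_rho) or fit.se_atanh_rho <= 0:
        raise InferenceError("missing standard error for atanh(rho)")
    stat = fit.wald_stat
    p = fit.wald_p
    if p >= alpha:
        label = "rho = 0"
    else:
        label = "rho<0" if fit.rho < 0 else "rho>0"
    return stat, p, label


def average_predicted_probability_biprobit(fit: BiprobitFit, X, d: int) -> float:
    """Counterfactual mean Phi(X @ beta1 + d*delta): structural outcome
    probability with the exposure set to d and unobservables marginalized."""
    if d not in (0, 1):
        raise DataError(f"d must be 0 or 1, got {d}")
    Xv = X.values if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    return float(ndtr(Xv @ fit.beta_outcome + d * fit.delta).mean())
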