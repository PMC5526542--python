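"""Single-equation probit maximum likelihood and counterfactual prediction.

The outcome equation is Y* = D*delta + X*beta + eps with eps ~ N(0, 1) and
Y = 1{Y* > 0}; D is one of the two binary ANC dimensions.  Estimation is
quasi-Newton from a zero start with the analytic gradient; standard errors
come from the inverse observed information (analytic Hessian).

Counterfactual average predicted probabilities follow the average
structural function: the dimension column is set to d for every row and
Phi(x_i(d) @ beta_hat) is averaged, i.e. the population-mean probability if
everyone were switched to exposure level d.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from .design import DesignMatrix
from .exceptions import ConvergenceError, DataError, SeparationError

logger = logging.getLogger("ancdelivery")

GRADIENT_TOL = 1e-8
MAX_ITER = 200


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ProbitFit:
    """Probit MLE: coefficients, covariance, fit diagnostics."""

    params: np.ndarray
    names: list[str]
    cov: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n: int
    gradient_norm: float
    dimension_col: str | None = None

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def coefficient_table(self) -> list[dict]:
        rows = []
        for name, b, s, z, p in zip(self.names, self.params, self.se,
                                    self.zvalues, self.pvalues):
            rows.append({"term": name, "coef": float(b), "se": float(s),
                         "z": float(z), "p": float(p),
                         "stars": significance_stars(float(p))})
        return rows


def _validate_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise DataError("outcome must be coded 0/1")
    return y.astype(float)


def probit_loglik(beta: np.ndarray, y, X) -> float:
    """Probit log-likelihood, numerically stable in the tails via log-CDF."""
    Xv = X.values if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    yv = _validate_binary(y)
    xb = Xv @ np.asarray(beta, dtype=float)
    return float(np.sum(yv * log_ndtr(xb) + (1.0 - yv) * log_ndtr(-xb)))


def _probit_score_weights(beta: np.ndarray, y: np.ndarray, X: np.ndarray) -> tuple:
    """Per-row generalized residual lambda_i and index xb (stable tails)."""
    xb = X @ beta
    # inverse Mills ratios via log-space: phi/Phi and phi/(1-Phi)
    mills_pos = np.exp(norm.logpdf(xb) - log_ndtr(xb))
    mills_neg = np.exp(norm.logpdf(xb) - log_ndtr(-xb))
    lam = y * mills_pos - (1.0 - y) * mills_neg
    return lam, xb


def _probit_grad(beta: np.ndarray, y: np.ndarray, X: np.ndarray) -> np.ndarray:
    lam, _ = _probit_score_weights(beta, y, X)
    return X.T @ lam


def _probit_hessian(beta: np.ndarray, y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Hessian of the log-likelihood (negative definite at the optimum)."""
    lam, xb = _probit_score_weights(beta, y, X)
    w = lam * (lam + xb)
    return -(X * w[:, None]).T @ X


def _check_separation(y: np.ndarray, xb: np.ndarray) -> bool:
    p = ndtr(xb)
    ones, zeros = y == 1, y == 0
    lo = p[ones].min() if ones.any() else 1.0
    hi = p[zeros].max() if zeros.any() else 0.0
    return lo > 0.9999 and hi < 0.0001


def fit_probit(y, X: DesignMatrix) -> ProbitFit:
    """Maximum-likelihood probit fit.

    Raises
    ------
    DataError
        If only one outcome class is present.
    SeparationError
        If the data are perfectly separated (MLE at infinity).
    ConvergenceError
        If the quasi-Newton iteration fails to meet the gradient tolerance.
    """
    yv = _validate_binary(y)
    if yv.min() == yv.max():
        raise DataError("outcome has a single class; probit not identified")
    Xv = X.values
    n, p = Xv.shape

    def negll(beta):
        return -probit_loglik(beta, yv, Xv)

    def neggrad(beta):
        return -_probit_grad(beta, yv, Xv)

    res = optimize.minimize(negll, np.zeros(p), jac=neggrad, method="BFGS",
                            options={"gtol": GRADIENT_TOL, "maxiter": MAX_ITER})
    beta = res.x
    gnorm = float(np.max(np.abs(_probit_grad(beta, yv, Xv))))
    if _check_separation(yv, Xv @ beta) or np.max(np.abs(beta)) > 50:
        raise SeparationError("perfect separation detected; probit MLE does not exist")
    # BFGS can stall on a nearly flat ridge; accept if the score is tiny
    # relative to n, otherwise polish with Newton steps.
    if not res.success and gnorm > GRADIENT_TOL * max(1.0, n):
        for _ in range(50):
            H = _probit_hessian(beta, yv, Xv)
            step = np.linalg.solve(H, _probit_grad(beta, yv, Xv))
            beta = beta - step
            gnorm = float(np.max(np.abs(_probit_grad(beta, yv, Xv))))
            if gnorm <= GRADIENT_TOL * max(1.0, n):
                break
        else:
            raise ConvergenceError(f"probit failed to converge (grad norm {gnorm:.3e})")
    H = _probit_hessian(beta, yv, Xv)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rank guarded upstream
        raise ConvergenceError("singular observed information") from exc
    ll = probit_loglik(beta, yv, Xv)
    fit = ProbitFit(params=beta, names=list(X.names), cov=cov,
                    se=np.sqrt(np.diag(cov)), loglik=ll, converged=True, n=n,
                    gradient_norm=gnorm, dimension_col=X.dimension_col)
    logger.info("probit fit: n=%d p=%d loglik=%.4f grad=%.2e", n, p, ll, gnorm)
    return fit


def average_predicted_probability(fit: ProbitFit, X: DesignMatrix, d: int) -> float:
    """Counterfactual mean Phi(x_i(d) @ beta_hat) with the dimension set to d."""
    if d not in (0, 1):
        raise DataError(f"d must be 0 or 1, got {d}")
    if X.dimension_col is None:
        xd = X.values
    else:
        xd = X.with_dimension(d)
    return float(ndtr(xd @ fit.params).mean())


def subgroup_predicted_probability(fit: ProbitFit, X: DesignMatrix, d: int) -> float:
    """Mean fitted probability among rows observed at dimension value d."""
    if X.dimension_col is None:
        raise DataError("design has no dimension column")
    mask = X.column(X.dimension_col) == d
    if not mask.any():
        return math.nan
    return float(ndtr(X.values[mask] @ fit.params).mean())
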