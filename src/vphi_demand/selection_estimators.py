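"""Probit ML, the inverse Mills ratio, and the two-step selection estimator.

Three stages, run in the order the method requires:

1. a reduced-form probit of participation on the full design Z (controls,
   log income, household size) — the selection equation;
2. the price (log-premium) equation on purchasers only, augmented with the
   inverse Mills ratio evaluated at the fitted selection index, which
   corrects for the fact that premiums are observed only upon purchase;
3. the structural participation probit in which the log premium is replaced
   by its stage-2 fitted value Z'delta_hat, the fitted-value instrumenting
   that breaks the correlation between the premium and the taste shock.

Household size identifies the system: it shifts the premium (more members,
larger bill) but is excluded from the structural equation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import special

from .exceptions import DesignError, DomainError, EstimationError
from .survey_data import AnalysisSample

_GRAD_TOL = 1e-8
_MAX_ITER = 100
_SEPARATION_BOUND = 25.0  # on standardized covariates


# --------------------------------------------------------------------------
# Inverse Mills ratio
# --------------------------------------------------------------------------


def mills_ratio(c):
    """Inverse Mills ratio lambda(c) = phi(c) / (1 - Phi(c)).

    Equals E[z | z > c] for standard normal z. Evaluated through the scaled
    complementary error function, sqrt(2/pi) / erfcx(c / sqrt(2)), which is
    stable in both tails (the naive ratio underflows past |c| ~ 37).
    """
    c_arr = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c_arr)):
        raise DomainError("mills_ratio requires finite input")
    out = np.sqrt(2.0 / np.pi) / special.erfcx(c_arr / np.sqrt(2.0))
    return float(out) if np.ndim(c) == 0 else out


# --------------------------------------------------------------------------
# Probit maximum likelihood
# --------------------------------------------------------------------------


@dataclasses.dataclass
class ProbitFit:
    coefficients: np.ndarray
    names: list[str]
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_used: int

    def index(self, design: np.ndarray) -> np.ndarray:
        return design @ self.coefficients


def _probit_loglik(y, eta):
    return float(np.sum(np.where(y == 1, special.log_ndtr(eta), special.log_ndtr(-eta))))


def fit_probit(outcome, design, names: list[str] | None = None) -> ProbitFit:
    """Probit maximum likelihood by Fisher scoring with step-halving.

    ``design`` must include any intercept column. Convergence is declared at
    score max-norm below 1e-8; quasi-complete separation is flagged when a
    coefficient exceeds 25 on internally standardized covariates.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise DesignError(f"design rows {X.shape[0]} != outcome length {y.shape[0]}")
    if not np.all(np.isin(y, [0.0, 1.0])):
        raise DomainError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise EstimationError("no variation in outcome (single class)")
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]

    # internal standardization: scale non-constant columns to unit SD so the
    # separation bound and the convergence metric are scale-free
    sds = X.std(axis=0)
    scale = np.where(sds > 0, sds, 1.0)
    Xs = X / scale
    # rank check on the k x k Gram matrix (cheaper than an SVD of X)
    gram_eigs = np.linalg.eigvalsh(Xs.T @ Xs)
    if gram_eigs[0] < 1e-9 * max(gram_eigs[-1], 1.0):
        raise DesignError("design matrix is rank deficient")

    beta = np.zeros(k)
    eta = Xs @ beta
    ll = _probit_loglik(y, eta)
    converged = False
    for _ in range(_MAX_ITER):
        # score: r_i = y*lambda(-eta) - (1-y)*lambda(eta)
        lam_pos = mills_ratio(-eta)   # phi/Phi(eta)
        lam_neg = mills_ratio(eta)    # phi/Phi(-eta)
        r = np.where(y == 1, lam_pos, -lam_neg)
        grad = Xs.T @ r
        if np.max(np.abs(grad)) < _GRAD_TOL:
            converged = True
            break
        # observed Hessian (negative definite everywhere: probit loglik is
        # concave), giving quadratic convergence near the optimum
        w = np.where(y == 1, lam_pos * (lam_pos + eta), lam_neg * (lam_neg - eta))
        XtWX = (Xs * w[:, None]).T @ Xs
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"information matrix singular: {exc}") from exc
        # step-halving on the log-likelihood
        t = 1.0
        for _ in range(40):
            beta_new = beta + t * step
            ll_new = _probit_loglik(y, Xs @ beta_new)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta, ll = beta_new, ll_new
        eta = Xs @ beta
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            raise EstimationError(
                "probable perfect separation: standardized coefficient "
                f"exceeded {_SEPARATION_BOUND}"
            )
    lam_pos = mills_ratio(-eta)
    lam_neg = mills_ratio(eta)
    w = lam_pos * lam_neg
    XtWX = (Xs * w[:, None]).T @ Xs
    vcov_s = np.linalg.inv(XtWX)
    coef = beta / scale
    vcov = vcov_s / np.outer(scale, scale)
    return ProbitFit(
        coefficients=coef,
        names=list(names),
        vcov=vcov,
        loglik=ll,
        converged=converged,
        n_used=n,
    )


# --------------------------------------------------------------------------
# Heckman-corrected price equation
# --------------------------------------------------------------------------


@dataclasses.dataclass
class PriceEquationFit:
    """OLS of the log premium on Z and the Mills ratio, purchasers only.

    ``lambda_coef`` estimates cov(u, xi)/sd(xi), the selection loading on
    the price-equation error (rho * sigma_u in the pure-selection case).
    """

    delta_hat: np.ndarray
    names: list[str]
    lambda_coef: float
    resid_sd: float
    n_used: int


def reduced_design(sample: AnalysisSample) -> tuple[np.ndarray, list[str]]:
    """Intercept + Z (controls, log income, instrument)."""
    Zd = np.column_stack([np.ones(sample.n), sample.Z])
    return Zd, ["intercept", *sample.z_names]


def heckit_price_equation(sample: AnalysisSample) -> tuple[ProbitFit, PriceEquationFit]:
    """Two-step selection-corrected premium equation.

    Step 1 fits the reduced-form participation probit on the full sample;
    step 2 regresses the observed log premium on Z plus the inverse Mills
    ratio at the fitted index, over purchasers only.
    """
    Zd, names = reduced_design(sample)
    k = Zd.shape[1]
    buyers = sample.vphi == 1
    n1 = int(buyers.sum())
    if n1 < k + 2:
        raise EstimationError(
            f"too few purchasers ({n1}) for a {k}-column price equation"
        )
    probit = fit_probit(sample.vphi, Zd, names=names)
    lam = mills_ratio(-probit.index(Zd))  # phi(index)/Phi(index) on purchasers
    D = np.column_stack([Zd[buyers], lam[buyers]])
    yb = sample.ln_premium[buyers]
    coef, _, rank, _ = np.linalg.lstsq(D, yb, rcond=None)
    if rank < D.shape[1]:
        raise DesignError("price-equation design is rank deficient")
    resid = yb - D @ coef
    dof = max(n1 - D.shape[1], 1)
    price = PriceEquationFit(
        delta_hat=coef[:-1],
        names=names,
        lambda_coef=float(coef[-1]),
        resid_sd=float(np.sqrt(resid @ resid / dof)),
        n_used=n1,
    )
    return probit, price


def predict_log_price(fit: PriceEquationFit, Z: np.ndarray) -> np.ndarray:
    """Unconditional premium prediction Z'delta_hat (no Mills term).

    ``Z`` must match the stage-2 design layout (intercept first), i.e. the
    matrix from :func:`reduced_design`; returns a prediction for every
    household, purchaser or not.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != fit.delta_hat.shape[0]:
        raise DesignError(
            f"Z has {Z.shape[1]} columns, price equation expects {fit.delta_hat.shape[0]}"
        )
    return Z @ fit.delta_hat


# --------------------------------------------------------------------------
# Structural (instrumented) participation probit
# --------------------------------------------------------------------------


@dataclasses.dataclass
class StructuralFit:
    """Fitted-value probit of participation; vcov_naive ignores that the
    premium prediction is itself estimated — use the bootstrap for inference."""

    beta_hat: np.ndarray
    names: list[str]
    vcov_naive: np.ndarray
    converged: bool
    loglik: float
    design: np.ndarray
    outcome: np.ndarray

    def coefficient(self, name: str) -> float:
        return float(self.beta_hat[self.names.index(name)])


def structural_design(sample: AnalysisSample, lnp_hat: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Intercept, predicted log premium, log income, controls X.

    Household size is deliberately excluded: the exclusion restriction is
    what identifies the price coefficient.
    """
    lnp_hat = np.asarray(lnp_hat, dtype=float).ravel()
    if lnp_hat.shape[0] != sample.n:
        raise DesignError(
            f"lnp_hat length {lnp_hat.shape[0]} does not match sample size {sample.n}"
        )
    D = np.column_stack([np.ones(sample.n), lnp_hat, sample.ln_income, sample.X])
    return D, ["intercept", "ln_premium_hat", "ln_income", *sample.x_names]


def fit_structural(
    sample: AnalysisSample,
    lnp_hat: np.ndarray,
    method: str = "probit",
) -> StructuralFit:
    """Structural participation equation with the instrumented premium.

    ``method="probit"`` (default, used for all reported results) plugs the
    fitted log premium into a probit. ``method="lpm2sls"`` is a
    linear-probability second stage kept for comparison runs only.
    """
    D, names = structural_design(sample, lnp_hat)
    y = np.asarray(sample.vphi, dtype=float)
    if method == "probit":
        fit = fit_probit(y, D, names=names)
        return StructuralFit(
            beta_hat=fit.coefficients,
            names=names,
            vcov_naive=fit.vcov,
            converged=fit.converged,
            loglik=fit.loglik,
            design=D,
            outcome=y,
        )
    if method == "lpm2sls":
        coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
        if rank < D.shape[1]:
            raise DesignError("structural design is rank deficient")
        resid = y - D @ coef
        s2 = resid @ resid / max(len(y) - D.shape[1], 1)
        vcov = s2 * np.linalg.inv(D.T @ D)
        return StructuralFit(
            beta_hat=coef,
            names=names,
            vcov_naive=vcov,
            converged=True,
            loglik=np.nan,
            design=D,
            outcome=y,
        )
    raise DomainError(f"unknown method {method!r}")
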