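"""Estimation for the joint Poisson mixed model.

The algorithm alternates three blocks until the total absolute parameter
change falls below a tolerance:

1. Newton scoring for the regression coefficients gamma = (alpha', beta')',
   solving the BLUP-based estimating equation
   psi(gamma) = sum_i X_i' (y_i - Vhat_i * mu_i) = 0.
2. Orthodox BLUP prediction of the random effects: the best linear (in y)
   unbiased predictors, which need only the first two moments and therefore
   no random-effect distribution.
3. Bias-corrected moment updates for sigma2, tau2_j and rho_j. BLUPs shrink
   toward the prior mean 1, so naive squared-BLUP moments are biased
   downward; each update adds the exact correction that restores the
   population identity (e.g. E(Uhat - 1)^2 + c = sigma2 at the truth).

Linear solves use a per-subject Cholesky of Var(Y_i) with a single jitter
retry; explicit inverses are never formed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.stats import norm

from .model_core import (
    ModelParams,
    PanelData,
    Predictions,
    SubjectMoments,
    build_correlation,
    stacked_design,
    subject_moments,
)

logger = logging.getLogger("poispair")

RHO_CLIP = 0.99


class NumericalError(RuntimeError):
    """A per-subject linear solve failed even after jitter."""


@dataclass
class FitResult:
    """Converged (or final) state of the iterative fit."""

    params: ModelParams
    se: np.ndarray
    pvalues: np.ndarray
    predictions: Predictions
    n_iter: int
    converged: bool
    trace: list[np.ndarray]
    tolerance: float
    gamma_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Per-subject workspace
# ---------------------------------------------------------------------------


class _SubjectWork:
    """Moments plus a reusable Cholesky factor of Var(Y_i) for one subject."""

    def __init__(self, params: ModelParams, sub) -> None:
        self.sub = sub
        self.sm: SubjectMoments = subject_moments(params, sub.Z, sub.X)
        V = self.sm.VarY
        try:
            self.factor = cho_factor(V, lower=True, check_finite=False)
        except LinAlgError:
            jitter = 1e-8 * float(np.mean(np.diag(V)))
            try:
                self.factor = cho_factor(
                    V + jitter * np.eye(V.shape[0]), lower=True, check_finite=False
                )
            except LinAlgError as exc:
                raise NumericalError(
                    f"Var(Y) for subject {sub.subject!r} is singular even "
                    "after jitter"
                ) from exc

    def solve(self, b: np.ndarray) -> np.ndarray:
        return cho_solve(self.factor, b, check_finite=False)

    def pieces(self) -> dict:
        """Quadratic-form pieces shared by the dispersion corrections.

        One multi-RHS solve yields, for each series j:
        G_j[t, t'] = Cov(V_jt, Y)' Var^-1(Y) Cov(Y, V_jt'),
        g_j[t] = mu' Var^-1(Y) Cov(Y, V_jt), and q_mu = mu' Var^-1(Y) mu.
        """
        if not hasattr(self, "_pieces"):
            mu = self.sm.mu
            T = self.sub.T
            sol = self.solve(np.column_stack([mu, self.sm.CovVY.T]))
            vinv_mu = sol[:, 0]
            out = {"q_mu": float(mu @ vinv_mu)}
            for j in (0, 1):
                C = self.sm.CovVY[j * T : (j + 1) * T, :]
                W = sol[:, 1 + j * T : 1 + (j + 1) * T]
                out[f"G{j}"] = C @ W
                out[f"g{j}"] = C @ vinv_mu
            self._pieces = out
        return self._pieces


def _workspaces(params: ModelParams, data: PanelData) -> list[_SubjectWork]:
    return [_SubjectWork(params, s) for s in data.subjects]


# ---------------------------------------------------------------------------
# BLUP prediction
# ---------------------------------------------------------------------------


def predict_random_effects(
    params: ModelParams, data: PanelData, _work: list[_SubjectWork] | None = None
) -> Predictions:
    """Orthodox BLUPs of the subject and serial random effects.

    Uhat_i = 1 + sigma2 * mu_i' Var^-1(Y_i) (y_i - mu_i)
    Vhat_i = 1 + Var(V_i) diag(mu_i) Var^-1(Y_i) (y_i - mu_i)

    Both are linear in y_i and collapse to 1 when all variance parameters
    vanish or the residual is zero.
    """
    work = _work if _work is not None else _workspaces(params, data)
    u_hat = np.empty(data.m)
    v_hat: list[np.ndarray] = []
    for i, w in enumerate(work):
        resid = w.sub.y - w.sm.mu
        s = w.solve(resid)
        u_hat[i] = 1.0 + w.sm.CovUY @ s
        v_hat.append(1.0 + w.sm.CovVY @ s)
    return Predictions(u_hat=u_hat, v_hat=v_hat)


# ---------------------------------------------------------------------------
# Regression parameters
# ---------------------------------------------------------------------------


def score_gamma(
    params: ModelParams, data: PanelData, predictions: Predictions
) -> np.ndarray:
    """BLUP-based estimating function psi(gamma) = sum_i X_i'(y_i - Vhat_i mu_i)."""
    psi = np.zeros(data.q + data.p)
    for i, sub in enumerate(data.subjects):
        Xi = stacked_design(sub.Z, sub.X)
        mu = np.exp(Xi @ params.gamma)
        psi += Xi.T @ (sub.y - predictions.v_hat[i] * mu)
    return psi


def sensitivity_matrix(
    params: ModelParams, data: PanelData, _work: list[_SubjectWork] | None = None
) -> np.ndarray:
    """S(gamma) = -sum_i X_i' diag(mu_i) Var^-1(Y_i) diag(mu_i) X_i.

    -S is the asymptotic precision of the regression estimator.
    """
    work = _work if _work is not None else _workspaces(params, data)
    S = np.zeros((data.q + data.p, data.q + data.p))
    for w in work:
        Xi = stacked_design(w.sub.Z, w.sub.X)
        A = w.sm.mu[:, None] * Xi
        S -= A.T @ w.solve(A)
    return S


def newton_step(
    params: ModelParams, data: PanelData, _work: list[_SubjectWork] | None = None
) -> np.ndarray:
    """One Newton-scoring update: gamma* = gamma - S^-1(gamma) psi(gamma)."""
    work = _work if _work is not None else _workspaces(params, data)
    pred = predict_random_effects(params, data, _work=work)
    psi = score_gamma(params, data, pred)
    S = sensitivity_matrix(params, data, _work=work)
    try:
        step = np.linalg.solve(S, psi)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "sensitivity matrix is singular; the stacked design may be "
            "rank-deficient — consider rescaling or dropping covariates"
        ) from exc
    return params.gamma - step


# ---------------------------------------------------------------------------
# Dispersion / correlation updates
# ---------------------------------------------------------------------------


def update_sigma2(
    params: ModelParams,
    data: PanelData,
    predictions: Predictions,
    _work: list[_SubjectWork] | None = None,
) -> float:
    """Bias-corrected moment update of the subject-effect variance.

    sigma2_new = (1/m) sum_i [(Uhat_i - 1)^2 + c_i], where the correction
    c_i = sigma2 - sigma2^2 * mu_i' Var^-1(Y_i) mu_i equals
    E(U_i - 1)^2 - E(Uhat_i - 1)^2 at the parameters used for prediction.
    Negative raw values are floored at zero.
    """
    work = _work if _work is not None else _workspaces(params, data)
    s2 = params.sigma2
    total = 0.0
    for i, w in enumerate(work):
        c_i = s2 - s2 * s2 * w.pieces()["q_mu"]
        total += (predictions.u_hat[i] - 1.0) ** 2 + c_i
    raw = total / data.m
    if raw < 0:
        logger.info("sigma2 update %.3g below zero; floored at 0", raw)
        return 0.0
    return raw


def update_tau2(
    params: ModelParams,
    data: PanelData,
    predictions: Predictions,
    j: int,
    _work: list[_SubjectWork] | None = None,
) -> float:
    """Bias-corrected moment update of the series-j serial dispersion.

    tau2_new = (1 / sum_i T_i) sum_{i,t} [(Vhat_ijt - Uhat_i)^2 + d_ijt] with

        d_ijt = tau2_j - sigma2^2 mu'V^-1 mu - Cov(V_jt,Y) V^-1 Cov(Y,V_jt)
                + 2 sigma2 mu' V^-1 Cov(Y,V_jt)

    which equals E(V_jt - U)^2 - E(Vhat_jt - Uhat)^2 at the parameters used
    for prediction. Floored at zero.
    """
    work = _work if _work is not None else _workspaces(params, data)
    s2, t2 = params.sigma2, float(params.tau2[j])
    total = 0.0
    n = 0
    for i, w in enumerate(work):
        T = w.sub.T
        pc = w.pieces()
        G, g, q_mu = pc[f"G{j}"], pc[f"g{j}"], pc["q_mu"]
        d = t2 - s2 * s2 * q_mu - np.diag(G) + 2.0 * s2 * g
        dev = predictions.v_hat[i][j * T : (j + 1) * T] - predictions.u_hat[i]
        total += float(np.sum(dev**2 + d))
        n += T
    raw = total / n
    if raw < 0:
        logger.info("tau2[%d] update %.3g below zero; floored at 0", j, raw)
        return 0.0
    return raw


def update_rho(
    params: ModelParams,
    data: PanelData,
    predictions: Predictions,
    j: int,
    _work: list[_SubjectWork] | None = None,
) -> float | np.ndarray:
    """Bias-corrected serial-correlation update for series j.

    Under AR(1) only the lag-1 correlation is needed: an adjusted Pearson
    ratio over consecutive pairs, with cross-correction

        b_j,(t,t') = rho tau2 - Cov(V_jt,Y) V^-1 Cov(Y,V_jt')
                     - sigma2^2 mu'V^-1 mu
                     + sigma2 mu'V^-1 Cov(Y,V_jt) + sigma2 mu'V^-1 Cov(Y,V_jt')

    equal to E(V_jt - U)(V_jt' - U) - E(Vhat_jt - Uhat)(Vhat_jt' - Uhat) at
    the prediction parameters. The result is clipped to [-0.99, 0.99].

    Under the unstructured structure the full matrix of adjusted Pearson
    estimates is returned (symmetric, unit diagonal); this needs a balanced
    panel.
    """
    work = _work if _work is not None else _workspaces(params, data)
    s2, t2 = params.sigma2, float(params.tau2[j])
    if params.corr_structure == "unstructured":
        return _update_rho_unstructured(params, data, predictions, j, work)

    if all(w.sub.T < 2 for w in work):
        raise ValueError("serial correlation is unidentifiable when every T_i = 1")
    rho = float(params.rho[j])
    num = 0.0
    den_left = 0.0
    den_right = 0.0
    for i, w in enumerate(work):
        T = w.sub.T
        if T < 2:
            continue
        pc = w.pieces()
        G, g, q_mu = pc[f"G{j}"], pc[f"g{j}"], pc["q_mu"]
        dev = predictions.v_hat[i][j * T : (j + 1) * T] - predictions.u_hat[i]
        d = t2 - s2 * s2 * q_mu - np.diag(G) + 2.0 * s2 * g
        lag = np.arange(T - 1)
        b = (
            rho * t2
            - G[lag, lag + 1]
            - s2 * s2 * q_mu
            + s2 * g[lag]
            + s2 * g[lag + 1]
        )
        num += float(np.sum(dev[:-1] * dev[1:] + b))
        den_left += float(np.sum(dev[:-1] ** 2 + d[:-1]))
        den_right += float(np.sum(dev[1:] ** 2 + d[1:]))
    if den_left <= 0 or den_right <= 0:
        logger.info("rho[%d] denominator non-positive; returning 0", j)
        return 0.0
    return float(np.clip(num / np.sqrt(den_left * den_right), -RHO_CLIP, RHO_CLIP))


def _update_rho_unstructured(
    params: ModelParams,
    data: PanelData,
    predictions: Predictions,
    j: int,
    work: list[_SubjectWork],
) -> np.ndarray:
    if not data.is_balanced():
        raise ValueError("unstructured correlation requires a balanced panel")
    T = data.subjects[0].T
    s2, t2 = params.sigma2, float(params.tau2[j])
    R_prev = params.correlation_matrix(j, T)
    num = np.zeros((T, T))
    den = np.zeros(T)
    for i, w in enumerate(work):
        pc = w.pieces()
        G, g, q_mu = pc[f"G{j}"], pc[f"g{j}"], pc["q_mu"]
        dev = predictions.v_hat[i][j * T : (j + 1) * T] - predictions.u_hat[i]
        b = (
            R_prev * t2
            - G
            - s2 * s2 * q_mu
            + s2 * (g[:, None] + g[None, :])
        )
        num += np.outer(dev, dev) + b
        d = t2 - s2 * s2 * q_mu - np.diag(G) + 2.0 * s2 * g
        den += dev**2 + d
    den = np.maximum(den, 1e-12)
    R = num / np.sqrt(np.outer(den, den))
    R = (R + R.T) / 2.0
    R = np.clip(R, -RHO_CLIP, RHO_CLIP)
    np.fill_diagonal(R, 1.0)
    return R


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def _poisson_irls(data: PanelData, max_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Plain Poisson regression on the stacked design via Fisher scoring.

    This is exactly the Newton-scoring step with all variance components at
    zero (Var(Y) = diag(mu), Vhat = 1), iterated to convergence.
    """
    params = ModelParams(alpha=np.zeros(data.q), beta=np.zeros(data.p))
    gamma = params.gamma
    for _ in range(max_iter):
        gamma_new = newton_step(params.with_gamma(gamma), data)
        if not np.all(np.isfinite(gamma_new)) or np.max(np.abs(gamma_new)) > 50:
            raise NumericalError("Poisson initialization diverged")
        if np.sum(np.abs(gamma_new - gamma)) < tol:
            return gamma_new
        gamma = gamma_new
    return gamma


def initialize(data: PanelData) -> ModelParams:
    """Starting values for the iterative fit.

    gamma0 comes from a plain Poisson regression on the stacked design
    (random effects ignored). The dispersion starts treat simple count
    averages as rough random-effect estimates:

        sigma2_0 = (1/m) sum_i [mean of subject i's counts - 1]^2
        tau2_j0  = (1/T) sum_t [mean over subjects of Y_ijt - 1]^2

    and rho_j0 is the average per-subject lag-1 Pearson autocorrelation of
    the series-j counts (zero-variance subjects skipped; fallback 0).
    """
    if sum(s.y1.sum() for s in data.subjects) == 0 or (
        sum(s.y2.sum() for s in data.subjects) == 0
    ):
        logger.warning(
            "one count series is identically zero; regression initial values "
            "fall back to a small negative intercept"
        )
        gamma0 = np.zeros(data.q + data.p)
        gamma0[0] = -1.0
    else:
        try:
            gamma0 = _poisson_irls(data)
        except NumericalError:
            logger.warning(
                "Poisson initialization diverged; falling back to a small "
                "negative intercept"
            )
            gamma0 = np.zeros(data.q + data.p)
            gamma0[0] = -1.0

    sigma2_0 = float(
        np.mean([(np.mean(s.y) - 1.0) ** 2 for s in data.subjects])
    )

    tau2_0 = np.zeros(2)
    times = sorted({int(t) for s in data.subjects for t in s.times})
    for j in (0, 1):
        per_time = []
        for t in times:
            vals = [
                (s.y1 if j == 0 else s.y2)[list(s.times).index(t)]
                for s in data.subjects
                if t in s.times
            ]
            per_time.append((np.mean(vals) - 1.0) ** 2)
        tau2_0[j] = float(np.mean(per_time))

    rho_0 = np.zeros(2)
    for j in (0, 1):
        cors = []
        for s in data.subjects:
            y = s.y1 if j == 0 else s.y2
            if s.T < 3 or np.std(y[:-1]) == 0 or np.std(y[1:]) == 0:
                continue
            cors.append(float(np.corrcoef(y[:-1], y[1:])[0, 1]))
        rho_0[j] = float(np.clip(np.mean(cors), -RHO_CLIP, RHO_CLIP)) if cors else 0.0

    q = data.q
    return ModelParams(
        alpha=gamma0[:q], beta=gamma0[q:], sigma2=sigma2_0, tau2=tau2_0, rho=rho_0
    )


# ---------------------------------------------------------------------------
# Full fit
# ---------------------------------------------------------------------------


def _param_vector(params: ModelParams) -> np.ndarray:
    if params.corr_structure == "unstructured":
        T = params.R1.shape[0]
        iu = np.triu_indices(T, k=1)
        extra = np.concatenate([params.R1[iu], params.R2[iu]])
    else:
        extra = params.rho
    return np.concatenate([params.gamma, [params.sigma2], params.tau2, extra])


def fit(
    data: PanelData,
    corr_structure: str = "ar1",
    tolerance: float = 1e-6,
    max_iter: int = 500,
    fix_variance_components: float | None = None,
    init: ModelParams | None = None,
    gamma_names: list[str] | None = None,
) -> FitResult:
    """Iterative estimation of the full model.

    Each iteration performs, in order: (1) one Newton-scoring update of
    gamma, (2) BLUP prediction of the random effects, (3) the sigma2 update,
    (4) the tau2_j updates, (5) the rho_j (or unstructured R_j) updates,
    refreshing predictions after each variance-parameter change. Iteration
    stops when the sum of absolute parameter changes drops below
    ``tolerance``.

    With ``fix_variance_components`` set (typically 0.0), sigma2 and tau2
    are pinned at that value and rho at 0, and only gamma is updated — with
    the value 0 this reduces exactly to a Poisson GLM on the stacked design.

    Non-convergence at ``max_iter`` returns a result with
    ``converged=False`` and a warning, not an exception.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    params = init if init is not None else initialize(data)
    fixed = fix_variance_components is not None
    if fixed:
        v = float(fix_variance_components)
        params = params.replace(sigma2=v, tau2=np.array([v, v]), rho=np.zeros(2))
    if corr_structure == "unstructured":
        if not data.is_balanced():
            raise ValueError("unstructured correlation requires a balanced panel")
        T = data.subjects[0].T
        params = params.replace(
            corr_structure="unstructured",
            R1=build_correlation(float(params.rho[0]), T),
            R2=build_correlation(float(params.rho[1]), T),
        )
    elif corr_structure != "ar1":
        raise ValueError(f"unknown corr_structure {corr_structure!r}")

    trace: list[np.ndarray] = []
    converged = False
    n_iter = 0
    serial_identifiable = any(s.T >= 2 for s in data.subjects)
    for n_iter in range(1, max_iter + 1):
        prev = _param_vector(params)

        work = _workspaces(params, data)
        gamma = newton_step(params, data, _work=work)
        params = params.with_gamma(gamma)

        if not fixed:
            # one BLUP pass at the current values feeds all variance updates,
            # whose bias corrections are identities at exactly those values
            work = _workspaces(params, data)
            pred = predict_random_effects(params, data, _work=work)
            sigma2 = update_sigma2(params, data, pred, _work=work)
            tau2 = np.array(
                [update_tau2(params, data, pred, j, _work=work) for j in (0, 1)]
            )
            updates = {"sigma2": sigma2, "tau2": tau2}
            if serial_identifiable and np.all(params.tau2 > 0):
                if corr_structure == "unstructured":
                    updates["R1"] = _update_rho_unstructured(params, data, pred, 0, work)
                    updates["R2"] = _update_rho_unstructured(params, data, pred, 1, work)
                else:
                    updates["rho"] = np.array(
                        [
                            update_rho(params, data, pred, j, _work=work)
                            for j in (0, 1)
                        ]
                    )
            params = params.replace(**updates)

        cur = _param_vector(params)
        trace.append(cur.copy())
        delta = float(np.sum(np.abs(cur - prev)))
        logger.info(
            "iter %d: sum|delta| = %.3e, |gamma| = %.4f",
            n_iter,
            delta,
            float(np.linalg.norm(params.gamma)),
        )
        if delta < tolerance:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"fit did not converge in {max_iter} iterations", RuntimeWarning
        )

    work = _workspaces(params, data)
    S = sensitivity_matrix(params, data, _work=work)
    cov = np.linalg.inv(-S)
    se = np.sqrt(np.diag(cov))
    z = params.gamma / se
    pvalues = 2.0 * (1.0 - norm.cdf(np.abs(z)))
    predictions = predict_random_effects(params, data, _work=work)

    if gamma_names is None:
        gamma_names = [f"alpha_{k}" for k in range(data.q)] + [
            f"beta_{k}" for k in range(data.p)
        ]
    return FitResult(
        params=params,
        se=se,
        pvalues=pvalues,
        predictions=predictions,
        n_iter=n_iter,
        converged=converged,
        trace=trace,
        tolerance=tolerance,
        gamma_names=list(gamma_names),
    )


def wald_table(result: FitResult) -> pd.DataFrame:
    """Estimates, standard errors and two-sided normal p-values per gamma
    coordinate, with the dispersion/correlation parameters appended (no
    standard errors are available for those under moment estimation)."""
    if not result.converged:
        warnings.warn("Wald table from a non-converged fit", RuntimeWarning)
    rows = []
    for name, est, se, p in zip(
        result.gamma_names, result.params.gamma, result.se, result.pvalues
    ):
        rows.append((name, est, se, p))
    rows.append(("sigma2", result.params.sigma2, np.nan, np.nan))
    rows.append(("tau2_1", result.params.tau2[0], np.nan, np.nan))
    rows.append(("tau2_2", result.params.tau2[1], np.nan, np.nan))
    if result.params.corr_structure == "ar1":
        rows.append(("rho_1", result.params.rho[0], np.nan, np.nan))
        rows.append(("rho_2", result.params.rho[1], np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["parameter", "estimate", "se", "p_value"])
    table.attrs["converged"] = result.converged
    return table
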