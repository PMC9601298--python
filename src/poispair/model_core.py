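"""Domain types and moment structure of the joint Poisson mixed model.

The model describes two longitudinal count series per subject (``y1`` =
successes, ``y2`` = failures) whose total is itself random and may be zero.
Conditionally on a positive subject effect ``U_i`` (mean 1, variance
``sigma2``) and two serially correlated positive effect series ``V_ijt``
(conditional mean ``U_i``, conditional variance ``tau2_j * U_i``, AR(1)
autocorrelation ``rho_j``), the counts are independent Poisson with

    E(Y_i1t | W) = V_i1t * exp(z_it' alpha + x_it' beta)
    E(Y_i2t | W) = V_i2t * exp(z_it' alpha)

so successes and failures share ``U_i`` and are positively cross-associated.
Everything downstream (BLUPs, estimating equations, dispersion updates) only
needs the first two moments assembled here; no random-effect distribution is
ever assumed.

Vector ordering convention: per subject, series-major — all series-1 entries
for t = 1..T, then all series-2 entries. Every 2T-length vector or 2T x 2T
matrix in the package follows this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np


class InvalidParameterError(ValueError):
    """A model parameter lies outside its admissible range."""


class PanelFormatError(ValueError):
    """Panel data violate a structural requirement."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """One subject's observed block: counts and covariates over time.

    ``times`` must be consecutive integers (gaps would silently change the
    lag semantics of the AR(1) correlation, so they are rejected).
    """

    subject: Any
    times: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    Z: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.y1 = np.asarray(self.y1)
        self.y2 = np.asarray(self.y2)
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        T = len(self.times)
        if T < 1:
            raise PanelFormatError(f"subject {self.subject!r}: empty block")
        if np.any(np.diff(self.times) != 1):
            raise PanelFormatError(
                f"subject {self.subject!r}: time indices must be consecutive "
                f"integers, got {self.times.tolist()}"
            )
        for name, y in (("y1", self.y1), ("y2", self.y2)):
            if y.shape != (T,):
                raise PanelFormatError(
                    f"subject {self.subject!r}: {name} has shape {y.shape}, "
                    f"expected ({T},)"
                )
            if np.any(y < 0) or np.any(y != np.floor(y)):
                raise PanelFormatError(
                    f"subject {self.subject!r}: {name} must be non-negative "
                    "integers"
                )
        self.y1 = self.y1.astype(float)
        self.y2 = self.y2.astype(float)
        if self.Z.shape[0] != T or self.X.shape[0] != T:
            raise PanelFormatError(
                f"subject {self.subject!r}: covariate rows must match T={T}"
            )
        if not (np.all(np.isfinite(self.Z)) and np.all(np.isfinite(self.X))):
            raise PanelFormatError(
                f"subject {self.subject!r}: non-finite covariate values"
            )

    @property
    def T(self) -> int:
        return len(self.times)

    @property
    def y(self) -> np.ndarray:
        """Stacked response (series 1 then series 2), length 2T."""
        return np.concatenate([self.y1, self.y2])

    @property
    def totals(self) -> np.ndarray:
        """N_it = Y_i1t + Y_i2t; may be zero."""
        return self.y1 + self.y2


@dataclass
class PanelData:
    """Long-format panel: a list of per-subject blocks.

    Panels may be unbalanced (T_i varies by subject); all moment formulas
    are per-subject so nothing requires a common T.
    """

    subjects: list[SubjectData]
    z_names: Sequence[str] | None = None
    x_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if len(self.subjects) < 1:
            raise PanelFormatError("panel has no subjects")
        q = self.subjects[0].Z.shape[1]
        p = self.subjects[0].X.shape[1]
        for s in self.subjects:
            if s.Z.shape[1] != q or s.X.shape[1] != p:
                raise PanelFormatError(
                    f"subject {s.subject!r}: covariate dimension mismatch"
                )

    @property
    def m(self) -> int:
        return len(self.subjects)

    @property
    def q(self) -> int:
        return self.subjects[0].Z.shape[1]

    @property
    def p(self) -> int:
        return self.subjects[0].X.shape[1]

    @property
    def n_obs(self) -> int:
        return sum(s.T for s in self.subjects)

    def is_balanced(self) -> bool:
        T0 = self.subjects[0].T
        return all(s.T == T0 for s in self.subjects)


@dataclass
class ModelParams:
    """Regression coefficients and random-effect parameters.

    gamma = (alpha', beta')' stacks the two linear predictors; ``sigma2`` is
    the subject-effect variance, ``tau2`` / ``rho`` the per-series serial
    dispersion and AR(1) correlation. Under ``corr_structure="unstructured"``
    the full correlation matrices ``R1``, ``R2`` are carried instead of rho.
    """

    alpha: np.ndarray
    beta: np.ndarray
    sigma2: float = 0.0
    tau2: np.ndarray = field(default_factory=lambda: np.zeros(2))
    rho: np.ndarray = field(default_factory=lambda: np.zeros(2))
    corr_structure: str = "ar1"
    R1: np.ndarray | None = None
    R2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.tau2 = np.asarray(self.tau2, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.sigma2 = float(self.sigma2)
        self.validate()

    def validate(self) -> None:
        if self.sigma2 < 0:
            raise InvalidParameterError(f"sigma2 must be >= 0, got {self.sigma2}")
        if self.tau2.shape != (2,) or np.any(self.tau2 < 0):
            raise InvalidParameterError(f"tau2 must be two non-negatives, got {self.tau2}")
        if self.corr_structure == "ar1":
            if self.rho.shape != (2,) or np.any(np.abs(self.rho) >= 1):
                raise InvalidParameterError(f"rho must be two values in (-1, 1), got {self.rho}")
        elif self.corr_structure == "unstructured":
            for name, R in (("R1", self.R1), ("R2", self.R2)):
                if R is None:
                    raise InvalidParameterError(f"{name} required for unstructured correlation")
                R = np.asarray(R, dtype=float)
                if R.ndim != 2 or R.shape[0] != R.shape[1]:
                    raise InvalidParameterError(f"{name} must be square")
                if not np.allclose(R, R.T, atol=1e-10):
                    raise InvalidParameterError(f"{name} must be symmetric")
                if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                    raise InvalidParameterError(f"{name} must have unit diagonal")
        else:
            raise InvalidParameterError(
                f"corr_structure must be 'ar1' or 'unstructured', got {self.corr_structure!r}"
            )

    @property
    def gamma(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.beta])

    def with_gamma(self, gamma: np.ndarray) -> "ModelParams":
        q = len(self.alpha)
        return self.replace(alpha=gamma[:q], beta=gamma[q:])

    def replace(self, **kw) -> "ModelParams":
        d = dict(
            alpha=self.alpha,
            beta=self.beta,
            sigma2=self.sigma2,
            tau2=self.tau2,
            rho=self.rho,
            corr_structure=self.corr_structure,
            R1=self.R1,
            R2=self.R2,
        )
        d.update(kw)
        return ModelParams(**d)

    def correlation_matrix(self, j: int, T: int) -> np.ndarray:
        """Series-j (0-based) correlation matrix for a block of T times."""
        if self.corr_structure == "ar1":
            return build_correlation(float(self.rho[j]), T)
        R = self.R1 if j == 0 else self.R2
        R = np.asarray(R, dtype=float)
        if R.shape[0] < T:
            raise InvalidParameterError(
                f"unstructured R{j + 1} is {R.shape[0]}x{R.shape[0]}, need T={T}"
            )
        return R[:T, :T]


@dataclass
class SubjectMoments:
    """Per-subject mean and covariance blocks of the joint model.

    mu     : E(Y_i), length 2T, series-major
    VarV   : Var(V_i) = sigma2 * J + blockdiag(tau2_1 R1, tau2_2 R2)
    VarY   : diag(mu) + diag(mu) VarV diag(mu)
    CovUY  : Cov(U_i, Y_i) = sigma2 * mu'   (length-2T vector)
    CovVY  : Cov(V_i, Y_i) = VarV diag(mu)
    """

    mu: np.ndarray
    VarV: np.ndarray
    VarY: np.ndarray
    CovUY: np.ndarray
    CovVY: np.ndarray


@dataclass
class Predictions:
    """Orthodox BLUPs per subject: u_hat[i] scalar, v_hat[i] length 2T_i."""

    u_hat: np.ndarray
    v_hat: list[np.ndarray]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_correlation(rho: float, T: int) -> np.ndarray:
    """AR(1) correlation matrix: entry (t, t') = rho ** |t - t'|."""
    if abs(rho) >= 1:
        raise InvalidParameterError(f"|rho| must be < 1, got {rho}")
    if T < 1:
        raise InvalidParameterError(f"T must be >= 1, got {T}")
    idx = np.arange(T)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def marginal_mean(params: ModelParams, Z: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Marginal mean vector, length 2T: exp(z'a + x'b) then exp(z'a).

    The random effects have mean one, so the regression coefficients carry
    the same interpretation marginally as conditionally.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if Z.shape[0] != X.shape[0]:
        raise ValueError(f"Z has {Z.shape[0]} rows but X has {X.shape[0]}")
    if Z.shape[1] != len(params.alpha):
        raise ValueError(f"Z has {Z.shape[1]} columns, alpha has length {len(params.alpha)}")
    if X.shape[1] != len(params.beta):
        raise ValueError(f"X has {X.shape[1]} columns, beta has length {len(params.beta)}")
    eta_z = Z @ params.alpha
    eta_x = X @ params.beta
    return np.concatenate([np.exp(eta_z + eta_x), np.exp(eta_z)])


def subject_moments(params: ModelParams, Z: np.ndarray, X: np.ndarray) -> SubjectMoments:
    """Assemble all first- and second-moment blocks for one subject."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite covariate values")
    mu = marginal_mean(params, Z, X)
    T = Z.shape[0]
    VarV = np.full((2 * T, 2 * T), params.sigma2)
    VarV[:T, :T] += params.tau2[0] * params.correlation_matrix(0, T)
    VarV[T:, T:] += params.tau2[1] * params.correlation_matrix(1, T)
    Dmu = mu[:, None]  # broadcasting stand-in for diag(mu) products
    VarY = np.diag(mu) + Dmu * VarV * mu[None, :]
    CovUY = params.sigma2 * mu
    CovVY = VarV * mu[None, :]
    return SubjectMoments(mu=mu, VarV=VarV, VarY=VarY, CovUY=CovUY, CovVY=CovVY)


def stacked_design(Z: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Design of the stacked single-Poisson representation, 2T x (q + p).

    Row for (series 1, t) is (z_it', x_it'); row for (series 2, t) is
    (z_it', 0'). Then exp(design @ gamma) reproduces the marginal mean with
    the same series-major ordering.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if Z.shape[0] != X.shape[0]:
        raise ValueError(f"Z has {Z.shape[0]} rows but X has {X.shape[0]}")
    top = np.hstack([Z, X])
    bottom = np.hstack([Z, np.zeros_like(X)])
    return np.vstack([top, bottom])


def binomial_probability(
    v1: float | np.ndarray,
    v2: float | np.ndarray,
    x: np.ndarray,
    beta: np.ndarray,
) -> float | np.ndarray:
    """Success probability of the induced binomial model.

    Conditionally on the total N_it and the random effects, the success
    count is binomial(N_it, p) with

        logit(p) = log(v1 / v2) + x' beta

    so beta is a log-odds effect; the shared predictor alpha cancels and
    never enters.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if np.any(v1 <= 0) or np.any(v2 <= 0):
        raise ValueError("serial effects v1, v2 must be strictly positive")
    xb = np.asarray(x, dtype=float) @ np.asarray(beta, dtype=float)
    num = v1 * np.exp(xb)
    out = num / (num + v2)
    return float(out) if out.ndim == 0 else out
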