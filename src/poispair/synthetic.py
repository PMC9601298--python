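"""Moment-exact simulation of longitudinal paired-count panels.

The estimation theory only assumes first and second moments of the random
effects, so the simulator's job is to realize those moments exactly:

* subject effects U_i: positive, i.i.d., mean 1, variance sigma2 — drawn
  from a gamma (default) or a moment-matched lognormal, so robustness to the
  random-effect family can be probed with identical moment parameters;
* serial effects V_ijt | U_i: a stationary gamma AR(1) built by
  beta-thinning, V_t = B_t V_{t-1} + G_t with B_t ~ Beta(k rho, k (1-rho))
  and G_t ~ Gamma(k (1-rho), theta), which preserves the Gamma(k, theta)
  marginal (shape k = u / tau2, scale theta = tau2, i.e. conditional mean u
  and variance tau2 * u) and has exact lag-h autocorrelation rho**h;
* counts: conditionally independent Poisson with mean V_ijt * mu_ijt.

Each series is then marginally a gamma-mixed Poisson, i.e. negative-
binomial-like, so panels are overdispersed and can produce zero totals
N_it = Y_i1t + Y_i2t with positive probability. Negative rho is not
representable by thinning and is rejected; the estimator itself has no such
restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelParams, PanelData, SubjectData

_FAMILIES = ("gamma", "lognormal")


@dataclass
class SimConfig:
    """Complete description of one simulated study.

    Covariates default to i.i.d. standard normals scaled by 0.1 (drawn once
    per seed); pass fixed ``Z``/``X`` matrices (T x q, T x p), shared by all
    subjects, to mimic a designed study.
    """

    m: int
    T: int
    params: ModelParams
    seed: int = 0
    subject_effect_family: str = "gamma"
    Z: np.ndarray | None = None
    X: np.ndarray | None = None
    covariate_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.m < 1 or self.T < 1:
            raise ValueError("m and T must be >= 1")
        if self.subject_effect_family not in _FAMILIES:
            raise ValueError(
                f"subject_effect_family must be one of {_FAMILIES}, "
                f"got {self.subject_effect_family!r}"
            )
        if self.params.corr_structure == "ar1" and np.any(self.params.rho < 0):
            raise ValueError(
                "the thinning construction cannot represent negative rho"
            )


def draw_subject_effects(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """m i.i.d. positive subject effects with mean 1 and variance sigma2."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    s2 = config.params.sigma2
    if s2 == 0:
        return np.ones(config.m)
    if config.subject_effect_family == "gamma":
        return rng.gamma(shape=1.0 / s2, scale=s2, size=config.m)
    # lognormal matched to mean 1, variance s2
    sig2 = np.log1p(s2)
    return rng.lognormal(mean=-0.5 * sig2, sigma=np.sqrt(sig2), size=config.m)


def _gamma_ar1(
    u: np.ndarray, tau2: float, rho: float, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized stationary gamma AR(1) by beta-thinning; one row per subject.

    Marginals are Gamma(shape=u/tau2, scale=tau2); Corr(V_t, V_t') =
    rho**|t-t'| exactly.
    """
    m = len(u)
    if tau2 == 0:
        return np.tile(u[:, None], (1, T))
    k = u / tau2
    V = np.empty((m, T))
    V[:, 0] = rng.gamma(shape=k, scale=tau2)
    if rho == 0:
        for t in range(1, T):
            V[:, t] = rng.gamma(shape=k, scale=tau2)
        return V
    for t in range(1, T):
        B = rng.beta(k * rho, k * (1.0 - rho))
        G = rng.gamma(shape=k * (1.0 - rho), scale=tau2)
        V[:, t] = B * V[:, t - 1] + G
    return V


def draw_serial_effects(
    u_i: float,
    tau2_j: float,
    rho_j: float,
    T: int,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """One subject's serial-effect series, conditional on its subject effect.

    Stationary with conditional mean ``u_i``, conditional variance
    ``tau2_j * u_i`` and autocorrelation ``rho_j ** lag``.
    """
    if u_i <= 0:
        raise ValueError("u_i must be positive")
    if tau2_j < 0:
        raise ValueError("tau2_j must be >= 0")
    if not 0 <= rho_j < 1:
        raise ValueError("the thinning construction needs rho in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    return _gamma_ar1(np.array([float(u_i)]), tau2_j, rho_j, T, rng)[0]


def simulate_panel(
    config: SimConfig, return_effects: bool = False
) -> PanelData | tuple[PanelData, dict]:
    """Draw a full panel under the model; optionally return the latents.

    With ``return_effects=True`` the second element is a dict holding the
    true ``u`` (length m) and ``v`` (m x 2T, series-major) used to generate
    the counts, for use as oracles in moment checks.
    """
    rng = np.random.default_rng(config.seed)
    p = config.params
    m, T = config.m, config.T

    def expand(arr, k):
        if arr is None:
            return config.covariate_scale * rng.standard_normal((m, T, k))
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:  # one design shared by all subjects
            arr = np.tile(arr[None, :, :], (m, 1, 1))
        if arr.shape != (m, T, k):
            raise ValueError(f"covariate array must have shape ({m}, {T}, {k})")
        return arr

    Z_all = expand(config.Z, len(p.alpha))
    X_all = expand(config.X, len(p.beta))

    u = draw_subject_effects(config, rng)
    rho = (p.rho if p.corr_structure == "ar1" else np.zeros(2))
    if p.corr_structure != "ar1":
        raise ValueError("the simulator supports the AR(1) structure only")
    v1 = _gamma_ar1(u, float(p.tau2[0]), float(rho[0]), T, rng)
    v2 = _gamma_ar1(u, float(p.tau2[1]), float(rho[1]), T, rng)

    eta_z = np.einsum("mtq,q->mt", Z_all, p.alpha)
    eta_x = np.einsum("mtp,p->mt", X_all, p.beta)
    mu1 = np.exp(eta_z + eta_x)
    mu2 = np.exp(eta_z)
    lam1 = v1 * mu1
    lam2 = v2 * mu2
    if np.any(lam1 > 1e12) or np.any(lam2 > 1e12):
        raise ValueError(
            "conditional Poisson mean exceeds 1e12; use smaller coefficients "
            "or covariates"
        )
    y1 = rng.poisson(lam1)
    y2 = rng.poisson(lam2)

    subjects = [
        SubjectData(
            subject=i + 1,
            times=np.arange(1, T + 1),
            y1=y1[i],
            y2=y2[i],
            Z=Z_all[i],
            X=X_all[i],
        )
        for i in range(m)
    ]
    q, pp = len(p.alpha), len(p.beta)
    panel = PanelData(
        subjects=subjects,
        z_names=[f"z{k}" for k in range(q)],
        x_names=[f"x{k}" for k in range(pp)],
    )
    if return_effects:
        return panel, {"u": u, "v": np.hstack([v1, v2]), "mu": np.hstack([mu1, mu2])}
    return panel
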