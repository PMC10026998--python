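"""Moderated confirmatory bifactor analysis (MCFA).

The measurement model is a four-indicator bifactor: every indicator
loads a general factor g and one of two specific factors (f1 for the
first pair, f2 for the second), all latents orthogonal with variance
fixed to 1.  An observed moderator m (standardized PC1 score) enters
the model per case:

    y_i ~ N( nu, Sigma(m_i) ),
    Sigma(m) = Lambda(m) Lambda(m)' + Theta(m),

where the specific-factor loading of a moderated indicator is
``lambda_f0 + lambda_f1 * m`` and its residual variance is
``theta0 + theta1 * m`` (floored; a log-linear residual link is
available for sensitivity analysis).  The g-loadings are never
moderated.  Estimation is full-information maximum likelihood with
analytic gradients, multi-start quasi-Newton optimization, sandwich
(robust) standard errors, and BIC-based comparison against the
unmoderated baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .cohorts import Cohort, DEFAULT_PAIR_MAP
from .moderator import ModeratorScores

__all__ = [
    "ModeratedBifactorModel",
    "ModerationConfig",
    "McfaSettings",
    "FitResult",
    "FitIndices",
    "ModerationReport",
    "implied_covariance",
    "simulate_from_model",
    "loglikelihood",
    "fit_mcfa",
    "delta_bic",
    "fit_indices",
    "rmsea",
    "rmsea_ci90",
    "cfi",
    "moderation_report",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_N_MOMENTS = 14  # 4 means + 10 distinct covariance elements

VARIANTS = ("none", "loading", "residual", "both")


@dataclass(frozen=True)
class ModerationConfig:
    """Which indicator is moderated and how.

    ``target_indicator`` is 1-based (1..4); ``variant`` is one of
    ``none`` (baseline), ``loading`` (specific-factor loading slope
    free), ``residual`` (residual-variance slope free), or ``both``.
    """

    target_indicator: Optional[int] = None
    variant: str = "none"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.variant == "none":
            if self.target_indicator is not None:
                raise ValueError("variant 'none' takes no target indicator")
        else:
            if self.target_indicator not in (1, 2, 3, 4):
                raise ValueError("target_indicator must be in 1..4")

    @property
    def moderates_loading(self) -> bool:
        return self.variant in ("loading", "both")

    @property
    def moderates_residual(self) -> bool:
        return self.variant in ("residual", "both")


@dataclass(frozen=True)
class McfaSettings:
    """Optimizer and identification settings.

    ``lambda_f_equality`` controls the identification constraint on the
    specific-factor base loadings: "pair" (default; the two loadings of
    each specific factor constrained equal), "all" (one common value),
    or "none" (all four free — not identified without further
    restrictions, offered for sensitivity checks only).
    """

    pair_map: tuple = DEFAULT_PAIR_MAP
    lambda_f_equality: str = "pair"
    residual_link: str = "linear"      # or "log"
    residual_floor: float = 1e-6
    n_restarts: int = 5
    jitter_sd: float = 0.05
    restart_seed: int = 0
    gradient_tol: float = 1e-5         # on the per-case-average gradient norm
    max_iter: int = 500

    def __post_init__(self):
        if self.lambda_f_equality not in ("pair", "all", "none"):
            raise ValueError("lambda_f_equality must be pair|all|none")
        if self.residual_link not in ("linear", "log"):
            raise ValueError("residual_link must be linear|log")


@dataclass
class ModeratedBifactorModel:
    """Full per-indicator parameter arrays of the moderated bifactor model."""

    nu: np.ndarray
    lambda_g: np.ndarray
    lambda_f0: np.ndarray
    lambda_f1: np.ndarray     # zero unless the loading is moderated
    theta0: np.ndarray
    theta1: np.ndarray        # zero unless the residual is moderated
    pair_map: tuple = DEFAULT_PAIR_MAP
    residual_link: str = "linear"
    residual_floor: float = 1e-6

    def __post_init__(self):
        for name in ("nu", "lambda_g", "lambda_f0", "lambda_f1", "theta0", "theta1"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (4,):
                raise ValueError(f"{name} must have 4 entries")
            setattr(self, name, v)
        if np.any(self.theta0 <= 0):
            raise ValueError("theta0 entries must be strictly positive")


def simulate_from_model(
    model: ModeratedBifactorModel, m: np.ndarray, seed: int
) -> np.ndarray:
    """Draw one y-row per moderator value from y | m ~ N(nu, Sigma(m)).

    The moderator is exogenous here (unlike the true-SLODR generator,
    where g itself moderates); this is the exact data-generating process
    the estimator assumes, so it is the right basis for parameter
    recovery checks.
    """
    m = np.asarray(m, dtype=float)
    n = m.size
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n)
    f = rng.standard_normal((n, 2))
    eps = rng.standard_normal((n, 4))
    pair = np.asarray(model.pair_map)
    lam_f = model.lambda_f0[None, :] + model.lambda_f1[None, :] * m[:, None]
    if model.residual_link == "log":
        theta = model.theta0[None, :] * np.exp(model.theta1[None, :] * m[:, None])
    else:
        theta = np.maximum(
            model.theta0[None, :] + model.theta1[None, :] * m[:, None],
            model.residual_floor,
        )
    return (
        model.nu[None, :]
        + model.lambda_g[None, :] * g[:, None]
        + lam_f * f[:, pair]
        + np.sqrt(theta) * eps
    )


def implied_covariance(model: ModeratedBifactorModel, m: float) -> np.ndarray:
    """Model-implied 4x4 covariance Sigma(m) at moderator value m."""
    lam_f = model.lambda_f0 + model.lambda_f1 * m
    pair = np.asarray(model.pair_map)
    sigma = np.outer(model.lambda_g, model.lambda_g)
    for p in (0, 1):
        c = np.where(pair == p, lam_f, 0.0)
        sigma = sigma + np.outer(c, c)
    if model.residual_link == "log":
        theta = model.theta0 * np.exp(model.theta1 * m)
    else:
        theta = np.maximum(model.theta0 + model.theta1 * m, model.residual_floor)
    return sigma + np.diag(theta)


# ---------------------------------------------------------------------------
# parameter packing


class _Layout:
    """Mapping between the free-parameter vector and model arrays."""

    def __init__(self, config: ModerationConfig, settings: McfaSettings):
        self.config = config
        self.settings = settings
        self.pair = np.asarray(settings.pair_map)
        self.target = None if config.target_indicator is None else config.target_indicator - 1
        names = [f"nu{j+1}" for j in range(4)] + [f"lambda_g{j+1}" for j in range(4)]
        eq = settings.lambda_f_equality
        if eq == "pair":
            self.lf0_groups = [tuple(np.flatnonzero(self.pair == p)) for p in (0, 1)]
            names += ["lambda_f0_pair1", "lambda_f0_pair2"]
        elif eq == "all":
            self.lf0_groups = [(0, 1, 2, 3)]
            names += ["lambda_f0"]
        else:
            self.lf0_groups = [(j,) for j in range(4)]
            names += [f"lambda_f0_{j+1}" for j in range(4)]
        self.i_lf0 = 8
        self.i_th0 = self.i_lf0 + len(self.lf0_groups)
        names += [f"theta0_{j+1}" for j in range(4)]
        idx = self.i_th0 + 4
        self.i_lf1 = self.i_th1 = None
        if config.moderates_loading:
            self.i_lf1 = idx
            names.append(f"lambda_f1_{config.target_indicator}")
            idx += 1
        if config.moderates_residual:
            self.i_th1 = idx
            names.append(f"theta1_{config.target_indicator}")
            idx += 1
        self.k = idx
        self.names = names

    def unpack(self, x: np.ndarray) -> ModeratedBifactorModel:
        lf0 = np.empty(4)
        for g, group in enumerate(self.lf0_groups):
            for j in group:
                lf0[j] = x[self.i_lf0 + g]
        lf1 = np.zeros(4)
        th1 = np.zeros(4)
        if self.i_lf1 is not None:
            lf1[self.target] = x[self.i_lf1]
        if self.i_th1 is not None:
            th1[self.target] = x[self.i_th1]
        return ModeratedBifactorModel(
            nu=x[0:4],
            lambda_g=x[4:8],
            lambda_f0=lf0,
            lambda_f1=lf1,
            theta0=x[self.i_th0 : self.i_th0 + 4],
            theta1=th1,
            pair_map=tuple(self.pair),
            residual_link=self.settings.residual_link,
            residual_floor=self.settings.residual_floor,
        )

    def pack(self, model: ModeratedBifactorModel) -> np.ndarray:
        x = np.empty(self.k)
        x[0:4] = model.nu
        x[4:8] = model.lambda_g
        for g, group in enumerate(self.lf0_groups):
            x[self.i_lf0 + g] = np.mean([model.lambda_f0[j] for j in group])
        x[self.i_th0 : self.i_th0 + 4] = model.theta0
        if self.i_lf1 is not None:
            x[self.i_lf1] = model.lambda_f1[self.target]
        if self.i_th1 is not None:
            x[self.i_th1] = model.theta1[self.target]
        return x

    def bounds(self):
        lo = [-np.inf] * self.k
        hi = [np.inf] * self.k
        for j in range(4):
            lo[self.i_th0 + j] = 1e-4
        return list(zip(lo, hi))


# ---------------------------------------------------------------------------
# likelihood and gradient


def _sigma_batch(model: ModeratedBifactorModel, m: np.ndarray, force_percase=False):
    """Per-case Sigma stack.  Returns (Sig, c0, c1, dtheta0, dtheta1).

    When nothing varies with m the stack has a leading dimension of 1
    and broadcasts against the n cases; ``force_percase`` keeps the full
    stack even at zero slopes (needed while a slope is a free but
    currently-zero parameter).  ``dtheta0``/``dtheta1`` are the per-case
    derivative factors of the residual variance with respect to theta0
    and theta1 (zero where the linear link is floored).
    """
    moderated = (
        force_percase
        or np.any(model.lambda_f1 != 0)
        or np.any(model.theta1 != 0)
    )
    mm = m[:, None] if moderated else np.zeros((1, 1))
    lam_f = model.lambda_f0[None, :] + model.lambda_f1[None, :] * mm
    pair = np.asarray(model.pair_map)
    c0 = np.where(pair[None, :] == 0, lam_f, 0.0)
    c1 = np.where(pair[None, :] == 1, lam_f, 0.0)
    if model.residual_link == "log":
        theta = model.theta0[None, :] * np.exp(model.theta1[None, :] * mm)
        dth0 = theta / model.theta0[None, :]
        dth1 = theta * mm
    else:
        lin = model.theta0[None, :] + model.theta1[None, :] * mm
        unclipped = lin > model.residual_floor
        theta = np.maximum(lin, model.residual_floor)
        dth0 = unclipped.astype(float)
        dth1 = dth0 * mm
    lg = model.lambda_g
    sig = (
        lg[None, :, None] * lg[None, None, :]
        + c0[:, :, None] * c0[:, None, :]
        + c1[:, :, None] * c1[:, None, :]
    )
    sig = sig + theta[:, None, :] * np.eye(4)[None, :, :]
    return sig, c0, c1, dth0, dth1


def _loglik_core(model, y, m, want_casegrad, layout=None):
    """Total log-likelihood, total gradient, optional per-case gradients."""
    n = y.shape[0]
    force = layout is not None and (
        layout.i_lf1 is not None or layout.i_th1 is not None
    )
    sig, c0, c1, dth0, dth1 = _sigma_batch(model, m, force_percase=force)
    try:
        chol = np.linalg.cholesky(sig)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    logdet = 2.0 * np.log(np.diagonal(chol, axis1=-2, axis2=-1)).sum(axis=-1)
    prec = np.linalg.inv(sig)
    r = y - model.nu[None, :]
    q = (prec @ r[:, :, None])[..., 0]
    quad = np.einsum("ni,ni->n", r, q)
    total_logdet = logdet.sum() * (n if logdet.size == 1 else 1)
    ll = -0.5 * (n * 4 * _LOG2PI + total_logdet + quad.sum())
    if layout is None:
        return ll, None, None

    lg = model.lambda_g
    plg = prec @ lg                                   # (·,4)
    pc0 = (prec @ c0[..., None])[..., 0]
    pc1 = (prec @ c1[..., None])[..., 0]
    pdiag = np.diagonal(prec, axis1=-2, axis2=-1)     # (·,4)
    lgq = q @ lg                                      # (n,)
    c0q = (c0 * q).sum(axis=1)
    c1q = (c1 * q).sum(axis=1)

    G = np.empty((n, layout.k))
    G[:, 0:4] = q
    G[:, 4:8] = q * lgq[:, None] - plg
    pcs = (pc0, pc1)
    cqs = (c0q, c1q)
    for g, group in enumerate(layout.lf0_groups):
        col = np.zeros(n)
        for j in group:
            p = layout.pair[j]
            col = col + (q[:, j] * cqs[p] - pcs[p][..., j])
        G[:, layout.i_lf0 + g] = col
    half = 0.5 * (q**2 - pdiag)
    G[:, layout.i_th0 : layout.i_th0 + 4] = half * dth0
    if layout.i_lf1 is not None:
        t = layout.target
        p = layout.pair[t]
        G[:, layout.i_lf1] = m * (q[:, t] * cqs[p] - pcs[p][..., t])
    if layout.i_th1 is not None:
        t = layout.target
        G[:, layout.i_th1] = half[:, t] * dth1[..., t]
    grad = G.sum(axis=0)
    return ll, grad, (G if want_casegrad else None)


def loglikelihood(
    model: ModeratedBifactorModel, cohort: Cohort, moderator: ModeratorScores
) -> float:
    """Sum of per-case 4-variate normal log-densities under Sigma(m_i)."""
    y = cohort.scores
    if moderator.n != cohort.n:
        raise ValueError("cohort and moderator must be aligned by row")
    ll, _, _ = _loglik_core(model, y, moderator.scores, False)
    if not np.isfinite(ll):
        sig, *_ = _sigma_batch(model, moderator.scores)
        eigs = np.linalg.eigvalsh(sig)
        bad = int(np.argmin(eigs.min(axis=-1)))
        raise ValueError(f"singular implied covariance at case index {bad}")
    return float(ll)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Estimates, robust SEs and information criteria of one MCFA fit."""

    param_names: list
    estimates: np.ndarray
    robust_se: np.ndarray
    log_likelihood: float
    k: int
    n: int
    bic: float
    converged: bool
    gradient_norm: float
    n_restarts_used: int
    config: ModerationConfig
    model: ModeratedBifactorModel = field(repr=False)
    at_variance_floor: bool = False

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.param_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.robust_se[self.param_names.index(name)])

    @property
    def loading_slope_name(self) -> Optional[str]:
        return next((n for n in self.param_names if n.startswith("lambda_f1")), None)

    @property
    def residual_slope_name(self) -> Optional[str]:
        return next((n for n in self.param_names if n.startswith("theta1")), None)


def _start_values(y: np.ndarray, layout: _Layout) -> np.ndarray:
    s = np.cov(y, rowvar=False, ddof=0)
    pair = layout.pair
    cross = [s[i, j] for i in range(4) for j in range(i + 1, 4) if pair[i] != pair[j]]
    lg = np.sqrt(max(float(np.mean(cross)), 0.04))
    lf0 = np.empty(4)
    for p in (0, 1):
        i, j = np.flatnonzero(pair == p)
        lf0[pair == p] = np.sqrt(max(s[i, j] - lg**2, 0.02))
    model = ModeratedBifactorModel(
        nu=y.mean(axis=0),
        lambda_g=np.full(4, lg),
        lambda_f0=lf0,
        lambda_f1=np.zeros(4),
        theta0=np.maximum(np.diag(s) - lg**2 - lf0**2, 0.05),
        theta1=np.zeros(4),
        pair_map=tuple(pair),
        residual_link=layout.settings.residual_link,
        residual_floor=layout.settings.residual_floor,
    )
    return layout.pack(model)


def fit_mcfa(
    cohort: Cohort,
    moderator: ModeratorScores,
    config: ModerationConfig = ModerationConfig(),
    baseline: Optional[FitResult] = None,
    settings: McfaSettings = McfaSettings(),
) -> FitResult:
    """Maximum-likelihood fit of one (possibly moderated) bifactor model.

    Starts from the unmoderated baseline when one is supplied (slopes
    zero), otherwise from moment-based values; keeps the best of
    ``settings.n_restarts`` jittered restarts.  Robust (sandwich)
    standard errors use the averaged Hessian and the outer product of
    per-case gradients.
    """
    y = cohort.scores
    n = y.shape[0]
    if n <= 50:
        raise ValueError("MCFA needs more than 50 respondents")
    if moderator.n != n:
        raise ValueError("cohort and moderator must be aligned by row")
    m = moderator.scores
    layout = _Layout(config, settings)

    if baseline is not None:
        x0 = layout.pack(baseline.model)
    else:
        x0 = _start_values(y, layout)

    scale = 1.0 / n

    def objective(x):
        ll, grad, _ = _loglik_core(layout.unpack(x), y, m, False, layout)
        if not np.isfinite(ll):
            return 1e10, np.zeros(layout.k)
        return -ll * scale, -grad * scale

    bounds = layout.bounds()
    rng = np.random.default_rng(settings.restart_seed)
    starts = [x0]
    for _ in range(settings.n_restarts):
        starts.append(x0 + settings.jitter_sd * rng.standard_normal(layout.k))
    for s in starts[1:]:
        np.clip(s[layout.i_th0 : layout.i_th0 + 4], 1e-3, None,
                out=s[layout.i_th0 : layout.i_th0 + 4])

    best = None
    opts = {"maxiter": settings.max_iter, "ftol": 1e-14, "gtol": 1e-9}
    for x_start in starts:
        res = optimize.minimize(
            objective, x_start, jac=True, method="L-BFGS-B",
            bounds=bounds, options=opts,
        )
        if best is None or res.fun < best.fun:
            best = res
    # Newton polish: near the optimum a couple of full Newton steps with the
    # finite-difference Hessian push the gradient to machine precision where
    # L-BFGS-B stops on its relative-reduction test
    x_hat = best.x
    ll, grad, _ = _loglik_core(layout.unpack(x_hat), y, m, False, layout)
    no_ascent = False
    for _ in range(4):
        if np.linalg.norm(grad * scale) < 0.1 * settings.gradient_tol:
            break
        H = _fd_hessian(x_hat, layout, y, m)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        improved = False
        frac = 1.0
        for _ in range(10):
            x_new = x_hat - frac * step
            x_new[layout.i_th0 : layout.i_th0 + 4] = np.maximum(
                x_new[layout.i_th0 : layout.i_th0 + 4], 1e-4
            )
            ll_new, grad_new, _ = _loglik_core(
                layout.unpack(x_new), y, m, False, layout
            )
            if np.isfinite(ll_new) and ll_new > ll + 1e-10:
                x_hat, ll, grad = x_new, ll_new, grad_new
                improved = True
                break
            frac *= 0.5
        if not improved:
            no_ascent = True
            break

    model = layout.unpack(x_hat)
    ll, grad, casegrad = _loglik_core(model, y, m, True, layout)
    grad_norm = float(np.linalg.norm(grad * scale))
    # when the linear residual-variance floor is active for some cases the
    # objective is kinked at the optimum and the gradient criterion cannot
    # be met; "no ascent direction" is the convergence certificate there
    floor_active = False
    if settings.residual_link == "linear" and np.any(model.theta1 != 0):
        lin = model.theta0[None, :] + model.theta1[None, :] * m[:, None]
        floor_active = bool(np.any(lin < settings.residual_floor))
    converged = bool(np.isfinite(ll)) and (
        grad_norm < settings.gradient_tol or (no_ascent and floor_active)
    )
    if not converged:
        warnings.warn(
            f"MCFA fit did not converge (per-case gradient norm {grad_norm:.2e})",
            UserWarning,
            stacklevel=2,
        )

    se = _sandwich_se(x_hat, layout, y, m, casegrad)
    ll = float(ll)
    k = layout.k
    bic = -2.0 * ll + k * np.log(n)
    return FitResult(
        param_names=layout.names,
        estimates=x_hat,
        robust_se=se,
        log_likelihood=float(ll),
        k=k,
        n=n,
        bic=float(bic),
        converged=converged,
        gradient_norm=grad_norm,
        n_restarts_used=settings.n_restarts,
        config=config,
        model=model,
        at_variance_floor=floor_active,
    )


def _fd_hessian(x_hat, layout, y, m) -> np.ndarray:
    """Hessian of the total log-likelihood by central differences of the
    analytic gradient."""
    k = layout.k
    H = np.empty((k, k))
    h = 1e-5 * np.maximum(np.abs(x_hat), 1.0)
    for j in range(k):
        xp = x_hat.copy()
        xp[j] += h[j]
        _, gp, _ = _loglik_core(layout.unpack(xp), y, m, False, layout)
        xm = x_hat.copy()
        xm[j] -= h[j]
        _, gm, _ = _loglik_core(layout.unpack(xm), y, m, False, layout)
        H[j] = (gp - gm) / (2.0 * h[j])
    return 0.5 * (H + H.T)


def _sandwich_se(x_hat, layout, y, m, casegrad) -> np.ndarray:
    """Robust SEs: sqrt(diag(A^-1 B A^-1 / n)) with A the average
    negative Hessian and B the average outer product of case gradients."""
    n = y.shape[0]
    B = casegrad.T @ casegrad / n
    A = -_fd_hessian(x_hat, layout, y, m) / n
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; SEs from pseudo-inverse",
                      UserWarning, stacklevel=2)
        Ainv = np.linalg.pinv(A)
    vcov = Ainv @ B @ Ainv / n
    d = np.diag(vcov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)


def delta_bic(model_fit: FitResult, baseline_fit: FitResult) -> tuple:
    """(moderated BIC - baseline BIC, significance flag).

    A negative difference favors the moderated model; the improvement
    is flagged significant when it exceeds 10 BIC points.
    """
    if model_fit.n != baseline_fit.n:
        raise ValueError("fits compare different sample sizes")
    d = model_fit.bic - baseline_fit.bic
    return float(d), bool(d < -10.0)


# ---------------------------------------------------------------------------
# fit indices


def rmsea(chi2: float, df: int, n: int) -> float:
    """Root-mean-square error of approximation, clamped at 0."""
    if df <= 0:
        return 0.0
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * n)))


def rmsea_ci90(chi2: float, df: int, n: int) -> tuple:
    """90% RMSEA confidence interval by noncentral-chi-square inversion."""
    if df <= 0:
        return (0.0, 0.0)

    def solve(prob):
        # find lam with ncx2.cdf(chi2, df, lam) == prob; cdf decreases in lam
        if stats.chi2.cdf(chi2, df) < prob:
            return 0.0
        hi = max(chi2, 1.0)
        while stats.ncx2.cdf(chi2, df, hi) > prob:
            hi *= 2.0
            if hi > 1e8:
                return hi
        return optimize.brentq(
            lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob, 0.0, hi, xtol=1e-10
        )

    lam_lo = solve(0.95)
    lam_hi = solve(0.05)
    return (
        float(np.sqrt(lam_lo / (df * n))),
        float(np.sqrt(lam_hi / (df * n))),
    )


def cfi(chi2: float, df: int, chi2_indep: float, df_indep: int) -> float:
    """Comparative fit index against the independence model."""
    num = max(chi2 - df, 0.0)
    den = max(chi2_indep - df_indep, chi2 - df, 0.0)
    if den == 0.0:
        return 1.0
    return float(1.0 - num / den)


@dataclass
class FitIndices:
    chi_square: float
    df: int
    rmsea: float
    rmsea_ci90: tuple
    cfi: float


def fit_indices(baseline_fit: FitResult, cohort: Cohort) -> FitIndices:
    """Chi-square, RMSEA (with 90% CI) and CFI of the baseline model.

    The saturated reference is the unrestricted multivariate normal
    (sample mean and ML covariance); the independence reference frees
    means and variances only.  Degrees of freedom are reported from the
    actual free-parameter count against the 14 first- and second-order
    moments.
    """
    y = cohort.scores
    n, p = y.shape
    s = np.cov(y, rowvar=False, ddof=0)
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("saturated covariance is singular")
    ll_sat = -0.5 * n * (p * _LOG2PI + logdet_s + p)
    ll_indep = -0.5 * n * (p * _LOG2PI + np.log(np.diag(s)).sum() + p)
    chi2 = 2.0 * (ll_sat - baseline_fit.log_likelihood)
    df = _N_MOMENTS - baseline_fit.k
    chi2_indep = 2.0 * (ll_sat - ll_indep)
    df_indep = _N_MOMENTS - 2 * p
    return FitIndices(
        chi_square=float(chi2),
        df=int(df),
        rmsea=rmsea(chi2, df, n),
        rmsea_ci90=rmsea_ci90(chi2, df, n),
        cfi=cfi(chi2, df, chi2_indep, df_indep),
    )


# ---------------------------------------------------------------------------
# the 13-fit moderation grid


@dataclass
class ModerationReport:
    """Per-indicator moderation results against a shared baseline."""

    dataset: str
    baseline: FitResult
    indices: FitIndices
    rows: list                      # one dict per indicator

    def to_dataframe(self):
        import pandas as pd

        records = []
        for row in self.rows:
            for variant in ("loading", "residual", "both"):
                records.append(
                    {
                        "dataset": self.dataset,
                        "indicator": row["indicator"],
                        "variant": variant,
                        "delta_bic": row[f"dbic_{variant}"],
                        "loading_slope": row.get(f"{variant}_loading_slope"),
                        "loading_se": row.get(f"{variant}_loading_se"),
                        "residual_slope": row.get(f"{variant}_residual_slope"),
                        "residual_se": row.get(f"{variant}_residual_se"),
                        "significant": row[f"significant_{variant}"],
                        "converged": row[f"converged_{variant}"],
                    }
                )
        return pd.DataFrame.from_records(records)


def _wald_significant(slope, se):
    if slope is None or se is None or not np.isfinite(se) or se == 0:
        return False
    return bool(abs(slope / se) > stats.norm.ppf(0.975))


def moderation_report(
    cohort: Cohort,
    moderator: ModeratorScores,
    dataset_label: str = "dataset",
    settings: McfaSettings = McfaSettings(),
) -> ModerationReport:
    """Run the full moderation grid: baseline + {loading, residual, both}
    for each of the four indicators (13 fits), with BIC differences,
    slope estimates, robust SEs and Wald significance flags."""
    base = fit_mcfa(cohort, moderator, ModerationConfig(), settings=settings)
    indices = fit_indices(base, cohort)
    rows = []
    for ind in (1, 2, 3, 4):
        row = {"indicator": ind}
        for variant in ("loading", "residual", "both"):
            cfg = ModerationConfig(target_indicator=ind, variant=variant)
            try:
                fit = fit_mcfa(cohort, moderator, cfg, baseline=base, settings=settings)
            except Exception as exc:   # isolate a failed cell, keep the grid going
                row[f"dbic_{variant}"] = np.nan
                row[f"significant_{variant}"] = False
                row[f"converged_{variant}"] = False
                row[f"error_{variant}"] = str(exc)
                continue
            d, _ = delta_bic(fit, base)
            row[f"dbic_{variant}"] = d
            row[f"converged_{variant}"] = fit.converged
            sig = False
            if fit.loading_slope_name:
                sl = fit.estimate(fit.loading_slope_name)
                se = fit.se(fit.loading_slope_name)
                row[f"{variant}_loading_slope"] = sl
                row[f"{variant}_loading_se"] = se
                sig = sig or _wald_significant(sl, se)
            if fit.residual_slope_name:
                sl = fit.estimate(fit.residual_slope_name)
                se = fit.se(fit.residual_slope_name)
                row[f"{variant}_residual_slope"] = sl
                row[f"{variant}_residual_se"] = se
                sig = sig or _wald_significant(sl, se)
            row[f"significant_{variant}"] = sig
        rows.append(row)
    return ModerationReport(
        dataset=dataset_label, baseline=base, indices=indices, rows=rows
    )
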