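"""Synthetic cohort generators for scale-artifact studies of SLODR.

Three generators produce four-variable score matrices with the same
correlation fingerprint (two highly correlated pairs embedded in a
positive manifold) but different causal origins:

* :func:`sample_mvn` + :func:`apply_case_selection` — a multivariate
  normal population truncated on its first principal-component score
  (range restriction / skewed subject selection);
* :func:`sample_mvn` + :func:`apply_task_density` — a normal population
  whose marginal scales are deformed by a piecewise power map (uneven
  density of easy vs. hard tasks);
* :func:`simulate_true_slodr` — a bifactor population whose specific
  loadings genuinely shrink, and residual variances genuinely grow,
  with the general factor (ability differentiation).

A fourth generator, :func:`simulate_item_responses`, produces binary
item-level data under a two-parameter logistic model with an injected
random-guesser subpopulation, feeding the IRT stage.

All generators are pure functions of ``(params, n, seed)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationSpec",
    "CaseSelectionParams",
    "TaskDensityParams",
    "TrueSlodrParams",
    "Cohort",
    "ItemBank",
    "ResponseMatrix",
    "sample_mvn",
    "apply_case_selection",
    "truncation_moment_oracle",
    "apply_task_density",
    "task_density_skewness_oracle",
    "simulate_true_slodr",
    "simulate_item_responses",
    "make_item_bank",
    "make_detection_bank",
    "DEFAULT_VARIABLE_NAMES",
]

DEFAULT_VARIABLE_NAMES = ("V11", "V12", "V21", "V22")
DEFAULT_PAIR_MAP = (0, 0, 1, 1)

_PSD_TOL = -1e-10


class NonPositiveSemidefiniteError(ValueError):
    """Raised when a correlation matrix has a meaningfully negative eigenvalue."""

    def __init__(self, eigenvalue: float):
        self.eigenvalue = eigenvalue
        super().__init__(
            f"correlation matrix is not positive semi-definite: "
            f"smallest eigenvalue {eigenvalue:.3e} < {_PSD_TOL:.0e}"
        )


@dataclass(frozen=True)
class CorrelationSpec:
    """A 4x4 correlation matrix for the observed score variables."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(m).min())
        if eigmin < _PSD_TOL:
            raise NonPositiveSemidefiniteError(eigmin)
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_pairs(
        cls, r12: float, r34: float, r_between: float = 0.57
    ) -> "CorrelationSpec":
        """Two tight pairs (1,2) and (3,4) with a common between-pair correlation."""
        m = np.full((4, 4), r_between)
        m[0, 1] = m[1, 0] = r12
        m[2, 3] = m[3, 2] = r34
        np.fill_diagonal(m, 1.0)
        return cls(m)

    @classmethod
    def case_selection_default(cls) -> "CorrelationSpec":
        """Pre-selection population correlations: r12=.71, r34=.66, others .57."""
        return cls.from_pairs(0.71, 0.66, 0.57)

    @classmethod
    def task_density_default(cls) -> "CorrelationSpec":
        """Correlation structure of the four real subtests (An, Syl, SM, VM)."""
        m = np.array(
            [
                [1.0, 0.536, 0.349, 0.323],
                [0.536, 1.0, 0.289, 0.311],
                [0.349, 0.289, 1.0, 0.464],
                [0.323, 0.311, 0.464, 1.0],
            ]
        )
        return cls(m)

    @classmethod
    def identity(cls) -> "CorrelationSpec":
        return cls(np.eye(4))

    @classmethod
    def equicorrelated(cls, rho: float) -> "CorrelationSpec":
        m = np.full((4, 4), rho)
        np.fill_diagonal(m, 1.0)
        return cls(m)


@dataclass(frozen=True)
class CaseSelectionParams:
    """Parameters of the truncation-on-PC1 selection step.

    The default retains exactly the 12,218 lowest-scoring of 17,000
    respondents (71.87%).  A literal standardized-score threshold rule
    is available as ``selection_rule="threshold_on_standardized_score"``.
    """

    n_initial: int = 17_000
    retained_count: int = 12_218
    selection_rule: str = "retain_lowest_count"
    threshold: float = 0.3

    def __post_init__(self):
        if not (0 < self.retained_count <= self.n_initial):
            raise ValueError(
                f"retained_count must be in (0, n_initial]; got "
                f"{self.retained_count} of {self.n_initial}"
            )
        if self.selection_rule not in (
            "retain_lowest_count",
            "threshold_on_standardized_score",
        ):
            raise ValueError(f"unknown selection_rule {self.selection_rule!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass(frozen=True)
class TaskDensityParams:
    """Exponents of the piecewise power deformation of a standardized scale.

    Negative scores x map to ``-(-x)**left_exponent`` (left semi-axis
    stretched for exponents > 1), positive scores to
    ``x**right_exponent`` (right semi-axis compressed for exponents < 1).
    0 and +/-1 are fixed points for any exponents.
    """

    left_exponent: float = 1.08
    right_exponent: float = 0.93

    def __post_init__(self):
        if self.left_exponent <= 0 or self.right_exponent <= 0:
            raise ValueError("exponents must be strictly positive")


@dataclass(frozen=True)
class TrueSlodrParams:
    """Generative parameters of the moderated ("true SLODR") bifactor model.

    Each indicator j obeys

        y_j = lambda_g[j] * g + (lambda_f0[j] + lambda_f1[j] * g) * f_pair(j) + e_j

    with g, f1, f2 independent standard normal and
    ``e_j | g ~ N(0, max(theta0[j] + theta1[j] * g, variance_floor))``.

    Defaults are calibrated by moment matching so that the population
    within-pair correlation is .54, the between-pair correlation .33,
    unit variances, and the third moment of every indicator exactly
    zero (``theta1 = -2 * lambda_f0 * lambda_f1``).
    """

    lambda_g: tuple = (0.5745, 0.5745, 0.5745, 0.5745)
    lambda_f0: tuple = (0.4471, 0.4471, 0.4471, 0.4471)
    lambda_f1: tuple = (-0.10, -0.10, -0.10, -0.10)
    theta0: tuple = (0.46, 0.46, 0.46, 0.46)
    theta1: tuple = (0.0894, 0.0894, 0.0894, 0.0894)
    variance_floor: float = 0.01
    pair_map: tuple = DEFAULT_PAIR_MAP

    def __post_init__(self):
        for name in ("lambda_g", "lambda_f0", "lambda_f1", "theta0", "theta1"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (4,):
                raise ValueError(f"{name} must have 4 entries")
            object.__setattr__(self, name, tuple(v))
        if any(t <= 0 for t in self.theta0):
            raise ValueError("theta0 entries must be strictly positive")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be strictly positive")
        pm = tuple(self.pair_map)
        if sorted(pm) != [0, 0, 1, 1]:
            raise ValueError("pair_map must assign two indicators to each pair")
        object.__setattr__(self, "pair_map", pm)

    def arrays(self):
        return tuple(
            np.asarray(getattr(self, n), dtype=float)
            for n in ("lambda_g", "lambda_f0", "lambda_f1", "theta0", "theta1")
        )


@dataclass
class Cohort:
    """An n x 4 continuous score matrix with provenance metadata.

    ``latent`` optionally carries the generating latent draws (e.g. the
    general-factor scores of the true-SLODR generator) for validation.
    """

    scores: np.ndarray
    variable_names: tuple = DEFAULT_VARIABLE_NAMES
    provenance: dict = field(default_factory=dict)
    latent: dict | None = None

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2:
            raise ValueError("scores must be a 2-D matrix")
        if s.shape[0] < 2:
            raise ValueError("cohort needs at least 2 respondents")
        if len(self.variable_names) != s.shape[1]:
            raise ValueError("variable_names length must match score columns")
        if not np.all(np.isfinite(s)):
            raise ValueError("scores contain missing or non-finite values")
        self.scores = s
        self.variable_names = tuple(self.variable_names)

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def with_transform(self, scores: np.ndarray, step: dict) -> "Cohort":
        """New cohort with updated scores and the step appended to history."""
        prov = dict(self.provenance)
        prov["transforms"] = list(prov.get("transforms", [])) + [step]
        return Cohort(
            scores=scores,
            variable_names=self.variable_names,
            provenance=prov,
            latent=self.latent,
        )


@dataclass(frozen=True)
class ItemBank:
    """Two-parameter logistic item bank: discrimination a, difficulty b, scale id."""

    a: np.ndarray
    b: np.ndarray
    scale_ids: tuple

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("a and b must be 1-D arrays of equal length")
        if a.size == 0:
            raise ValueError("item bank is empty")
        if np.any(a <= 0):
            raise ValueError("discriminations must be strictly positive")
        ids = tuple(self.scale_ids)
        if len(ids) != a.size:
            raise ValueError("scale_ids length must match item count")
        counts: dict = {}
        for s in ids:
            counts[s] = counts.get(s, 0) + 1
        if any(c < 2 for c in counts.values()):
            raise ValueError("every scale needs at least 2 items")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "scale_ids", ids)

    @property
    def n_items(self) -> int:
        return self.a.size

    @property
    def scales(self) -> tuple:
        seen = []
        for s in self.scale_ids:
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def items_in_scale(self, scale) -> np.ndarray:
        return np.array([j for j, s in enumerate(self.scale_ids) if s == scale])


@dataclass
class ResponseMatrix:
    """An n x items binary response matrix with an item-to-scale mapping."""

    responses: np.ndarray
    item_scales: tuple
    respondent_ids: tuple | None = None

    def __post_init__(self):
        r = np.asarray(self.responses)
        if r.ndim != 2:
            raise ValueError("responses must be a 2-D matrix")
        if not np.isin(r, (0, 1)).all():
            raise ValueError("responses must be binary 0/1")
        if len(self.item_scales) != r.shape[1]:
            raise ValueError("item_scales must cover every item column")
        self.responses = r.astype(np.int8)
        self.item_scales = tuple(self.item_scales)
        if self.respondent_ids is None:
            self.respondent_ids = tuple(range(r.shape[0]))
        else:
            self.respondent_ids = tuple(self.respondent_ids)
            if len(self.respondent_ids) != r.shape[0]:
                raise ValueError("respondent_ids length must match rows")

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def scales(self) -> tuple:
        seen = []
        for s in self.item_scales:
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def subset(self, keep_rows: np.ndarray) -> "ResponseMatrix":
        ids = tuple(np.asarray(self.respondent_ids, dtype=object)[keep_rows])
        return ResponseMatrix(self.responses[keep_rows], self.item_scales, ids)


# ---------------------------------------------------------------------------
# continuous-score generators


def sample_mvn(spec: CorrelationSpec, n: int, seed: int) -> Cohort:
    """Draw n cases from a 4-variate normal with the given correlations.

    Marginals are standard normal; the draw is a deterministic function
    of (spec, n, seed).
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    evals, evecs = np.linalg.eigh(spec.matrix)
    factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 4))
    scores = z @ factor.T
    return Cohort(
        scores=scores,
        provenance={
            "generator": "sample_mvn",
            "seed": int(seed),
            "params": {"correlations": spec.matrix.tolist(), "n": int(n)},
            "transforms": [],
        },
    )


def _standardized_pc1(scores: np.ndarray) -> np.ndarray:
    """First principal-component scores (correlation PCA), unit sample variance."""
    z = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    corr = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    v = evecs[:, -1]
    if v.sum() < 0:
        v = -v
    raw = z @ v
    return (raw - raw.mean()) / raw.std(ddof=1)


def apply_case_selection(cohort: Cohort, params: CaseSelectionParams) -> Cohort:
    """Retain the low-ability tail of a cohort, by count or threshold.

    The selection score is the standardized first principal-component
    score computed on the *input* cohort.  Under the default
    ``retain_lowest_count`` rule, exactly ``retained_count`` rows with
    the lowest scores survive (ties broken by row order); under the
    threshold rule, all rows with scores strictly below ``threshold``.
    """
    if cohort.n < params.retained_count:
        raise ValueError(
            f"cannot retain {params.retained_count} of {cohort.n} rows"
        )
    pc1 = _standardized_pc1(cohort.scores)
    if params.selection_rule == "retain_lowest_count":
        order = np.argsort(pc1, kind="stable")
        keep = np.sort(order[: params.retained_count])
    else:
        keep = np.flatnonzero(pc1 < params.threshold)
        if keep.size < 2:
            raise ValueError("threshold rule retained fewer than 2 rows")
    out = cohort.with_transform(
        cohort.scores[keep],
        {
            "step": "case_selection",
            "rule": params.selection_rule,
            "retained_count": int(keep.size),
            "threshold": float(params.threshold),
        },
    )
    if out.latent is not None:
        out.latent = {k: np.asarray(v)[keep] for k, v in out.latent.items()}
    out.provenance["selection_scores_retained_variance"] = float(
        pc1[keep].var(ddof=1)
    )
    return out


def truncation_moment_oracle(retained_fraction: float) -> tuple:
    """Exact (mean, variance, skewness) of a lower-truncated standard normal.

    The retained distribution is Z | Z < c with c the standard-normal
    quantile of ``retained_fraction`` — the analytic counterpart of the
    selection-score distribution after :func:`apply_case_selection`.
    """
    if not (0 < retained_fraction < 1):
        raise ValueError("retained_fraction must lie strictly inside (0, 1)")
    c = stats.norm.ppf(retained_fraction)
    mean, var, skew = stats.truncnorm.stats(-np.inf, c, moments="mvs")
    return float(mean), float(var), float(skew)


def apply_task_density(cohort: Cohort, params: TaskDensityParams) -> Cohort:
    """Deform each score by the piecewise power map.

    x < 0 maps to -(-x)**left_exponent, x > 0 to x**right_exponent.
    Strictly monotone; emits a warning when inputs look far from
    standardized (the exponents are meant for a z-scale).
    """
    x = cohort.scores
    if np.abs(x.mean(axis=0)).max() > 0.25 or np.abs(x.std(axis=0) - 1).max() > 0.25:
        warnings.warn(
            "task-density map applied to scores that look unstandardized",
            UserWarning,
            stacklevel=2,
        )
    new = _piecewise_power(x, params.left_exponent, params.right_exponent)
    return cohort.with_transform(
        new,
        {
            "step": "task_density",
            "left_exponent": params.left_exponent,
            "right_exponent": params.right_exponent,
        },
    )


def _piecewise_power(x: np.ndarray, left: float, right: float) -> np.ndarray:
    out = np.where(x < 0, -np.power(-np.minimum(x, 0.0), left), 0.0)
    out = out + np.where(x > 0, np.power(np.maximum(x, 0.0), right), 0.0)
    return out


def task_density_skewness_oracle(
    params: TaskDensityParams = TaskDensityParams(), n_nodes: int = 201
) -> float:
    """Population skewness of the power-deformed standard normal.

    Computed by Gauss–Hermite quadrature of the first three moments of
    the transform of a standard normal variate.
    """
    t, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / w.sum()
    y = _piecewise_power(t, params.left_exponent, params.right_exponent)
    m1 = np.sum(w * y)
    m2 = np.sum(w * (y - m1) ** 2)
    m3 = np.sum(w * (y - m1) ** 3)
    return float(m3 / m2**1.5)


def simulate_true_slodr(params: TrueSlodrParams, n: int, seed: int) -> Cohort:
    """Sample a bifactor cohort whose SLODR is real.

    Specific-factor loadings decrease, and residual variances increase,
    linearly in the general-factor score g.  The generating g is stored
    in ``cohort.latent["g"]`` for validation.
    """
    lg, lf0, lf1, t0, t1 = params.arrays()
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n)
    f = rng.standard_normal((n, 2))
    eps = rng.standard_normal((n, 4))
    pair = np.asarray(params.pair_map)
    load_f = lf0[None, :] + lf1[None, :] * g[:, None]
    resid_var = np.maximum(t0[None, :] + t1[None, :] * g[:, None], params.variance_floor)
    y = (
        lg[None, :] * g[:, None]
        + load_f * f[:, pair]
        + np.sqrt(resid_var) * eps
    )
    return Cohort(
        scores=y,
        provenance={
            "generator": "simulate_true_slodr",
            "seed": int(seed),
            "params": {
                "lambda_g": list(lg),
                "lambda_f0": list(lf0),
                "lambda_f1": list(lf1),
                "theta0": list(t0),
                "theta1": list(t1),
                "variance_floor": params.variance_floor,
                "pair_map": list(params.pair_map),
                "n": int(n),
            },
            "transforms": [],
        },
        latent={"g": g, "f": f},
    )


# ---------------------------------------------------------------------------
# item-level generator


def make_item_bank(
    n_scales: int = 1,
    items_per_scale: int = 30,
    a: float | Sequence[float] = 1.2,
    b_range: tuple = (-2.0, 2.0),
    seed: int | None = None,
) -> ItemBank:
    """Construct a 2PL item bank with difficulties spread over ``b_range``.

    With ``seed=None`` difficulties are equally spaced; otherwise they
    are drawn uniformly (and discriminations log-normally around ``a``).
    """
    J = n_scales * items_per_scale
    scale_ids = tuple(
        f"scale{s + 1}" for s in range(n_scales) for _ in range(items_per_scale)
    )
    if seed is None:
        b = np.tile(np.linspace(*b_range, items_per_scale), n_scales)
        a_arr = np.broadcast_to(np.asarray(a, dtype=float), (J,)).copy()
    else:
        rng = np.random.default_rng(seed)
        b = rng.uniform(*b_range, size=J)
        a_arr = np.asarray(a, dtype=float) * np.exp(0.15 * rng.standard_normal(J))
    return ItemBank(a=a_arr, b=b, scale_ids=scale_ids)


def make_detection_bank(
    n_scales: int = 10, n_easy: int = 5, n_hard: int = 40
) -> ItemBank:
    """An item bank on which the guesser-flag rule has real power.

    Flags accumulate only on items whose model-predicted success
    probability sits below the chance level, and a flat random guesser
    answers those at the chance rate — so per scale the flag count is
    binomial with success 0.2 over the eligible items.  Exceeding 10
    flags therefore needs many eligible items AND an ability estimate
    that stays low despite the lucky hard-item successes.  Each scale
    here pairs a few highly discriminating easy anchors (which pin a
    random responder's ability far below the honest range) with a long
    block of weakly discriminating hard items (all flag-eligible at
    that ability, while contributing little upward pull).  On
    difficulty-matched scales the same rule has essentially no power —
    the eligible-item count shrinks as the guesser's estimated ability
    rises with their score.
    """
    a = np.concatenate([np.full(n_easy, 3.0), np.full(n_hard, 0.8)])
    b = np.concatenate(
        [np.linspace(-2.2, -1.8, n_easy), np.linspace(2.5, 3.5, n_hard)]
    )
    ids = tuple(
        f"scale{s + 1}" for s in range(n_scales) for _ in range(n_easy + n_hard)
    )
    return ItemBank(a=np.tile(a, n_scales), b=np.tile(b, n_scales), scale_ids=ids)


def simulate_item_responses(
    bank: ItemBank,
    abilities: np.ndarray,
    guesser_ids: Sequence | None = None,
    guess_probability: float = 0.2,
    seed: int = 0,
) -> ResponseMatrix:
    """Simulate binary responses with an injected random-guesser subpopulation.

    Honest respondents answer item j correctly with the 2PL probability
    ``1 / (1 + exp(-a_j (theta_i - b_j)))``; guessers answer every item
    correctly with probability ``guess_probability`` regardless of
    ability (a respondent choosing among five options at random).
    """
    theta = np.asarray(abilities, dtype=float)
    if theta.ndim != 1:
        raise ValueError("abilities must be a 1-D vector")
    n = theta.size
    guessers = set() if guesser_ids is None else set(int(g) for g in guesser_ids)
    if not guessers <= set(range(n)):
        raise ValueError("guesser_ids must be a subset of respondent indices")
    p = 1.0 / (1.0 + np.exp(-bank.a[None, :] * (theta[:, None] - bank.b[None, :])))
    if guessers:
        idx = np.fromiter(guessers, dtype=int)
        p[idx, :] = guess_probability
    rng = np.random.default_rng(seed)
    responses = (rng.random((n, bank.n_items)) < p).astype(np.int8)
    return ResponseMatrix(responses=responses, item_scales=bank.scale_ids)
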