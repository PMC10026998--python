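"""Two-parameter logistic IRT scoring with guesser flagging and exclusion.

Each scale is scored with a unidimensional 2PL model

    P(X_ij = 1 | theta_i) = 1 / (1 + exp(-a_j (theta_i - b_j)))

estimated by marginal maximum likelihood EM over a fixed grid of
quadrature nodes under a standard-normal latent, with EAP ability
scores.  A respondent whose correct answers pile up on items where the
fitted model gives them less than a 1-in-5 chance is flagged as a
guesser; respondents flagged more than ``max_flags`` times within one
scale are excluded and the model is refitted once on the clean sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp, log_expit, expit

from .cohorts import ItemBank, ResponseMatrix

__all__ = [
    "GuesserRule",
    "AbilityEstimates",
    "fit_2pl",
    "predicted_probability",
    "flag_guessers",
    "exclusion_refit_loop",
    "screen_degenerate_items",
]

_A_MAX = 8.0
_A_MIN = 0.01


@dataclass(frozen=True)
class GuesserRule:
    """Flag thresholds: predicted probability strictly below
    ``probability_threshold`` on a correct answer counts as one flag;
    strictly more than ``max_flags`` flags within one scale excludes."""

    probability_threshold: float = 0.2
    max_flags: int = 10

    def __post_init__(self):
        if not (0 < self.probability_threshold < 1):
            raise ValueError("probability_threshold must lie in (0, 1)")
        if self.max_flags < 1:
            raise ValueError("max_flags must be at least 1")


@dataclass
class AbilityEstimates:
    """EAP ability scores (theta) and posterior SDs, per respondent per scale."""

    theta: np.ndarray              # (n, n_scales)
    posterior_sd: np.ndarray       # (n, n_scales)
    scales: tuple
    respondent_ids: tuple
    loglik_history: dict = field(default_factory=dict)   # scale -> [ll, ...]
    converged: dict = field(default_factory=dict)        # scale -> bool
    kept_columns: tuple = ()       # original response columns used in the fit

    def scale_index(self, scale) -> int:
        return self.scales.index(scale)


def screen_degenerate_items(responses: ResponseMatrix):
    """Drop items answered identically by everyone; returns (matrix, dropped)."""
    X = responses.responses
    variable = X.min(axis=0) != X.max(axis=0)
    dropped = tuple(int(j) for j in np.flatnonzero(~variable))
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} degenerate item(s) with constant responses",
            UserWarning,
            stacklevel=2,
        )
        keep = np.flatnonzero(variable)
        scales = tuple(responses.item_scales[j] for j in keep)
        responses = ResponseMatrix(X[:, keep], scales, responses.respondent_ids)
        return responses, dropped, tuple(int(j) for j in keep)
    return responses, dropped, tuple(range(X.shape[1]))


def _item_q(a, d, nodes, r_q, n_q):
    """Expected complete-data log-likelihood of one item."""
    z = a * nodes + d
    return float(np.sum(r_q * log_expit(z) + (n_q - r_q) * log_expit(-z)))


def _fit_scale(X, n_quad, max_iter, tol):
    """EM for one scale.  Returns (a, b, theta, psd, ll_history, converged)."""
    n, J = X.shape
    nodes = np.linspace(-4.0, 4.0, n_quad)
    logw = stats.norm.logpdf(nodes)
    logw = logw - logsumexp(logw)

    pbar = X.mean(axis=0)
    a = np.ones(J)
    d = np.log(pbar / (1.0 - pbar))       # intercept parameterization: z = a*theta + d
    ll_history = []
    converged = False
    Xf = X.astype(float)
    for _ in range(max_iter):
        z = a[None, :] * nodes[:, None] + d[None, :]      # (q, J)
        logp = log_expit(z)
        log1p = log_expit(-z)
        logL = Xf @ logp.T + (1.0 - Xf) @ log1p.T          # (n, q)
        joint = logL + logw[None, :]
        ll_i = logsumexp(joint, axis=1)
        ll = float(ll_i.sum())
        post = np.exp(joint - ll_i[:, None])               # (n, q)
        n_q = post.sum(axis=0)
        R = Xf.T @ post                                    # (J, q)

        for j in range(J):
            a[j], d[j] = _newton_item(a[j], d[j], nodes, R[j], n_q)

        ll_history.append(ll)
        if len(ll_history) > 1 and abs(ll_history[-1] - ll_history[-2]) < tol * n:
            converged = True
            break

    # final E-step quantities for EAP scoring
    z = a[None, :] * nodes[:, None] + d[None, :]
    logL = Xf @ log_expit(z).T + (1.0 - Xf) @ log_expit(-z).T
    joint = logL + logw[None, :]
    ll_i = logsumexp(joint, axis=1)
    ll_history.append(float(ll_i.sum()))
    post = np.exp(joint - ll_i[:, None])
    theta = post @ nodes
    second = post @ nodes**2
    psd = np.sqrt(np.maximum(second - theta**2, 1e-12))
    b = -d / a
    return a, b, theta, psd, ll_history, converged


def _newton_item(a, d, nodes, r_q, n_q, max_steps=5):
    """A few Newton steps on one item's Q-function, with step-halving so the
    expected complete-data log-likelihood never decreases (keeps EM monotone)."""
    for _ in range(max_steps):
        q_old = _item_q(a, d, nodes, r_q, n_q)
        p = expit(a * nodes + d)
        e = r_q - n_q * p
        g = np.array([np.sum(e * nodes), np.sum(e)])
        wgt = n_q * p * (1.0 - p)
        h11 = np.sum(wgt * nodes**2)
        h12 = np.sum(wgt * nodes)
        h22 = np.sum(wgt)
        det = h11 * h22 - h12 * h12
        if det <= 1e-12:
            break
        step_a = (h22 * g[0] - h12 * g[1]) / det
        step_d = (h11 * g[1] - h12 * g[0]) / det
        frac = 1.0
        accepted = False
        for _ in range(20):
            cand_a = float(np.clip(a + frac * step_a, _A_MIN, _A_MAX))
            cand_d = d + frac * step_d
            if _item_q(cand_a, cand_d, nodes, r_q, n_q) >= q_old:
                a, d = cand_a, cand_d
                accepted = True
                break
            frac *= 0.5
        if not accepted or (abs(step_a) < 1e-8 and abs(step_d) < 1e-8):
            break
    return a, d


def fit_2pl(
    responses: ResponseMatrix,
    n_quad: int = 41,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> tuple:
    """Marginal-ML 2PL fit per scale; returns (ItemBank, AbilityEstimates).

    Warns below 200 respondents or 10 items per scale.  Items with
    constant responses are dropped with a warning; the returned bank
    covers the kept items (original columns in
    ``AbilityEstimates.kept_columns``).  Scales that hit ``max_iter``
    are flagged unconverged, never silently returned.
    """
    responses, _, kept = screen_degenerate_items(responses)
    if responses.n < 200:
        warnings.warn("fewer than 200 respondents; 2PL estimates will be noisy",
                      UserWarning, stacklevel=2)
    scales = responses.scales
    n = responses.n
    a_all = np.empty(responses.n_items)
    b_all = np.empty(responses.n_items)
    theta = np.empty((n, len(scales)))
    psd = np.empty((n, len(scales)))
    histories, conv = {}, {}
    item_scales = np.asarray(responses.item_scales, dtype=object)
    for s_idx, scale in enumerate(scales):
        cols = np.flatnonzero(item_scales == scale)
        if cols.size < 10:
            warnings.warn(f"scale {scale!r} has fewer than 10 items",
                          UserWarning, stacklevel=2)
        a, b, th, sd, hist, ok = _fit_scale(
            responses.responses[:, cols], n_quad, max_iter, tol
        )
        if not ok:
            warnings.warn(f"EM did not converge for scale {scale!r}",
                          UserWarning, stacklevel=2)
        a_all[cols], b_all[cols] = a, b
        theta[:, s_idx], psd[:, s_idx] = th, sd
        histories[scale], conv[scale] = hist, ok
    bank = ItemBank(a=a_all, b=b_all, scale_ids=responses.item_scales)
    abilities = AbilityEstimates(
        theta=theta,
        posterior_sd=psd,
        scales=scales,
        respondent_ids=responses.respondent_ids,
        loglik_history=histories,
        converged=conv,
        kept_columns=kept,
    )
    return bank, abilities


def predicted_probability(bank: ItemBank, theta: float, item: int) -> float:
    """2PL probability of a correct answer on one item at ability theta."""
    if not (0 <= item < bank.n_items):
        raise KeyError(f"item {item} not in bank")
    return float(expit(bank.a[item] * (theta - bank.b[item])))


def flag_guessers(
    responses: ResponseMatrix,
    bank: ItemBank,
    abilities: AbilityEstimates,
    rule: GuesserRule = GuesserRule(),
) -> tuple:
    """Count low-probability correct answers per respondent per scale.

    A flag is a correct answer on an item whose model-predicted success
    probability for that respondent is strictly below the threshold.
    Respondents with strictly more than ``max_flags`` flags within any
    single scale are excluded.  Returns (flag_counts (n, n_scales),
    excluded respondent ids).
    """
    X = responses.responses
    if X.shape[1] != bank.n_items:
        if abilities.kept_columns and len(abilities.kept_columns) == bank.n_items:
            X = X[:, list(abilities.kept_columns)]
        else:
            raise ValueError("responses and item bank have mismatched items")
    scales = abilities.scales
    scale_of_item = np.array(
        [scales.index(s) for s in bank.scale_ids], dtype=int
    )
    th = abilities.theta[:, scale_of_item]             # (n, J)
    p = expit(bank.a[None, :] * (th - bank.b[None, :]))
    flags = (p < rule.probability_threshold) & (X == 1)
    counts = np.zeros((X.shape[0], len(scales)), dtype=int)
    for s_idx in range(len(scales)):
        counts[:, s_idx] = flags[:, scale_of_item == s_idx].sum(axis=1)
    excluded_rows = np.flatnonzero((counts > rule.max_flags).any(axis=1))
    excluded_ids = [responses.respondent_ids[i] for i in excluded_rows]
    return counts, excluded_ids


def exclusion_refit_loop(
    responses: ResponseMatrix,
    rule: GuesserRule = GuesserRule(),
    n_quad: int = 41,
    max_iter: int = 500,
    iterate_to_fixed_point: bool = False,
) -> tuple:
    """Fit, flag, exclude, and refit once on the clean sample.

    Returns (clean ResponseMatrix, final ItemBank, final
    AbilityEstimates, report dict).  Errors out if more than 20% of the
    sample would be excluded — a sign of a degenerate bank or rule.
    ``iterate_to_fixed_point`` repeats the pass until no further
    exclusions (capped at 10 passes).
    """
    current = responses
    all_excluded: list = []
    max_passes = 10 if iterate_to_fixed_point else 1
    bank, abilities = fit_2pl(current, n_quad=n_quad, max_iter=max_iter)
    for _ in range(max_passes):
        counts, excluded = flag_guessers(current, bank, abilities, rule)
        if not excluded:
            break
        all_excluded.extend(excluded)
        if len(all_excluded) > 0.2 * responses.n:
            raise ValueError(
                f"{len(all_excluded)} of {responses.n} respondents excluded "
                "(> 20%); the item bank or guesser rule looks degenerate"
            )
        banned = set(excluded)
        keep = np.array([rid not in banned for rid in current.respondent_ids])
        current = current.subset(np.flatnonzero(keep))
        bank, abilities = fit_2pl(current, n_quad=n_quad, max_iter=max_iter)
    final_bank, final_abilities = bank, abilities
    report = {
        "excluded_ids": list(all_excluded),
        "n_excluded": len(all_excluded),
        "exclusion_rate": len(all_excluded) / responses.n,
        "n_initial": responses.n,
        "n_final": current.n,
        "rule": {
            "probability_threshold": rule.probability_threshold,
            "max_flags": rule.max_flags,
        },
    }
    return current, final_bank, final_abilities, report
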