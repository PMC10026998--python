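"""Observed moderator scores: standardized first principal component.

The moderated factor analysis needs an observed per-case proxy for
general ability.  Following common practice, this is the first
principal-component score of the four analyzed variables (PCA on the
correlation matrix), standardized to mean 0 and unit sample variance,
with the eigenvector oriented so its component sum is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohorts import Cohort

__all__ = ["ModeratorScores", "pc1_scores"]


@dataclass
class ModeratorScores:
    scores: np.ndarray            # length n, mean 0, sample variance 1
    loadings: np.ndarray          # first eigenvector, component sum > 0
    explained_variance: float     # first eigenvalue of the correlation matrix

    @property
    def n(self) -> int:
        return self.scores.size


def pc1_scores(cohort: Cohort) -> ModeratorScores:
    """Standardized first-principal-component scores of a cohort.

    PCA is performed on the correlation matrix (variables are
    z-scored first), so the result is invariant to affine rescaling of
    individual variables.
    """
    x = cohort.scores
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more respondents than variables")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = cohort.variable_names[int(np.argmin(sd))]
        raise ValueError(f"variable {bad!r} has zero variance")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    v = evecs[:, -1]
    if v.sum() < 0:
        v = -v
    raw = z @ v
    scores = (raw - raw.mean()) / raw.std(ddof=1)
    return ModeratorScores(
        scores=scores, loadings=v, explained_variance=float(evals[-1])
    )
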