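"""PWM-to-PWM similarity with a column-permutation null.

Two motifs for the same kinase obtained by different experimental routes
(e.g., microarray-derived versus positional-scanning peptide library) are
compared column-by-column: the score is the mean Pearson correlation of the
20-dimensional amino-acid probability columns, excluding the center column
(it is phosphoacceptor-constrained in both motifs and would inflate
similarity). Significance comes from shuffling the non-center columns of one
motif: the null preserves per-column information content, a stricter test
than i.i.d. random columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alphabet import AMINO_ACIDS
from .motif import PWMMatrix


@dataclass(frozen=True)
class MotifSimilarity:
    score: float
    p_value: float
    n_permutations: int


def _center_align(a: PWMMatrix, b: PWMMatrix,
                  background: Optional[np.ndarray] = None
                  ) -> tuple[np.ndarray, np.ndarray, int]:
    """Pad the narrower motif with background columns so centers coincide.

    Returns 20-row probability matrices (pad row dropped, renormalized)
    and the shared center index.
    """
    if (a.width - b.width) % 2 != 0:
        raise ValueError("width difference must be even to share a center")
    if background is None:
        background = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    va, vb = a.without_pad(), b.without_pad()
    half = abs(a.width - b.width) // 2
    if half:
        pad = np.tile(background[:, None], (1, half))
        if a.width < b.width:
            va = np.hstack([pad, va, pad])
        else:
            vb = np.hstack([pad, vb, pad])
    width = max(a.width, b.width)
    return va, vb, (width - 1) // 2


def _column_correlations(va: np.ndarray, vb: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between all columns of va and of vb.

    Zero-variance columns yield correlation 0 by definition.
    """
    def standardize(m):
        c = m - m.mean(axis=0, keepdims=True)
        sd = c.std(axis=0, keepdims=True)
        ok = sd[0] > 0
        c = np.where(ok[None, :], c / np.where(sd == 0, 1.0, sd), 0.0)
        return c, ok

    ca, oka = standardize(va)
    cb, okb = standardize(vb)
    corr = ca.T @ cb / va.shape[0]
    corr[~oka, :] = 0.0
    corr[:, ~okb] = 0.0
    return corr


def pwm_similarity(a: PWMMatrix, b: PWMMatrix,
                   background: Optional[np.ndarray] = None) -> float:
    """Mean over non-center columns of the column-wise Pearson correlation."""
    va, vb, center = _center_align(a, b, background)
    corr = _column_correlations(va, vb)
    idx = [j for j in range(va.shape[1]) if j != center]
    return float(np.mean([corr[j, j] for j in idx]))


def similarity_pvalue(a: PWMMatrix, b: PWMMatrix,
                      n_permutations: int = 999,
                      rng_seed: int = 0,
                      background: Optional[np.ndarray] = None
                      ) -> MotifSimilarity:
    """Permutation p-value: how often a column-shuffled ``b`` matches ``a``
    at least as well as the observed alignment.

    p = (1 + #{null >= score}) / (n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    va, vb, center = _center_align(a, b, background)
    corr = _column_correlations(va, vb)
    idx = np.array([j for j in range(va.shape[1]) if j != center])
    score = float(corr[idx, idx].mean())

    rng = np.random.default_rng(rng_seed)
    sub = corr[np.ix_(idx, idx)]  # correlations among non-center columns
    null = np.empty(n_permutations)
    m = len(idx)
    rows = np.arange(m)
    for t in range(n_permutations):
        perm = rng.permutation(m)
        null[t] = sub[rows, perm].mean()
    p = (1.0 + np.count_nonzero(null >= score)) / (n_permutations + 1.0)
    return MotifSimilarity(score=score, p_value=float(p),
                           n_permutations=n_permutations)
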