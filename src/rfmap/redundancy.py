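"""Cohort-level RFM redundancy pruning.

For each subject the pairwise Pearson correlation between flattened feature
maps is computed; the per-subject matrices are averaged elementwise across
the cohort and highly correlated pairs (|r| above a threshold, default 0.95)
are greedily eliminated, leaving a de-duplicated retained feature list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rfm_engine import RFMStack

__all__ = ["CorrelationMatrix", "subject_corr", "average_corr", "prune"]


@dataclass
class CorrelationMatrix:
    """Symmetric feature x feature Pearson matrix with averaging provenance."""

    values: np.ndarray
    names: tuple[str, ...]
    n_subjects_averaged: int = 1
    degenerate: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.names):
            raise ValueError("values must be square and match names")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.values = v


def subject_corr(stack: RFMStack) -> CorrelationMatrix:
    """Pearson correlations between all pairs of a subject's feature maps.

    Maps are flattened over all patch pixels.  Zero-variance (degenerate)
    maps get r = 0 off-diagonal and are flagged.
    """
    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least two maps to correlate")
    X = np.stack([stack.maps[n].ravel() for n in names])
    sd = X.std(axis=1)
    degenerate = tuple(n for n, s in zip(names, sd) if s == 0)
    ok = sd > 0
    C = np.zeros((len(names), len(names)))
    if ok.sum() >= 2:
        C[np.ix_(ok, ok)] = np.corrcoef(X[ok])
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2, -1.0, 1.0)
    return CorrelationMatrix(C, names, 1, degenerate)


def average_corr(matrices: list[CorrelationMatrix]) -> CorrelationMatrix:
    """Elementwise mean of per-subject correlation matrices."""
    if not matrices:
        raise ValueError("no matrices to average")
    names = matrices[0].names
    for m in matrices[1:]:
        if m.names != names:
            raise ValueError("correlation matrices index different features")
    avg = np.mean([m.values for m in matrices], axis=0)
    degenerate = tuple(sorted(set().union(*(m.degenerate for m in matrices))))
    return CorrelationMatrix(avg, names, sum(m.n_subjects_averaged for m in matrices),
                             degenerate)


def prune(avg: CorrelationMatrix, threshold: float = 0.95) -> list[str]:
    """Greedy de-duplication: drop features until no retained pair has
    |r| > ``threshold``.

    When a pair exceeds the threshold the member with the higher mean
    absolute correlation to all still-retained features is dropped; ties go
    against the feature later in canonical order.  Returns retained names in
    canonical order.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    n = len(avg.names)
    C = np.abs(avg.values.copy())
    np.fill_diagonal(C, 0.0)
    alive = np.ones(n, dtype=bool)
    while True:
        sub = np.where(alive)[0]
        block = C[np.ix_(sub, sub)]
        if block.size == 0 or block.max() <= threshold:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(block), block.shape)
        a, b = sub[i_loc], sub[j_loc]
        mean_a = block[i_loc].sum() / max(len(sub) - 1, 1)
        mean_b = block[j_loc].sum() / max(len(sub) - 1, 1)
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)  # tie: later canonical position goes
        alive[drop] = False
    return [avg.names[i] for i in range(n) if alive[i]]
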