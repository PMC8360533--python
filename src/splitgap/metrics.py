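"""AUC, DeLong confidence intervals, generalization-gap records, and
the unit-hypercube mean-distance utility.

The AUC is the Mann-Whitney two-sample statistic: the probability that a
random positive scores above a random negative, with ties counting 1/2.
Its sampling variance is estimated nonparametrically with the DeLong
U-statistic decomposition: per-positive placements V10 (each positive's
mean win rate over the negatives) and per-negative placements V01, giving

    var(AUC) = S10 / m + S01 / n

with S10, S01 the sample variances of the placements and m, n the class
sizes.  Wald intervals are clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DeLongResult",
    "GapRecord",
    "TrialSummary",
    "auc_mann_whitney",
    "delong_variance_ci",
    "generalization_gap",
    "summarize_trials",
    "hypercube_mean_distance",
]


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to compute an AUC")
    return pos, neg


def auc_mann_whitney(scores, labels) -> float:
    """Empirical AUC: mean over positive-negative pairs of win(1)/tie(1/2).

    Computed via midranks, which is algebraically identical to exhaustive
    pair enumeration with the tie-counts-half convention.
    """
    pos, neg = _split_scores(scores, labels)
    m, n = pos.size, neg.size
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


@dataclass(frozen=True)
class DeLongResult:
    """AUC with DeLong variance and a clipped Wald confidence interval."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    confidence_level: float = 0.95


def delong_variance_ci(scores, labels, level: float = 0.95) -> DeLongResult:
    """DeLong variance and confidence interval for the empirical AUC.

    Requires at least two members per class (the placement variances are
    undefined otherwise).
    """
    pos, neg = _split_scores(scores, labels)
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >= 2 samples in each class")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    # Placements: V10 per positive (win rate over negatives), V01 per negative.
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    variance = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(variance, 0.0))
    return DeLongResult(
        auc=auc,
        variance=variance,
        ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        confidence_level=level,
    )


@dataclass(frozen=True)
class GapRecord:
    """Internal estimate vs. test AUC for one split, in both sign conventions.

    ``optimism`` (estimate minus test) is positive when the internal
    estimate was too rosy; ``printed_difference`` (test minus estimate)
    follows the opposite convention used by per-trial report tables.
    """

    estimate_auc: float
    test_auc: float

    @property
    def optimism(self) -> float:
        return self.estimate_auc - self.test_auc

    @property
    def printed_difference(self) -> float:
        return self.test_auc - self.estimate_auc


def generalization_gap(estimate_auc: float, test_auc: float) -> GapRecord:
    for name, value in (("estimate_auc", estimate_auc), ("test_auc", test_auc)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return GapRecord(estimate_auc=float(estimate_auc), test_auc=float(test_auc))


@dataclass(frozen=True)
class TrialSummary:
    """Across-trial means and sample SDs of test AUC and optimism."""

    mean_test_auc: float
    sd_test_auc: float
    mean_optimism: float
    sd_optimism: float
    n_trials: int
    sd_defined: bool  # False when only one trial (SD reported as 0)


def summarize_trials(gaps: list[GapRecord]) -> TrialSummary:
    """Mean (+/- sample SD, n-1 denominator) of test AUC and optimism."""
    if not gaps:
        raise ValueError("cannot summarize an empty trial list")
    test = np.array([g.test_auc for g in gaps], dtype=float)
    opt = np.array([g.optimism for g in gaps], dtype=float)
    single = test.size == 1
    return TrialSummary(
        mean_test_auc=float(test.mean()),
        sd_test_auc=0.0 if single else float(test.std(ddof=1)),
        mean_optimism=float(opt.mean()),
        sd_optimism=0.0 if single else float(opt.std(ddof=1)),
        n_trials=int(test.size),
        sd_defined=not single,
    )


def hypercube_mean_distance(
    dim: int, n_pairs: int, seed: int, chunk: int = 200_000
) -> tuple[float, float]:
    """Monte-Carlo mean Euclidean distance between uniform points in [0,1]^dim.

    Returns ``(mean, standard_error)``.  In one dimension the exact value
    is 1/3; in the unit square it is about 0.52 and in the unit cube about
    0.66, and it grows with the dimension — the geometric intuition for why
    high-dimensional feature spaces make two random subsets of a small
    sample look different.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    total = 0.0
    total_sq = 0.0
    done = 0
    while done < n_pairs:
        k = min(chunk, n_pairs - done)
        diff = rng.random((k, dim)) - rng.random((k, dim))
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        total += float(d.sum())
        total_sq += float((d * d).sum())
        done += k
    mean = total / n_pairs
    var = max(total_sq / n_pairs - mean * mean, 0.0)
    se = float(np.sqrt(var / n_pairs))
    return mean, se
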