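"""Cross-session ensemble matching and the reactivation statistics.

Similarity between two sessions' ensemble patterns is the cosine (normalized
dot product) of their pattern vectors, which for non-negative vectors lies in
[0, 1] — 0 for completely different ensembles, 1 for identical ones.  An
ensemble of session X is *matched* (reactivated) in session Y when some
pattern of Y exceeds the threshold c (default 0.6, strict inequality).  The
matching score

    MS(X, Y) = (1 / N_X) · Σ_i Θ( max_j  p_i·q_j / (‖p_i‖‖q_j‖)  −  c )

is the fraction of X's patterns reactivated in Y; it is asymmetric in X and Y.
The three-session analysis partitions Day 1 context ensembles by whether they
reactivate during Day 1 rest, and reports within each partition the
percentage that also reactivates in the Day 2 context session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .extract import EnsembleSet
from .synthetic import pattern_cosines


class MatchError(ValueError):
    """Sessions cannot be compared (e.g. neuron identities differ)."""


@dataclass(frozen=True)
class MatchConfig:
    """Similarity threshold c for declaring two patterns the same ensemble."""

    threshold_c: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_c < 1.0:
            raise MatchError(f"threshold_c must lie in (0, 1), got {self.threshold_c}")


@dataclass
class SimilarityMatrix:
    """All pairwise pattern cosines between two sessions, N_X × N_Y."""

    values: np.ndarray
    session_x: str
    session_y: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise MatchError("cosine similarities of non-negative patterns must lie in [0, 1]")


@dataclass
class MatchResult:
    similarity: SimilarityMatrix
    matched_x: np.ndarray          # bool per X ensemble: any partner above c
    matching_score: float
    best_partner_index: np.ndarray  # argmax_j similarity[i, j]
    best_partner_value: np.ndarray
    threshold_c: float


@dataclass
class ReactivationResult:
    """Day 1 ensembles partitioned by rest-session reactivation.

    Percentages are ``None`` (undefined, not 0) when the partition is empty.
    """

    n_reactivated_in_rest: int
    n_nonreactivated_in_rest: int
    pct_reactivated_also_in_day2: float | None
    pct_nonreactivated_also_in_day2: float | None


def _check_alignment(x: EnsembleSet, y: EnsembleSet) -> None:
    if not np.array_equal(x.neuron_ids, y.neuron_ids):
        only_x = sorted(set(x.neuron_ids.tolist()) - set(y.neuron_ids.tolist()))
        only_y = sorted(set(y.neuron_ids.tolist()) - set(x.neuron_ids.tolist()))
        raise MatchError(
            "sessions must share an identical neuron-id ordering; "
            f"only in X: {only_x}, only in Y: {only_y}")


def cosine_similarity_matrix(x: EnsembleSet, y: EnsembleSet) -> SimilarityMatrix:
    """Cosine of every pattern pair across two sessions.

    All-zero pattern vectors (removed during extraction, so defensive only)
    yield similarity 0 by convention.
    """
    _check_alignment(x, y)
    return SimilarityMatrix(pattern_cosines(x.patterns, y.patterns),
                            session_x=x.session_id, session_y=y.session_id)


def matching_score(x: EnsembleSet, y: EnsembleSet,
                   cfg: MatchConfig | None = None) -> MatchResult:
    """Fraction of X's ensembles with a partner in Y strictly above c.

    Asymmetric by construction: MS(X, Y) ≠ MS(Y, X) in general, since only
    X's patterns are in the numerator's denominator N_X.
    """
    if cfg is None:
        cfg = MatchConfig()
    if x.n_ensembles < 1 or y.n_ensembles < 1:
        raise MatchError("matching score needs at least one ensemble per session")
    sim = cosine_similarity_matrix(x, y)
    best = sim.values.max(axis=1)
    matched = best > cfg.threshold_c  # strict: ties at exactly c are unmatched
    return MatchResult(similarity=sim, matched_x=matched,
                       matching_score=float(matched.mean()),
                       best_partner_index=sim.values.argmax(axis=1),
                       best_partner_value=best, threshold_c=cfg.threshold_c)


def classify_matched(x: EnsembleSet, y: EnsembleSet,
                     cfg: MatchConfig | None = None):
    """Matched/unmatched flags for both sessions from one similarity matrix.

    Returns ``(matched_x, matched_y)`` boolean arrays: an ensemble is matched
    iff it has any cross-session partner strictly above the threshold.
    """
    if cfg is None:
        cfg = MatchConfig()
    sim = cosine_similarity_matrix(x, y).values
    return sim.max(axis=1) > cfg.threshold_c, sim.max(axis=0) > cfg.threshold_c


def reactivation_analysis(day1: EnsembleSet, rest: EnsembleSet, day2: EnsembleSet,
                          cfg: MatchConfig | None = None) -> ReactivationResult:
    """Three-session reactivation statistic.

    Each Day 1 context ensemble is matched independently against the rest
    session and against the Day 2 context session (no transitivity assumed).
    Within the rest-reactivated and rest-non-reactivated partitions, the
    percentage also matched in Day 2 is

        100 · (# matched in rest AND in Day 2) / (# [non-]reactivated in rest).

    An empty partition yields ``None`` for its percentage.
    """
    if cfg is None:
        cfg = MatchConfig()
    in_rest, _ = classify_matched(day1, rest, cfg)
    in_day2, _ = classify_matched(day1, day2, cfg)
    n_re = int(in_rest.sum())
    n_non = int((~in_rest).sum())
    pct_re = 100.0 * float((in_rest & in_day2).sum()) / n_re if n_re else None
    pct_non = 100.0 * float((~in_rest & in_day2).sum()) / n_non if n_non else None
    return ReactivationResult(n_reactivated_in_rest=n_re,
                              n_nonreactivated_in_rest=n_non,
                              pct_reactivated_also_in_day2=pct_re,
                              pct_nonreactivated_also_in_day2=pct_non)


def welch_ttest(scores_a, scores_b):
    """Descriptive two-sided Welch t-test between two groups of matching scores.

    Returns ``(t, p)``.  Provided for group-level reporting; the package's
    claims are the scores themselves.
    """
    t, p = stats.ttest_ind(np.asarray(scores_a, dtype=float),
                           np.asarray(scores_b, dtype=float), equal_var=False)
    return float(t), float(p)
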