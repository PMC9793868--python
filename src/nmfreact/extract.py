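"""Neuronal-ensemble extraction by non-negative matrix factorization.

The binned, rectified activity matrix V (time bins × neurons) is factorized
as V ≈ W·H with W ≥ 0 the occurrence matrix (bins × ensembles) and H ≥ 0 the
ensemble pattern (basis) matrix (ensembles × neurons), minimizing the squared
Frobenius reconstruction error ‖V − WH‖²_F by multiplicative updates.  Many
random restarts are attempted and the factorization with the lowest final
cost is kept.  The number of ensembles is selected by the Akaike information
criterion with second-order (small-sample) correction,

    AICc(r) = n·ln(RSS_r / n) + 2k + 2k(k+1)/(n − k − 1),

with n = n_bins × n_neurons Gaussian-residual observations and
k = r·(n_bins + n_neurons) free parameters at rank r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import BinnedMatrix

logger = logging.getLogger("nmfreact")

_EPS = 1e-12          # denominator guard in multiplicative updates
_RSS_FLOOR_REL = 1e-6  # RSS below this fraction of ||V||²_F is treated as exact


class ExtractionError(ValueError):
    """Factorization cannot proceed (e.g. all-zero input)."""


@dataclass(frozen=True)
class FactorizationConfig:
    """Controls the multi-restart NMF and AICc rank search.

    ``n_restarts`` defaults to 1000 random initializations; analyses at desk
    scale typically lower this (each restart is an independent local
    minimization, so fewer restarts only risks a slightly worse local
    optimum).  ``rank_range`` is the inclusive candidate band for the number
    of ensembles.
    """

    n_restarts: int = 1000
    max_iter: int = 500
    rel_tol: float = 1e-6
    rank_range: tuple[int, int] = (1, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ExtractionError("n_restarts must be >= 1")
        lo, hi = self.rank_range
        if not 1 <= lo <= hi:
            raise ExtractionError(f"invalid rank_range {self.rank_range}")


@dataclass
class EnsembleSet:
    """One session's factorization: unit-norm patterns plus occurrences."""

    patterns: np.ndarray      # ensembles × neurons, rows L2-normalized
    occurrences: np.ndarray   # bins × ensembles
    n_ensembles: int
    session_id: str
    cost: float               # final squared-Frobenius reconstruction cost
    neuron_ids: np.ndarray
    cost_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.occurrences = np.asarray(self.occurrences, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=int)
        if np.any(self.patterns < 0) or np.any(self.occurrences < 0):
            raise ExtractionError("NMF factors must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.patterns.shape[1]

    def reconstruction(self) -> np.ndarray:
        return self.occurrences @ self.patterns


@dataclass
class RankSelectionTable:
    """Per-rank AICc scores; ties broken toward the smaller rank."""

    candidate_ranks: np.ndarray
    aicc: np.ndarray
    rss: np.ndarray
    chosen_rank: int

    def to_dict(self) -> dict:
        return {
            "candidate_ranks": [int(r) for r in self.candidate_ranks],
            "aicc": [float(a) for a in self.aicc],
            "rss": [float(r) for r in self.rss],
            "chosen_rank": int(self.chosen_rank),
        }


# ---------------------------------------------------------------------------
# multiplicative-update core


def _restart_rng(seed: int, rank: int, restart: int) -> np.random.Generator:
    # stable per-(rank, restart) stream so a standalone factorization at a
    # given rank reproduces exactly what the rank search computed
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rank, restart)))


def _mu_nmf(V: np.ndarray, rank: int, rng: np.random.Generator,
            max_iter: int, rel_tol: float):
    """One seeded multiplicative-update run; returns (W, H, costs)."""
    n_bins, n_neurons = V.shape
    scale = np.sqrt(V.mean() / rank)
    W = scale * np.abs(rng.standard_normal((n_bins, rank)))
    H = scale * np.abs(rng.standard_normal((rank, n_neurons)))
    norm_v2 = float((V * V).sum())
    costs = []
    prev = np.inf
    for _ in range(max_iter):
        # H step: H <- H * (WᵀV) / (WᵀW H)
        WtV = W.T @ V
        WtW = W.T @ W
        H *= WtV / (WtW @ H + _EPS)
        # W step: W <- W * (VHᵀ) / (W HHᵀ)
        VHt = V @ H.T
        HHt = H @ H.T
        W *= VHt / (W @ HHt + _EPS)
        # cost ‖V − WH‖² via Gram identities (VHt is valid: H unchanged since)
        cross = float((W * VHt).sum())
        quad = float(((W.T @ W) * HHt).sum())
        cost = norm_v2 - 2.0 * cross + quad
        costs.append(cost)
        if prev - cost < rel_tol * max(abs(prev), 1.0e-30):
            break
        prev = cost
    return W, H, np.asarray(costs)


def _best_factorization(V: np.ndarray, rank: int, cfg: FactorizationConfig):
    """Best-of-``cfg.n_restarts`` factorization of V at the given rank."""
    best = None
    for j in range(cfg.n_restarts):
        rng = _restart_rng(cfg.seed, rank, j)
        W, H, costs = _mu_nmf(V, rank, rng, cfg.max_iter, cfg.rel_tol)
        if best is None or costs[-1] < best[2][-1]:
            best = (W, H, costs)
    return best


def nmf_factorize(binned: BinnedMatrix, rank: int,
                  cfg: FactorizationConfig | None = None) -> EnsembleSet:
    """Factorize a binned session at a fixed rank, best of seeded restarts.

    Pattern rows are L2-normalized with the norm folded into the occurrence
    columns, so the reconstruction W·H is unchanged.  All-zero pattern rows
    (components that died during the updates) are dropped.

    Raises
    ------
    ExtractionError
        If the input matrix is all zeros (no ensembles definable) or the
        rank is out of range.
    """
    if cfg is None:
        cfg = FactorizationConfig()
    V = binned.values
    if not np.any(V):
        raise ExtractionError(
            f"session {binned.session_id!r}: input matrix is all zeros, no ensembles definable")
    if not 1 <= rank <= min(V.shape):
        raise ExtractionError(f"rank {rank} outside [1, {min(V.shape)}]")
    W, H, costs = _best_factorization(V, rank, cfg)

    norms = np.linalg.norm(H, axis=1)
    keep = norms > 0
    if not np.all(keep):
        logger.info("nmf_factorize: dropping %d all-zero pattern row(s) at rank %d",
                    int((~keep).sum()), rank)
    H = H[keep] / norms[keep, None]
    W = W[:, keep] * norms[keep][None, :]
    return EnsembleSet(patterns=H, occurrences=W, n_ensembles=int(keep.sum()),
                       session_id=binned.session_id, cost=float(costs[-1]),
                       neuron_ids=binned.neuron_ids, cost_trace=costs)


# ---------------------------------------------------------------------------
# rank selection


def _aicc(rss: float, n: int, k: int, norm_v2: float) -> float:
    # floor near-exact residuals so AICc does not diverge to -inf and the
    # smaller-rank tie-break decides among indistinguishably perfect fits
    rss_eff = max(rss, _RSS_FLOOR_REL * norm_v2)
    return n * np.log(rss_eff / n) + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def select_rank_aicc(binned: BinnedMatrix, cfg: FactorizationConfig | None = None,
                     _keep_models: dict | None = None) -> RankSelectionTable:
    """Pick the number of ensembles by AICc over ``cfg.rank_range``.

    Ranks whose parameter count makes the correction term undefined
    (n − k − 1 ≤ 0) are excluded and logged.  Ties go to the smaller rank.
    """
    if cfg is None:
        cfg = FactorizationConfig()
    V = binned.values
    if not np.any(V):
        raise ExtractionError(
            f"session {binned.session_id!r}: input matrix is all zeros, no ensembles definable")
    n_bins, n_neurons = V.shape
    n = n_bins * n_neurons
    norm_v2 = float((V * V).sum())
    lo, hi = cfg.rank_range
    hi = min(hi, min(V.shape))
    ranks, aiccs, rsss = [], [], []
    for r in range(lo, hi + 1):
        k = r * (n_bins + n_neurons)
        if n - k - 1 <= 0:
            logger.info("select_rank_aicc: rank %d excluded (n - k - 1 = %d <= 0)",
                        r, n - k - 1)
            continue
        W, H, costs = _best_factorization(V, r, cfg)
        rss = float(costs[-1])
        ranks.append(r)
        rsss.append(rss)
        aiccs.append(_aicc(rss, n, k, norm_v2))
        if _keep_models is not None:
            _keep_models[r] = (W, H, costs)
    if not ranks:
        raise ExtractionError("no candidate rank admissible under the AICc correction term")
    ranks_arr = np.asarray(ranks)
    aicc_arr = np.asarray(aiccs)
    chosen = int(ranks_arr[int(np.argmin(aicc_arr))])  # argmin returns first min → smaller rank
    return RankSelectionTable(ranks_arr, aicc_arr, np.asarray(rsss), chosen)


def extract_ensembles(binned: BinnedMatrix,
                      cfg: FactorizationConfig | None = None):
    """Rank selection followed by factorization at the chosen rank.

    Returns ``(EnsembleSet, RankSelectionTable)``.  Fully reproducible under
    ``cfg.seed``: the chosen-rank factorization reuses the same seeded
    restart schedule the rank search evaluated.
    """
    if cfg is None:
        cfg = FactorizationConfig()
    models: dict = {}
    try:
        table = select_rank_aicc(binned, cfg, _keep_models=models)
    except ExtractionError as err:
        raise ExtractionError(f"session {binned.session_id!r}: {err}") from err
    W, H, costs = models[table.chosen_rank]
    norms = np.linalg.norm(H, axis=1)
    keep = norms > 0
    H = H[keep] / norms[keep, None]
    W = W[:, keep] * norms[keep][None, :]
    ens = EnsembleSet(patterns=H, occurrences=W, n_ensembles=int(keep.sum()),
                      session_id=binned.session_id, cost=float(costs[-1]),
                      neuron_ids=binned.neuron_ids, cost_trace=costs)
    return ens, table
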