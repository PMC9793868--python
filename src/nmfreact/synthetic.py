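"""Synthetic calcium-imaging sessions with planted neuronal ensembles.

Emulates the structure the downstream analysis assumes: subsets of neurons
(ensembles) that fire synchronously, each activation producing a calcium
transient (linear rise, exponential decay) on every member neuron, riding on
a constant baseline with slow sinusoidal drift, sparse per-neuron background
transients, and additive Gaussian noise, sampled at 20 frames/s.  Sessions
can share a controllable fraction of their ensembles, mimicking a Day 1 /
Day 2 context-re-exposure design, and every generated object carries the
ground truth needed to score recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import FluorescenceMatrix

__all__ = [
    "SimulationError",
    "SimulationParams",
    "GroundTruthEnsembles",
    "GroundTruthSession",
    "generate_ensembles",
    "generate_session",
    "generate_session_pair",
    "generate_session_trio",
]


class SimulationError(ValueError):
    """Infeasible or invalid simulation request."""


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the session simulator.

    Defaults describe a 90 s session at 20 frames/s with transients of unit
    amplitude (a.u.) on a baseline of 1 a.u. and noise SD 0.1 a.u.
    """

    n_neurons: int = 12
    n_ensembles: int = 3
    neurons_per_ensemble: int = 4
    max_overlap: float = 0.3        # max pairwise cosine between planted patterns
    frame_rate: float = 20.0        # Hz
    duration: float = 90.0          # s
    event_rate: float = 0.2         # ensemble activations per second
    amplitude: float = 1.0          # transient peak, a.u.
    amplitude_jitter_sigma: float = 0.2   # lognormal sigma on event amplitude
    decay_tau: float = 0.5          # s
    rise_frames: int = 2
    baseline: float = 1.0           # a.u.
    noise_sd: float = 0.1           # a.u.
    drift_amplitude: float = 0.05   # a.u.
    drift_freq: float = 0.002       # Hz, must stay well below the 0.01 Hz high-pass
    background_rate: float = 0.02   # independent per-neuron transients per second
    shared_fraction: float = 0.5    # ensembles common to a session pair
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.frame_rate > 0 and self.duration > 0):
            raise SimulationError("frame_rate and duration must be positive")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise SimulationError("shared_fraction must lie in [0, 1]")
        if self.drift_freq >= 0.005:
            raise SimulationError("drift_freq must stay below 0.005 Hz")
        for name in ("event_rate", "amplitude", "noise_sd", "drift_amplitude",
                     "background_rate", "decay_tau", "baseline"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise SimulationError(f"{name} must be finite and non-negative, got {v}")
        if self.rise_frames < 1:
            raise SimulationError("rise_frames must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class GroundTruthEnsembles:
    """Planted ensemble membership weights, ensembles × neurons."""

    membership: np.ndarray
    neuron_ids: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=int)
        if self.membership.ndim != 2:
            raise SimulationError("membership must be 2-D (ensembles × neurons)")
        if np.any(self.membership < 0):
            raise SimulationError("membership weights must be non-negative")
        if np.any((self.membership > 0).sum(axis=1) < 2):
            raise SimulationError("every ensemble needs at least 2 member neurons")

    @property
    def n_ensembles(self) -> int:
        return self.membership.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.membership.shape[1]

    @property
    def pairwise_overlap(self) -> float:
        """Max cosine between distinct planted patterns (0 if fewer than 2)."""
        sims = pattern_cosines(self.membership, self.membership)
        if sims.shape[0] < 2:
            return 0.0
        np.fill_diagonal(sims, -np.inf)
        return float(sims.max())

    def subset(self, indices) -> "GroundTruthEnsembles":
        return GroundTruthEnsembles(self.membership[np.asarray(indices, dtype=int)],
                                    self.neuron_ids)


@dataclass
class GroundTruthSession:
    """One simulated session: traces plus the ground truth that produced them."""

    occurrence_times: list[np.ndarray]   # per-ensemble sorted frame indices
    traces: FluorescenceMatrix
    params: SimulationParams
    ensembles: GroundTruthEnsembles

    def __post_init__(self) -> None:
        n_frames = self.traces.n_frames
        self.occurrence_times = [np.sort(np.asarray(t, dtype=int)) for t in self.occurrence_times]
        for t in self.occurrence_times:
            if t.size and (t.min() < 0 or t.max() >= n_frames):
                raise SimulationError("occurrence times must lie within [0, n_frames)")


def pattern_cosines(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cosine similarity between all row pairs of two non-negative matrices.

    All-zero rows yield similarity 0 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        an = np.where(na > 0, a / na, 0.0)
        bn = np.where(nb > 0, b / nb, 0.0)
    return np.clip(an @ bn.T, 0.0, 1.0)


# ---------------------------------------------------------------------------
# ensembles


def generate_ensembles(n_neurons: int, n_ensembles: int, neurons_per_ensemble: int,
                       max_overlap: float = 0.25, seed: int = 0,
                       rng: np.random.Generator | None = None) -> GroundTruthEnsembles:
    """Plant ``n_ensembles`` weighted neuron subsets with bounded pairwise cosine.

    Member weights are drawn uniformly from [0.6, 1.4] so patterns are
    identifiable but not binary.  ``max_overlap = 0`` forces disjoint supports.

    Raises
    ------
    SimulationError
        If the overlap constraint cannot be satisfied (too many ensembles for
        the neuron count, or rejection sampling exhausts its attempt budget).
    """
    if not 0.0 <= max_overlap < 1.0:
        raise SimulationError(f"max_overlap must lie in [0, 1), got {max_overlap}")
    if neurons_per_ensemble < 2:
        raise SimulationError("neurons_per_ensemble must be >= 2")
    if neurons_per_ensemble > n_neurons:
        raise SimulationError("neurons_per_ensemble cannot exceed n_neurons")
    if rng is None:
        rng = np.random.default_rng(seed)

    membership = np.zeros((n_ensembles, n_neurons))
    if max_overlap == 0.0:
        if n_ensembles * neurons_per_ensemble > n_neurons:
            raise SimulationError(
                f"max_overlap=0 requires disjoint supports: {n_ensembles} ensembles × "
                f"{neurons_per_ensemble} neurons > {n_neurons} available neurons")
        order = rng.permutation(n_neurons)
        for e in range(n_ensembles):
            support = order[e * neurons_per_ensemble:(e + 1) * neurons_per_ensemble]
            membership[e, support] = rng.uniform(0.6, 1.4, neurons_per_ensemble)
    else:
        max_attempts = 5000
        for e in range(n_ensembles):
            for attempt in range(max_attempts):
                cand = np.zeros(n_neurons)
                support = rng.choice(n_neurons, neurons_per_ensemble, replace=False)
                cand[support] = rng.uniform(0.6, 1.4, neurons_per_ensemble)
                if e == 0 or pattern_cosines(cand[None, :], membership[:e]).max() <= max_overlap:
                    membership[e] = cand
                    break
            else:
                raise SimulationError(
                    f"could not place ensemble {e}: pairwise cosine <= {max_overlap} "
                    f"infeasible after {max_attempts} attempts with {n_neurons} neurons "
                    f"and {neurons_per_ensemble} members per ensemble")
    return GroundTruthEnsembles(membership, np.arange(n_neurons))


# ---------------------------------------------------------------------------
# sessions


def _transient_kernel(params: SimulationParams) -> np.ndarray:
    """Unit-peak kernel: linear rise over rise_frames, then exp decay with decay_tau."""
    rise = np.arange(1, params.rise_frames + 1) / params.rise_frames
    n_decay = max(1, int(np.ceil(6.0 * params.decay_tau * params.frame_rate)))
    t = np.arange(1, n_decay + 1) / params.frame_rate
    decay = np.exp(-t / params.decay_tau)
    return np.concatenate([rise, decay])


def _impulse_train(n_frames: int, times: np.ndarray, amps: np.ndarray) -> np.ndarray:
    train = np.zeros(n_frames)
    np.add.at(train, times, amps)
    return train


def generate_session(gt: GroundTruthEnsembles, params: SimulationParams,
                     session_id: str = "",
                     rng: np.random.Generator | None = None,
                     occurrence_times: dict[int, np.ndarray] | None = None) -> GroundTruthSession:
    """Simulate one session of fluorescence traces from planted ensembles.

    The trace of neuron *i* is::

        baseline + drift sinusoid
        + Σ_events  amplitude_jitter · membership[e, i] · kernel(t − t_event)
        + background transients (per-neuron Poisson)
        + N(0, noise_sd)

    Ensemble activation counts are Poisson(event_rate × duration) with
    uniformly distributed times, unless explicit ``occurrence_times``
    (ensemble index → frame indices) are supplied.
    """
    if gt.n_neurons == 0:
        raise SimulationError("ground truth has no neurons")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_frames = params.n_frames
    kernel = _transient_kernel(params)

    # ensemble activations
    occ: list[np.ndarray] = []
    activity = np.zeros((n_frames, gt.n_ensembles))
    for e in range(gt.n_ensembles):
        if occurrence_times is not None and e in occurrence_times:
            times = np.sort(np.asarray(occurrence_times[e], dtype=int))
        else:
            n_events = rng.poisson(params.event_rate * params.duration)
            times = np.sort(rng.integers(0, n_frames, size=n_events))
        amps = params.amplitude * rng.lognormal(0.0, params.amplitude_jitter_sigma, times.size)
        activity[:, e] = np.convolve(_impulse_train(n_frames, times, amps), kernel)[:n_frames]
        occ.append(times)

    values = params.baseline + activity @ gt.membership

    if params.drift_amplitude > 0:
        t = np.arange(n_frames) / params.frame_rate
        phases = rng.uniform(0.0, 2.0 * np.pi, gt.n_neurons)
        values += params.drift_amplitude * np.sin(
            2.0 * np.pi * params.drift_freq * t[:, None] + phases[None, :])

    if params.background_rate > 0:
        for i in range(gt.n_neurons):
            n_bg = rng.poisson(params.background_rate * params.duration)
            if n_bg:
                times = rng.integers(0, n_frames, size=n_bg)
                amps = params.amplitude * rng.lognormal(0.0, params.amplitude_jitter_sigma, n_bg)
                values[:, i] += np.convolve(
                    _impulse_train(n_frames, times, amps), kernel)[:n_frames]

    if params.noise_sd > 0:
        values += rng.normal(0.0, params.noise_sd, values.shape)

    traces = FluorescenceMatrix(values, frame_rate=params.frame_rate,
                                session_id=session_id, neuron_ids=gt.neuron_ids)
    return GroundTruthSession(occ, traces, params, gt)


# ---------------------------------------------------------------------------
# multi-session designs


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _fresh_patterns(n_fresh: int, existing: np.ndarray, params: SimulationParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw fresh patterns with cosine ≤ max_overlap against all existing rows."""
    nn, npe = params.n_neurons, params.neurons_per_ensemble
    rows: list[np.ndarray] = []
    for f in range(n_fresh):
        ref = np.vstack([existing, *rows]) if rows else existing
        for _ in range(50000):
            cand = np.zeros(nn)
            support = rng.choice(nn, npe, replace=False)
            cand[support] = rng.uniform(0.6, 1.4, npe)
            if ref.size == 0 or pattern_cosines(cand[None, :], ref).max() <= params.max_overlap:
                rows.append(cand)
                break
        else:
            raise SimulationError(
                f"could not draw fresh pattern {f}: cosine <= {params.max_overlap} against "
                f"{ref.shape[0]} existing pattern(s) infeasible on {nn} neurons")
    return np.vstack(rows)


def _transversal_fresh(base: "GroundTruthEnsembles", n_fresh: int,
                       params: SimulationParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Fresh patterns over a tiled base: each takes one neuron from ``npe``
    distinct base ensembles (Latin-style transversal), so fresh patterns are
    mutually disjoint and share at most one neuron with any base pattern."""
    n, npe, nn = base.n_ensembles, params.neurons_per_ensemble, params.n_neurons
    # a layout (row shuffles + row order) fixes which base neuron each fresh
    # pattern shares; some layouts force irreducibly high cosines, so retry
    # the whole layout when any pattern cannot meet the bound
    for _layout in range(100):
        rows = [rng.permutation(np.flatnonzero(m > 0)) for m in base.membership]
        row_order = rng.permutation(n)
        patterns = np.zeros((n_fresh, nn))
        ok = True
        for t in range(n_fresh):
            support = np.array([rows[row_order[(t + c) % n]][c] for c in range(npe)])
            for _ in range(500):
                cand = np.zeros(nn)
                cand[support] = rng.uniform(0.6, 1.4, npe)
                if pattern_cosines(cand[None, :], base.membership).max() <= params.max_overlap:
                    patterns[t] = cand
                    break
            else:
                ok = False
                break
        if ok:
            return patterns
    raise SimulationError(
        f"could not place fresh patterns with cosine <= {params.max_overlap} against a "
        f"tiling of {n} ensembles x {npe} neurons; the overlap bound is too tight")


def _session_family(params: SimulationParams, keep_counts: list[tuple[int, int]],
                    rng_gt: np.random.Generator):
    """Base membership for session A plus derived memberships for later sessions.

    ``keep_counts[j] = (n_keep, n_fresh)``: session j reuses the first
    ``n_keep`` of A's patterns and adds ``n_fresh`` new ones.  When the neuron
    count equals n_ensembles × neurons_per_ensemble the base ensembles tile
    the whole population (every recorded cell participates in an ensemble, as
    expected of cells detected from their own activity); otherwise base
    patterns are rejection-sampled under ``max_overlap``.  Fresh patterns are
    rejection-sampled over all neurons under the same bound.
    """
    n, npe, nn = params.n_ensembles, params.neurons_per_ensemble, params.n_neurons
    tiled = nn == n * npe
    base = generate_ensembles(nn, n, npe, 0.0 if tiled else params.max_overlap,
                              rng=rng_gt)
    memberships = []
    prior: list[np.ndarray] = []  # fresh patterns of earlier sessions stay distinct too
    for n_keep, n_fresh in keep_counts:
        kept = base.membership[:n_keep]
        if n_fresh == 0:
            memberships.append(kept)
            continue
        if tiled and npe <= n and n_fresh <= n:
            fresh = _transversal_fresh(base, n_fresh, params, rng_gt)
        else:
            existing = np.vstack([base.membership, *prior]) if prior else base.membership
            fresh = _fresh_patterns(n_fresh, existing, params, rng_gt)
        prior.append(fresh)
        memberships.append(np.vstack([kept, fresh]) if n_keep else fresh)
    return base, memberships


def generate_session_pair(params: SimulationParams, shared_fraction: float | None = None,
                          seed: int | None = None):
    """Two sessions sharing ``round(shared_fraction × n_ensembles)`` ensembles.

    Emulates Day 1 / Day 2 exposure to the same context: some ensembles recur
    identically, the rest are session-specific with pairwise cosine bounded by
    ``params.max_overlap`` (kept below the matching threshold).  Session B's
    ensemble order is shuffled so matching is non-trivial.

    Returns
    -------
    (session_a, session_b, shared_map)
        ``shared_map`` maps session A ensemble index → session B ensemble
        index for each shared ensemble.  The ideal matching score of A
        against B is ``len(shared_map) / n_ensembles``.
    """
    if shared_fraction is None:
        shared_fraction = params.shared_fraction
    if seed is None:
        seed = params.seed
    if not 0.0 <= shared_fraction <= 1.0:
        raise SimulationError("shared_fraction must lie in [0, 1]")
    n = params.n_ensembles
    n_shared = int(round(shared_fraction * n))

    rng_gt, rng_a, rng_b, rng_perm = _child_rngs(seed, 4)
    base, (memb_b,) = _session_family(params, [(n_shared, n - n_shared)], rng_gt)

    perm = rng_perm.permutation(n)
    gt_a = GroundTruthEnsembles(base.membership, base.neuron_ids)
    gt_b = GroundTruthEnsembles(memb_b[perm], base.neuron_ids)
    shared_map = {int(i): int(np.flatnonzero(perm == i)[0]) for i in range(n_shared)}

    ses_a = generate_session(gt_a, params, session_id="day1_context", rng=rng_a)
    ses_b = generate_session(gt_b, params, session_id="day2_context", rng=rng_b)
    return ses_a, ses_b, shared_map


def generate_session_trio(params: SimulationParams, n_rest_shared: int,
                          n_day2_from_rest: int, n_rest_fresh: int = 0,
                          n_day2_fresh: int = 0, seed: int | None = None):
    """Day 1 context / Day 1 rest / Day 2 context design with planted reactivation.

    Of the ``params.n_ensembles`` Day 1 ensembles, the first ``n_rest_shared``
    recur in the rest session and the first ``n_day2_from_rest`` of *those*
    recur again on Day 2; optional fresh ensembles pad rest and Day 2.

    Returns
    -------
    (day1, rest, day2, rest_map, day2_map)
        Maps from Day 1 ensemble index to the index in the rest / Day 2
        session.
    """
    n = params.n_ensembles
    if not 0 <= n_day2_from_rest <= n_rest_shared <= n:
        raise SimulationError("need 0 <= n_day2_from_rest <= n_rest_shared <= n_ensembles")
    rng_gt, rng_1, rng_r, rng_2 = _child_rngs(params.seed if seed is None else seed, 4)
    base, (memb_r, memb_2) = _session_family(
        params, [(n_rest_shared, n_rest_fresh), (n_day2_from_rest, n_day2_fresh)], rng_gt)

    ids = base.neuron_ids
    day1 = generate_session(GroundTruthEnsembles(base.membership, ids), params,
                            session_id="day1_context", rng=rng_1)
    rest = generate_session(GroundTruthEnsembles(memb_r, ids), params,
                            session_id="day1_rest", rng=rng_r)
    day2 = generate_session(GroundTruthEnsembles(memb_2, ids), params,
                            session_id="day2_context", rng=rng_2)
    rest_map = {i: i for i in range(n_rest_shared)}
    day2_map = {i: i for i in range(n_day2_from_rest)}
    return day1, rest, day2, rest_map, day2_map
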