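# Methods

## Scope and model

`nmfreact` implements the trace-level analysis used to quantify reactivation
of hippocampal neuronal ensembles across calcium-imaging sessions.  Its input
is a per-session fluorescence matrix F (frames × neurons) with consistent
neuron identity across sessions (as produced upstream by cell-identification
tools such as CNMF-E run on concatenated movies); movie-level processing
(motion correction, spatial filtering, cell segmentation) is out of scope.

The processing chain, in order:

1. **ΔF/F** — per neuron, ΔF(t)/F0 = (F(t) − F0)/F0 with F0 the neuron's
   mean fluorescence over the whole session.  Undefined (error) if any
   F0 = 0.
2. **Event counting** (reported descriptively, not used downstream) — a
   Ca²⁺ event is an upward crossing of the per-neuron threshold
   max(0.01 a.u., 3 × SD), SD taken over the entire session.  The threshold
   conditions define *when* activity counts; what constitutes *one* event is
   a modelling decision: we count rising-edge crossings with a 10-frame
   (0.5 s at 20 frames/s) refractory period, so a multi-peaked burst counts
   once.  SD is per neuron, since amplitudes vary strongly by cell.
3. **High-pass filter, 0.01 Hz** — 4th-order Butterworth applied
   forward–backward (zero phase, so event times are not shifted).  The
   effective padding is set to ~3 filter time constants (~950 frames at
   20 Hz); the default `scipy` padding of a dozen frames is far too short
   for so low a cutoff and leaks large edge transients that masquerade as
   shared structure across neurons.
4. **Rectified z-score** — per neuron: subtract session mean, divide by
   session SD, set negatives to zero.  Zero-SD neurons become all-zero
   columns (logged).  Rectification provides the non-negativity NMF needs.
5. **Binning** — mean over every 4 frames (200 ms at 20 frames/s); a
   trailing partial bin is dropped.  The mean (not sum) keeps values on the
   z-score scale; a sum aggregator is available.
6. **NMF** — the binned matrix V (bins × neurons) is factorized as
   V ≈ W·H, W ≥ 0 the occurrence matrix (bins × ensembles), H ≥ 0 the
   ensemble pattern matrix (ensembles × neurons), minimizing ‖V − WH‖²_F by
   multiplicative updates (monotone; denominators guarded by 1e−12).  A
   restart draws W, H entries as |N(0, 1)| scaled to the data mean; the best
   of `n_restarts` (default 1000; studies here use 15–50) final costs wins.
   A restart stops when the relative cost change is below `rel_tol`
   (default 1e−6) or after `max_iter` = 500 iterations.  Pattern rows are
   L2-normalized with norms folded into W, leaving the reconstruction
   unchanged; all-zero rows are dropped.
7. **Rank selection** — the number of ensembles minimizes the small-sample
   corrected Akaike criterion
   AICc(r) = n·ln(RSS_r/n) + 2k + 2k(k+1)/(n−k−1), with n = n_bins·n_neurons
   Gaussian-residual observations and k = r·(n_bins + n_neurons) free
   parameters.  Ranks with n − k − 1 ≤ 0 are excluded; ties break toward the
   smaller rank.  RSS is floored at 1e−6·‖V‖²_F before the log so that
   (near-)exact factorizations at different ranks tie instead of sending the
   likelihood term to −∞ (otherwise any noiseless input would select the
   largest candidate rank on meaningless sub-precision residuals).
8. **Matching** — similarity of two patterns is their cosine (normalized dot
   product), in [0, 1] for non-negative vectors; all-zero patterns get 0 by
   convention.  An ensemble of session X is *reactivated* in Y if some
   pattern of Y exceeds the threshold c = 0.6 — strictly, so a tie at
   exactly c is unmatched.  The matching score MS(X, Y) is the fraction of
   X's patterns reactivated in Y; it is asymmetric.  The three-session
   analysis partitions Day 1 context ensembles by reactivation in the Day 1
   rest session and reports, per partition, the percentage also reactivated
   in the Day 2 context session; an empty partition yields an undefined
   (None) percentage, never 0.

## Synthetic sessions

The generator emulates what the analysis assumes about the data rather than
the raw optics: co-active neuron subsets, calcium-transient kinetics, slow
drift, and noise.  A session is

    baseline + drift + Σ ensemble transients + background transients + noise

with ensemble activations Poisson(`event_rate` × duration) at uniform times,
each activation adding a membership-weighted kernel (linear rise over
`rise_frames`, exponential decay with `decay_tau`) to every member neuron,
scaled by a shared lognormal amplitude jitter (σ = 0.2) so NMF weights are
identifiable but not binary.  Background clutter is independent per-neuron
Poisson transients.  Drift is a per-neuron-phase sinusoid well below the
high-pass cutoff, specifically to exercise that stage.  All randomness flows
from one seeded generator per call; fixed seed ⇒ byte-identical output.

Defaults (units; rationale):

| parameter | default | note |
|---|---|---|
| frame_rate | 20 Hz | acquisition rate of the emulated recordings |
| duration | 90 s | desk-scale context session |
| n_neurons / n_ensembles / per-ensemble | 12 / 3 / 4 | tiled population, see below |
| event_rate | 0.2 s⁻¹ | ensemble activations during active exploration |
| amplitude / baseline | 1.0 / 1.0 a.u. | transient peak ≈ baseline, typical for GCaMP ΔF/F ≈ 1 |
| noise_sd | 0.1 a.u. | event SNR 10 |
| decay_tau / rise_frames | 0.5 s / 2 | GCaMP-like kinetics |
| drift | 0.05 a.u. at 0.002 Hz | slow baseline wander |
| background_rate | 0.02 s⁻¹ | sparse independent transients |
| max_overlap | 0.3 | max pairwise cosine between planted patterns |

Session pairs copy `round(shared_fraction × n_ensembles)` patterns verbatim
into session B (shuffled order) and draw the rest fresh under the overlap
bound, so the ideal matching score is known exactly.  When
n_neurons = n_ensembles × neurons_per_ensemble the base session's ensembles
*tile* the population — every neuron belongs to exactly one ensemble — and
fresh patterns take one neuron from each of several base ensembles
(transversal construction), guaranteeing single-neuron overlaps.  The trio
generator plants the Day 1 / rest / Day 2 design with chosen reactivation
counts.

## What the simulations do and do not show

The rectified z-score stage makes recovery sensitivities explicit, and two
findings shaped the default study conditions:

- **Near-silent neurons become structure.**  Z-scoring rescales every neuron
  to unit variance, so a neuron belonging to no ensemble is pure amplified
  noise plus solo background transients — genuine sparse non-negative
  structure that AICc legitimately counts as additional patterns.  Real
  cell-identification pipelines only emit cells with actual activity, so the
  planted-rank studies use tiled populations (every neuron a member).
- **Rectified noise is not white.**  Clipping noise at the (negative)
  between-event baseline leaves a dense positive floor whose conditional
  mean varies with signal occupancy; at low event rates or extreme noise
  this floor is itself a detectable component.  With the default event rate
  and SNR the floor stays below the AICc penalty (≈ 2(n_bins+n_neurons)
  observations' worth of log-likelihood per rank) and the planted rank is
  recovered in ≥ 90 % of seeded replicates.

Pattern recovery (cosine between planted and recovered patterns) is robust
across all of these regimes (≈ 0.97–0.99 per pattern); only the *count* of
ensembles is delicate.  The generator does not model pixel-level artifacts,
motion, spike inference, or amplitude adaptation, so passing tests certify
the trace-level statistics, not upstream processing.

Study sizes (chosen once as desk-scale conditions): rank/pattern recovery
uses 20 seeded 90 s sessions (12 neurons, 3 tiled ensembles, 50 restarts,
ranks 1–6); shared-fraction recovery uses 20 session pairs (40 neurons, 10
tiled ensembles, sharing 0.5, 15 restarts, ranks 6–14); the group study
simulates 4 "control" (sharing 0.30) and 4 "anesthesia" (sharing 0.10) mice
with the same settings and compares mean matching scores by a two-sided
Welch t-test.  Restart counts in these studies stand in for the production
default of 1000 restarts; each restart is an independent seeded local
minimization, so fewer restarts only risks slightly worse local optima.

## Numerical choices

- Multiplicative updates guarantee monotone cost; tests allow a 1e−9
  relative slack for floating-point jitter.
- Cost is evaluated per iteration from Gram matrices
  (‖V‖² − 2⟨W, VHᵀ⟩ + ⟨WᵀW, HHᵀ⟩), avoiding a full reconstruction.
- Per-restart seeds derive from `SeedSequence(seed, spawn_key=(rank, restart))`,
  so a standalone factorization at the chosen rank reproduces exactly what
  the rank search computed.
- The pipeline derives per-stage seeds by hashing stage names into the run
  seed (CRC-32, masked to 31 bits), so stages can be re-run in isolation.
- Zero-SD columns: z-scoring maps them to zero (logged); event detection
  reports 0 events; an all-zero binned matrix is an explicit error (no
  ensembles definable).
- Degenerate similarity: all-zero pattern vectors have cosine 0 by
  convention (defensive; extraction removes such rows).

## Known limitations

- AICc rank selection inherits the Gaussian-residual assumption, which
  rectified data violate; the RSS floor and the study conditions above are
  the package's mitigations, and the rank table (with RSS and AICc per
  candidate) is always returned so alternative criteria can be audited.
- The matching threshold c = 0.6 is a fixed operating point, not estimated;
  scores near the threshold are sensitive to extraction noise.
- Group-level statistics (Welch t-test) are descriptive output only.
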