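# Methods

`lfpdecode` implements an end-to-end pipeline for decoding a continuous
force signal from multichannel local field potentials (LFP): a synthetic
session generator with known ground truth, a band-power feature pipeline,
two decoders (PLS-1 and a stack LSTM), and a cross-validated evaluation
harness. This note records the models, the parameters that matter, and the
design decisions taken where the design was genuinely open.

## The decoding problem

A subject presses a force sensor; simultaneously, 16 channels of
motor-cortex LFP are recorded at 1000 Hz. Each trial is the 3 s window
from 1 s before to 2 s after the moment the force crosses a 0.15 N
threshold, i.e. a `(3000, 16)` voltage matrix paired with a length-3000
force trace. The decoder's task is to predict the force trajectory from
the LFP alone — a regression from high-dimensional, noisy, temporally
structured features to a non-negative 1-D signal.

## Synthetic sessions

Recordings of this kind are rarely public, so the generator is a
first-class module, not a test fixture. It produces sessions in which
**band power is the information channel by construction**, which is
exactly the assumption the feature pipeline makes:

- For every band `b` (δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–120, high-γ
  120–200 Hz) and channel `c`, white noise is band-passed with the same
  zero-phase filter bank used in preprocessing, normalized to unit RMS,
  and amplitude-modulated by `baseline + g[b,c] · f(force(t))`. The LFP is
  the sum over bands.
- `f` is either the identity (newtons) or the saturating map
  `f(x) = x/(x + k)` with `k` the 0.15 N threshold. The saturating variant
  gives the nonlinear decoder something a linear model cannot fit exactly.
- All channels share one common-mode noise trace (sd 0.5 in carrier RMS
  units) — the component CAR removes — plus independent wideband channel
  noise (sd 0.3).
- The clean force profile is a smooth cosine-ramp press: flat zero, a
  monotone rise that passes the threshold **exactly** at t = 1 s (the
  amplitude is solved from the randomized rise geometry so the crossing
  sample equals the threshold), a peak at 1.1–1.9 × threshold, and a
  monotone decay. Observed force adds 2 mN low-pass Gaussian noise,
  truncated at zero (force sensors do not go negative) and faded out near
  the crossing so each trial keeps exactly one upward crossing at t = 1 s.
- A configurable `coupling_lead` shifts the envelope forward in time so
  the simulator can create sessions where neural activity *leads* force —
  the ground truth regime where explicit time lags must help.
- Default coupling gains rise with frequency (1.0 … 6.0 from δ to high-γ),
  placing most decodable signal in the β/γ/high-γ bands, the regime
  typically reported for motor cortex.

Everything is derived from one seed through `numpy.random.SeedSequence`,
so a session regenerates bit-identically.

What the generator does *not* emulate: spikes and the 10 kHz raw stream,
1/f background spectra, electrode drift, cross-channel correlation
structure beyond the common-mode trace, and behavioral variability beyond
randomized press geometry. Tests passing on these sessions therefore show
that the pipeline recovers band-power-encoded force under realistic noise
— not that real cortical LFP encodes force this way.

Because all trials are presses of the same shape, the concatenated force
target is *stereotyped*: a features-blind predictor that outputs the mean
training profile already achieves a high R² (~0.95 on the reference
session). Chance level for leakage diagnostics is therefore that
stereotype score, not zero, and the lag expansion's zero-padded boundary
rows (which implicitly encode time-within-trial) alone are worth a small
positive R² on zero-coupling sessions. Both effects are asserted in the
test suite.

## Feature pipeline

Per trial: common average reference (subtract the instantaneous
cross-channel mean) → 4th-order Butterworth band-pass per band, applied
forward-backward (`sosfiltfilt`, zero phase, so envelopes are not delayed
against force) → absolute value → Savitzky–Golay smoothing (3rd order,
151-sample window) → block-mean downsampling by 100 → a `(30, 96)` matrix
(features band-major: column = band·16 + channel) and, from the force
trace, a 5 Hz zero-phase low-pass followed by decimation to 30 targets.
Features are z-scored per column with statistics estimated on training
trials only, to keep cross-validation leak-free.

Numerical choices:

- *Savitzky–Golay window*: an even window (150) is undefined for the
  filter; 151 is the nearest valid odd width (configurable).
- *Normalization order*: z-scoring is applied after downsampling (its
  signature operates on `(30, 96)` tensors). Since block-means commute
  with affine maps, this differs from normalizing at 1000 Hz only in the
  std estimate, which the per-column scale absorbs.
- *Downsampling*: block means for envelopes (already smooth, alias-safe);
  low-pass + decimate for force, whose threshold crossing at t = 1 s lands
  on target index 10.
- *Lag expansion* for linear decoders: row `t` concatenates feature rows
  `t … t−9` (lag-major blocks, 960 columns). Rows before trial start are
  zero-filled and lags never cross trial boundaries, preserving 30 targets
  per trial and trial independence.

## PLS-1 decoder

The estimator is the classical stepwise recursion for a univariate
response: `w = X'y`, `t = Xw`, `p = X't/t't`, `q = y't/t't`, deflation
`X ← X − tp'`, `y ← y − tq`, repeated `l` times; then
`β = W(P'W)⁻¹Q`, `β₀ = q₁ − p₁'β`. With all components on full-rank X
this reproduces unregularized least squares (a test asserts it), and a
degenerate score (`t't ≤ 1e−12·‖X‖²_F`) stops extraction early.

The raw recursion deliberately contains no centering step. In the
pipeline, however, X columns are z-scored (mean zero over training rows),
so `Xβ` cannot represent the positive mean of the force target and the
printed intercept collapses toward zero; left uncentered, held-out R²
saturates well below what the features support. The model therefore
exposes a `center` flag — off by default at the estimator level, **on in
the cross-validation pipeline** — which subtracts training means of X and
y before the recursion and restores them at prediction. This is the
package's own choice of intercept handling; the uncentered behavior
remains available and tested.

Model order is selected by Wold's criterion: PRESS(l), the out-of-fold
squared error from a seeded 10-fold cross-validation *within the training
set* (folds are trial-blocked, since rows within a trial are dependent),
and the smallest `l` with `PRESS(l+1)/PRESS(l) ≥ 0.9` wins — adding a
component that buys less than a 10 % error reduction is not worth it. If
the ratio never reaches the threshold, `max_l` is returned flagged. The
PRESS curve is computed from one `max_l` fit per fold and truncated per
`l`; a test verifies this equals literal refitting, exactly.

## Stack LSTM decoder

The cell is intentionally *not* the textbook LSTM. With
`z = [y⟨t−1⟩, x⟨t⟩]`:

    C̃ = tanh(W_c z)
    Γ_u, Γ_f, Γ_o = σ(W_u z), σ(W_f z), σ(W_o z)
    C⟨t⟩ = Γ_u ⊙ C̃ + Γ_f ⊙ C⟨t−1⟩
    y⟨t⟩ = Γ_o ⊙ C⟨t⟩

No bias terms, and no tanh on the output — the carry passes to the output
gated but unsquashed. This formulation is the package's reference
implementation; a `variant="standard"` flag restores biases and the
output tanh for comparison (biases are implemented as an extra constant
column of `z`, so the same backward pass covers both variants).

Architecture: 96 inputs → 30-unit layer → 15-unit layer → one dense
neuron with ReLU, one prediction per time step. ReLU clamps predictions
at zero, matching the force sensor's floor — a linear readout instead
fluctuates around zero at rest. State starts at zero at each trial start,
and prediction at step `t` cannot depend on inputs after `t` (a causality
test asserts this).

Training: mean absolute error (robust to envelope noise) plus an L2
penalty on the dense weights only; Adam with β₁ = 0.9, β₂ = 0.999;
batches are whole trials; dropout is variational — one mask per sequence
per batch — on both the forward input and the recurrent path of each
layer, with inverted scaling so inference needs no correction. Gradients
are exact hand-derived backpropagation through time, verified against
central finite differences in the test suite (both variants, with and
without dropout). Weights are seeded Glorot-uniform; the whole procedure
is deterministic given its seed. Forward and backward passes are written
in NumPy — the model is small enough (≈19k weights, 30-step sequences)
that batched matrix products at this scale train a session-sized fold in
seconds on one CPU.

Hyper-parameters come from a fixed discrete grid (four dropout rates
0–0.5; readout L2 0–0.9; learning rate 0.001–0.003; batch size 5–30;
epochs 30–120) and are chosen by seeded random search over that grid,
scored by validation R² on a held-out 20 % of the training trials. The
default budget is 30 evaluations; study-scale runs in this repository
use a budget of 5 with epochs capped at 50, which on the reference
synthetic sessions already separates configurations cleanly.

## Evaluation harness

Seven-fold, trial-level cross-validation with identical folds for every
compared method. Per fold, normalization statistics, Wold selection and
the hyper-parameter search see training trials only. A fold's test trials
are concatenated before scoring (per-trial scoring is available) with
Pearson's r and R² = 1 − SSE/SST. Paired method comparisons use the
two-sided Wilcoxon signed-rank test on per-fold scores, exact null for
≤ 25 pairs, zero differences dropped; with 7 folds the smallest
attainable two-sided p is 2/2⁷ ≈ 0.0156.

Band contributions are read from the first LSTM layer: for each band, the
absolute values of the 16 corresponding input columns of all four gate
matrices are summed and normalized by the grand total, giving a
probability vector over bands (averaged across fold models when several
are supplied).

## Problem sizes used in the shipped experiments

Reference sessions use 74 trials (mirroring typical session sizes for
this task), 7-fold CV, PLS `max_l` 15, and the reduced LSTM search budget
described above. The acceptance script regenerates all sessions from its
`--seed`, runs both decoders and both ablations, and writes every metric
it computes; on one CPU it completes in a few minutes.

## Known limitations

- The generator's coupling model (multiplicative envelope gain, per-band
  scalar profile) is an assumption; real LFP–force coupling is not
  characterized to this level, so parameter-recovery results speak to the
  pipeline, not to cortex.
- PRESS-based Wold selection inherits the variance of its inner 10-fold
  split; with strongly correlated lagged features the selected component
  count can vary by ±1 across seeds.
- The random-search tuner does not model the response surface; with tiny
  budgets it is a uniform sample of the grid. That is adequate for the
  shipped experiments and keeps the dependency surface to NumPy/SciPy.
- Only univariate-response PLS-1 is implemented (no PLS-2/SIMPLS), and
  only the two recurrent variants described above (no GRU/plain RNN).
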