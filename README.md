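# lfpdecode

Decoding continuous force from multichannel local field potentials (LFP).

During fine motor acts like grasping, the pressure a subject applies to an
object is encoded in the spectral power of motor-cortex LFP. This package
implements a complete decoding pipeline for that setting — 16-channel LFP
at 1000 Hz, trials of 3 s windowed around a 0.15 N force-threshold
crossing — for researchers building continuous brain–computer interfaces
or studying force representation in motor cortex:

- **Synthetic sessions with ground truth** (`lfpdecode.simulate`): trials
  whose band-limited carriers are amplitude-modulated by a latent force
  profile through a known coupling `baseline + g[band, channel]·f(force)`,
  with common-mode noise, channel noise and a zero-truncated observed
  force. Everything regenerates bit-identically from one seed.
- **Band-power features** (`lfpdecode.preprocess`): common average
  reference → zero-phase Butterworth bank (δ, θ, α, β, γ, high-γ) →
  rectification + Savitzky–Golay smoothing → downsampling to a `(30, 96)`
  feature matrix and 30 force targets per trial, plus the 10-lag expansion
  (960 columns) used by linear decoders.
- **PLS-1** (`lfpdecode.pls`): the stepwise partial-least-squares
  recursion for a univariate response, written from scratch
  (`w = X'y`, `t = Xw`, deflation, `β = W(P'W)⁻¹Q`), with the number of
  latent components chosen by Wold's criterion
  `PRESS(l+1)/PRESS(l) ≥ 0.9` over a trial-blocked inner cross-validation.
- **Stack LSTM** (`lfpdecode.lstm`): a bias-free cell
  (`C = Γ_u⊙tanh(W_c z) + Γ_f⊙C_prev`, `y = Γ_o⊙C`, no output tanh),
  stacked 96 → 30 → 15 → 1 with a ReLU readout so predicted force is
  non-negative by construction; trained with MAE + Adam, whole-trial
  batches, variational forward/recurrent dropout, exact hand-derived
  backpropagation through time in NumPy, and seeded random search over a
  discrete hyper-parameter grid.
- **Evaluation** (`lfpdecode.evaluate`): seven-fold trial-level
  cross-validation with shared folds across methods, Pearson r and
  R² = 1 − SSE/SST on concatenated test trials, exact Wilcoxon
  signed-rank comparisons, a PLS lag-count sweep, and the per-band
  contribution of first-layer LSTM weights.

Model objects follow a fit/results convention: `PLS1Model(X, y).fit(l)`
and `ForceLSTM(features, targets).fit(hp)` return results objects carrying
estimates, diagnostics, `predict()` and `summary()`.

## Worked example

```python
import numpy as np
from lfpdecode import (SyntheticConfig, generate_session,
                       extract_session_features, kfold_split, run_experiment)

config = SyntheticConfig(n_trials=21, seed=42, output_nonlinearity="saturating")
trials, truth = generate_session(config)              # 21 x (3000, 16) LFP + force
features, targets = extract_session_features(trials)  # 21 x (30, 96) and (30,)
folds = kfold_split(len(trials), k=7, seed=0)

pls = run_experiment((features, targets), "pls", folds, seed=0)
print(pls.summary())
```

```
7-fold CV — pls
========================================
fold    r        R^2      settings
   0   0.991    0.979    4
   1   0.980    0.959    4
   2   0.990    0.980    4
   3   0.987    0.973    4
   4   0.989    0.976    4
   5   0.987    0.972    4
   6   0.982    0.964    4
mean   0.986    0.972   (sd 0.004 / 0.008)
```

Per fold: Wold's criterion selected 4 latent components (the `settings`
column), and the held-out force trace is reconstructed with r ≈ 0.99 and
R² ≈ 0.97 — on this synthetic session the 10-lag band-power features carry
essentially the whole force signal. Swapping `"pls"` for `"lstm"` runs the
recurrent decoder with its inner hyper-parameter search on the same folds;
`compare_methods(pls, lstm)` then reports the exact paired Wilcoxon test
(with 7 folds the smallest attainable two-sided p is 2/2⁷ ≈ 0.016).

The same pipeline is scriptable from a shell:

```bash
lfpdecode simulate --out sess/ --n-trials 74 --seed 1
lfpdecode extract  --session sess/ --out feats/ --lags 10
lfpdecode run      --features feats/ --method pls  --out runs/pls
lfpdecode run      --features feats/ --method lstm --out runs/lstm --budget 5 --epoch-cap 50
lfpdecode compare  runs/pls/results_pls.csv runs/lstm/results_lstm.csv
```

## Layout

```
src/lfpdecode/
  simulate.py     synthetic sessions with known coupling (ground truth kept)
  preprocess.py   CAR, filter bank, envelopes, downsampling, lags, z-scoring
  pls.py          PLS-1 model/results + PRESS / Wold selection
  lstm.py         bias-free stack LSTM: forward, BPTT, Adam, dropout, search
  evaluate.py     k-fold harness, metrics, lag sweep, band contribution, Wilcoxon
  cli.py          simulate / extract / run / compare commands
docs/methods.md   models, assumptions, parameter choices, limitations
```
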