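"""Feature extraction for multichannel LFP trials.

The pipeline turns a raw trial — a ``(time, channel)`` voltage matrix at
1000 Hz together with a simultaneously sampled force trace — into the
feature/target pair the decoders consume:

1. common average reference (CAR) across channels,
2. zero-phase Butterworth decomposition into six canonical bands
   (delta 1–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–120,
   high-gamma 120–200 Hz),
3. full-wave rectification followed by Savitzky–Golay smoothing of each
   band envelope,
4. 100-fold downsampling, flattening band × channel to one feature row
   per 100 ms,
5. per-column z-scoring with statistics estimated on training trials only.

For a 3 s, 16-channel trial this yields a ``(30, 96)`` feature matrix and a
length-30 force target at 10 Hz.  Linear decoders additionally expand the
features with explicit time lags (:func:`build_lag_matrix`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "NormalizationStats",
    "car_filter",
    "bandpass_bank",
    "rectify_smooth",
    "fit_normalizer",
    "apply_normalizer",
    "downsample_features",
    "downsample_force",
    "extract_features",
    "build_lag_matrix",
    "feature_index",
]


@dataclass(frozen=True)
class BandDefinition:
    """One pass-band of the filter bank, edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0.0 < self.low < self.high:
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 120.0),
    BandDefinition("high_gamma", 120.0, 200.0),
)


def feature_index(band: int, channel: int, n_channels: int = 16) -> int:
    """Column of (band, channel) in the flattened feature matrix.

    Ordering is band-major: columns ``b * n_channels .. (b+1) * n_channels - 1``
    hold band ``b`` across channels.  Kept as the single source of truth so the
    per-band weight grouping in the contribution analysis cannot drift.
    """
    return band * n_channels + channel


def car_filter(lfp: np.ndarray) -> np.ndarray:
    """Common average reference: subtract the cross-channel mean per sample.

    Removes any signal component shared identically by all channels
    (common-mode noise).  Idempotent, and exactly invariant to adding the
    same trace to every channel.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.ndim != 2 or lfp.shape[1] < 2:
        raise ValueError("CAR needs a (time, channel) matrix with >= 2 channels")
    return lfp - lfp.mean(axis=1, keepdims=True)


def _design_bank(
    bands: Sequence[BandDefinition], fs: float, order: int
) -> list[np.ndarray]:
    nyq = fs / 2.0
    sos = []
    for b in bands:
        if b.high >= nyq:
            raise ValueError(
                f"band {b.name!r} upper edge {b.high} Hz >= Nyquist {nyq} Hz"
            )
        sos.append(signal.butter(order, [b.low, b.high], btype="bandpass", fs=fs, output="sos"))
    return sos


def bandpass_bank(
    lfp: np.ndarray,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    fs: float = 1000.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase band decomposition.

    Each band is a 4th-order Butterworth band-pass applied forward and
    backward (``sosfiltfilt``), so the output is acausal and phase-free:
    band envelopes are not delayed relative to the force trace.

    Returns an array of shape ``(n_bands, n_time, n_channels)``.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.ndim != 2:
        raise ValueError("expected a (time, channel) matrix")
    out = np.empty((len(bands), lfp.shape[0], lfp.shape[1]))
    for i, sos in enumerate(_design_bank(bands, fs, order)):
        out[i] = signal.sosfiltfilt(sos, lfp, axis=0)
    return out


def rectify_smooth(
    band_signals: np.ndarray, sg_order: int = 3, sg_window: int = 151
) -> np.ndarray:
    """Band-power envelope: absolute value then Savitzky–Golay smoothing.

    The polynomial smoother preserves local extrema better than a moving
    average.  ``sg_window`` must be odd and larger than ``sg_order``; the
    default 151 samples is 151 ms at 1000 Hz.
    """
    if sg_window % 2 == 0:
        raise ValueError(f"Savitzky–Golay window must be odd, got {sg_window}")
    if sg_window <= sg_order:
        raise ValueError("Savitzky–Golay window must exceed the polynomial order")
    x = np.abs(np.asarray(band_signals, dtype=float))
    return signal.savgol_filter(x, sg_window, sg_order, axis=-2)


@dataclass
class NormalizationStats:
    """Per-feature-column mean and standard deviation, fit on training data."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        bad = np.flatnonzero(~(self.std > 0))
        if bad.size:
            raise ValueError(f"zero/invalid std in feature column(s) {bad.tolist()}")


def fit_normalizer(feature_tensors: Sequence[np.ndarray]) -> NormalizationStats:
    """Estimate z-scoring statistics over the stacked rows of training trials.

    Statistics must come from training trials only; applying them to held-out
    trials avoids test-set leakage in cross-validation.
    """
    stacked = np.vstack([np.asarray(f, dtype=float) for f in feature_tensors])
    if stacked.shape[0] < 2:
        raise ValueError("need at least 2 rows to estimate normalization statistics")
    return NormalizationStats(stacked.mean(axis=0), stacked.std(axis=0))


def apply_normalizer(stats: NormalizationStats, features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.shape[-1] != stats.mean.shape[0]:
        raise ValueError("feature column count does not match normalizer")
    return (features - stats.mean) / stats.std


def downsample_features(envelopes: np.ndarray, factor: int = 100) -> np.ndarray:
    """Block-mean downsample envelopes and flatten to ``(n_blocks, bands*channels)``.

    Envelopes are already low-pass by construction (rectified + smoothed), so
    the mean of each non-overlapping block is alias-safe.  Column ordering is
    band-major (see :func:`feature_index`).
    """
    env = np.asarray(envelopes, dtype=float)
    n_bands, n_time, n_ch = env.shape
    if n_time % factor:
        raise ValueError(f"time length {n_time} not divisible by factor {factor}")
    n_blocks = n_time // factor
    blocks = env.reshape(n_bands, n_blocks, factor, n_ch).mean(axis=2)
    # (band, block, ch) -> (block, band, ch) -> (block, band*ch)
    return blocks.transpose(1, 0, 2).reshape(n_blocks, n_bands * n_ch)


def downsample_force(
    force_raw: np.ndarray,
    fs: float = 1000.0,
    factor: int = 100,
    cutoff: float = 5.0,
    order: int = 4,
) -> np.ndarray:
    """Low-pass the force trace (zero-phase Butterworth) and decimate.

    Force has negligible content above a few Hz; a 5 Hz cut-off followed by
    taking every ``factor``-th sample gives one target per feature row.
    """
    f = np.asarray(force_raw, dtype=float)
    if f.ndim != 1:
        raise ValueError("force must be a 1-D trace")
    if f.shape[0] % factor:
        raise ValueError(f"force length {f.shape[0]} not divisible by factor {factor}")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    smooth = signal.sosfiltfilt(sos, f)
    return smooth[::factor]


def extract_features(
    trial,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    *,
    car: bool = True,
    fs: float = 1000.0,
    filter_order: int = 4,
    sg_order: int = 3,
    sg_window: int = 151,
    factor: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the full pipeline on one trial.

    ``trial`` is any object with ``lfp`` ((time, channel) matrix) and
    ``force_raw`` attributes, or a ``(lfp, force)`` tuple.  Returns the
    un-normalized ``(n_blocks, n_bands*n_channels)`` feature matrix and the
    downsampled force target; z-scoring is deferred to
    :func:`fit_normalizer` / :func:`apply_normalizer` so that statistics can
    be restricted to training trials.
    """
    if hasattr(trial, "lfp"):
        lfp, force = trial.lfp, trial.force_raw
    else:
        lfp, force = trial
    x = car_filter(lfp) if car else np.asarray(lfp, dtype=float)
    banded = bandpass_bank(x, bands, fs=fs, order=filter_order)
    env = rectify_smooth(banded, sg_order=sg_order, sg_window=sg_window)
    feats = downsample_features(env, factor=factor)
    target = downsample_force(force, fs=fs, factor=factor)
    return feats, target


def build_lag_matrix(features: np.ndarray, n_lags: int = 10) -> np.ndarray:
    """Expand a feature matrix with explicit time lags.

    Row ``t`` of the output concatenates feature rows ``t, t-1, …,
    t-(n_lags-1)`` (lag-major block ordering, lag 0 first).  Lags that would
    reach before the trial start are zero-filled; lags never cross trial
    boundaries, so call this per trial before concatenating trials.
    """
    f = np.asarray(features, dtype=float)
    if f.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    n, m = f.shape
    if n_lags < 0:
        raise ValueError("n_lags must be >= 0")
    if n_lags > n:
        raise ValueError(f"n_lags {n_lags} exceeds the {n} rows available")
    out = np.zeros((n, m * n_lags))
    for lag in range(n_lags):
        out[lag:, lag * m : (lag + 1) * m] = f[: n - lag]
    return out
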