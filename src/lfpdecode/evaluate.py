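"""Cross-validated decoder comparison, metrics and contribution analyses.

Both decoders are scored with the same seven-fold, trial-level
cross-validation: the session's trials are partitioned into k near-equal
folds, preprocessing statistics and all model selection (Wold's criterion
for PLS, the hyper-parameter search for the LSTM) are fit on the training
folds only, and the held-out fold's concatenated predictions are scored
with Pearson's r and the coefficient of determination

    R^2 = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2 ,

which may be negative for a decoder worse than predicting the mean.
Method differences across folds are tested with the two-sided Wilcoxon
signed-rank test (exact distribution — seven pairs are far too few for the
normal approximation).

The module also implements the two ablations that probe *why* the decoders
work: a lag-count sweep for PLS (is there usable information in past
samples?) and the per-frequency-band contribution of the LSTM's first-layer
weights,

    C_band = sum_channels |W[band, channel]| / sum_all |W| ,

summed over all four gate matrices' input columns and normalized to a
probability vector over the six bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from . import preprocess as pp
from .lstm import ForceLSTM, NetworkParams
from .pls import PLS1Model

__all__ = [
    "FoldAssignment",
    "CVResult",
    "BandContribution",
    "kfold_split",
    "pearson_r",
    "coeff_determination",
    "extract_session_features",
    "run_experiment",
    "lag_sweep",
    "band_contribution",
    "compare_methods",
    "PairedComparison",
]


@dataclass
class FoldAssignment:
    """Seeded trial-level partition into k near-equal folds."""

    k: int
    folds: list[np.ndarray]  # trial indices per test fold
    seed: int

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.folds[fold]
        train = np.concatenate([f for i, f in enumerate(self.folds) if i != fold])
        return np.sort(train), np.sort(test)


def kfold_split(n_trials: int, k: int = 7, seed: int = 0) -> FoldAssignment:
    if n_trials < k:
        raise ValueError(f"{k}-fold CV needs at least {k} trials, got {n_trials}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trials)
    folds = [np.sort(f) for f in np.array_split(perm, k)]
    return FoldAssignment(k=k, folds=folds, seed=seed)


def pearson_r(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation between observed and predicted traces."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 samples")
    dy = y - y.mean()
    dh = yhat - yhat.mean()
    denom = np.sqrt(np.sum(dy**2)) * np.sqrt(np.sum(dh**2))
    if denom == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.sum(dy * dh) / denom)


def coeff_determination(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSE/SST (can be negative)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 samples")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("R^2 undefined for a constant target")
    return float(1.0 - np.sum((y - yhat) ** 2) / sst)


@dataclass
class CVResult:
    """Per-fold scores and predictions of one decoder on one session."""

    method: str
    fold_assignment: FoldAssignment
    r: list[float] = field(default_factory=list)
    r2: list[float] = field(default_factory=list)
    predictions: list[np.ndarray] = field(default_factory=list)
    truths: list[np.ndarray] = field(default_factory=list)
    settings: list[object] = field(default_factory=list)  # selected l / HyperParams
    models: list[object] = field(default_factory=list)

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r))

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2))

    @property
    def std_r(self) -> float:
        return float(np.std(self.r, ddof=1))

    @property
    def std_r2(self) -> float:
        return float(np.std(self.r2, ddof=1))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "fold": np.arange(len(self.r)),
                "method": self.method,
                "r": self.r,
                "r2": self.r2,
                "settings": [str(s) for s in self.settings],
            }
        )

    def summary(self) -> str:
        lines = [
            f"{self.fold_assignment.k}-fold CV — {self.method}",
            "=" * 40,
            "fold    r        R^2      settings",
        ]
        for i, (r, r2, s) in enumerate(zip(self.r, self.r2, self.settings)):
            lines.append(f"{i:>4}  {r: .3f}   {r2: .3f}    {s}")
        lines.append(
            f"mean  {self.mean_r: .3f}   {self.mean_r2: .3f}"
            f"   (sd {self.std_r:.3f} / {self.std_r2:.3f})"
        )
        return "\n".join(lines)

    def plot_fold(self, fold: int = 0, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        t = np.arange(self.truths[fold].size) * 0.1
        ax.plot(t, self.truths[fold], label="observed force", lw=1.5)
        ax.plot(t, self.predictions[fold], label=self.method, lw=1.0)
        ax.set_xlabel("time (s, concatenated test trials)")
        ax.set_ylabel("force (N)")
        ax.legend()
        return ax


def extract_session_features(
    trials: Sequence,
    *,
    car: bool = True,
    bands=pp.DEFAULT_BANDS,
    sg_window: int = 151,
    fs: float = 1000.0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Run the feature pipeline over every trial of a session."""
    feats, targets = [], []
    for tr in trials:
        f, y = pp.extract_features(tr, bands, car=car, fs=fs, sg_window=sg_window)
        feats.append(f)
        targets.append(y)
    return feats, targets


def _as_features(session, *, car: bool, sg_window: int):
    """Accept either a list of trials or a precomputed (features, targets) pair."""
    if (
        isinstance(session, tuple)
        and len(session) == 2
        and not hasattr(session[0], "lfp")
    ):
        return list(session[0]), list(session[1])
    return extract_session_features(session, car=car, sg_window=sg_window)


def run_experiment(
    session,
    method: str,
    folds: FoldAssignment,
    *,
    car: bool = True,
    sg_window: int = 151,
    n_lags: int = 10,
    max_l: int = 15,
    wold_threshold: float = 0.9,
    press_folds: int = 10,
    pls_center: bool = True,
    search_budget: int = 30,
    search_grid: dict | None = None,
    epoch_cap: int | None = None,
    variant: str = "paper",
    seed: int = 0,
) -> CVResult:
    """Cross-validate one decoder over a session with shared folds.

    ``session`` is either a list of trial recordings or a precomputed
    ``(features, targets)`` pair of per-trial arrays.  Per fold, the
    normalizer, the PLS lag expansion + Wold selection (or the LSTM
    hyper-parameter search on an inner 20% validation split) see training
    trials only; scores are computed on the fold's concatenated test trials.
    """
    if method not in ("pls", "lstm"):
        raise ValueError("method must be 'pls' or 'lstm'")
    feats, targets = _as_features(session, car=car, sg_window=sg_window)
    n_trials = len(feats)
    if any(idx.max() >= n_trials for idx in folds.folds):
        raise ValueError("fold assignment references trials beyond the session")

    result = CVResult(method=method, fold_assignment=folds)
    for fold in range(folds.k):
        train_idx, test_idx = folds.train_test(fold)
        stats_ = pp.fit_normalizer([feats[i] for i in train_idx])
        norm = [pp.apply_normalizer(stats_, f) for f in feats]
        fold_seed = seed * 1009 + fold  # distinct, reproducible per fold

        y_test = np.concatenate([targets[i] for i in test_idx])
        if method == "pls":
            X_train = np.vstack([pp.build_lag_matrix(norm[i], n_lags) for i in train_idx])
            y_train = np.concatenate([targets[i] for i in train_idx])
            groups = np.repeat(train_idx, feats[0].shape[0])
            model = PLS1Model(X_train, y_train, center=pls_center)
            res = model.fit_wold(
                max_l=max_l,
                threshold=wold_threshold,
                folds=min(press_folds, len(train_idx)),  # trial-blocked folds need trials
                seed=fold_seed,
                groups=groups,
            )
            pred = np.concatenate(
                [res.predict(pp.build_lag_matrix(norm[i], n_lags)) for i in test_idx]
            )
            setting = res.n_components
            fitted = res
        else:
            train_trials_f = [norm[i] for i in train_idx]
            train_trials_y = [targets[i] for i in train_idx]
            model = ForceLSTM(train_trials_f, train_trials_y, variant=variant)
            hp, _ = model.tune(
                budget=search_budget,
                seed=fold_seed,
                grid=search_grid,
                epoch_cap=epoch_cap,
            )
            fitted = model.fit(hp, seed=fold_seed, epoch_cap=epoch_cap)
            pred = np.concatenate([fitted.predict(norm[i]) for i in test_idx])
            setting = hp
        result.r.append(pearson_r(y_test, pred))
        result.r2.append(coeff_determination(y_test, pred))
        result.predictions.append(pred)
        result.truths.append(y_test)
        result.settings.append(setting)
        result.models.append(fitted)
    return result


def lag_sweep(
    session,
    lag_counts: Sequence[int],
    folds: FoldAssignment,
    **pls_options,
) -> dict[int, CVResult]:
    """PLS cross-validation repeated at each lag count on identical folds."""
    feats_targets = _as_features(
        session,
        car=pls_options.pop("car", True),
        sg_window=pls_options.pop("sg_window", 151),
    )
    out = {}
    for n_lags in lag_counts:
        if n_lags < 1:
            raise ValueError("lag counts must be >= 1")
        out[n_lags] = run_experiment(
            feats_targets, "pls", folds, n_lags=n_lags, **pls_options
        )
    return out


@dataclass
class BandContribution:
    """Normalized first-layer weight mass per frequency band."""

    band_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isclose(self.values.sum(), 1.0, atol=1e-12):
            raise ValueError("band contributions must sum to 1")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"band": self.band_names, "contribution": self.values})


def band_contribution(
    params: NetworkParams | Sequence[NetworkParams],
    n_channels: int = 16,
    band_names: Sequence[str] | None = None,
) -> BandContribution:
    """Share of absolute first-layer input weight carried by each band.

    For each band the |weights| of the 16 corresponding input columns are
    summed over all four gate matrices and normalized by the grand total;
    recurrent (and bias) columns are excluded.  Given several fitted
    networks (one per fold), contributions are averaged.
    """
    if isinstance(params, NetworkParams):
        params = [params]
    per_model = []
    for p in params:
        layer = p.layer1
        d = layer.input_dim
        if band_names is None:
            if d % n_channels:
                raise ValueError(
                    f"layer input dim {d} is not a multiple of n_channels {n_channels}"
                )
            names = tuple(b.name for b in pp.DEFAULT_BANDS[: d // n_channels])
        else:
            names = tuple(band_names)
        n_bands = len(names)
        if n_bands * n_channels != d:
            raise ValueError("band/channel ordering does not match the layer input size")
        u = layer.units
        absw = sum(
            np.abs(getattr(layer, g)[:, u : u + d]) for g in ("W_c", "W_u", "W_f", "W_o")
        )
        per_band = absw.reshape(u, n_bands, n_channels).sum(axis=(0, 2))
        per_model.append(per_band / per_band.sum())
    values = np.mean(per_model, axis=0)
    return BandContribution(band_names=names, values=values / values.sum())


@dataclass
class PairedComparison:
    """Two-sided Wilcoxon signed-rank comparison of per-fold scores."""

    metric: str
    statistic: float
    pvalue: float
    mean_diff: float  # b - a
    n_pairs: int
    degenerate: bool = False

    def __str__(self) -> str:
        if self.degenerate:
            return f"{self.metric}: identical per-fold scores (no detectable difference)"
        direction = "b > a" if self.mean_diff > 0 else "b < a"
        return (
            f"{self.metric}: W={self.statistic:.1f}, p={self.pvalue:.4g}, "
            f"mean diff {self.mean_diff:+.4f} ({direction}, n={self.n_pairs})"
        )


def compare_methods(
    results_a: CVResult, results_b: CVResult
) -> dict[str, PairedComparison]:
    """Paired Wilcoxon signed-rank tests on per-fold r and R^2.

    Requires both results to come from the identical fold assignment.
    Zero differences are dropped (classic Wilcoxon treatment); with <= 25
    informative pairs the exact null distribution is used.
    """
    fa, fb = results_a.fold_assignment, results_b.fold_assignment
    if fa.k != fb.k or any(
        not np.array_equal(x, y) for x, y in zip(fa.folds, fb.folds)
    ):
        raise ValueError("results are not paired: fold assignments differ")
    out = {}
    for metric in ("r", "r2"):
        a = np.asarray(getattr(results_a, metric))
        b = np.asarray(getattr(results_b, metric))
        diff = b - a
        nz = diff[diff != 0]
        if nz.size == 0:
            out[metric] = PairedComparison(metric, np.nan, 1.0, 0.0, 0, degenerate=True)
            continue
        method = "exact" if nz.size <= 25 else "approx"
        res = stats.wilcoxon(nz, alternative="two-sided", method=method)
        out[metric] = PairedComparison(
            metric=metric,
            statistic=float(res.statistic),
            pvalue=float(res.pvalue),
            mean_diff=float(diff.mean()),
            n_pairs=int(nz.size),
        )
    return out
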