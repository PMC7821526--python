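"""Synthetic LFP/force sessions with known band-power-to-force coupling.

Real recordings of this kind — a rodent pressing a load cell while
16-channel motor-cortex LFP is sampled at 1000 Hz — are rarely public, so
this module generates sessions with the statistical structure the decoders
assume and with the ground truth retained:

* each trial is a 3 s window aligned so that the force trace crosses the
  0.15 N reward threshold exactly at t = 1 s (one upward crossing per trial);
* each frequency band on each channel carries a band-limited noise carrier
  whose instantaneous amplitude is ``baseline + g[band, channel] * f(force)``,
  where ``f`` is either the identity or a saturating map — band power is the
  controlled information channel, exactly what the feature pipeline measures;
* all channels share one common-mode noise trace (what CAR removes) and
  receive independent wideband channel noise;
* the observed force is the clean latent profile plus smooth, zero-truncated
  Gaussian noise, preserving the hard zero floor of a force sensor.

Everything is driven by a single seed: regenerating with the same
configuration reproduces the session bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

from .preprocess import DEFAULT_BANDS, BandDefinition, _design_bank

__all__ = [
    "SyntheticConfig",
    "TrialRecording",
    "GroundTruthMap",
    "generate_force_profile",
    "generate_trial",
    "generate_session",
    "save_session",
    "load_session",
    "session_to_hdf5",
    "session_from_hdf5",
]

#: Default per-band coupling strength (envelope gain per unit drive).
#: Rising with frequency so that the beta/gamma/high-gamma bands carry most
#: of the decodable signal, the regime typically reported for motor LFP.
DEFAULT_BAND_GAINS = (1.0, 1.5, 2.0, 3.0, 4.5, 6.0)


@dataclass
class SyntheticConfig:
    """Generation parameters for one session.

    The defaults define the reference study condition used throughout the
    tests: 74 trials of 3 s at 1000 Hz on 16 channels, 0.15 N threshold,
    moderate common-mode and channel noise, linear force-to-envelope
    coupling.
    """

    n_channels: int = 16
    fs_lfp: float = 1000.0
    trial_duration: float = 3.0
    n_trials: int = 74
    force_threshold: float = 0.15
    coupling_gain: np.ndarray | None = None  # (n_bands, n_channels), >= 0
    baseline: float = 1.0
    common_noise_sd: float = 0.5
    channel_noise_sd: float = 0.3
    force_noise_sd: float = 0.002
    output_nonlinearity: str = "linear"  # or "saturating"
    coupling_lead: int = 0  # samples by which band power leads force
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.trial_duration * self.fs_lfp
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration * fs_lfp must be an integer sample count")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")
        if self.force_threshold <= 0:
            raise ValueError("force_threshold must be positive")
        if self.output_nonlinearity not in ("linear", "saturating"):
            raise ValueError("output_nonlinearity must be 'linear' or 'saturating'")
        if min(self.common_noise_sd, self.channel_noise_sd, self.force_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.coupling_lead < 0:
            raise ValueError("coupling_lead must be >= 0 samples")
        if self.coupling_gain is None:
            self.coupling_gain = np.outer(
                DEFAULT_BAND_GAINS[: len(self.bands)], np.ones(self.n_channels)
            )
        self.coupling_gain = np.asarray(self.coupling_gain, dtype=float)
        if self.coupling_gain.shape != (len(self.bands), self.n_channels):
            raise ValueError(
                f"coupling_gain must have shape {(len(self.bands), self.n_channels)}"
            )
        if np.any(self.coupling_gain < 0):
            raise ValueError("coupling_gain entries must be non-negative")
        if not np.any(self.coupling_gain > 0) and self.n_trials > 0:
            # all-zero coupling is allowed (no-signal control sessions)
            pass

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.fs_lfp))

    def to_dict(self) -> dict:
        d = {
            "n_channels": self.n_channels,
            "fs_lfp": self.fs_lfp,
            "trial_duration": self.trial_duration,
            "n_trials": self.n_trials,
            "force_threshold": self.force_threshold,
            "coupling_gain": np.asarray(self.coupling_gain).tolist(),
            "baseline": self.baseline,
            "common_noise_sd": self.common_noise_sd,
            "channel_noise_sd": self.channel_noise_sd,
            "force_noise_sd": self.force_noise_sd,
            "output_nonlinearity": self.output_nonlinearity,
            "coupling_lead": self.coupling_lead,
            "bands": [[b.name, b.low, b.high] for b in self.bands],
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(BandDefinition(*b) for b in d["bands"])
        if d.get("coupling_gain") is not None:
            d["coupling_gain"] = np.asarray(d["coupling_gain"], dtype=float)
        return cls(**d)


@dataclass
class TrialRecording:
    """One trial: raw LFP matrix, observed force trace, identifiers."""

    lfp: np.ndarray  # (n_samples, n_channels)
    force_raw: np.ndarray  # (n_samples,), newtons, >= 0
    trial_id: int


@dataclass
class GroundTruthMap:
    """What the generator actually used — enables parameter-recovery tests."""

    config: SyntheticConfig
    coupling_gain: np.ndarray
    force_clean: list[np.ndarray] = field(default_factory=list)
    trial_seeds: list[int] = field(default_factory=list)


def _drive(force: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Map force (N) to the envelope drive, with optional neural lead."""
    if config.coupling_lead > 0:
        lead = config.coupling_lead
        force = np.concatenate([force[lead:], np.full(lead, force[-1])])
    if config.output_nonlinearity == "saturating":
        k = config.force_threshold
        return force / (force + k)
    return force


def generate_force_profile(
    duration: float = 3.0,
    fs: float = 1000.0,
    threshold: float = 0.15,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One clean press profile crossing ``threshold`` exactly at t = 1 s.

    The profile is a smooth (sub-1 Hz content) cosine-ramp bump: flat zero,
    a monotone rise that passes through the threshold at the 1 s sample by
    construction, a peak in (1.1, 1.9) × threshold, and a monotone decay back
    to zero.  Values are bounded in [0, 2 × threshold] and there is exactly
    one upward threshold crossing (the decay re-crosses downward, as any
    press that ends must).
    """
    n_f = duration * fs
    if abs(n_f - round(n_f)) > 1e-9:
        raise ValueError("duration * fs must be an integer sample count")
    n = int(round(n_f))
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    t = np.arange(n) / fs
    t_cross = 1.0
    # Peak time, rise-phase fraction at the crossing, and decay end.  The
    # fraction s fixes the rise start t0 so that the half-cosine ramp passes
    # through `threshold` exactly at t_cross; s is kept in a range where the
    # implied peak amplitude A = threshold / r stays within [1.1, 1.9]*threshold.
    tp = rng.uniform(1.30, 1.55)
    s = rng.uniform(0.53, min(0.70, 0.97 / tp))
    te = rng.uniform(2.30, 2.80)
    t0 = (t_cross - s * tp) / (1.0 - s)
    r = 0.5 * (1.0 - np.cos(np.pi * s))
    amp = threshold / r

    profile = np.zeros(n)
    rise = (t >= t0) & (t <= tp)
    profile[rise] = amp * 0.5 * (1.0 - np.cos(np.pi * (t[rise] - t0) / (tp - t0)))
    fall = (t > tp) & (t <= te)
    profile[fall] = amp * 0.5 * (1.0 + np.cos(np.pi * (t[fall] - tp) / (te - tp)))
    # pin the crossing sample exactly (guards against rounding in the ramp)
    i_cross = int(round(t_cross * fs))
    if i_cross < n:
        profile[i_cross] = threshold
    return np.clip(profile, 0.0, 2.0 * threshold)


def _upward_crossings(x: np.ndarray, threshold: float) -> np.ndarray:
    below = x[:-1] < threshold
    at_or_above = x[1:] >= threshold
    return np.flatnonzero(below & at_or_above) + 1


def generate_trial(config: SyntheticConfig, trial_seed: int, trial_id: int = 0):
    """Synthesize one trial; returns ``(TrialRecording, force_clean)``.

    For every band b and channel c a unit-RMS carrier (white noise band-passed
    with the same zero-phase filter bank the feature pipeline uses) is
    amplitude-modulated by ``baseline + g[b, c] * f(force)``.  The channel's
    LFP is the sum over bands plus the session's common-mode noise trace and
    independent channel noise.
    """
    rng = np.random.default_rng(trial_seed)
    n, n_ch = config.n_samples, config.n_channels
    fs = config.fs_lfp

    force_clean = generate_force_profile(
        config.trial_duration, fs, config.force_threshold, rng=rng
    )
    drive = _drive(force_clean, config)

    sos_bank = _design_bank(config.bands, fs, order=4)
    lfp = np.zeros((n, n_ch))
    for b, sos in enumerate(sos_bank):
        carrier = signal.sosfiltfilt(sos, rng.standard_normal((n, n_ch)), axis=0)
        rms = carrier.std(axis=0)
        rms[rms == 0] = 1.0
        carrier /= rms
        envelope = config.baseline + np.outer(drive, config.coupling_gain[b])
        lfp += carrier * envelope

    if config.common_noise_sd > 0:
        common = config.common_noise_sd * rng.standard_normal(n)
        lfp += common[:, None]
    if config.channel_noise_sd > 0:
        lfp += config.channel_noise_sd * rng.standard_normal((n, n_ch))

    force_raw = force_clean
    if config.force_noise_sd > 0:
        noise = rng.standard_normal(n) * config.force_noise_sd
        sos_lp = signal.butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
        noise = signal.sosfiltfilt(sos_lp, noise)
        # fade the noise out around the threshold crossing so each trial keeps
        # exactly one upward crossing, at t = 1 s
        t = np.arange(n) / fs
        notch = 1.0 - np.exp(-(((t - 1.0) / 0.08) ** 2))
        force_raw = np.clip(force_clean + noise * notch, 0.0, None)

    rec = TrialRecording(lfp=lfp, force_raw=force_raw, trial_id=trial_id)
    return rec, force_clean


def generate_session(
    config: SyntheticConfig,
) -> tuple[list[TrialRecording], GroundTruthMap]:
    """Generate ``config.n_trials`` independent trials plus the ground truth."""
    if config.n_trials < 1:
        raise ValueError("n_trials must be >= 1 for a session")
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_trials)
    truth = GroundTruthMap(config=config, coupling_gain=np.array(config.coupling_gain))
    trials = []
    for i, s in enumerate(seeds):
        rec, clean = generate_trial(config, int(s), trial_id=i)
        trials.append(rec)
        truth.force_clean.append(clean)
        truth.trial_seeds.append(int(s))
    return trials, truth


# ---------------------------------------------------------------------------
# serialization


def save_session(path, trials: Sequence[TrialRecording], truth: GroundTruthMap) -> None:
    """Write a session as per-trial arrays plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": truth.config.to_dict(),
        "trial_ids": [t.trial_id for t in trials],
        "trial_seeds": truth.trial_seeds,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for t, clean in zip(trials, truth.force_clean):
        np.save(path / f"lfp_{t.trial_id:04d}.npy", t.lfp)
        np.save(path / f"force_{t.trial_id:04d}.npy", t.force_raw)
        np.save(path / f"force_clean_{t.trial_id:04d}.npy", clean)


def load_session(path) -> tuple[list[TrialRecording], GroundTruthMap]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    config = SyntheticConfig.from_dict(manifest["config"])
    truth = GroundTruthMap(
        config=config,
        coupling_gain=np.array(config.coupling_gain),
        trial_seeds=list(manifest["trial_seeds"]),
    )
    trials = []
    for tid in manifest["trial_ids"]:
        trials.append(
            TrialRecording(
                lfp=np.load(path / f"lfp_{tid:04d}.npy"),
                force_raw=np.load(path / f"force_{tid:04d}.npy"),
                trial_id=tid,
            )
        )
        truth.force_clean.append(np.load(path / f"force_clean_{tid:04d}.npy"))
    return trials, truth


def session_to_hdf5(path, trials: Sequence[TrialRecording], truth: GroundTruthMap) -> None:
    """Export a session as one HDF5 container (/lfp, /force)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("lfp", data=np.stack([t.lfp for t in trials]))
        h5.create_dataset("force", data=np.stack([t.force_raw for t in trials]))
        h5.create_dataset("force_clean", data=np.stack(truth.force_clean))
        h5.attrs["config"] = json.dumps(truth.config.to_dict())
        h5.attrs["trial_seeds"] = truth.trial_seeds


def session_from_hdf5(path) -> tuple[list[TrialRecording], GroundTruthMap]:
    import h5py

    with h5py.File(path, "r") as h5:
        config = SyntheticConfig.from_dict(json.loads(h5.attrs["config"]))
        lfp = h5["lfp"][...]
        force = h5["force"][...]
        clean = h5["force_clean"][...]
        seeds = [int(s) for s in h5.attrs["trial_seeds"]]
    trials = [
        TrialRecording(lfp=lfp[i], force_raw=force[i], trial_id=i)
        for i in range(lfp.shape[0])
    ]
    truth = GroundTruthMap(
        config=config,
        coupling_gain=np.array(config.coupling_gain),
        force_clean=list(clean),
        trial_seeds=seeds,
    )
    return trials, truth
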