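"""Synthetic CBFV cohorts: pulsatile maximal-velocity envelopes with
class-dependent morphology, session structure, artifacts, and matching
Doppler spectrograms for envelope-recovery experiments.

The beat model is deliberately simple — a diastolic floor plus a systolic
Gaussian upstroke and a smaller dicrotic Gaussian, with per-beat period
jitter and additive Gaussian noise — because downstream code only needs the
statistical structure of pulsatile flow, not hemodynamic realism.  The two
classes differ by construction: the critically-ill ("ICU") parameter
distribution has a depressed diastolic floor and elevated pulsatility
relative to the healthy one.  This separation is a design convention of the
generator, chosen so that classification experiments on synthetic cohorts
have signal to find; it is not a clinical claim.

Default cohort structure: 6 healthy and 12 ICU subjects, one recording
session each of 300 s at 217 Hz, with sparse NaN cuts and flat-line
artifacts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .envelope import Spectrogram, VelocityEnvelope, envelope_to_csv

__all__ = ["WaveformParams", "SyntheticCohortSpec", "HEALTHY_PARAMS",
           "ICU_PARAMS", "generate_velocity_waveform", "sample_params",
           "generate_cohort", "inject_artifacts", "synth_doppler_spectrogram"]


@dataclass(frozen=True)
class WaveformParams:
    systolic_peak: float          # cm/s
    diastolic_floor: float        # cm/s
    heart_rate: float             # bpm
    dicrotic_amplitude: float = 0.2   # fraction of the pulse height
    beat_jitter: float = 0.03     # sd of per-beat period, fraction of period
    noise_sd: float = 1.0         # cm/s additive noise

    def __post_init__(self):
        if not 0 < self.diastolic_floor < self.systolic_peak <= 300:
            raise ValueError("need 0 < diastolic_floor < systolic_peak <= 300")
        if not 30 <= self.heart_rate <= 180:
            raise ValueError("heart_rate must be within 30-180 bpm")

    def beat_shape(self, fs: float) -> np.ndarray:
        """One noise-free beat sampled at fs; peak occurs early in the cycle."""
        period = 60.0 / self.heart_rate
        n = int(round(period * fs))
        tau = np.arange(n) / fs / period  # normalized phase in [0, 1)
        pulse = (np.exp(-0.5 * ((tau - 0.13) / 0.055) ** 2)
                 + self.dicrotic_amplitude
                 * np.exp(-0.5 * ((tau - 0.42) / 0.075) ** 2))
        height = self.systolic_peak - self.diastolic_floor
        return self.diastolic_floor + height * pulse / pulse.max()

    def implied_pulsatility_index(self, fs: float = 217.0) -> float:
        """(max - min)/mean of the noise-free beat — the generator's PI."""
        beat = self.beat_shape(fs)
        return float((beat.max() - beat.min()) / beat.mean())


# Class parameter distributions (mean values; sample_params adds spread).
HEALTHY_PARAMS = WaveformParams(systolic_peak=95.0, diastolic_floor=45.0,
                                heart_rate=70.0, dicrotic_amplitude=0.25,
                                noise_sd=1.5)
ICU_PARAMS = WaveformParams(systolic_peak=115.0, diastolic_floor=22.0,
                            heart_rate=85.0, dicrotic_amplitude=0.10,
                            noise_sd=2.5)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_healthy: int = 6
    n_icu: int = 12
    recordings_per_subject: int = 1
    duration_s: float = 300.0
    fs: float = 217.0
    nan_cut_rate: float = 0.5    # expected cuts per recording
    flat_line_rate: float = 0.5  # expected flat-line runs per recording
    seed: int = 0

    def __post_init__(self):
        if min(self.n_healthy, self.n_icu, self.recordings_per_subject) < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.nan_cut_rate and 0 <= self.flat_line_rate):
            raise ValueError("artifact rates must be non-negative")


def generate_velocity_waveform(params: WaveformParams, duration_s: float,
                               fs: float = 217.0,
                               seed: int | np.random.Generator = 0
                               ) -> VelocityEnvelope:
    """Jittered beat train with additive noise, clamped to (0, 300] cm/s."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    period = 60.0 / params.heart_rate
    if duration_s < period:
        raise ValueError("duration shorter than one cardiac cycle")
    n_out = int(round(duration_s * fs))
    chunks = []
    total = 0
    while total < n_out:
        p = params if params.beat_jitter == 0 else replace(
            params, heart_rate=float(np.clip(
                params.heart_rate / max(1.0 + params.beat_jitter * rng.standard_normal(), 0.5),
                30.0, 180.0)))
        beat = p.beat_shape(fs)
        chunks.append(beat)
        total += len(beat)
    samples = np.concatenate(chunks)[:n_out]
    if params.noise_sd > 0:
        samples = samples + rng.normal(0.0, params.noise_sd, size=n_out)
    samples = np.clip(samples, 1e-3, 300.0)
    return VelocityEnvelope(samples, sample_rate=fs)


def sample_params(base: WaveformParams, rng: np.random.Generator
                  ) -> WaveformParams:
    """Per-subject draw around a class's mean morphology."""
    systolic = float(np.clip(rng.normal(base.systolic_peak, 8.0), 40, 290))
    return WaveformParams(
        systolic_peak=systolic,
        diastolic_floor=float(np.clip(rng.normal(base.diastolic_floor, 4.0),
                                      5, systolic - 10)),
        heart_rate=float(np.clip(rng.normal(base.heart_rate, 8.0), 45, 140)),
        dicrotic_amplitude=float(np.clip(rng.normal(base.dicrotic_amplitude, 0.04),
                                         0.0, 0.6)),
        beat_jitter=base.beat_jitter,
        noise_sd=float(np.clip(rng.normal(base.noise_sd, 0.3), 0.2, 6.0)),
    )


def inject_artifacts(env: VelocityEnvelope,
                     nan_cuts: int = 0, flat_lines: int = 0, spikes: int = 0,
                     cut_length: int = 100, flat_length: int = 300,
                     seed: int | np.random.Generator = 0) -> VelocityEnvelope:
    """Insert NaN cuts, constant ("plane line") runs and spike noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = env.samples.copy()
    valid = env.valid_mask.copy()
    n = len(samples)
    for _ in range(nan_cuts):
        s = int(rng.integers(0, max(n - cut_length, 1)))
        samples[s:s + cut_length] = np.nan
        valid[s:s + cut_length] = False
    for _ in range(flat_lines):
        s = int(rng.integers(0, max(n - flat_length, 1)))
        level = samples[s] if np.isfinite(samples[s]) else 50.0
        samples[s:s + flat_length] = level
    for _ in range(spikes):
        s = int(rng.integers(0, n))
        if np.isfinite(samples[s]):
            samples[s] = min(samples[s] + float(rng.uniform(50, 150)), 300.0)
    return VelocityEnvelope(samples, sample_rate=env.sample_rate,
                            valid_mask=valid, session_id=env.session_id,
                            subject_id=env.subject_id, class_label=env.class_label)


def generate_cohort(spec: SyntheticCohortSpec, out_dir=None
                    ) -> tuple[pd.DataFrame, dict[str, VelocityEnvelope]]:
    """Generate a full cohort; returns (manifest, session_id -> envelope).

    When `out_dir` is given, each envelope is written as a two-column CSV and
    the manifest as ``manifest.csv`` with a ``path`` column.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    envelopes: dict[str, VelocityEnvelope] = {}
    session_counter = 1
    for class_label, base, count in (("Healthy", HEALTHY_PARAMS, spec.n_healthy),
                                     ("ICU", ICU_PARAMS, spec.n_icu)):
        for s in range(count):
            subject_id = f"{class_label[0]}{s + 1:02d}"
            params = sample_params(base, rng)
            for _ in range(spec.recordings_per_subject):
                session_id = f"S{session_counter:03d}"
                session_counter += 1
                env = generate_velocity_waveform(params, spec.duration_s,
                                                 fs=spec.fs, seed=rng)
                env = inject_artifacts(
                    env,
                    nan_cuts=int(rng.poisson(spec.nan_cut_rate)),
                    flat_lines=int(rng.poisson(spec.flat_line_rate)),
                    seed=rng)
                env.session_id = session_id
                env.subject_id = subject_id
                env.class_label = class_label
                envelopes[session_id] = env
                rows.append(dict(path=f"{session_id}.csv", session_id=session_id,
                                 subject_id=subject_id, class_label=class_label,
                                 quality=""))
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for session_id, env in envelopes.items():
            envelope_to_csv(env, out_dir / f"{session_id}.csv")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, envelopes


def synth_doppler_spectrogram(env: VelocityEnvelope, noise_floor_db: float = -40.0,
                              bin_width: float = 1.0, hop_s: float = 0.01,
                              v_max: float = 200.0, speckle_rate: float = 0.0,
                              seed: int = 0) -> Spectrogram:
    """Filled-spectrum magnitude image from a known velocity curve.

    Bins at or below v(t) get unit magnitude, bins above sit at the noise
    floor; optional speckle flips isolated above-envelope pixels to full
    magnitude at `speckle_rate`.  Ground truth for envelope recovery.
    """
    rng = np.random.default_rng(seed)
    t_frames = np.arange(0, (len(env) - 1) / env.sample_rate + 1e-12, hop_s)
    idx = np.clip((t_frames * env.sample_rate).round().astype(int), 0, len(env) - 1)
    v_t = env.samples[idx]
    vel_axis = np.arange(0.0, v_max + bin_width / 2, bin_width)
    floor = 10.0 ** (noise_floor_db / 20.0)
    mag = np.full((len(vel_axis), len(t_frames)), floor)
    finite = np.isfinite(v_t)
    filled = vel_axis[:, None] <= np.where(finite, v_t, -np.inf)[None, :]
    mag[filled] = 1.0
    if speckle_rate > 0:
        speckle = (rng.random(mag.shape) < speckle_rate) & ~filled
        mag[speckle] = 1.0
    return Spectrogram(mag, vel_axis, t_frames)


def cohort_checksum(envelopes: dict[str, VelocityEnvelope]) -> str:
    """Stable digest of a generated cohort, for reproducibility checks."""
    h = hashlib.sha256()
    for sid in sorted(envelopes):
        env = envelopes[sid]
        h.update(sid.encode())
        h.update(np.nan_to_num(env.samples).tobytes())
        h.update(env.valid_mask.tobytes())
    return h.hexdigest()
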