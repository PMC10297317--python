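"""Envelope cleaning, fixed-length segmentation and quality annotation.

Recordings arrive as velocity envelopes with validity masks.  Stretches of
invalid samples ("signal cuts") are removed by splitting the envelope into
maximal valid runs; runs are cut into 1024-sample windows (optionally
overlapping, e.g. 80 % overlap for training-set augmentation); each window
receives a quality tag — ``clear``, ``corrupted`` or ``rejected`` — from a
morphology heuristic, with manifest-provided manual labels taking precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .envelope import VelocityEnvelope

SEGMENT_LENGTH = 1024
CLASS_LABELS = ("Healthy", "ICU")
QUALITY_LABELS = ("clear", "corrupted", "rejected")

__all__ = ["Segment", "SEGMENT_LENGTH", "CLASS_LABELS", "QUALITY_LABELS",
           "remove_cuts", "segment", "segment_stride", "auto_annotate",
           "validate_manifest", "segment_envelope"]


@dataclass
class Segment:
    samples: np.ndarray          # exactly SEGMENT_LENGTH values, cm/s
    session_id: str
    subject_id: str
    class_label: str
    quality: str = "clear"
    start_index: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape != (SEGMENT_LENGTH,):
            raise ValueError(f"segment must hold exactly {SEGMENT_LENGTH} samples")
        if self.quality not in QUALITY_LABELS:
            raise ValueError(f"unknown quality {self.quality!r}")
        if self.quality != "rejected" and not np.isfinite(self.samples).all():
            raise ValueError("non-rejected segments must be NaN-free")


def remove_cuts(env: VelocityEnvelope,
                min_run: int = SEGMENT_LENGTH) -> list[np.ndarray]:
    """Split an envelope into maximal valid runs of length >= min_run."""
    ok = env.valid_mask & np.isfinite(env.samples)
    edges = np.diff(np.concatenate(([0], ok.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [env.samples[s:e] for s, e in zip(starts, ends) if e - s >= min_run]


def segment_stride(length: int, overlap_fraction: float) -> int:
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    return int(np.floor(length * (1.0 - overlap_fraction)))


def segment(run: np.ndarray, length: int = SEGMENT_LENGTH,
            overlap_fraction: float = 0.0) -> list[np.ndarray]:
    """Sliding windows over a valid run.

    Starts at multiples of stride = floor(length * (1 - overlap)); the window
    count is floor((L - length)/stride) + 1, zero when the run is too short.
    """
    run = np.asarray(run, dtype=np.float64)
    L = len(run)
    if L < length:
        return []
    stride = segment_stride(length, overlap_fraction)
    starts = range(0, L - length + 1, stride)
    return [run[s:s + length] for s in starts]


def auto_annotate(samples: np.ndarray, fs: float = 217.0,
                  flat_run_max: int = 217, v_max: float = 300.0,
                  periodicity_threshold: float = 0.3) -> str:
    """Heuristic quality label for a 1024-sample window.

    ``rejected``: any NaN, any constant ("plane-line") run longer than
    `flat_run_max` samples (~1 s), or values outside (0, v_max] cm/s —
    i.e. no physiological information.  Otherwise the cardiac periodicity is
    scored by the normalized autocorrelation peak in the 0.4-1.5 s lag band
    (40-150 bpm); below `periodicity_threshold` the window is ``corrupted``,
    else ``clear``.
    """
    x = np.asarray(samples, dtype=np.float64)
    if not np.isfinite(x).all():
        return "rejected"
    if (x <= 0).any() or (x > v_max).any():
        return "rejected"
    # longest constant run
    changes = np.flatnonzero(np.diff(x) != 0)
    bounds = np.concatenate(([-1], changes, [len(x) - 1]))
    if np.diff(bounds).max() > flat_run_max:
        return "rejected"
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        return "rejected"
    # FFT-based autocorrelation (zero-padded to avoid circular wrap)
    nfft = 2 * len(xc)
    spec_pow = np.abs(np.fft.rfft(xc, nfft)) ** 2
    ac = np.fft.irfft(spec_pow, nfft)[:len(xc)] / denom
    lo, hi = int(0.4 * fs), min(int(1.5 * fs), len(ac) - 1)
    score = float(ac[lo:hi + 1].max())
    return "clear" if score >= periodicity_threshold else "corrupted"


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check the session -> (subject, class) mapping is single-valued."""
    required = {"session_id", "subject_id", "class_label"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    per_session = manifest.groupby("session_id")[["subject_id", "class_label"]].nunique()
    conflicted = per_session[(per_session > 1).any(axis=1)]
    if len(conflicted):
        raise ValueError("sessions mapping to multiple subjects/classes: "
                         f"{list(conflicted.index)}")
    bad = set(manifest["class_label"]) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return manifest


def segment_envelope(env: VelocityEnvelope, overlap_fraction: float = 0.0,
                     length: int = SEGMENT_LENGTH, annotate: bool = True,
                     manual_quality: str | None = None) -> list[Segment]:
    """remove_cuts -> segment -> annotate, carrying session metadata.

    A `manual_quality` label (e.g. from a curated manifest) overrides the
    heuristic for every produced segment.
    """
    segments: list[Segment] = []
    for run in remove_cuts(env, min_run=length):
        offset = 0  # start indices are within-run; absolute index not tracked per cut
        for window in segment(run, length=length, overlap_fraction=overlap_fraction):
            if manual_quality is not None:
                quality = manual_quality
            elif annotate:
                quality = auto_annotate(window, fs=env.sample_rate)
            else:
                quality = "clear"
            segments.append(Segment(window, env.session_id, env.subject_id,
                                    env.class_label, quality=quality,
                                    start_index=offset))
            offset += segment_stride(length, overlap_fraction)
    return segments
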