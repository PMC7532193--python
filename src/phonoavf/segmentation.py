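"""Heart-cycle segmentation of bruit recordings.

The bruit is amplitude-modulated by the heartbeat, so the boundaries between
consecutive heart cycles show up as local minima of the signal envelope.  The
envelope is a moving RMS (default 50 ms window — long against the 20–700 Hz
carrier, short against the ~1 Hz beat); cut points are envelope minima kept
subject to a refractory spacing (default 0.3 s, i.e. a 200 bpm ceiling) and a
relative prominence threshold that suppresses jitter minima.  Segments
partition the analysed span exactly: sorted, contiguous, non-overlapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import EmptyInputError
from .io import Phonoangiogram, WORKING_RATE

logger = logging.getLogger(__name__)

DEFAULT_ENVELOPE_WINDOW_S = 0.05
DEFAULT_MIN_CYCLE_S = 0.3
DEFAULT_PROMINENCE_FRAC = 0.1


@dataclass
class Envelope:
    """Moving-RMS envelope of a recording; same length as the waveform."""

    values: np.ndarray
    window_s: float


@dataclass
class HeartCycleSegment:
    """One heartbeat's worth of samples, located in its parent recording."""

    samples: np.ndarray
    start_index: int
    source_patient: str = ""
    label: str | None = None

    def __len__(self) -> int:
        return len(self.samples)


def moving_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Moving RMS with the window shrunk at the boundaries (same length as x)."""
    if window < 2:
        raise ValueError(f"window must span at least 2 samples, got {window}")
    x = np.asarray(x, dtype=np.float64)
    kernel = np.ones(window)
    power = np.convolve(x * x, kernel, mode="same")
    counts = np.convolve(np.ones(len(x)), kernel, mode="same")
    return np.sqrt(power / counts)


def compute_envelope(
    signal: Phonoangiogram, window_s: float = DEFAULT_ENVELOPE_WINDOW_S
) -> Envelope:
    """Moving-RMS envelope of a recording over a ``window_s`` smoothing scale."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if len(signal.samples) == 0:
        raise EmptyInputError("cannot compute envelope of an empty signal")
    window = int(round(window_s * signal.rate))
    return Envelope(values=moving_rms(signal.samples, window), window_s=window_s)


def _cut_points(
    env: np.ndarray,
    rate: int,
    min_cycle_s: float,
    prominence_frac: float,
) -> np.ndarray:
    """Indices of retained envelope minima (sorted ascending)."""
    span = float(env.max() - env.min())
    if span <= 1e-9 * max(float(env.max()), np.finfo(float).tiny):
        return np.empty(0, dtype=int)  # flat envelope: no meaningful minima
    distance = max(1, int(round(min_cycle_s * rate)))
    # find_peaks on the negated envelope: its `distance` rule keeps the
    # highest peak (deepest minimum) among neighbours closer than the
    # refractory spacing, which is exactly the tie-break we want.
    minima, _ = find_peaks(-env, distance=distance, prominence=prominence_frac * span)
    return minima


def segment_cycles(
    signal: Phonoangiogram,
    min_cycle_s: float = DEFAULT_MIN_CYCLE_S,
    envelope_window_s: float = DEFAULT_ENVELOPE_WINDOW_S,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> list[HeartCycleSegment]:
    """Split a recording into single heart cycles at envelope minima.

    Returns ``n_retained_minima + 1`` contiguous segments whose concatenation
    reconstructs the signal.  Partial first/last cycles are kept.  A signal
    shorter than ``min_cycle_s`` is returned as a single segment (logged).
    """
    if signal.rate != WORKING_RATE:
        raise ValueError(f"segmentation expects {WORKING_RATE} S/s, got {signal.rate}")
    if len(signal.samples) == 0:
        raise EmptyInputError("cannot segment an empty signal")

    if signal.duration_s < min_cycle_s:
        logger.warning(
            "recording %r shorter than min_cycle_s=%.2fs; returning one segment",
            signal.patient_id,
            min_cycle_s,
        )
        cuts = np.empty(0, dtype=int)
    else:
        env = compute_envelope(signal, envelope_window_s)
        cuts = _cut_points(env.values, signal.rate, min_cycle_s, prominence_frac)

    bounds = np.concatenate(([0], cuts, [len(signal.samples)]))
    segments = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        segments.append(
            HeartCycleSegment(
                samples=signal.samples[lo:hi],
                start_index=int(lo),
                source_patient=signal.patient_id,
                label=signal.label,
            )
        )
    return segments


def segments_to_frame(segments: list[HeartCycleSegment]):
    """Tabular dump of a segmentation: ``patient_id,label,start_index,length``."""
    import pandas as pd

    return pd.DataFrame(
        {
            "patient_id": [s.source_patient for s in segments],
            "label": [s.label for s in segments],
            "start_index": [s.start_index for s in segments],
            "length": [len(s) for s in segments],
        }
    )
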