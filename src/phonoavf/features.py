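"""Third-octave spectral features of heart-cycle segments.

Each heart cycle is zero-padded or truncated to exactly 8192 samples, giving
a 1 Hz spectral resolution at the 8000 S/s working rate.  The FFT magnitude
X[i] is normalized by its total over all 8192 bins,

    X_N[i] = X[i] / sum_n X[n],

which makes every downstream feature invariant to recording gain.  The band
feature T_f for the third-octave band with nominal center f is the inclusive
sum of X_N over the band's integer bin range [f_dt, f_gt].

The 16 bands have nominal centers 20 … 630 Hz.  Band edges are exact base-2
thirds, f_c * 2^(±1/6) (exact center 31.5 Hz for the nominal "31").  Integer
bin borders take f_dt = round(lower edge) and let each band run up to the
next band's f_dt − 1, so the 16 bands tile the 18–706 Hz range with no gap or
overlap; the top border round(630 * 2^(1/6)) − 1 = 706 Hz.

Six additional time-domain waveform descriptors are computed per segment.
They are not part of the third-octave feature set and are prefixed
``aux_`` in tabular output; the default classification model uses only
the eight selected band features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateSignalError
from .io import Phonoangiogram, WORKING_RATE
from .segmentation import (
    DEFAULT_ENVELOPE_WINDOW_S,
    DEFAULT_MIN_CYCLE_S,
    DEFAULT_PROMINENCE_FRAC,
    HeartCycleSegment,
    moving_rms,
    segment_cycles,
)

logger = logging.getLogger(__name__)

FFT_SIZE = 8192

#: Nominal third-octave band centers, Hz.  "31" has exact center 31.5 Hz.
BAND_CENTERS = (20, 25, 31, 40, 50, 63, 80, 100, 125, 160, 200, 250, 315, 400, 500, 630)

_EXACT_CENTERS = {31: 31.5}

TIME_FEATURE_NAMES = (
    "duration_s",
    "rms",
    "peak_abs",
    "crest_factor",
    "zero_crossing_rate",
    "envelope_min_max_ratio",
)


@dataclass(frozen=True)
class ThirdOctaveBand:
    """One third-octave band with integer-bin borders (inclusive), Hz."""

    center_hz: int
    f_dt: int
    f_gt: int

    @property
    def width(self) -> int:
        return self.f_gt - self.f_dt + 1

    @property
    def name(self) -> str:
        return f"T_{self.center_hz}"


def make_band_table() -> list[ThirdOctaveBand]:
    """The 16 third-octave bands, tiling a contiguous integer bin range.

    Lower borders are rounded exact edges f_c * 2^(-1/6); each band's upper
    border is the next band's lower border minus one, and the last band ends
    at round(630 * 2^(1/6)) − 1 = 706 Hz.
    """
    exact = [float(_EXACT_CENTERS.get(c, c)) for c in BAND_CENTERS]
    lowers = [int(round(c * 2 ** (-1 / 6))) for c in exact]
    top = int(round(exact[-1] * 2 ** (1 / 6))) - 1
    uppers = [lo - 1 for lo in lowers[1:]] + [top]
    return [
        ThirdOctaveBand(center_hz=c, f_dt=lo, f_gt=hi)
        for c, lo, hi in zip(BAND_CENTERS, lowers, uppers)
    ]


def band_feature_names() -> list[str]:
    """Feature names ``T_20 … T_630`` in band order."""
    return [f"T_{c}" for c in BAND_CENTERS]


def pad_or_truncate(segment: HeartCycleSegment | np.ndarray, n: int = FFT_SIZE) -> np.ndarray:
    """Fix a segment to exactly ``n`` samples: zero-pad short, cut long."""
    x = segment.samples if isinstance(segment, HeartCycleSegment) else np.asarray(segment, float)
    if len(x) == 0:
        raise ValueError("segment must be non-empty")
    if len(x) >= n:
        return np.asarray(x[:n], dtype=np.float64)
    out = np.zeros(n, dtype=np.float64)
    out[: len(x)] = x
    return out


def fft_magnitude(x: np.ndarray, window: str = "rectangular") -> np.ndarray:
    """|DFT| of an 8192-sample sequence; bin i is i Hz for i ≤ 4096.

    The rectangular window (i.e. none) is the default; a Hann window is
    available to check that the windowing choice does not alter decisions.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) != FFT_SIZE:
        raise ValueError(f"expected {FFT_SIZE} samples, got {len(x)}")
    if window == "hann":
        x = x * np.hanning(FFT_SIZE)
    elif window != "rectangular":
        raise ValueError(f"unknown window {window!r}")
    return np.abs(np.fft.fft(x))


def normalize_spectrum(X: np.ndarray) -> np.ndarray:
    """Normalize an FFT magnitude by its sum over all 8192 bins (unit total)."""
    X = np.asarray(X, dtype=np.float64)
    if len(X) != FFT_SIZE:
        raise ValueError(f"expected {FFT_SIZE} bins, got {len(X)}")
    total = X.sum()
    if total <= 0.0:
        raise DegenerateSignalError("all-zero spectrum cannot be normalized")
    return X / total


def band_energy(X_N: np.ndarray, band: ThirdOctaveBand) -> float:
    """Inclusive sum of the normalized spectrum over [f_dt, f_gt]."""
    if not (0 <= band.f_dt < band.f_gt <= FFT_SIZE // 2):
        raise ValueError(f"band {band} outside the usable spectrum range")
    return float(X_N[band.f_dt : band.f_gt + 1].sum())


def time_domain_features(
    segment: HeartCycleSegment | np.ndarray, rate: int = WORKING_RATE
) -> dict[str, float]:
    """Six waveform descriptors of a raw (unpadded) heart-cycle segment."""
    x = segment.samples if isinstance(segment, HeartCycleSegment) else np.asarray(segment, float)
    if len(x) == 0:
        raise ValueError("segment must be non-empty")
    rms = float(np.sqrt(np.mean(x * x)))
    peak = float(np.max(np.abs(x)))
    crest = peak / rms if rms > 0 else 0.0
    # sign changes per sample pair; exact zeros carry the preceding sign
    signs = np.sign(x)
    signs[signs == 0] = 1
    zcr = float(np.count_nonzero(np.diff(signs))) / max(1, len(x) - 1)
    if len(x) >= 2:
        env = moving_rms(x, max(2, int(round(DEFAULT_ENVELOPE_WINDOW_S * rate))))
        ratio = float(env.min() / env.max()) if env.max() > 0 else 0.0
    else:
        ratio = 1.0
    return {
        "duration_s": len(x) / rate,
        "rms": rms,
        "peak_abs": peak,
        "crest_factor": crest,
        "zero_crossing_rate": zcr,
        "envelope_min_max_ratio": ratio,
    }


def segment_features(
    segment: HeartCycleSegment, bands: list[ThirdOctaveBand], window: str = "rectangular"
) -> dict[str, float] | None:
    """Band energies + time descriptors for one segment; None if degenerate."""
    padded = pad_or_truncate(segment)
    X = fft_magnitude(padded, window=window)
    try:
        X_N = normalize_spectrum(X)
    except DegenerateSignalError:
        logger.info(
            "dropping degenerate (zero-energy) segment at index %d of patient %r",
            segment.start_index,
            segment.source_patient,
        )
        return None
    row: dict[str, float] = {b.name: band_energy(X_N, b) for b in bands}
    for k, v in time_domain_features(segment).items():
        row[f"aux_{k}"] = v
    return row


def extract_features(
    recording: Phonoangiogram,
    window: str = "rectangular",
    min_cycle_s: float = DEFAULT_MIN_CYCLE_S,
    envelope_window_s: float = DEFAULT_ENVELOPE_WINDOW_S,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> pd.DataFrame:
    """One feature row per heart cycle of a recording.

    Columns: ``patient_id, label, T_20 … T_630, aux_*``.  Zero-energy
    segments are dropped; a recording with no valid segment yields an empty
    frame (logged).
    """
    bands = make_band_table()
    segments = segment_cycles(
        recording,
        min_cycle_s=min_cycle_s,
        envelope_window_s=envelope_window_s,
        prominence_frac=prominence_frac,
    )
    rows = []
    for seg in segments:
        feats = segment_features(seg, bands, window=window)
        if feats is None:
            continue
        rows.append({"patient_id": recording.patient_id, "label": recording.label, **feats})
    if not rows:
        logger.warning("recording %r produced no valid segments", recording.patient_id)
        cols = ["patient_id", "label", *band_feature_names()] + [
            f"aux_{n}" for n in TIME_FEATURE_NAMES
        ]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def extract_cohort(
    recordings: list[Phonoangiogram], window: str = "rectangular", **kwargs
) -> pd.DataFrame:
    """Concatenated feature table over a list of recordings."""
    frames = [extract_features(r, window=window, **kwargs) for r in recordings]
    frames = [f for f in frames if len(f)]
    if not frames:
        return extract_features(recordings[0], window=window, **kwargs)
    return pd.concat(frames, ignore_index=True)


class BruitFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer from recordings to the per-cycle feature table.

    ``transform`` accepts a list of :class:`Phonoangiogram` and returns the
    concatenated feature DataFrame; stateless (``fit`` is a no-op), so it
    slots into sklearn pipelines ahead of a selector and classifier.
    """

    def __init__(
        self,
        window: str = "rectangular",
        min_cycle_s: float = DEFAULT_MIN_CYCLE_S,
        envelope_window_s: float = DEFAULT_ENVELOPE_WINDOW_S,
        prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    ):
        self.window = window
        self.min_cycle_s = min_cycle_s
        self.envelope_window_s = envelope_window_s
        self.prominence_frac = prominence_frac

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X: list[Phonoangiogram]) -> pd.DataFrame:
        return extract_cohort(
            list(X),
            window=self.window,
            min_cycle_s=self.min_cycle_s,
            envelope_window_s=self.envelope_window_s,
            prominence_frac=self.prominence_frac,
        )
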