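"""PSD estimation and the 112-column band-power feature table.

Features are the absolute (uV^2) and relative (%) power in seven bands —
delta [1,4), theta [4,8), alpha [8,13), beta [13,30), low beta [13,20),
high beta [20,30), gamma [30,45] Hz — on 8 channels, i.e. 8 x 7 x 2 = 112
features per (subject, setting, condition) cell. Band edges are half-open at
shared boundaries so the five canonical bands (delta, theta, alpha, beta,
gamma) tile [1, 45] Hz exactly; relative power uses that broadband total as
its denominator, so the canonical five always sum to 100%.

PSD is estimated by Welch's method (Hann window, 50% overlap, segment length
min(1 s, epoch length)); per-epoch features are averaged arithmetically over
all epochs of a condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EpochSet, DEFAULT_CHANNELS

__all__ = [
    "BANDS",
    "CANONICAL_BANDS",
    "TOTAL_BAND",
    "Spectrum",
    "psd_welch",
    "band_power",
    "relative_power",
    "extract_condition_features",
    "feature_columns",
    "feature_table",
]

#: name -> (low_hz, high_hz); half-open [low, high) except gamma closed at 45.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "low_beta": (13.0, 20.0),
    "high_beta": (20.0, 30.0),
    "gamma": (30.0, 45.0),
}

CANONICAL_BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: Broadband range used as the relative-power denominator.
TOTAL_BAND: tuple[float, float] = (1.0, 45.0)

POWER_TYPES: tuple[str, ...] = ("absolute", "relative")


@dataclass(frozen=True)
class Spectrum:
    """One-sided PSD on a uniform grid: ``density`` is channels x freqs, uV^2/Hz."""

    frequencies: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, float)
        d = np.atleast_2d(np.asarray(self.density, float))
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "density", d)
        if d.shape[-1] != f.size:
            raise ValueError("density/frequency grid mismatch")
        if f.size > 1 and not np.allclose(np.diff(f), f[1] - f[0]):
            raise ValueError("frequency grid must be uniform")
        if np.any(d < -1e-12):
            raise ValueError("PSD must be non-negative")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def psd_welch(data: np.ndarray, sfreq: float, segment_s: float = 1.0,
              overlap: float = 0.5) -> Spectrum:
    """Welch PSD of a channels x samples array (Hann, 50% overlap default).

    The segment length is min(segment_s, signal length); requesting a segment
    longer than the data raises. With ``segment_s`` equal to the full epoch
    length and no averaging this reduces to the plain periodogram.
    """
    data = np.atleast_2d(np.asarray(data, float))
    n = data.shape[-1]
    nperseg = int(round(segment_s * sfreq))
    if nperseg > n:
        raise ValueError(
            f"epoch of {n} samples shorter than Welch segment ({nperseg})")
    f, p = signal.welch(data, fs=sfreq, window="hann", nperseg=min(nperseg, n),
                        noverlap=int(min(nperseg, n) * overlap), axis=-1)
    return Spectrum(f, p)


def _band_mask(spec: Spectrum, low: float, high: float) -> np.ndarray:
    f = spec.frequencies
    if low < f[0] - spec.df / 2 or high > f[-1] + spec.df / 2:
        raise ValueError(f"band [{low}, {high}] outside spectral range")
    closed_top = high >= TOTAL_BAND[1]  # gamma / broadband close at 45 Hz
    return (f >= low) & ((f <= high) if closed_top else (f < high))


def band_power(spec: Spectrum, band: str | tuple[float, float]) -> np.ndarray:
    """Absolute band power (uV^2) per channel: sum of density x bin width."""
    low, high = BANDS[band] if isinstance(band, str) else band
    mask = _band_mask(spec, low, high)
    return spec.density[..., mask].sum(axis=-1) * spec.df


def relative_power(spec: Spectrum, band: str | tuple[float, float]) -> np.ndarray:
    """Band power as % of the broadband [1, 45] Hz total, per channel."""
    total = band_power(spec, TOTAL_BAND)
    if np.any(total <= 0):
        raise ValueError("zero total power: relative power undefined")
    return 100.0 * band_power(spec, band) / total


def feature_columns(channels: Iterable[str] = DEFAULT_CHANNELS) -> list[str]:
    """The canonical 112 feature column names, channel-major order."""
    return [f"{ch}|{band}|{ptype}"
            for ch in channels for band in BANDS for ptype in POWER_TYPES]


def _epoch_features(data: np.ndarray, sfreq: float,
                    segment_s: float) -> np.ndarray:
    """channels x (7 bands x 2 types) feature block for one epoch."""
    spec = psd_welch(data, sfreq, segment_s=segment_s)
    total = band_power(spec, TOTAL_BAND)
    if np.any(total <= 0):
        raise ValueError("zero total power in an epoch")
    cols = []
    for band in BANDS:
        absolute = band_power(spec, band)
        cols.append(absolute)
        cols.append(100.0 * absolute / total)
    return np.stack(cols, axis=1)  # ch x 14


def extract_condition_features(
    epochs: EpochSet,
    subject: int | str,
    setting: str,
    condition: str,
    level: int | None = None,
    segment_s: float = 1.0,
) -> pd.Series:
    """Average the 112 per-epoch band-power features over all epochs.

    Returns a Series with metadata fields (subject, setting, condition,
    level, n_epochs) followed by the 112 feature columns.
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty EpochSet: no epochs to average")
    seg = min(segment_s, epochs.epoch_duration)
    per_epoch = np.stack([
        _epoch_features(epochs.epochs[i], epochs.sfreq, seg)
        for i in range(epochs.n_epochs)
    ])                                   # epochs x ch x 14
    mean = per_epoch.mean(axis=0).reshape(-1)
    meta = {"subject": subject, "setting": setting, "condition": condition,
            "level": level, "n_epochs": epochs.n_epochs}
    return pd.Series({**meta, **dict(zip(feature_columns(epochs.channels), mean))})


def feature_table(rows: Iterable[pd.Series | Mapping]) -> pd.DataFrame:
    """Assemble condition rows into a subject x condition feature table."""
    df = pd.DataFrame([pd.Series(r) for r in rows]).reset_index(drop=True)
    missing = [c for c in feature_columns() if c not in df.columns]
    if missing and len(missing) < 112:
        raise ValueError(f"feature table missing columns, e.g. {missing[:3]}")
    return df
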