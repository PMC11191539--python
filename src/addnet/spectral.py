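"""Band-pass filtering, analytic signals, relative band power, median frequency.

Filtering is zero-phase frequency-domain masking with one-bin raised-cosine
edges; analytic signals use the one-sided-spectrum (FFT phase-shift) Hilbert
construction.  Spectral estimates are single-epoch periodograms; band
integrals use half-open intervals ``[low, high)`` so disjoint bands tiling the
total range sum exactly to the total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert as _hilbert
from scipy.signal import periodogram

__all__ = [
    "BandDefinition",
    "FC_BANDS",
    "POWER_BANDS",
    "TOTAL_RANGE",
    "AnalyticSignal",
    "bandpass",
    "analytic",
    "relative_band_power",
    "median_frequency",
    "peak_frequency",
    "edge_trim_slice",
    "epoch_spectral_summary",
]

#: default spectral integration range (Hz)
TOTAL_RANGE = (0.5, 48.0)

#: fraction of samples discarded at each epoch edge for phase/envelope averages
EDGE_TRIM_FRACTION = 0.01


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.name}: need 0 < low < high")


def _band_dict(pairs) -> dict[str, BandDefinition]:
    return {n: BandDefinition(n, lo, hi) for n, (lo, hi) in pairs.items()}


#: bands in which functional connectivity is evaluated
FC_BANDS = _band_dict(
    {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}
)

#: bands for relative-power time courses (gamma upper edge is a configurable default)
POWER_BANDS = _band_dict(
    {
        "delta": (0.5, 4.0),
        "theta": (4.0, 8.0),
        "alpha1": (8.0, 10.0),
        "alpha2": (10.0, 13.0),
        "beta": (13.0, 30.0),
        "gamma": (30.0, 48.0),
    }
)


def edge_trim_slice(n_samples: int, fraction: float = EDGE_TRIM_FRACTION) -> slice:
    """Interior slice excluding ``fraction`` of samples at each edge."""
    k = int(round(n_samples * fraction))
    return slice(k, n_samples - k if k else n_samples)


def bandpass(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase band-pass via FFT masking (along axis 0 for 2-D input).

    Gain is 1 inside ``[low, high]``, 0 beyond one frequency bin outside, with
    a half-cosine taper over the single transition bin.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 64:
        raise ValueError("series too short to filter (need >= 64 samples)")
    if band.high >= fs / 2:
        raise ValueError(f"band {band.name} ({band.high} Hz) exceeds Nyquist ({fs / 2} Hz)")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    df = fs / n
    gain = np.zeros_like(freqs)
    inside = (freqs >= band.low) & (freqs <= band.high)
    gain[inside] = 1.0
    for edge, sgn in ((band.low, -1.0), (band.high, 1.0)):
        trans = (freqs - edge) * sgn
        sel = (trans > 0) & (trans < df)
        gain[sel] = 0.5 * (1.0 + np.cos(np.pi * trans[sel] / df))
    spec = np.fft.rfft(x, axis=0)
    shape = (-1,) + (1,) * (x.ndim - 1)
    return np.fft.irfft(spec * gain.reshape(shape), n=n, axis=0)


@dataclass(frozen=True)
class AnalyticSignal:
    """Analytic signal ``z = x + i x~ = A exp(i phi)`` of a real series."""

    real: np.ndarray
    imag: np.ndarray

    @property
    def z(self) -> np.ndarray:
        return self.real + 1j * self.imag

    @property
    def phase(self) -> np.ndarray:
        """Instantaneous phase in (-pi, pi]."""
        return np.arctan2(self.imag, self.real)

    @property
    def envelope(self) -> np.ndarray:
        """Instantaneous amplitude ``sqrt(x^2 + x~^2)``."""
        return np.hypot(self.real, self.imag)


def analytic(x: np.ndarray) -> AnalyticSignal:
    """One-sided-spectrum analytic signal (Hilbert transform along axis 0)."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x, axis=0).min() == 0:
        warnings.warn("constant series: instantaneous phase is undefined", stacklevel=2)
    z = _hilbert(x, axis=0)
    return AnalyticSignal(real=np.real(z), imag=np.imag(z))


def _mean_periodogram(x: np.ndarray, fs: float):
    x = np.asarray(x, dtype=float)
    f, p = periodogram(x - x.mean(axis=0), fs=fs, axis=0)
    if p.ndim > 1:
        p = p.mean(axis=tuple(range(1, p.ndim)))
    return f, p


def relative_band_power(
    x: np.ndarray,
    fs: float,
    bands: dict[str, BandDefinition] | None = None,
    total_range: tuple[float, float] = TOTAL_RANGE,
) -> dict[str, float]:
    """Fraction of total power (within ``total_range``) in each band.

    Multi-channel input (samples x channels) is averaged across channels.
    """
    bands = bands or POWER_BANDS
    f, p = _mean_periodogram(x, fs)
    total = p[(f >= total_range[0]) & (f < total_range[1])].sum()
    if total <= 0:
        raise ValueError("zero total power in range")
    return {
        name: float(p[(f >= b.low) & (f < b.high)].sum() / total) for name, b in bands.items()
    }


def median_frequency(
    x: np.ndarray, fs: float, frange: tuple[float, float] = TOTAL_RANGE
) -> float:
    """Frequency below which half of the in-range power lies (bin-interpolated)."""
    f, p = _mean_periodogram(x, fs)
    sel = (f >= frange[0]) & (f < frange[1])
    fr, pr = f[sel], p[sel]
    total = pr.sum()
    if total <= 0:
        raise ValueError("zero power in range")
    cum = np.cumsum(pr)
    k = int(np.searchsorted(cum, 0.5 * total))
    prev = cum[k - 1] if k > 0 else 0.0
    frac = (0.5 * total - prev) / pr[k] if pr[k] > 0 else 0.0
    df = f[1] - f[0]
    return float(fr[k] - df / 2 + frac * df)


def peak_frequency(
    x: np.ndarray, fs: float, frange: tuple[float, float] = TOTAL_RANGE
) -> float:
    """Frequency of the periodogram maximum within ``frange``."""
    f, p = _mean_periodogram(x, fs)
    sel = (f >= frange[0]) & (f < frange[1])
    if not sel.any() or p[sel].sum() <= 0:
        raise ValueError("zero power in range")
    return float(f[sel][np.argmax(p[sel])])


def epoch_spectral_summary(
    signals: np.ndarray,
    fs: float,
    bands: dict[str, BandDefinition] | None = None,
    total_range: tuple[float, float] = TOTAL_RANGE,
) -> dict[str, float]:
    """Relative power per band plus median and peak frequency for one epoch."""
    out = {f"rel_{k}": v for k, v in relative_band_power(signals, fs, bands, total_range).items()}
    out["median_frequency"] = median_frequency(signals, fs, total_range)
    out["peak_frequency"] = peak_frequency(signals, fs, total_range)
    return out
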