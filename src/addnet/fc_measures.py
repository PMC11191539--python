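"""Pairwise functional-connectivity measures: AEC/AECc, PLI, PLT, JPE.

All four are symmetric under channel swap and, by construction, blind to
purely volume-conducted (zero-lag, positively scaled) coupling: the PLI and
PLT vanish for identical phases, the AECc orthogonalizes before correlating,
and the JPE excludes symmetric and anti-symmetric ordinal-pattern pairs.

Conventions that deviate from naive readings of the defining formulas (the
restored time average in the PLI, the ``1 - exp(-T)`` form of the PLT, and
the ``1 - H/H_max`` orientation of the JPE) are documented on the individual
functions; literal variants stay available behind flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert as _hilbert

from .spectral import EDGE_TRIM_FRACTION, BandDefinition, bandpass, edge_trim_slice

__all__ = [
    "MEASURES",
    "OrdinalPatternConfig",
    "FCMatrix",
    "aec",
    "pli",
    "plt",
    "jpe",
    "symbolize",
    "fc_matrix",
    "roi_means",
    "whole_brain_mean",
]

#: measures computable by :func:`fc_matrix`
MEASURES = ("AEC", "AECc", "PLI", "PLT", "JPE")


@dataclass(frozen=True)
class OrdinalPatternConfig:
    """Ordinal-pattern settings: pattern length ``n``, time lag ``tau``."""

    n: int = 4
    tau: int = 1

    def __post_init__(self) -> None:
        if self.n < 2 or self.tau < 1:
            raise ValueError("need n >= 2 and tau >= 1")

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.n)

    @property
    def max_entropy(self) -> float:
        """log((n! - 1)^2): joint entropy ceiling after (anti)symmetric exclusion."""
        return math.log((self.n_patterns - 1) ** 2)

    @property
    def span(self) -> int:
        return (self.n - 1) * self.tau


# cached per (n,): (code lookup over base-n keys, reversal map)
_PATTERN_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _pattern_tables(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _PATTERN_CACHE:
        perms = list(permutations(range(n)))
        lookup = np.full(n**n, -1, dtype=np.int64)
        powers = n ** np.arange(n)
        for code, p in enumerate(perms):
            lookup[int(np.dot(p, powers))] = code
        index = {p: i for i, p in enumerate(perms)}
        reverse = np.array([index[p[::-1]] for p in perms], dtype=np.int64)
        _PATTERN_CACHE[n] = (lookup, reverse)
    return _PATTERN_CACHE[n]


def symbolize(x: np.ndarray, cfg: OrdinalPatternConfig = OrdinalPatternConfig()) -> np.ndarray:
    """Map a series to ordinal-pattern codes (rank order, highest sample = rank 1).

    Codes index the ``n!`` permutations; ties rank the earlier sample higher.
    Output length is ``len(x) - (n - 1) * tau``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("symbolize expects a 1-D series")
    if len(x) <= cfg.span + 1:
        raise ValueError(f"series too short for patterns (need > {cfg.span + 1} samples)")
    win = sliding_window_view(x, cfg.span + 1)[:, :: cfg.tau]
    order = np.argsort(-win, axis=1, kind="stable")
    lookup, _ = _pattern_tables(cfg.n)
    powers = cfg.n ** np.arange(cfg.n)
    return lookup[order @ powers]


def pli(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase lag index: absolute time average of ``sign(sin(phase difference))``.

    The defining formula omits the time average over samples; it is restored
    here (matching the measure's original definition), with ``sign(0)``
    contributing zero.  Range [0, 1]; 0 for identical phases.
    """
    dphi = np.asarray(phase_x, dtype=float) - np.asarray(phase_y, dtype=float)
    return float(abs(np.mean(np.sign(np.sin(dphi)))))


def plt(
    phase_x: np.ndarray,
    phase_y: np.ndarray,
    fs: float,
    boundary: str = "truncated",
) -> float:
    """Phase lag time: ``1 - exp(-T)`` with ``T`` the mean duration (s) of
    intervals between successive sign changes of the phase difference.

    The printed form ``1 - e^T`` cannot lie in [0, 1); the sign of the
    exponent is corrected so volume conduction (zero phase difference, T
    treated as 0) maps to 0 and persistent lead/lag maps toward 1.

    ``boundary='truncated'`` (default) counts the partial intervals at the
    epoch edges with their truncated durations; ``boundary='complete'``
    averages only interior complete intervals (falling back to the full
    window duration when no sign change occurs).
    """
    if boundary not in ("truncated", "complete"):
        raise ValueError("boundary must be 'truncated' or 'complete'")
    dphi = np.asarray(phase_x, dtype=float) - np.asarray(phase_y, dtype=float)
    s = np.sign(np.sin(dphi))
    nz = np.flatnonzero(s)
    if nz.size == 0:  # identically zero phase difference (volume conduction)
        return 0.0
    sn = s[nz]
    change = np.flatnonzero(sn[:-1] != sn[1:])
    duration = len(dphi) / fs
    if boundary == "truncated":
        t_mean = duration / (len(change) + 1)
    else:
        if len(change) >= 2:
            # change k happens between original samples nz[change[k]] and nz[change[k]+1]
            pts = (nz[change] + nz[change + 1]) / 2.0
            t_mean = float(np.mean(np.diff(pts))) / fs
        else:
            t_mean = duration
    return 1.0 - math.exp(-t_mean)


def jpe(
    x: np.ndarray,
    y: np.ndarray,
    cfg: OrdinalPatternConfig = OrdinalPatternConfig(),
    literal: bool = False,
) -> float:
    """Joint permutation entropy of co-occurring ordinal patterns, normalized
    and oriented to increase with coupling.

    Symbol pairs where the two patterns are identical or exact rank reversals
    of each other are excluded before the joint histogram is formed (volume
    conduction correction).  With natural-log Shannon entropy ``H`` of the
    remaining pairs, the returned value is ``1 - H / log((n! - 1)^2)``;
    ``literal=True`` instead returns the sign-inverted unshifted form
    ``-H / log((n! - 1)^2)``.

    A fully (anti)symmetric pair (e.g. ``y`` is ``x`` exactly) leaves no
    co-occurrences: a warning is emitted and the degenerate maximum-coupling
    value is returned.
    """
    sx = symbolize(x, cfg)
    sy = symbolize(y, cfg)
    _, reverse = _pattern_tables(cfg.n)
    keep = (sy != sx) & (sy != reverse[sx])
    if not keep.any():
        warnings.warn("degenerate: fully symmetric channel pair", stacklevel=2)
        h = 0.0
    else:
        counts = np.bincount(
            sx[keep] * cfg.n_patterns + sy[keep], minlength=cfg.n_patterns**2
        )
        p = counts[counts > 0] / keep.sum()
        h = float(-(p * np.log(p)).sum())
    if literal:
        return -h / cfg.max_entropy
    return 1.0 - h / cfg.max_entropy


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        raise ValueError("zero-variance envelope")
    return float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))


def aec(
    x: np.ndarray,
    y: np.ndarray,
    corrected: bool = False,
    edge_trim: float = EDGE_TRIM_FRACTION,
) -> float:
    """Amplitude envelope correlation of two band-filtered series.

    Uncorrected: Pearson correlation of the Hilbert envelopes.  Corrected
    (AECc): remove the instantaneous least-squares projection of one series
    on the other, correlate the envelopes of the residual and the reference,
    repeat with roles swapped, and average.  A residual that is numerically
    null (``y`` proportional to ``x``) contributes 0 by convention.

    Envelope samples within ``edge_trim`` of the epoch edges are excluded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    tr = edge_trim_slice(len(x), edge_trim)
    zx = _hilbert(x)
    zy = _hilbert(y)
    if not corrected:
        return _pearson(np.abs(zx)[tr], np.abs(zy)[tr])
    vals = []
    for za, a, zb, b in ((zx, x, zy, y), (zy, y, zx, x)):
        beta = float(np.dot(a, b) / np.dot(a, a))
        resid_env = np.abs(zb - beta * za)[tr]
        if resid_env.max() < 1e-10 * np.abs(zb)[tr].max():
            vals.append(0.0)
        else:
            vals.append(_pearson(np.abs(za)[tr], resid_env))
    return float(np.mean(vals))


@dataclass
class FCMatrix:
    """N x N symmetric matrix of one connectivity measure, one band, one epoch."""

    measure: str
    band: BandDefinition
    values: np.ndarray
    epoch_index: int | None = None
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("FC matrix must be symmetric")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def fc_matrix(
    signals: np.ndarray,
    measure: str,
    band: BandDefinition,
    fs: float,
    epoch_index: int | None = None,
    cfg: OrdinalPatternConfig = OrdinalPatternConfig(),
    edge_trim: float = EDGE_TRIM_FRACTION,
    plt_boundary: str = "truncated",
    labels: list[str] | None = None,
) -> FCMatrix:
    """Compute one measure for all channel pairs of a (samples x channels) epoch.

    Channel-shared quantities (filtered series, analytic signals, ordinal
    symbols) are computed once; pairwise values agree with looping the
    pairwise functions over raw channel pairs to float-roundoff accuracy.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[1] < 2:
        raise ValueError("signals must be (samples x channels) with >= 2 channels")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    n_samp, n_ch = signals.shape
    xf = bandpass(signals, band, fs)
    out = np.zeros((n_ch, n_ch))
    tr = edge_trim_slice(n_samp, edge_trim)

    if measure == "JPE":
        syms = [symbolize(xf[:, i], cfg) for i in range(n_ch)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(n_ch):
                for j in range(i + 1, n_ch):
                    out[i, j] = out[j, i] = _jpe_from_symbols(syms[i], syms[j], cfg)
        return FCMatrix(measure, band, out, epoch_index, labels or [])

    z = _hilbert(xf, axis=0)
    if measure in ("PLI", "PLT"):
        ph = np.angle(z)[tr]
        for i in range(n_ch):
            for j in range(i + 1, n_ch):
                if measure == "PLI":
                    val = pli(ph[:, i], ph[:, j])
                else:
                    val = plt(ph[:, i], ph[:, j], fs, boundary=plt_boundary)
                out[i, j] = out[j, i] = val
        return FCMatrix(measure, band, out, epoch_index, labels or [])

    env = np.abs(z)[tr]
    if measure == "AEC":
        c = np.corrcoef(env.T)
        out = c - np.diag(np.diag(c))
        return FCMatrix(measure, band, out, epoch_index, labels or [])

    # AECc via linearity of the Hilbert transform: hilbert(y - beta x) = zy - beta zx
    dots = xf.T @ xf
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            vals = []
            for a, b in ((i, j), (j, i)):
                beta = dots[a, b] / dots[a, a]
                resid_env = np.abs(z[:, b] - beta * z[:, a])[tr]
                if resid_env.max() < 1e-10 * np.abs(z[:, b])[tr].max():
                    vals.append(0.0)
                else:
                    vals.append(_pearson(env[:, a], resid_env))
            out[i, j] = out[j, i] = float(np.mean(vals))
    return FCMatrix(measure, band, out, epoch_index, labels or [])


def _jpe_from_symbols(sx: np.ndarray, sy: np.ndarray, cfg: OrdinalPatternConfig) -> float:
    _, reverse = _pattern_tables(cfg.n)
    keep = (sy != sx) & (sy != reverse[sx])
    if not keep.any():
        warnings.warn("degenerate: fully symmetric channel pair", stacklevel=2)
        return 1.0
    counts = np.bincount(sx[keep] * cfg.n_patterns + sy[keep], minlength=cfg.n_patterns**2)
    p = counts[counts > 0] / keep.sum()
    h = float(-(p * np.log(p)).sum())
    return 1.0 - h / cfg.max_entropy


def roi_means(m: FCMatrix) -> np.ndarray:
    """Mean off-diagonal connectivity of each ROI (row means excluding self)."""
    v = m.values
    n = v.shape[0]
    return (v.sum(axis=1) - np.diag(v)) / (n - 1)


def whole_brain_mean(m: FCMatrix) -> float:
    """Mean over all off-diagonal entries."""
    v = m.values
    n = v.shape[0]
    return float((v.sum() - np.trace(v)) / (n * (n - 1)))
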