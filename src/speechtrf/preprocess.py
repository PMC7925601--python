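"""EEG preprocessing: resampling, band-pass filtering, bad-channel handling,
spherical-spline interpolation and mastoid referencing.

The canonical chain is downsample -> band-pass -> bad-channel detection and
interpolation -> mastoid referencing -> (group MCCA, see
:mod:`speechtrf.mcca`).
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from numpy.polynomial import legendre
from scipy import signal

from .containers import ChannelLayout, EEGRecording, MASTOID

__all__ = [
    "downsample",
    "bandpass",
    "detect_bad_channels",
    "interpolate_channels",
    "rereference",
]


def downsample(rec: EEGRecording, target_fs: float = 128.0) -> EEGRecording:
    """Anti-aliased polyphase resampling to ``target_fs``.

    ``target_fs`` must rationally relate to ``rec.fs`` and may not exceed it.
    """
    if target_fs > rec.fs:
        raise ValueError(f"target_fs {target_fs} exceeds fs {rec.fs}")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    if not math.isclose(float(frac), target_fs / rec.fs, rel_tol=1e-9):
        raise ValueError(
            f"target_fs {target_fs} not rationally related to fs {rec.fs}"
        )
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.with_data(out, fs=target_fs)


def bandpass(
    rec: EEGRecording, lo: float = 0.5, hi: float = 8.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward, order doubles)."""
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError(f"invalid band ({lo}, {hi}) at fs {rec.fs}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


def detect_bad_channels(rec: EEGRecording, factor: float = 2.5) -> np.ndarray:
    """Flag channels whose sd deviates from the others' by more than ``factor``.

    A channel is bad when its standard deviation exceeds ``factor`` times the
    mean standard deviation of all *other* channels, or falls below that mean
    divided by ``factor``. Raises if every channel is flagged (unusable trial).
    """
    if rec.n_channels < 3:
        raise ValueError("need at least 3 channels")
    sds = rec.data.std(axis=1)
    total = sds.sum()
    n = rec.n_channels
    loo_mean = (total - sds) / (n - 1)
    bad = (sds > factor * loo_mean) | (sds < loo_mean / factor)
    if bad.all():
        raise ValueError("all channels flagged bad; trial unusable")
    return bad


def _spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 7) -> np.ndarray:
    """Spherical-spline basis g(cos angle), order-m Legendre series."""
    coef = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        coef[n] = (2 * n + 1) / (n**m * (n + 1) ** m)
    return legendre.legval(cosang, coef) / (4 * np.pi)


def interpolate_channels(
    rec: EEGRecording,
    layout: ChannelLayout,
    bad_mask: np.ndarray | None = None,
    order: int = 4,
    n_terms: int = 7,
    reg: float = 0.0,
) -> EEGRecording:
    """Replace bad channels by spherical-spline interpolation of clean ones.

    Uses the standard spherical-spline formulation (order-``order`` Legendre
    expansion truncated at ``n_terms`` terms) with a constant term; clean
    channels are returned untouched. The linear system is solved by least
    squares so exactly co-located sensors remain well posed.
    """
    # reg=0 with a least-squares solve keeps interpolation exact at sensor
    # sites even when two sensors coincide (exactly singular Gram matrix).
    mask = rec.bad_mask if bad_mask is None else np.asarray(bad_mask, dtype=bool)
    if layout.n_channels != rec.n_channels:
        raise ValueError("layout/recording channel count mismatch")
    if not mask.any():
        return rec
    good = ~mask
    if good.sum() < 4:
        raise ValueError("need at least 4 clean channels to interpolate")
    pos_g = layout.positions[good]
    pos_b = layout.positions[mask]
    G = _spline_g(pos_g @ pos_g.T, m=order, n_terms=n_terms)
    G = G + reg * np.eye(G.shape[0])
    Gb = _spline_g(pos_b @ pos_g.T, m=order, n_terms=n_terms)
    ng = G.shape[0]
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    Y = np.vstack([rec.data[good], np.zeros(rec.n_samples)])
    sol, *_ = np.linalg.lstsq(A, Y, rcond=None)
    c, d = sol[:ng], sol[ng]
    data = rec.data.copy()
    data[mask] = Gb @ c + d
    out = rec.with_data(data)
    out.bad_mask = mask.copy()
    return out


def rereference(rec: EEGRecording) -> EEGRecording:
    """Subtract the mean of the two mastoid channels from every channel."""
    idx = rec.mastoid_indices()
    if len(idx) != 2:
        raise ValueError(f"need exactly 2 mastoid channels, found {len(idx)}")
    ref = rec.data[idx].mean(axis=0)
    return rec.with_data(rec.data - ref)
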