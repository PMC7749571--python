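"""Artifact screening, interference filtering, spike screening, clean-window
selection and multi-band decomposition.

The processing chain mirrors standard resting-state MEG practice: samples with
any channel exceeding an absolute amplitude bound (default 6 pT) are excluded;
mains interference around 50 Hz is notch-filtered; high-amplitude epileptiform
transients are flagged on the 1-70 Hz filtered signal with a robust z-score
(an algorithmic stand-in for visual spike marking); the earliest contiguous
window (default 60 s) free of flagged samples is selected; and that window is
decomposed into the seven canonical bands, delta through fast ripple, with
zero-phase band-pass filters.

All filters are 4th-order Butterworth applied forward-backward
(``sosfiltfilt``), so the effective magnitude response is |H|^2 and the phase
response is exactly zero — a property the correlation-based connectivity stage
depends on.  The synthetic generator reuses these same filters, so planted
band-limited correlations survive re-filtering unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import signal

from .io_core import (
    AnalysisConfig,
    BandDefinition,
    ParameterError,
    ScreeningError,
    SourceTimeSeries,
)

logger = logging.getLogger(__name__)

FILTER_ORDER = 4


# ---------------------------------------------------------------------------
# filter design + spectral gain integrals
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def band_sos(lo: float, hi: float, fs: float) -> tuple:
    """4th-order Butterworth band-pass in second-order sections (cached)."""
    if not (0 < lo < hi < fs / 2):
        raise ParameterError(
            f"band ({lo}, {hi}) Hz invalid at fs={fs} (Nyquist {fs / 2})"
        )
    sos = signal.butter(FILTER_ORDER, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return tuple(map(tuple, sos))


def _sos_array(sos: tuple) -> np.ndarray:
    return np.asarray(sos, dtype=np.float64)


@lru_cache(maxsize=256)
def _mag2_grid(lo: float, hi: float, fs: float, worN: int = 8192):
    """|H(f)|^2 of the single-pass filter on a uniform grid up to Nyquist."""
    w, h = signal.sosfreqz(_sos_array(band_sos(lo, hi, fs)), worN=worN, fs=fs)
    return w, np.abs(h) ** 2


@lru_cache(maxsize=256)
def filtfilt_noise_gain(lo: float, hi: float, fs: float) -> float:
    """Variance of unit white noise after forward-backward band-pass.

    filtfilt squares the magnitude response, so the output power of unit-
    variance white noise is (2/fs) * integral_0^{fs/2} |H(f)|^4 df.
    """
    w, m2 = _mag2_grid(lo, hi, fs)
    return float(np.trapezoid(m2**2, w) * 2.0 / fs)


@lru_cache(maxsize=1024)
def cross_band_gain(
    lo_c: float, hi_c: float, lo_a: float, hi_a: float, fs: float
) -> float:
    """Variance of a *unit-variance* carrier of band c after re-filtering
    into analysis band a (both forward-backward).

    The carrier is white noise filtfilt'ed into band c and normalized to unit
    variance, so its spectral density is |H_c|^4 / g_c; passing through the
    analysis filtfilt multiplies by |H_a|^4.
    """
    w, m2c = _mag2_grid(lo_c, hi_c, fs)
    _, m2a = _mag2_grid(lo_a, hi_a, fs)
    g_c = filtfilt_noise_gain(lo_c, hi_c, fs)
    return float(np.trapezoid(m2c**2 * m2a**2, w) * 2.0 / fs / g_c)


def band_filter(data: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase band-pass of a channels × samples matrix.

    The edge padding is scaled to the low cutoff's impulse-response length
    (scipy's default pad is far too short for cutoffs near 1 Hz and leaves
    large boundary transients that masquerade as spikes).
    """
    data = np.asarray(data, dtype=np.float64)
    sos = _sos_array(band_sos(band.lo, band.hi, fs))
    padlen = min(data.shape[-1] - 1, max(int(3 * fs / band.lo), 24))
    return signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen_artifacts(ts: SourceTimeSeries, amp_pT: float = 6.0) -> np.ndarray:
    """Boolean mask, one entry per sample: True iff any channel's absolute
    amplitude exceeds ``amp_pT``."""
    if not amp_pT > 0:
        raise ParameterError(f"amp_pT must be positive, got {amp_pT}")
    return (np.abs(ts.data) > amp_pT).any(axis=0)


def notch_filter(ts: SourceTimeSeries, freq: float = 50.0, bw: float = 2.0) -> SourceTimeSeries:
    """Zero-phase notch at ``freq`` Hz (mains interference).

    A second-order IIR notch of -3 dB bandwidth ``bw`` applied forward-
    backward: >=20 dB attenuation at the notch, <1 dB ripple outside
    freq ± bw.
    """
    if freq >= ts.fs / 2:
        raise ParameterError(
            f"notch frequency {freq} Hz at or above Nyquist ({ts.fs / 2} Hz)"
        )
    b, a = signal.iirnotch(freq, Q=freq / bw, fs=ts.fs)
    return ts.copy_with(signal.filtfilt(b, a, ts.data, axis=-1))


def dilate_mask(mask: np.ndarray, n: int) -> np.ndarray:
    """Extend every flagged run by ``n`` samples on each side."""
    if n <= 0 or not mask.any():
        return mask.copy()
    idx = np.flatnonzero(mask)
    out = np.zeros_like(mask)
    lo = np.maximum(idx - n, 0)
    hi = np.minimum(idx + n + 1, len(mask))
    # mark [lo, hi) runs via difference array
    diff = np.zeros(len(mask) + 1, dtype=np.int64)
    np.add.at(diff, lo, 1)
    np.add.at(diff, hi, -1)
    return np.cumsum(diff[:-1]) > 0


def screen_spikes(
    ts: SourceTimeSeries,
    band: tuple[float, float] = (1.0, 70.0),
    z_thresh: float = 8.0,
    dilate_s: float = 0.2,
    edge_guard_s: float = 0.5,
) -> np.ndarray:
    """Flag spike-like transients on the band-filtered signal.

    A sample is flagged when any channel's 1-70 Hz filtered amplitude exceeds
    ``z_thresh`` robust deviations (median ± z * 1.4826 MAD); a channel with
    zero MAD falls back to its SD, and a fully constant channel contributes
    nothing.  Flags are dilated by ±``dilate_s`` seconds.  The first and last
    ``edge_guard_s`` seconds are never flagged: the zero-phase filter's
    boundary transient inflates amplitudes there and would produce spurious
    detections on perfectly clean data.
    """
    if z_thresh <= 0:
        raise ParameterError("z_thresh must be positive")
    lo, hi = band
    hi = min(hi, 0.45 * ts.fs)  # keep the visualization band legal at low fs
    if not (0 < lo < hi):
        raise ParameterError(f"invalid spike band {band} at fs={ts.fs}")
    filt = band_filter(ts.data, BandDefinition("spike_view", lo, hi), ts.fs)
    med = np.median(filt, axis=1, keepdims=True)
    mad = np.median(np.abs(filt - med), axis=1, keepdims=True)
    scale = 1.4826 * mad
    sd = filt.std(axis=1, keepdims=True)
    scale = np.where(scale > 0, scale, sd)
    # a (near-)constant channel leaves only numerical residue after the
    # band-pass; judge "constant" relative to the raw record's scale
    tol = 1e-12 * max(float(np.sqrt(np.mean(ts.data**2))), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(filt - med) / scale
    z = np.where(scale > tol, z, 0.0)
    mask = (z > z_thresh).any(axis=0)
    guard = int(round(edge_guard_s * ts.fs))
    if guard > 0 and guard < mask.size // 2:
        mask[:guard] = False
        mask[-guard:] = False
    return dilate_mask(mask, int(round(dilate_s * ts.fs)))


# ---------------------------------------------------------------------------
# clean-window selection + band decomposition
# ---------------------------------------------------------------------------

@dataclass
class CleanWindow:
    """A contiguous artifact/spike-free segment plus its per-band copies."""

    subject_id: str
    group: str
    fs: float
    channel_labels: tuple[str, ...]
    start: int
    stop: int  # half-open
    data: np.ndarray  # channels × (stop-start), after notch
    region_labels: Optional[dict[str, str]] = None
    band_data: dict[str, np.ndarray] = field(default_factory=dict)
    n_flagged: int = 0

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


def select_clean_window(
    ts: SourceTimeSeries, mask: np.ndarray, window_s: float = 60.0
) -> CleanWindow:
    """Earliest contiguous window of ``window_s`` seconds with no flagged
    sample.  Raises :class:`ScreeningError` naming the subject if none exists.
    """
    ws = int(round(window_s * ts.fs))
    if ws > ts.n_samples:
        raise ParameterError(
            f"window of {ws} samples exceeds record length {ts.n_samples}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ts.n_samples,):
        raise ParameterError("mask length must equal n_samples")
    cs = np.concatenate([[0], np.cumsum(mask.astype(np.int64))])
    window_bad = cs[ws:] - cs[:-ws]  # flagged count per candidate start
    clean = np.flatnonzero(window_bad == 0)
    if clean.size == 0:
        raise ScreeningError(
            f"subject {ts.subject_id}: no clean {window_s:g}-s window "
            f"({int(mask.sum())} of {ts.n_samples} samples flagged)"
        )
    start = int(clean[0])
    return CleanWindow(
        subject_id=ts.subject_id,
        group=ts.group,
        fs=ts.fs,
        channel_labels=ts.channel_labels,
        start=start,
        stop=start + ws,
        data=ts.data[:, start : start + ws].copy(),
        region_labels=ts.region_labels,
        n_flagged=int(mask.sum()),
    )


_warned_bands: set[tuple[str, float]] = set()


def usable_bands(
    bands: tuple[BandDefinition, ...], fs: float
) -> tuple[BandDefinition, ...]:
    """Drop (with a logged warning, once per band+fs) bands whose upper edge
    reaches Nyquist."""
    keep = []
    for b in bands:
        if b.hi < fs / 2:
            keep.append(b)
        elif (b.name, fs) not in _warned_bands:
            _warned_bands.add((b.name, fs))
            logger.warning(
                "dropping band %s (%g-%g Hz): upper edge >= Nyquist (%g Hz)",
                b.name, b.lo, b.hi, fs / 2,
            )
    return tuple(keep)


def bandpass_decompose(
    window: CleanWindow, bands: tuple[BandDefinition, ...]
) -> CleanWindow:
    """Populate ``window.band_data`` with zero-phase band-pass copies.

    Bands violating Nyquist at this sampling rate are skipped with a warning;
    an empty band list is a parameter error.
    """
    if not bands:
        raise ParameterError("empty band list")
    keep = usable_bands(bands, window.fs)
    if not keep:
        raise ParameterError(
            f"no band below Nyquist at fs={window.fs}; nothing to decompose"
        )
    for b in keep:
        window.band_data[b.name] = band_filter(window.data, b, window.fs)
    return window


def preprocess_subject(ts: SourceTimeSeries, config: AnalysisConfig) -> CleanWindow:
    """Full screening chain for one subject: amplitude screen -> notch ->
    spike screen -> clean-window selection -> band decomposition."""
    amask = screen_artifacts(ts, config.artifact_amp_pT)
    ts_n = notch_filter(ts, config.notch_hz)
    smask = screen_spikes(ts_n, config.spike_band, config.spike_z)
    window = select_clean_window(ts_n, amask | smask, config.window_s)
    return bandpass_decompose(window, config.bands)
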