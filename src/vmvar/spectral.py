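"""Spectral quantification of membrane-potential fluctuations.

Welch power-spectral density with 4-s Hann windows and 50% overlap, band
powers by composite-Simpson integration over the canonical EEG-style bands
(delta 0.5-4, theta 4-7, alpha 8-12, beta 13-30, gamma 30-100 Hz), a
single-periodogram variant for 200-ms trial baselines, and a complex Morlet
time-frequency transform whose per-frequency widths follow

    width(y) = (w * Fs) / (2 * y * pi)

with mother-wavelet frequency ``w`` (default 4 Hz) and sampling rate ``Fs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, signal

from .trace import ValidationError, VmTrace, TrialSet

__all__ = [
    "BandDefinition",
    "PSDResult",
    "WaveletPower",
    "DEFAULT_BANDS",
    "welch_psd",
    "band_power",
    "short_window_psd",
    "morlet_power",
    "morlet_width",
    "assign_band",
]

WELCH_SEGMENT_S = 4.0  # -> 0.25 Hz resolution


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValidationError(f"invalid band {self.name}: [{self.f_lo}, {self.f_hi}]")


#: Canonical band edges used throughout the analysis.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 100.0),
)


@dataclass
class PSDResult:
    freqs: np.ndarray  # Hz, uniform ascending
    psd: np.ndarray  # mV^2/Hz, one-sided density
    band_powers: dict[str, float] = field(default_factory=dict)

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def total_power(self) -> float:
        """Integrated PSD over the full one-sided grid (mV^2).

        Trapezoid rule: with the one-sided density scaling this equals the
        signal variance (Parseval) even for line spectra, where Simpson's
        alternating weights misweight a near-delta peak.
        """
        return float(integrate.trapezoid(self.psd, x=self.freqs))


@dataclass
class WaveletPower:
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s
    power: np.ndarray  # |coefficient|, shape (n_freqs, n_times)
    w: float  # mother wavelet frequency (Hz)
    widths: np.ndarray  # per-frequency scale factors (samples)
    display_saturation: float = 3.0  # presentation metadata only


def assign_band(
    freq: float, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> str | None:
    """Band containing ``freq``; shared edges belong to the upper band
    (half-open ``[f_lo, f_hi)``), except the last band which is closed."""
    for i, b in enumerate(bands):
        closed = i == len(bands) - 1
        if b.f_lo <= freq < b.f_hi or (closed and freq == b.f_hi):
            return b.name
    return None


def welch_psd(
    trace: VmTrace,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> PSDResult:
    """One-sided Welch PSD with 4-s Hann segments, 50% overlap, mean averaging.

    Density scaling is used so that the integral of the PSD over frequency
    equals the signal variance (Parseval). Requires at least one full 4-s
    segment; shorter epochs (per-trial baselines) go through
    :func:`short_window_psd` instead.
    """
    nperseg = int(round(WELCH_SEGMENT_S * trace.fs))
    if trace.n_samples < nperseg:
        raise ValidationError(
            "epoch shorter than the 4-s Welch window; use short_window_psd"
        )
    freqs, psd = signal.welch(
        trace.samples,
        fs=trace.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
        average="mean",
    )
    result = PSDResult(freqs=freqs, psd=psd)
    result.band_powers = {b.name: band_power(result, b) for b in bands}
    return result


def band_power(psd: PSDResult, band: BandDefinition) -> float:
    """Composite-Simpson integral of the PSD over ``[f_lo, f_hi]`` (mV^2)."""
    f_nyq = psd.freqs[-1]
    if band.f_lo < psd.freqs[0] or band.f_hi > f_nyq:
        raise ValidationError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] outside PSD grid"
        )
    sel = (psd.freqs >= band.f_lo - 1e-12) & (psd.freqs <= band.f_hi + 1e-12)
    if np.count_nonzero(sel) < 3:
        raise ValidationError(
            f"fewer than 3 PSD points in band {band.name}; resolution insufficient"
        )
    return float(integrate.simpson(psd.psd[sel], x=psd.freqs[sel]))


def short_window_psd(
    trialset: TrialSet,
    trial_idx: int,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> dict[str, dict[str, float]]:
    """Per-trial baseline band powers from a single Hann periodogram.

    A 4-s Welch segment cannot fit in the 200-ms pre-stimulus baseline, so the
    baseline spectrum is a single Hann-tapered periodogram (5 Hz resolution at
    the default window). Returns raw band powers and powers normalized by the
    magnitude of the mean baseline Vm.
    """
    x = trialset.baseline(trial_idx)
    fs = trialset.trace.fs
    freqs, psd = signal.periodogram(
        x, fs=fs, window="hann", detrend="constant", scaling="density"
    )
    df = freqs[1] - freqs[0]
    powers: dict[str, float] = {}
    # at ~5 Hz resolution the narrow bands hold too few bins for Simpson;
    # integrate by binned rectangles, NaN when a band contains no bin
    for i, b in enumerate(bands):
        closed = i == len(bands) - 1
        sel = (freqs >= b.f_lo) & ((freqs <= b.f_hi) if closed else (freqs < b.f_hi))
        powers[b.name] = float(np.sum(psd[sel]) * df) if np.any(sel) else np.nan
    vm_mag = abs(float(np.mean(x)))
    normalized = {
        name: (p / vm_mag if vm_mag > 0 else np.nan) for name, p in powers.items()
    }
    return {"band_powers": powers, "band_powers_norm": normalized}


def morlet_width(freq: float, fs: float, w: float = 4.0) -> float:
    """Per-frequency Morlet scale factor ``(w * Fs) / (2 * y * pi)``."""
    if freq <= 0:
        raise ValidationError("frequency must be positive")
    return (w * fs) / (2.0 * freq * np.pi)


def _morlet2(m: int, s: float, w: float) -> np.ndarray:
    """Complex Morlet wavelet on ``m`` samples at scale ``s`` (samples)."""
    x = (np.arange(0, m) - (m - 1.0) / 2) / s
    return np.sqrt(1.0 / s) * np.exp(1j * w * x) * np.exp(-0.5 * x**2) * np.pi**-0.25


def morlet_power(
    trace: VmTrace, freqs: np.ndarray, w: float = 4.0
) -> WaveletPower:
    """Complex Morlet wavelet power of a trace over the requested frequencies.

    The per-frequency widths follow the scale rule above; power is the
    magnitude of the complex coefficients. The 0-3 display saturation used for
    color plots is carried as presentation metadata only.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= trace.fs / 2):
        raise ValidationError("frequencies must lie in (0, fs/2)")
    n = trace.n_samples
    power = np.empty((freqs.size, n))
    widths = np.array([morlet_width(f, trace.fs, w) for f in freqs])
    for i, s in enumerate(widths):
        m = min(int(10 * s), n)
        wavelet = _morlet2(m, s, w)
        coef = signal.fftconvolve(trace.samples, np.conj(wavelet)[::-1], mode="same")
        power[i] = np.abs(coef)
    return WaveletPower(
        freqs=freqs, times=trace.times(), power=power, w=w, widths=widths
    )
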