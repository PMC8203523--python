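"""LFP preprocessing, Morlet spectrograms, and pairwise wavelet coherence.

The pipeline operates on local field potentials decimated to 1250 Hz
(anti-aliased at 300 Hz).  Time-frequency decomposition uses the analytic
Morlet wavelet (omega0 = 6) on a logarithmic frequency grid, and coherence
between two channels is the magnitude-squared smoothed cross-spectrum
normalised by the smoothed auto-spectra, averaged over a frequency band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import fft as sfft
from scipy import signal
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

#: Morlet wavelet non-dimensional centre frequency (omega0).
MORLET_OMEGA0 = 6.0
#: Centre frequency in cycles per unit time: scale = _FC * rate / freq.
_FC = MORLET_OMEGA0 / (2.0 * math.pi)

#: Gamma sub-bands (Hz).  The union 40-100 Hz is "gamma" writ large.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "low_gamma": (45.0, 75.0),
    "high_gamma": (75.0, 100.0),
}

LFP_RATE = 1250.0
DEFAULT_VOICES = 8


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelInfo:
    """One recording site: id, brain region, shank and site index, depth."""

    id: int
    region: str
    shank: int
    site: int
    depth_um: float


@dataclass
class LFPRecording:
    """Multichannel decimated field-potential matrix with probe geometry.

    ``samples`` is time x channel in microvolts at ``rate`` Hz (1250 Hz for
    the canonical pipeline).  Channel ids must be unique.
    """

    samples: np.ndarray
    rate: float
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [time x channel] array")
        if self.samples.shape[1] != len(self.channels):
            raise ValueError(
                f"sample matrix has {self.samples.shape[1]} columns but "
                f"{len(self.channels)} channel descriptors were given"
            )
        ids = [c.id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("channel ids must be unique")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def channel_ids(self) -> list[int]:
        return [c.id for c in self.channels]

    def channel_index(self, channel_id: int) -> int:
        for i, c in enumerate(self.channels):
            if c.id == channel_id:
                return i
        raise KeyError(f"channel id {channel_id} not in recording")

    def region_channels(self, region: str) -> list[ChannelInfo]:
        return [c for c in self.channels if c.region == region]

    def get(self, channel_id: int) -> np.ndarray:
        return self.samples[:, self.channel_index(channel_id)]


@dataclass
class Spectrogram:
    """Complex Morlet coefficients [frequency x time] for one channel."""

    coefficients: np.ndarray
    frequencies: np.ndarray
    rate: float

    @property
    def scales(self) -> np.ndarray:
        return _FC * self.rate / self.frequencies

    def power(self, normalize: bool = True) -> np.ndarray:
        """|W|^2, by default divided by scale so white noise is flat in f."""
        p = np.abs(self.coefficients) ** 2
        if normalize:
            p = p / self.scales[:, None]
        return p

    def coi_mask(self) -> np.ndarray:
        """Boolean [freq x time]; True where outside the cone of influence."""
        n = self.coefficients.shape[1]
        t = np.arange(n)
        edge = np.minimum(t, n - 1 - t)[None, :]
        coi = math.sqrt(2.0) * self.scales[:, None]
        return edge >= coi


@dataclass
class CoherenceSeries:
    """Band-averaged squared wavelet coherence between one channel pair."""

    pair: tuple[int, int]
    band: tuple[float, float]
    band_label: str
    values: np.ndarray
    rate: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones_like(self.values, dtype=bool)


# ---------------------------------------------------------------------------
# frequency grids
# ---------------------------------------------------------------------------


def log_freq_grid(
    f_min: float = 1.0, f_max: float = 110.0, voices: int = DEFAULT_VOICES
) -> np.ndarray:
    """Logarithmic frequency grid, ``voices`` points per octave."""
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    n = int(math.floor(voices * math.log2(f_max / f_min))) + 1
    freqs = f_min * 2.0 ** (np.arange(n) / voices)
    if freqs[-1] < f_max * (1 - 1e-9):
        freqs = np.append(freqs, f_max)
    return freqs


def resolve_band(band) -> tuple[str, tuple[float, float]]:
    """Accept a band label from ``DEFAULT_BANDS`` or an (f_lo, f_hi) tuple."""
    if isinstance(band, str):
        if band not in DEFAULT_BANDS:
            raise ValueError(f"unknown band label {band!r}")
        return band, DEFAULT_BANDS[band]
    lo, hi = float(band[0]), float(band[1])
    if not 0 < lo < hi:
        raise ValueError("band edges must satisfy 0 < f_lo < f_hi")
    return f"{lo:g}-{hi:g}Hz", (lo, hi)


def band_freq_grid(
    band: tuple[float, float], voices: int = DEFAULT_VOICES
) -> np.ndarray:
    """Grid points of the global log grid that fall inside ``band``."""
    lo, hi = band
    grid = lo * 2.0 ** (np.arange(int(math.floor(voices * math.log2(hi / lo))) + 1) / voices)
    grid = grid[grid <= hi * (1 + 1e-9)]
    if grid.size < 3:
        grid = np.geomspace(lo, hi, 3)
    return grid


# ---------------------------------------------------------------------------
# decimation
# ---------------------------------------------------------------------------


def decimate_lfp(
    raw: np.ndarray,
    raw_rate: float,
    channels: list[ChannelInfo] | None = None,
    target_rate: float = LFP_RATE,
    corner_hz: float = 300.0,
    transition_hz: float = 100.0,
    stopband_db: float = 60.0,
) -> LFPRecording:
    """Zero-phase FIR low-pass at ``corner_hz`` then resample to ``target_rate``.

    The filter is a Kaiser-window FIR with at least ``stopband_db``
    attenuation beyond ``corner_hz + transition_hz``; filtering is applied
    forward-backward (zero phase).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    if raw_rate < 2 * corner_hz:
        raise ValueError(
            f"raw rate {raw_rate} Hz is below twice the {corner_hz} Hz corner"
        )
    if corner_hz >= target_rate / 2:
        raise ValueError("anti-alias corner must be below the target Nyquist")

    if raw_rate != target_rate:
        numtaps, beta = signal.kaiserord(stopband_db, transition_hz / (raw_rate / 2.0))
        numtaps |= 1  # odd length for a symmetric (linear-phase) filter
        taps = signal.firwin(
            numtaps, corner_hz + transition_hz / 2.0, window=("kaiser", beta), fs=raw_rate
        )
        filtered = signal.filtfilt(taps, [1.0], raw, axis=0)
        ratio = Fraction(raw_rate / target_rate).limit_denominator(1000)
        if ratio.denominator == 1:
            out = filtered[:: ratio.numerator]
        else:
            out = signal.resample_poly(filtered, ratio.denominator, ratio.numerator, axis=0)
    else:
        out = raw

    if channels is None:
        channels = [
            ChannelInfo(id=i, region="NA", shank=0, site=i, depth_um=0.0)
            for i in range(out.shape[1])
        ]
    return LFPRecording(samples=out, rate=target_rate, channels=channels)


# ---------------------------------------------------------------------------
# continuous wavelet transform
# ---------------------------------------------------------------------------


def _cwt(data: np.ndarray, freqs: np.ndarray, rate: float) -> np.ndarray:
    """Analytic Morlet CWT along the last axis; returns [freq, ..., time].

    Implemented as FFT convolution with psi(t/s) where
    psi(t) = (2 pi)^(-1/2) exp(-t^2/2) exp(i omega0 t); the kernel is not
    amplitude-rescaled, so E|W|^2 for white noise grows linearly with
    scale and |W|^2 / scale (see :meth:`Spectrogram.power`) is flat across
    the grid.  Zero padding wide enough for the largest wavelet prevents
    wrap-around.
    """
    data = np.asarray(data, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= rate / 2):
        raise ValueError("frequencies must lie strictly inside (0, rate/2)")
    scales = _FC * rate / freqs  # in samples
    n = data.shape[-1]
    nfft = sfft.next_fast_len(n + int(math.ceil(8.0 * scales.max())))
    xf = sfft.fft(data, nfft, axis=-1)
    omega = 2.0 * math.pi * np.arange(nfft) / nfft  # rad / sample, [0, 2pi)
    out = np.empty(scales.shape + data.shape, dtype=complex)
    for i, s in enumerate(scales):
        # DFT of psi(t/s): the response at wrapped (negative) frequencies
        # is < exp(-omega0^2/2) ~ 1e-8 and vanishes naturally.
        kernel = s * np.exp(-0.5 * (s * omega - MORLET_OMEGA0) ** 2)
        out[i] = sfft.ifft(xf * kernel, axis=-1)[..., :n]
    return out


def cwt_spectrogram(
    rec: LFPRecording,
    channel: int,
    freqs: np.ndarray | None = None,
    f_min: float = 1.0,
    f_max: float = 110.0,
    voices: int = DEFAULT_VOICES,
) -> Spectrogram:
    """Morlet spectrogram of one channel (default log grid 1-110 Hz)."""
    if freqs is None:
        freqs = log_freq_grid(f_min, f_max, voices)
    freqs = np.asarray(freqs, dtype=float)
    x = rec.get(channel)
    coef = _cwt(x, freqs, rec.rate)
    return Spectrogram(coefficients=coef, frequencies=freqs, rate=rec.rate)


# ---------------------------------------------------------------------------
# wavelet coherence
# ---------------------------------------------------------------------------


def _smooth_time(a: np.ndarray, scales: np.ndarray, sigma_scales: float) -> np.ndarray:
    """Gaussian smoothing along time, sigma proportional to wavelet scale."""
    out = np.empty_like(a)
    for i, s in enumerate(scales):
        sigma = max(sigma_scales * s, 1e-9)
        if np.iscomplexobj(a):
            out[i] = gaussian_filter1d(a[i].real, sigma, mode="reflect") + 1j * gaussian_filter1d(
                a[i].imag, sigma, mode="reflect"
            )
        else:
            out[i] = gaussian_filter1d(a[i], sigma, mode="reflect")
    return out


def _smooth_scale(a: np.ndarray, voices: int) -> np.ndarray:
    """Boxcar over +-1 voice in scale (3 grid points at voice spacing)."""
    if a.shape[0] < 3:
        return a
    if np.iscomplexobj(a):
        return uniform_filter1d(a.real, 3, axis=0, mode="nearest") + 1j * uniform_filter1d(
            a.imag, 3, axis=0, mode="nearest"
        )
    return uniform_filter1d(a, 3, axis=0, mode="nearest")


def wavelet_coherence(
    rec: LFPRecording,
    ch_a: int,
    ch_b: int,
    band="low_gamma",
    voices: int = DEFAULT_VOICES,
    smoothing: str = "gaussian",
    sigma_scales: float = 1.0,
    scale_smoothing: bool = True,
    exclude_coi: bool = True,
    squared: bool = True,
) -> CoherenceSeries:
    """Band-averaged wavelet coherence time series between two channels.

    Coherence is |S(Wx Wy*)|^2 / (S|Wx|^2 S|Wy|^2) with S the smoothing
    operator: a Gaussian in time with width proportional to scale plus a
    boxcar over +-1 voice in scale (Torrence-Webster style).  With
    ``smoothing='none'`` the magnitude coherence is identically 1 — kept as
    a degeneracy guard, not for analysis.
    """
    if ch_a == ch_b:
        raise ValueError("self-coherence is degenerate; channel ids must differ")
    label, (lo, hi) = resolve_band(band)
    if hi >= rec.rate / 2:
        raise ValueError("band extends beyond the Nyquist frequency")
    freqs = band_freq_grid((lo, hi), voices)
    scales = _FC * rec.rate / freqs

    data = np.stack([rec.get(ch_a), rec.get(ch_b)])
    w = _cwt(data, freqs, rec.rate)  # (F, 2, T)
    wx, wy = w[:, 0, :], w[:, 1, :]

    cross = wx * np.conj(wy)
    pxx = np.abs(wx) ** 2
    pyy = np.abs(wy) ** 2
    if smoothing == "gaussian":
        cross = _smooth_time(cross, scales, sigma_scales)
        pxx = _smooth_time(pxx, scales, sigma_scales)
        pyy = _smooth_time(pyy, scales, sigma_scales)
        if scale_smoothing:
            cross = _smooth_scale(cross, voices)
            pxx = _smooth_scale(pxx, voices)
            pyy = _smooth_scale(pyy, voices)
    elif smoothing != "none":
        raise ValueError(f"unknown smoothing mode {smoothing!r}")

    denom = pxx * pyy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(cross) ** 2 / np.where(denom > 0, denom, np.inf)
    coh = np.clip(coh, 0.0, 1.0)
    if not squared:
        coh = np.sqrt(coh)

    values = coh.mean(axis=0)
    if exclude_coi:
        n = values.size
        t = np.arange(n)
        edge = np.minimum(t, n - 1 - t)
        valid = edge >= math.sqrt(2.0) * scales.max()
        if not valid.any():  # very short segments: keep everything
            valid = np.ones(n, dtype=bool)
    else:
        valid = np.ones(values.size, dtype=bool)
    return CoherenceSeries(
        pair=(ch_a, ch_b), band=(lo, hi), band_label=label,
        values=values, rate=rec.rate, valid=valid,
    )


def pairwise_band_coherence(
    rec: LFPRecording,
    channels_a: Sequence[int],
    channels_b: Sequence[int],
    band,
    intervals: Sequence[tuple[float, float]],
    voices: int = DEFAULT_VOICES,
    pad_s: float = 0.25,
) -> np.ndarray:
    """Interval-averaged squared coherence for every (a, b) channel pair.

    For each half-open interval [t0, t1) the cross- and auto-spectra are
    averaged over the whole interval (boxcar smoothing spanning the
    averaging window) and over the band's frequency grid, yielding one
    scalar per pair per interval.  Returns an array
    ``(len(channels_a), len(channels_b), len(intervals))``.

    Segments are padded by ``pad_s`` on each side before the transform so
    interval samples are free of edge effects.
    """
    _, (lo, hi) = resolve_band(band)
    if hi >= rec.rate / 2:
        raise ValueError("band extends beyond the Nyquist frequency")
    freqs = band_freq_grid((lo, hi), voices)

    all_ids = list(dict.fromkeys(list(channels_a) + list(channels_b)))
    cols = [rec.channel_index(c) for c in all_ids]
    ia = [all_ids.index(c) for c in channels_a]
    ib = [all_ids.index(c) for c in channels_b]

    out = np.empty((len(channels_a), len(channels_b), len(intervals)))
    npad = int(round(pad_s * rec.rate))
    for k, (t0, t1) in enumerate(intervals):
        if not t1 > t0:
            raise ValueError(f"empty interval ({t0}, {t1})")
        s0 = int(round(t0 * rec.rate))
        s1 = int(round(t1 * rec.rate))
        p0 = max(s0 - npad, 0)
        p1 = min(s1 + npad, rec.n_samples)
        seg = rec.samples[p0:p1, cols].T  # (C, T)
        w = _cwt(seg, freqs, rec.rate)  # (F, C, T)
        w = w[:, :, s0 - p0 : s1 - p0]
        t_len = w.shape[2]
        acc = np.zeros((len(ia), len(ib)))
        for f in range(len(freqs)):
            x = w[f][ia]  # (na, T)
            y = w[f][ib]  # (nb, T)
            sxy = x @ y.conj().T / t_len
            pxx = np.mean(np.abs(x) ** 2, axis=1)
            pyy = np.mean(np.abs(y) ** 2, axis=1)
            denom = np.outer(pxx, pyy)
            with np.errstate(invalid="ignore", divide="ignore"):
                coh = np.abs(sxy) ** 2 / np.where(denom > 0, denom, np.inf)
            acc += np.clip(coh, 0.0, 1.0)
        out[:, :, k] = acc / len(freqs)
    return out


# ---------------------------------------------------------------------------
# band / interval averaging
# ---------------------------------------------------------------------------


def _intervals_to_mask(intervals, n: int, rate: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for t0, t1 in intervals:
        s0, s1 = int(round(t0 * rate)), int(round(t1 * rate))
        if s1 <= s0:
            raise ValueError(f"empty interval ({t0}, {t1})")
        mask[max(s0, 0) : min(s1, n)] = True
    return mask


def band_average(obj, band=None, interval=None, exclude_invalid: bool = True) -> float:
    """Mean over band frequencies and interval samples.

    ``obj`` may be a :class:`CoherenceSeries` (band already applied) or a
    :class:`Spectrogram` (normalised power averaged over ``band``).
    ``interval`` is one (t0, t1) pair or a list of them (half-open,
    seconds); None means the full extent.
    """
    if isinstance(obj, CoherenceSeries):
        values = obj.values
        rate = obj.rate
        keep = obj.valid.copy() if exclude_invalid else np.ones(values.size, bool)
    elif isinstance(obj, Spectrogram):
        if band is None:
            raise ValueError("band is required for a Spectrogram")
        _, (lo, hi) = resolve_band(band)
        sel = (obj.frequencies >= lo) & (obj.frequencies <= hi)
        if not sel.any():
            raise ValueError("band does not intersect the frequency grid")
        values = obj.power()[sel].mean(axis=0)
        rate = obj.rate
        keep = np.ones(values.size, bool)
    else:
        raise TypeError("expected a CoherenceSeries or Spectrogram")

    if interval is not None:
        if np.ndim(interval[0]) == 0:
            interval = [tuple(interval)]
        keep &= _intervals_to_mask(interval, values.size, rate)
    if not keep.any():
        raise ValueError("empty interval after masking")
    return float(values[keep].mean())
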