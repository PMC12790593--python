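"""Welch spectra, relative normalization and canonical band powers.

Absolute spectra are one-sided Welch densities (microvolts^2/Hz) on an exact
1 Hz grid (1-s Hamming windows, 50% overlap). Relative spectra divide by the
summed power from 5 to 95 Hz and multiply by 100, so those 91 integer bins
sum to exactly 100%.

Band powers are arithmetic means of the bins in the half-open interval
[f_lo, f_hi) so adjacent canonical bands never share a bin; the band edges
follow the clinical convention: delta 2-4, theta 4-9, alpha 9-13, low beta
13-20, high beta 20-30, low gamma 30-45, mid gamma 45-60 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from .recording import LfpRecording

__all__ = [
    "Spectrum",
    "BandDefinition",
    "CANONICAL_BANDS",
    "BETA_VARIANTS",
    "preprocess",
    "welch_psd",
    "interpolate_line_noise",
    "to_relative",
    "band_power",
    "midgamma_proxy",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name!r}: f_lo must be < f_hi")


CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2, 4),
    BandDefinition("theta", 4, 9),
    BandDefinition("alpha", 9, 13),
    BandDefinition("low_beta", 13, 20),
    BandDefinition("high_beta", 20, 30),
    BandDefinition("low_gamma", 30, 45),
    BandDefinition("mid_gamma", 45, 60),
)

#: Beta-range variants most often used in the across-study literature.
BETA_VARIANTS: tuple[BandDefinition, ...] = (
    BandDefinition("alpha_beta", 8, 35),
    BandDefinition("beta", 13, 30),
    BandDefinition("low_beta", 13, 20),
)


@dataclass
class Spectrum:
    """Power values on a uniform 1 Hz grid with a scale tag."""

    frequencies: np.ndarray  # Hz, strictly increasing, 1 Hz spacing
    power: np.ndarray  # uV^2/Hz (absolute) or % (relative)
    scale: str = "absolute"  # 'absolute' | 'relative'
    patient_id: str = ""
    hemisphere: str = ""
    condition: str = ""
    dataset_id: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency and power grids differ in length")
        if self.frequencies.size > 1 and not np.all(np.diff(self.frequencies) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.scale not in ("absolute", "relative"):
            raise ValueError("scale must be 'absolute' or 'relative'")

    def index_of(self, freq: float) -> int:
        idx = int(np.argmin(np.abs(self.frequencies - freq)))
        if abs(self.frequencies[idx] - freq) > 1e-6:
            raise ValueError(f"{freq} Hz not on the grid")
        return idx

    def slice(self, f_lo: float, f_hi: float, half_open: bool = True) -> np.ndarray:
        sel = (self.frequencies >= f_lo) & (
            (self.frequencies < f_hi) if half_open else (self.frequencies <= f_hi)
        )
        return self.power[sel]

    def copy_with(self, **kw) -> "Spectrum":
        out = Spectrum(
            frequencies=kw.pop("frequencies", self.frequencies.copy()),
            power=kw.pop("power", self.power.copy()),
            scale=kw.pop("scale", self.scale),
            patient_id=self.patient_id,
            hemisphere=self.hemisphere,
            condition=self.condition,
            dataset_id=self.dataset_id,
            channel=self.channel,
        )
        for k, v in kw.items():
            setattr(out, k, v)
        return out


def preprocess(recording: LfpRecording, target_rate: float = 2000.0) -> LfpRecording:
    """1 Hz high-pass, anti-alias low-pass, and resampling to target_rate.

    The high-pass is a zero-phase 4th-order Butterworth. Resampling uses a
    polyphase FIR whose Kaiser-windowed low-pass provides the anti-alias
    filter; if the recording is already at the target rate only the filters
    are applied. The good-segment mask is carried through at the new rate.
    """
    if target_rate > recording.sample_rate:
        raise ValueError(
            f"target rate {target_rate} Hz exceeds input rate {recording.sample_rate} Hz"
        )
    sos = scipy.signal.butter(4, 1.0, btype="highpass", fs=recording.sample_rate, output="sos")
    data = scipy.signal.sosfiltfilt(sos, recording.data, axis=1)
    if target_rate == recording.sample_rate:
        return recording.with_data(data, recording.channels)
    from fractions import Fraction

    frac = Fraction(target_rate / recording.sample_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = scipy.signal.resample_poly(data, up, down, axis=1)
    n_new = out.shape[1]
    idx = np.minimum((np.arange(n_new) * down / up).astype(int), recording.n_samples - 1)
    return replace(
        recording,
        data=out,
        sample_rate=target_rate,
        good_mask=recording.good_mask[idx],
    )


def welch_psd(
    recording: LfpRecording,
    channel: int = 0,
    *,
    window: str = "hamming",
    min_clean_s: float = 2.0,
) -> Spectrum:
    """Welch PSD at 1 Hz resolution (1-s windows, 50% overlap).

    Windows overlapping a masked (bad) sample are dropped; the estimate is
    the arithmetic mean of the remaining windowed periodograms scaled as a
    one-sided density.
    """
    fs = recording.sample_rate
    nperseg = int(round(fs))
    if abs(nperseg - fs) > 1e-9:
        raise ValueError("sample rate must be an integer number of Hz for a 1 Hz grid")
    x = recording.data[channel]
    step = nperseg // 2
    starts = np.arange(0, recording.n_samples - nperseg + 1, step)
    clean = [s for s in starts if recording.good_mask[s : s + nperseg].all()]
    # 50% overlap: k clean windows span >= (k+1)/2 seconds of clean signal
    if (len(clean) + 1) / 2.0 < max(min_clean_s, 2.0):
        total_clean = recording.good_mask.sum() / fs
        raise ValueError(
            f"insufficient clean signal: {total_clean:.1f} s unmasked, "
            f"{len(clean)} usable 1-s windows"
        )
    win = scipy.signal.get_window(window, nperseg)
    scale = 1.0 / (fs * (win**2).sum())
    segs = np.stack([x[s : s + nperseg] for s in clean])
    spec = np.fft.rfft(segs * win, axis=1)
    psd = (np.abs(spec) ** 2).mean(axis=0) * scale
    psd[1:-1] *= 2.0  # one-sided density; DC and Nyquist not doubled
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    ch = recording.channels[channel]
    return Spectrum(
        frequencies=freqs,
        power=psd,
        scale="absolute",
        patient_id=recording.patient_id,
        hemisphere=recording.hemisphere,
        condition=recording.condition,
        dataset_id=recording.dataset_id,
        channel=ch.label,
    )


def interpolate_line_noise(
    spectrum: Spectrum,
    line_freq: float = 50.0,
    halfwidth: float = 2.0,
    harmonics: int = 1,
) -> Spectrum:
    """Linearly interpolate across line-noise bins (and optional harmonics).

    Bins with |f - k*line_freq| <= halfwidth are replaced by the linear
    interpolant between the nearest bins outside the notch. Each harmonic is
    handled independently; harmonics beyond the grid are skipped.
    """
    freqs, power = spectrum.frequencies, spectrum.power.copy()
    for k in range(1, harmonics + 1):
        f0 = k * line_freq
        if f0 + halfwidth > freqs[-1] and k > 1:
            continue
        inside = np.abs(freqs - f0) <= halfwidth
        if not inside.any():
            continue
        lo, hi = np.flatnonzero(inside)[[0, -1]]
        if lo == 0 or hi == freqs.size - 1:
            raise ValueError(f"line-noise notch at {f0} Hz touches the grid edge")
        power[lo : hi + 1] = np.interp(
            freqs[lo : hi + 1], [freqs[lo - 1], freqs[hi + 1]], [power[lo - 1], power[hi + 1]]
        )
    return spectrum.copy_with(power=power)


def to_relative(spectrum: Spectrum, f_lo: float = 5.0, f_hi: float = 95.0) -> Spectrum:
    """Normalize so the inclusive 5-95 Hz bins sum to 100 (percent units)."""
    if spectrum.scale == "relative":
        return spectrum.copy_with()
    sel = (spectrum.frequencies >= f_lo) & (spectrum.frequencies <= f_hi)
    if not sel.any():
        raise ValueError("grid does not cover the normalization range")
    total = spectrum.power[sel].sum()
    if total <= 0:
        raise ValueError("zero total power in the normalization range")
    return spectrum.copy_with(power=spectrum.power * (100.0 / total), scale="relative")


def band_power(spectrum: Spectrum, band: BandDefinition) -> float:
    """Arithmetic mean of the bins in [f_lo, f_hi) (half-open)."""
    if band.f_lo < spectrum.frequencies[0] or band.f_hi > spectrum.frequencies[-1] + 1:
        raise ValueError(f"band {band.name!r} outside the spectrum grid")
    vals = spectrum.slice(band.f_lo, band.f_hi, half_open=True)
    if vals.size == 0:
        raise ValueError(f"band {band.name!r} contains no grid bins")
    return float(vals.mean())


def midgamma_proxy(spectrum: Spectrum, f_lo: float = 45.0, f_hi: float = 60.0,
                   halfwidth: float = 2.5) -> float:
    """Maximum-centred +/-2.5 Hz spectral mean within the mid-gamma range.

    Locates the largest bin in [f_lo, f_hi] (inclusive) and averages the bins
    within +/-halfwidth of it, clamping the window to [f_lo, f_hi]. A
    real-time-extractable proxy for aperiodic broadband power.
    """
    freqs = spectrum.frequencies
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    if not sel.any():
        raise ValueError("grid does not cover the mid-gamma range")
    sub_f, sub_p = freqs[sel], spectrum.power[sel]
    fpk = sub_f[int(np.argmax(sub_p))]
    win = (freqs >= max(f_lo, fpk - halfwidth)) & (freqs <= min(f_hi, fpk + halfwidth))
    return float(spectrum.power[win].mean())


def spectra_to_frame(spectra: list[Spectrum]) -> "pd.DataFrame":
    """Tidy long-format table of a spectrum collection."""
    import pandas as pd

    rows = []
    for sp in spectra:
        for f, p in zip(sp.frequencies, sp.power):
            rows.append(
                {
                    "patient_id": sp.patient_id,
                    "dataset_id": sp.dataset_id,
                    "hemisphere": sp.hemisphere,
                    "condition": sp.condition,
                    "channel": sp.channel,
                    "frequency": f,
                    "power": p,
                    "scale": sp.scale,
                }
            )
    return pd.DataFrame(rows)
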