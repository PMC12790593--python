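import numpy as np
import pytest
import scipy.signal

from stnpower.spectral import Spectrum
from stnpower.synthetic import CohortSpec, simulate_cohort


def make_spectrum(power, f0=0.0, scale="absolute", **meta):
    power = np.asarray(power, dtype=float)
    freqs = f0 + np.arange(power.size, dtype=float)
    return Spectrum(frequencies=freqs, power=power, scale=scale, **meta)


def welch_expectation(spec, nperseg=None):
    """Independent oracle: E[Welch PSD] = analytic PSD (*) Hamming kernel.

    Returns (integer_freqs, expected_psd) for the 1 Hz Welch grid.
    """
    fs = spec.sample_rate
    nperseg = nperseg or int(fs)
    w = scipy.signal.get_window("hamming", nperseg)
    nfine = 16 * nperseg
    W = np.abs(np.fft.fft(w, nfine)) ** 2
    nu = np.fft.fftfreq(nfine, d=1.0 / fs)
    dnu = nu[1] - nu[0]
    K = W / (W.sum() * dnu)
    S_full = spec.analytic_psd(np.abs(nu))
    conv = np.fft.ifft(np.fft.fft(S_full) * np.fft.fft(K)).real * dnu
    f_int = np.arange(0, int(fs // 2) + 1)
    idx = (f_int / dnu).astype(int)
    return f_int.astype(float), conv[idx]


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient full-montage cohort at desk scale (20 s @ 500 Hz)."""
    spec = CohortSpec(
        n_patients=6,
        duration_s=20.0,
        sample_rate=500.0,
        seed=42,
        effect_map={"low_beta": 0.4},
    )
    return simulate_cohort(spec)[0]


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    from stnpower.features import cohort_feature_table

    df, spectra = cohort_feature_table(small_cohort, keep_spectra=True)
    return df, spectra
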