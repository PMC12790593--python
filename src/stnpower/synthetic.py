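"""Simulation of STN-LFP recordings and full synthetic cohorts.

The single-recording simulator builds a one-sided Fourier power spectrum as a
1/f^m power law plus Gaussian oscillatory peaks, draws uniformly random
phases, enforces Hermitian symmetry and applies the inverse FFT, so the
expected Welch spectrum of the output equals the analytic target

    S(f) = offset * f^(-m) + sum_k A_k * exp(-(f - fc_k)^2 / (2 * sigma_k^2))

in microvolts^2/Hz. Peak amplitudes ``A`` are additive in linear power on the
Fourier spectrum; the log10-space peak height seen by the spectral
parameterization module is ``log10(1 + A / (offset * fc^-m))`` at the centre
frequency.

The cohort generator extends this to patients x hemispheres x conditions with
planted statistical structure: across-patient correlations between band
(peak) power and UPDRS-III scores via a Gaussian copula, a within-patient
broadband (aperiodic offset) elevation in the hemisphere contralateral to the
more affected hemibody, and per-band Levodopa modulation factors. Scores are
integers on the UPDRS scale; the total is assembled from lateralized
subscores plus an axial remainder so subscore sums can never exceed it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recording import (
    CONDITIONS,
    HEMISPHERES,
    ClinicalAssessment,
    ContactChannel,
    LfpRecording,
)

__all__ = [
    "SimPeak",
    "SimulationSpec",
    "CohortSpec",
    "Cohort",
    "simulate_recording",
    "simulate_cohort",
    "scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class SimPeak:
    """Gaussian peak on the Fourier power spectrum.

    amplitude is the peak height A in linear power units (microvolts^2/Hz)
    added on top of the aperiodic background.
    """

    centre_frequency: float  # Hz
    amplitude: float  # uV^2/Hz, >= 0
    sigma_f: float  # Hz, spectral SD

    def __post_init__(self) -> None:
        if self.centre_frequency <= 0:
            raise ValueError("centre_frequency must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.sigma_f <= 0:
            raise ValueError("sigma_f must be > 0")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated LFP trace."""

    exponent: float = 1.5  # 1/f^m slope m
    offset: float = 1.0  # uV^2/Hz at 1 Hz; log10(offset) is the aperiodic offset a
    peaks: tuple[SimPeak, ...] = ()
    duration_s: float = 180.0
    sample_rate: float = 2400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.offset <= 0:
            raise ValueError("offset must be > 0")
        object.__setattr__(self, "peaks", tuple(self.peaks))
        for pk in self.peaks:
            fmax = pk.centre_frequency + 3.0 * pk.sigma_f
            if self.sample_rate <= 2.0 * fmax:
                raise ValueError(
                    f"sample_rate {self.sample_rate} Hz too low for peak at "
                    f"{pk.centre_frequency} Hz (needs > {2 * fmax:.1f} Hz)"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate))

    @property
    def offset_log10(self) -> float:
        return math.log10(self.offset)

    def analytic_psd(self, freqs: np.ndarray) -> np.ndarray:
        """Target one-sided PSD in uV^2/Hz on an arbitrary frequency grid."""
        freqs = np.asarray(freqs, dtype=float)
        psd = np.zeros_like(freqs)
        pos = freqs > 0
        psd[pos] = self.offset * freqs[pos] ** (-self.exponent)
        for pk in self.peaks:
            psd += pk.amplitude * np.exp(-((freqs - pk.centre_frequency) ** 2) / (2 * pk.sigma_f**2))
        psd[~pos] = 0.0
        return psd


def simulate_recording(
    spec: SimulationSpec,
    *,
    rng: np.random.Generator | None = None,
    patient_id: str = "sim",
    hemisphere: str = "left",
    condition: str = "off",
    dataset_id: str = "synthetic",
) -> LfpRecording:
    """Inverse-FFT simulation of a single-channel LFP trace.

    The rFFT coefficient magnitudes are fixed by the target spectrum
    (|X_k|^2 = S(f_k) * fs * n / 2, the one-sided density convention) and
    only the phases are random, so a single realization already follows the
    target spectrum up to Welch windowing effects. DC and Nyquist bins are
    zeroed; the inverse real FFT output is exactly real.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate)
    psd = spec.analytic_psd(freqs)
    mags = np.sqrt(psd * spec.sample_rate * n / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    coeffs = mags * np.exp(1j * phases)
    coeffs[0] = 0.0
    if n % 2 == 0:
        coeffs[-1] = 0.0  # Nyquist bin must be real; drop it instead
    x = np.fft.irfft(coeffs, n=n)
    return LfpRecording(
        patient_id=patient_id,
        hemisphere=hemisphere,
        condition=condition,
        sample_rate=spec.sample_rate,
        data=x[np.newaxis, :],
        channels=[ContactChannel(level=1)],
        dataset_id=dataset_id,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Default centre frequency (Hz), spectral SD (Hz) and probability that a
#: given STN expresses a peak in each canonical band. Low-beta peaks are
#: absent in roughly half of STNs off medication, high-beta peaks in ~30%.
DEFAULT_PEAK_TEMPLATES: dict[str, dict] = {
    "theta": {"centre": 6.0, "centre_sd": 0.8, "sigma": 1.2, "presence": 0.7, "rel_amp": 0.8},
    "low_beta": {"centre": 16.0, "centre_sd": 1.5, "sigma": 1.8, "presence": 0.5, "rel_amp": 2.0},
    "high_beta": {"centre": 25.0, "centre_sd": 2.0, "sigma": 2.2, "presence": 0.7, "rel_amp": 1.2},
    "low_gamma": {"centre": 38.0, "centre_sd": 3.0, "sigma": 3.0, "presence": 0.3, "rel_amp": 0.8},
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-level description of a simulated patient cohort.

    effect_map plants across-patient Spearman correlations between a band's
    peak amplitude and the UPDRS-III total (same condition); bands named in
    the map always express their peak. asymmetry_log10 is the aperiodic
    offset elevation (log10 units) of the STN contralateral to the more
    affected hemibody. levodopa_band_factors multiply peak amplitudes
    off -> on.
    """

    n_patients: int = 30
    n_datasets: int = 1
    dataset_prefix: str = "synthetic"
    effect_map: dict = field(default_factory=dict)  # band -> target Spearman rho
    asymmetry_log10: float = 0.3
    levodopa_band_factors: dict = field(
        default_factory=lambda: {"theta": 1.3, "low_beta": 0.75}
    )
    levodopa_exponent_delta: float = 0.05  # on-state exponent shift
    levodopa_offset_log10_delta: float = 0.02  # on-state offset shift (log10)
    updrs_off_mean: float = 34.9
    updrs_off_sd: float = 12.9
    updrs_on_mean: float = 19.0
    updrs_on_sd: float = 9.2
    exponent_mean: float = 1.5
    exponent_sd: float = 0.15
    offset_log10_mean: float = -0.3
    offset_log10_sd: float = 0.15
    amplitude_log10_sd: float = 0.25  # across-patient spread of peak amplitudes
    peak_templates: dict = field(default_factory=lambda: DEFAULT_PEAK_TEMPLATES)
    frac_symmetric: float = 0.10  # patients with no hemibody asymmetry
    frac_inconsistent: float = 0.05  # asymmetry flips sign between conditions
    duration_s: float = 180.0
    sample_rate: float = 2400.0
    full_montage: bool = True  # emit 4-level montages (else the bipolar source only)
    directional_prob: float = 0.3  # fraction of leads with directional levels 2-3
    seed: int = 0

    def __post_init__(self) -> None:
        for band, rho in self.effect_map.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation target for {band!r} outside [-1, 1]")
            if band not in self.peak_templates:
                raise ValueError(f"unknown band {band!r} in effect_map")
        r = np.array([_copula_r(v) for v in self.effect_map.values()])
        if r.size:
            # joint correlation matrix of [score latent, band latents]
            k = r.size
            mat = np.eye(k + 1)
            mat[0, 1:] = r
            mat[1:, 0] = r
            mat[1:, 1:] = np.outer(r, r) + np.diag(1.0 - r**2)
            if np.linalg.eigvalsh(mat).min() < -1e-10:
                raise ValueError("requested correlation targets are jointly infeasible")


@dataclass
class Cohort:
    """Bundle of recordings and assessments from one simulated dataset."""

    recordings: list[LfpRecording]
    assessments: list[ClinicalAssessment]
    spec: CohortSpec
    truth: pd.DataFrame  # per patient/hemisphere/condition generating parameters

    def assessment(self, patient_id: str, condition: str) -> ClinicalAssessment:
        for a in self.assessments:
            if a.patient_id == patient_id and a.condition == condition:
                return a
        raise KeyError((patient_id, condition))

    def recording(self, patient_id: str, hemisphere: str, condition: str) -> LfpRecording:
        for r in self.recordings:
            if (
                r.patient_id == patient_id
                and r.hemisphere == hemisphere
                and r.condition == condition
            ):
                return r
        raise KeyError((patient_id, hemisphere, condition))

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.assessments:
            seen.setdefault(a.patient_id, None)
        return list(seen)


def _copula_r(rho_s: float) -> float:
    """Pearson correlation of the Gaussian copula giving Spearman rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


# Monopolar mixing gains per stimulation level. The bipolar pair bracketing
# the stimulation contact recovers the source with unit gain, and among ring
# levels 2/3 the stimulation level carries the most source power, so the
# high-beta fallback and the sweet-spot rule agree.
_MONTAGE_GAINS = {2: (1.3, 1.2, 0.3, 0.1), 3: (0.1, 0.3, 1.2, 1.3)}

#: Approximate published STN stimulation sweet spot (right hemisphere, MNI mm).
DEFAULT_SWEET_SPOT_RIGHT = (12.5, -12.7, -5.4)


def sweet_spot_mni(hemisphere: str, base: tuple[float, float, float] = DEFAULT_SWEET_SPOT_RIGHT):
    x, y, z = base
    return (x, y, z) if hemisphere == "right" else (-x, y, z)


def simulate_cohort(spec: CohortSpec) -> list[Cohort]:
    """Simulate ``n_datasets`` cohorts of ``n_patients`` each.

    One global seed fans out through ``numpy.random.SeedSequence`` spawns to
    per-dataset and per-patient substreams, so enlarging the cohort leaves
    existing patients' data untouched.
    """
    root = np.random.SeedSequence(spec.seed)
    dataset_seeds = root.spawn(spec.n_datasets)
    return [
        _simulate_dataset(spec, f"{spec.dataset_prefix}{d:02d}", dataset_seeds[d])
        for d in range(spec.n_datasets)
    ]


def _simulate_dataset(spec: CohortSpec, dataset_id: str, ss: np.random.SeedSequence) -> Cohort:
    patient_seeds = ss.spawn(spec.n_patients)
    recordings: list[LfpRecording] = []
    assessments: list[ClinicalAssessment] = []
    truth_rows: list[dict] = []
    for p in range(spec.n_patients):
        pid = f"{dataset_id}_p{p:03d}"
        recs, assess, rows = _simulate_patient(spec, dataset_id, pid, patient_seeds[p])
        recordings.extend(recs)
        assessments.extend(assess)
        truth_rows.extend(rows)
    return Cohort(recordings, assessments, spec, pd.DataFrame(truth_rows))


def _simulate_patient(spec, dataset_id, pid, ss):
    # substream 0: patient-level draws; 1..4: one per hemisphere x condition
    streams = ss.spawn(5)
    rng = np.random.default_rng(streams[0])
    rec_stream = {
        (h, c): streams[1 + 2 * i + j]
        for i, h in enumerate(HEMISPHERES)
        for j, c in enumerate(CONDITIONS)
    }
    z = rng.standard_normal()  # latent disease severity

    # --- clinical scores (integer UPDRS points, built from parts) ---------
    off_total_target = spec.updrs_off_mean + spec.updrs_off_sd * z
    on_latent = 0.85 * z + math.sqrt(1 - 0.85**2) * rng.standard_normal()
    on_total_target = spec.updrs_on_mean + spec.updrs_on_sd * on_latent

    u = rng.uniform()
    if u < spec.frac_symmetric:
        asym_kind = "symmetric"
    elif u < spec.frac_symmetric + spec.frac_inconsistent:
        asym_kind = "inconsistent"
    else:
        asym_kind = "consistent"
    asym_sign = 1 if rng.uniform() < 0.5 else -1  # +1: right hemibody worse

    scores: dict[str, ClinicalAssessment] = {}
    for cond, target in (("off", off_total_target), ("on", on_total_target)):
        total = int(np.clip(round(target), 5, 108))
        br_total = int(round(0.55 * total))
        if asym_kind == "symmetric":
            diff = 0
        else:
            diff = int(1 + rng.poisson(2.0))
            sign = asym_sign
            if asym_kind == "inconsistent" and cond == "on":
                sign = -sign
            diff *= sign
        br_right = int(np.clip(round((br_total + diff) / 2.0), 0, 40))
        br_left = int(np.clip(br_total - br_right, 0, 40))
        # Re-derive the realized (post-clipping) signed asymmetry
        trem_right = int(rng.integers(0, 4))
        trem_left = int(rng.integers(0, 4))
        axial = max(total - br_left - br_right - trem_left - trem_right, 0)
        total = br_left + br_right + trem_left + trem_right + axial
        scores[cond] = ClinicalAssessment(
            patient_id=pid,
            condition=cond,
            updrs_total=total,
            brady_rigidity_left_body=br_left,
            brady_rigidity_right_body=br_right,
            tremor_left_body=trem_left,
            tremor_right_body=trem_right,
            dataset_id=dataset_id,
        )

    # --- spectral parameters ----------------------------------------------
    exponent = spec.exponent_mean + spec.exponent_sd * rng.standard_normal()
    offset_log10 = spec.offset_log10_mean + spec.offset_log10_sd * rng.standard_normal()

    # Band latents correlated with severity via the Gaussian copula.
    band_latent: dict[str, float] = {}
    for band in spec.peak_templates:
        rho = spec.effect_map.get(band, 0.0)
        r = _copula_r(rho)
        band_latent[band] = r * z + math.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal()

    presence = {
        band: (band in spec.effect_map) or (rng.uniform() < tpl["presence"])
        for band, tpl in spec.peak_templates.items()
    }
    centres = {
        band: tpl["centre"] + tpl["centre_sd"] * rng.standard_normal()
        for band, tpl in spec.peak_templates.items()
    }

    directional = rng.uniform() < spec.directional_prob
    stim_level = {h: int(rng.integers(2, 4)) for h in HEMISPHERES}

    recordings, truth_rows = [], []
    for hemisphere in HEMISPHERES:
        # more affected hemisphere = contralateral to worse hemibody (off state)
        off = scores["off"]
        contra = off.contralateral_brady_rigidity(hemisphere)
        ipsi = off.contralateral_brady_rigidity("left" if hemisphere == "right" else "right")
        if contra > ipsi:
            hemi_shift = +spec.asymmetry_log10 / 2.0
            more_affected = True
        elif contra < ipsi:
            hemi_shift = -spec.asymmetry_log10 / 2.0
            more_affected = False
        else:
            hemi_shift, more_affected = 0.0, False
        hemi_offset_jitter = 0.03 * rng.standard_normal()
        for condition in CONDITIONS:
            exp_c = exponent + (spec.levodopa_exponent_delta if condition == "on" else 0.0)
            off_log10 = (
                offset_log10
                + hemi_shift
                + hemi_offset_jitter
                + (spec.levodopa_offset_log10_delta if condition == "on" else 0.0)
            )
            offset_lin = 10.0**off_log10
            peaks = []
            for band, tpl in spec.peak_templates.items():
                if not presence[band]:
                    continue
                fc = centres[band]
                background = offset_lin * fc ** (-exp_c)
                amp = tpl["rel_amp"] * background * 10.0 ** (
                    spec.amplitude_log10_sd * band_latent[band]
                )
                if condition == "on":
                    amp *= spec.levodopa_band_factors.get(band, 1.0)
                peaks.append(SimPeak(fc, amp, tpl["sigma"]))
            sim = SimulationSpec(
                exponent=exp_c,
                offset=offset_lin,
                peaks=tuple(peaks),
                duration_s=spec.duration_s,
                sample_rate=spec.sample_rate,
            )
            rec_rng = np.random.default_rng(rec_stream[(hemisphere, condition)])
            source = simulate_recording(
                sim,
                rng=rec_rng,
                patient_id=pid,
                hemisphere=hemisphere,
                condition=condition,
                dataset_id=dataset_id,
            ).data[0]
            if spec.full_montage:
                rec = _build_montage(
                    source, sim, rec_rng, pid, dataset_id, hemisphere, condition,
                    stim_level[hemisphere], directional,
                )
            else:
                rec = LfpRecording(
                    patient_id=pid,
                    dataset_id=dataset_id,
                    hemisphere=hemisphere,
                    condition=condition,
                    sample_rate=sim.sample_rate,
                    data=source[np.newaxis, :],
                    channels=[ContactChannel(level=1)],
                )
            recordings.append(rec)
            truth_rows.append(
                {
                    "patient_id": pid,
                    "dataset_id": dataset_id,
                    "hemisphere": hemisphere,
                    "condition": condition,
                    "severity_latent": z,
                    "exponent": exp_c,
                    "offset_log10": off_log10,
                    "more_affected": more_affected,
                    "asym_kind": asym_kind,
                    "stim_level": stim_level[hemisphere],
                    **{f"latent_{b}": band_latent[b] for b in spec.peak_templates},
                    **{f"present_{b}": presence[b] for b in spec.peak_templates},
                }
            )
    return recordings, list(scores.values()), truth_rows


def _build_montage(source, sim, rng, pid, dataset_id, hemisphere, condition,
                   stim_level, directional):
    """Mix the bipolar source into a 4-level monopolar montage.

    A shared pink-noise common mode is added to every level; the bipolar pair
    bracketing the stimulation contact cancels it exactly and recovers the
    source with unit gain.
    """
    gains = _MONTAGE_GAINS[stim_level]
    common = simulate_recording(
        replace(sim, peaks=(), offset=sim.offset * 2.0, exponent=1.0),
        rng=rng,
    ).data[0]
    sweet = sweet_spot_mni(hemisphere)
    data, channels = [], []
    for level, g in zip((1, 2, 3, 4), gains):
        sig = common + g * source
        # lead runs ventral->dorsal; the stimulation level sits at the sweet spot
        mni = (sweet[0], sweet[1], sweet[2] + 2.0 * (level - stim_level))
        if directional and level in (2, 3):
            devs = rng.standard_normal((3, 1)) * 0.05
            devs -= devs.mean(axis=0, keepdims=True)  # deviations average to zero
            ref = simulate_recording(replace(sim, peaks=()), rng=rng).data[0]
            for sub, dev in zip("abc", devs):
                data.append(sig + dev * ref)
                channels.append(ContactChannel(level=level, sub=sub, mni=mni))
        else:
            data.append(sig)
            channels.append(ContactChannel(level=level, mni=mni))
    return LfpRecording(
        patient_id=pid,
        dataset_id=dataset_id,
        hemisphere=hemisphere,
        condition=condition,
        sample_rate=sim.sample_rate,
        data=np.vstack(data),
        channels=channels,
    )


# ---------------------------------------------------------------------------
# Didactic scenarios: normalization and parameterization artifacts
# ---------------------------------------------------------------------------

_BASELINE = SimulationSpec(
    exponent=1.5,
    offset=1.0,
    peaks=(
        SimPeak(6.0, 0.06, 1.0),  # theta
        SimPeak(16.0, 0.04, 2.0),  # low beta
    ),
)

SCENARIOS = ("theta_increase", "beta_narrowing", "offset_increase", "exponent_decrease")


def scenario(name: str) -> tuple[SimulationSpec, SimulationSpec]:
    """Baseline/perturbed spec pairs differing in exactly one parameter.

    These reproduce the classic normalization artifacts: a theta-amplitude
    increase leaves absolute beta power untouched but depresses *relative*
    beta power; an offset increase (or exponent decrease) moves absolute and
    relative band power in opposite directions while periodic power is
    unchanged.
    """
    base = _BASELINE
    theta, beta = base.peaks
    if name == "theta_increase":
        pert = replace(base, peaks=(replace(theta, amplitude=2 * theta.amplitude), beta))
    elif name == "beta_narrowing":
        pert = replace(base, peaks=(theta, replace(beta, sigma_f=beta.sigma_f / 2)))
    elif name == "offset_increase":
        pert = replace(base, offset=2.0 * base.offset)
    elif name == "exponent_decrease":
        pert = replace(base, exponent=base.exponent - 0.3)
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return base, pert
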