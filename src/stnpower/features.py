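"""Pipeline glue: cohorts of recordings -> tidy spectral feature tables.

For each recording: bipolar contact selection, preprocessing, Welch PSD,
line-noise interpolation, relative normalization and parameterization; then
one feature row per patient x hemisphere x condition carrying total
(absolute and relative) band powers for the canonical bands and beta
variants, the mid-gamma proxy, and - where the fit passes the R^2 filter -
aperiodic offset/exponent, aperiodic broadband power, and periodic band
powers. This single table feeds the multiverse, framework-comparison and
within-patient stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import select_bipolar
from .parameterize import (
    ParameterizationSettings,
    aperiodic_broadband_power,
    parameterize,
    periodic_band_power,
)
from .recording import LfpRecording
from .spectral import (
    BETA_VARIANTS,
    CANONICAL_BANDS,
    Spectrum,
    band_power,
    interpolate_line_noise,
    midgamma_proxy,
    preprocess,
    to_relative,
    welch_psd,
)
from .synthetic import Cohort

__all__ = ["extract_features", "cohort_feature_table", "recording_spectra"]


@dataclass
class RecordingFeatures:
    row: dict
    absolute: Spectrum
    relative: Spectrum


def recording_spectra(
    recording: LfpRecording,
    target_rate: float | None = 2000.0,
    line_freq: float = 50.0,
    line_halfwidth: float = 2.0,
    line_harmonics: int = 1,
    select_contacts: bool = True,
) -> tuple[Spectrum, Spectrum, dict]:
    """Absolute and relative spectra of the analysis bipolar channel."""
    report = {}
    rec = recording
    if select_contacts and len(recording.channels) > 1:
        rec, sel = select_bipolar(recording)
        report = {"stim_level": sel.stim_level, "pair": sel.pair, "method": sel.method}
    if target_rate is not None and target_rate < rec.sample_rate:
        rec = preprocess(rec, target_rate)
    else:
        rec = preprocess(rec, rec.sample_rate)
    spec = welch_psd(rec)
    spec = interpolate_line_noise(spec, line_freq, line_halfwidth, line_harmonics)
    return spec, to_relative(spec), report


def extract_features(
    recording: LfpRecording,
    settings: ParameterizationSettings = ParameterizationSettings(),
    **spectra_kw,
) -> RecordingFeatures:
    absolute, relative, sel = recording_spectra(recording, **spectra_kw)
    row = {
        "patient_id": recording.patient_id,
        "dataset_id": recording.dataset_id,
        "hemisphere": recording.hemisphere,
        "condition": recording.condition,
        **sel,
    }
    for b in CANONICAL_BANDS:
        row[f"absolute_{b.name}"] = band_power(absolute, b)
        row[f"relative_{b.name}"] = band_power(relative, b)
    for b in BETA_VARIANTS:
        row[f"relative_{b.name}"] = band_power(relative, b)
        row[f"absolute_{b.name}"] = band_power(absolute, b)
    row["midgamma_proxy"] = midgamma_proxy(absolute)
    pspec = parameterize(absolute, settings)
    row["r_squared"] = pspec.r_squared
    row["fit_accepted"] = pspec.accepted
    if pspec.accepted:
        row["aperiodic_offset"] = pspec.aperiodic.offset
        row["aperiodic_exponent"] = pspec.aperiodic.exponent
        row["aperiodic_broadband"] = aperiodic_broadband_power(pspec.aperiodic)
        for b in CANONICAL_BANDS:
            if b.f_hi <= settings.f_hi:
                row[f"periodic_{b.name}"] = periodic_band_power(
                    pspec, b, mode=settings.periodic_mode
                )
    else:
        row["aperiodic_offset"] = np.nan
        row["aperiodic_exponent"] = np.nan
        row["aperiodic_broadband"] = np.nan
        for b in CANONICAL_BANDS:
            if b.f_hi <= settings.f_hi:
                row[f"periodic_{b.name}"] = np.nan
    return RecordingFeatures(row, absolute, relative)


def cohort_feature_table(
    cohort: Cohort,
    settings: ParameterizationSettings = ParameterizationSettings(),
    keep_spectra: bool = False,
    **spectra_kw,
):
    """Feature rows (plus scores) for every recording of a cohort.

    Returns (features_frame, spectra_dict) where spectra_dict maps
    (patient_id, hemisphere, condition) -> (absolute, relative) when
    keep_spectra is set, else an empty dict.
    """
    rows, spectra = [], {}
    for rec in cohort.recordings:
        feats = extract_features(rec, settings, **spectra_kw)
        assess = cohort.assessment(rec.patient_id, rec.condition)
        feats.row["updrs_total"] = assess.updrs_total
        feats.row["contra_brady_rigidity"] = assess.contralateral_brady_rigidity(
            rec.hemisphere
        )
        feats.row["contra_tremor"] = assess.contralateral_tremor(rec.hemisphere)
        rows.append(feats.row)
        if keep_spectra:
            spectra[(rec.patient_id, rec.hemisphere, rec.condition)] = (
                feats.absolute,
                feats.relative,
            )
    return pd.DataFrame(rows), spectra
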