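"""Reduction of multi-contact DBS recordings to one bipolar channel per STN.

Directional sub-contacts are ring-averaged per level; the likely monopolar
stimulation contact (level 2 or 3) is chosen by proximity to the stimulation
sweet spot when MNI coordinates are known, otherwise by the larger high-beta
(20-30 Hz) power; the analysed bipolar channel is the pair bracketing that
level: stimulation at 2 -> contacts 1-3, at 3 -> contacts 2-4. Ties go to
the more ventral level (2). Bipolar polarity is lower- minus higher-index
contact; polarity does not affect power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .recording import ContactChannel, LfpRecording
from .spectral import BandDefinition, band_power, welch_psd
from .synthetic import sweet_spot_mni

__all__ = [
    "average_directional",
    "estimate_stim_contact",
    "choose_bipolar_pair",
    "select_bipolar",
    "SelectionReport",
]

HIGH_BETA = BandDefinition("high_beta", 20, 30)


@dataclass(frozen=True)
class SelectionReport:
    patient_id: str
    hemisphere: str
    condition: str
    method: str  # 'sweet_spot' | 'high_beta'
    stim_level: int
    pair: tuple[int, int]


def average_directional(recording: LfpRecording) -> LfpRecording:
    """Collapse directional sub-contacts to ring-equivalent levels.

    Levels carrying a single (ring) channel pass through unchanged; levels
    with three directional segments are replaced by their arithmetic mean.
    Any other sub-contact count is rejected.
    """
    data, channels = [], []
    for level in recording.levels:
        rows = [
            (ch, sig)
            for ch, sig in zip(recording.channels, recording.data)
            if ch.level == level
        ]
        if len(rows) not in (1, 3):
            raise ValueError(
                f"level {level} has {len(rows)} sub-contacts; expected 1 (ring) or 3 (directional)"
            )
        sigs = np.stack([sig for _, sig in rows])
        data.append(sigs.mean(axis=0))
        channels.append(ContactChannel(level=level, mni=rows[0][0].mni))
    return recording.with_data(np.stack(data), channels)


def estimate_stim_contact(
    recording: LfpRecording,
    sweet_spot: tuple[float, float, float] | None = None,
    high_beta_power: dict[int, float] | None = None,
) -> tuple[int, str]:
    """Most likely stimulation level (2 or 3) and the method that decided it.

    With MNI coordinates for levels 2 and 3 (and a sweet-spot coordinate),
    the nearer level wins (Euclidean distance). Otherwise the level with the
    larger high-beta power wins. Exact ties pick level 2 (more ventral).
    """
    coords = {ch.level: ch.mni for ch in recording.channels if ch.sub is None}
    have_coords = coords.get(2) is not None and coords.get(3) is not None
    if have_coords:
        if sweet_spot is None:
            sweet_spot = sweet_spot_mni(recording.hemisphere)
        d = {
            lvl: math.dist(coords[lvl], sweet_spot)
            for lvl in (2, 3)
        }
        level = 2 if d[2] <= d[3] else 3
        return level, "sweet_spot"
    if high_beta_power is None:
        high_beta_power = {
            lvl: band_power(welch_psd(recording, _level_index(recording, lvl)), HIGH_BETA)
            for lvl in (2, 3)
            if _has_level(recording, lvl)
        }
    if not (2 in high_beta_power and 3 in high_beta_power):
        raise ValueError("need either MNI coordinates or high-beta power for levels 2 and 3")
    level = 2 if high_beta_power[2] >= high_beta_power[3] else 3
    return level, "high_beta"


def choose_bipolar_pair(stim_level: int) -> tuple[int, int]:
    """Bipolar pair bracketing the stimulation contact: 2 -> (1,3), 3 -> (2,4)."""
    if stim_level == 2:
        return (1, 3)
    if stim_level == 3:
        return (2, 4)
    raise ValueError(f"stimulation level must be 2 or 3, got {stim_level}")


def select_bipolar(
    recording: LfpRecording,
    sweet_spot: tuple[float, float, float] | None = None,
) -> tuple[LfpRecording, SelectionReport]:
    """Full selection: ring-average, pick stim level, form the bipolar channel.

    The bipolar signal is level_a - level_b (lower minus higher index).
    """
    ringed = average_directional(recording)
    level, method = estimate_stim_contact(ringed, sweet_spot=sweet_spot)
    pair = choose_bipolar_pair(level)
    sig = ringed.channel_data(pair[0]) - ringed.channel_data(pair[1])
    coords = {ch.level: ch.mni for ch in ringed.channels}
    mni = None
    if coords.get(pair[0]) is not None and coords.get(pair[1]) is not None:
        mni = tuple(
            (a + b) / 2.0 for a, b in zip(coords[pair[0]], coords[pair[1]])
        )
    out = recording.with_data(
        sig[np.newaxis, :], [ContactChannel(level=level, mni=mni)]
    )
    report = SelectionReport(
        patient_id=recording.patient_id,
        hemisphere=recording.hemisphere,
        condition=recording.condition,
        method=method,
        stim_level=level,
        pair=pair,
    )
    return out, report


def _has_level(recording: LfpRecording, level: int) -> bool:
    return any(ch.level == level and ch.sub is None for ch in recording.channels)


def _level_index(recording: LfpRecording, level: int) -> int:
    for i, ch in enumerate(recording.channels):
        if ch.level == level and ch.sub is None:
            return i
    raise KeyError(level)
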