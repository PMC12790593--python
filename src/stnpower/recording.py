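"""Containers and disk formats for STN-LFP recordings and clinical scores.

An :class:`LfpRecording` holds one hemisphere x medication-condition recording
from a DBS lead: one or more contact channels (ring levels 1-4, ventral to
dorsal, optionally split into directional sub-contacts), a good-segment mask,
and provenance labels. Signals are microvolts throughout.

On disk a recording is a raw little-endian float64 binary (channels x samples,
C order) next to a JSON sidecar describing channels, sampling rate and units.
Clinical assessments travel as one tidy CSV row per patient x condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")
CONDITIONS = ("off", "on")


@dataclass(frozen=True)
class ContactChannel:
    """One recorded channel: a ring level or a directional sub-contact."""

    level: int  # 1 (ventral) .. 4 (dorsal)
    sub: str | None = None  # 'a'|'b'|'c' for directional segments, None for rings
    mni: tuple[float, float, float] | None = None  # mm, optional

    @property
    def label(self) -> str:
        return f"{self.level}{self.sub or ''}"


@dataclass
class LfpRecording:
    """Multichannel LFP time series for one STN in one medication condition."""

    patient_id: str
    hemisphere: str
    condition: str
    sample_rate: float
    data: np.ndarray  # (n_channels, n_samples), microvolts
    channels: list[ContactChannel]
    good_mask: np.ndarray | None = None  # bool, per sample; None = all good
    dataset_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel descriptors for {self.data.shape[0]} data rows"
            )
        if self.good_mask is None:
            self.good_mask = np.ones(self.n_samples, dtype=bool)
        else:
            self.good_mask = np.asarray(self.good_mask, dtype=bool)
            if self.good_mask.shape != (self.n_samples,):
                raise ValueError("good_mask length must equal the sample count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def levels(self) -> list[int]:
        return sorted({ch.level for ch in self.channels})

    def channel_data(self, level: int, sub: str | None = None) -> np.ndarray:
        for ch, row in zip(self.channels, self.data):
            if ch.level == level and ch.sub == sub:
                return row
        raise KeyError(f"no channel level={level} sub={sub!r}")

    def with_data(self, data: np.ndarray, channels: list[ContactChannel]) -> "LfpRecording":
        return replace(self, data=data, channels=channels)


@dataclass
class ClinicalAssessment:
    """UPDRS-III total and lateralized subscores for one patient x condition.

    Subscores follow the standard lateralization: the bradykinesia-rigidity
    subscore of a hemibody sums UPDRS items 22-26 for that body side, the
    tremor subscore items 20-21. A hemisphere's *contralateral* subscore is
    the opposite hemibody's value.
    """

    patient_id: str
    condition: str
    updrs_total: int
    brady_rigidity_left_body: int
    brady_rigidity_right_body: int
    tremor_left_body: int = 0
    tremor_right_body: int = 0
    dataset_id: str = "synthetic"

    def contralateral_brady_rigidity(self, hemisphere: str) -> int:
        """Subscore of the hemibody controlled by the given STN hemisphere."""
        if hemisphere == "left":
            return self.brady_rigidity_right_body
        if hemisphere == "right":
            return self.brady_rigidity_left_body
        raise ValueError(f"unknown hemisphere {hemisphere!r}")

    def contralateral_tremor(self, hemisphere: str) -> int:
        if hemisphere == "left":
            return self.tremor_right_body
        if hemisphere == "right":
            return self.tremor_left_body
        raise ValueError(f"unknown hemisphere {hemisphere!r}")


def assessments_to_frame(assessments: list[ClinicalAssessment]) -> pd.DataFrame:
    rows = [vars(a).copy() for a in assessments]
    return pd.DataFrame(rows)


def write_assessments_csv(assessments: list[ClinicalAssessment], path: str | Path) -> None:
    assessments_to_frame(assessments).to_csv(path, index=False)


def read_assessments_csv(path: str | Path) -> list[ClinicalAssessment]:
    df = pd.read_csv(path)
    return [ClinicalAssessment(**row) for row in df.to_dict(orient="records")]


def write_recording(recording: LfpRecording, directory: str | Path, stem: str | None = None) -> Path:
    """Write raw float64 binary + JSON sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if stem is None:
        stem = f"{recording.patient_id}_{recording.hemisphere}_{recording.condition}"
    bin_path = directory / f"{stem}.bin"
    recording.data.astype("<f8").tofile(bin_path)
    sidecar = {
        "patient": recording.patient_id,
        "dataset": recording.dataset_id,
        "hemisphere": recording.hemisphere,
        "condition": recording.condition,
        "sample_rate": recording.sample_rate,
        "n_channels": recording.data.shape[0],
        "n_samples": recording.n_samples,
        "units": "uV",
        "binary": bin_path.name,
        "channels": [
            {"level": ch.level, "sub": ch.sub, "mni": list(ch.mni) if ch.mni else None}
            for ch in recording.channels
        ],
        "good_mask_runs": _mask_to_runs(recording.good_mask),
    }
    sidecar_path = directory / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return sidecar_path


def read_recording(sidecar_path: str | Path) -> LfpRecording:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    data = np.fromfile(sidecar_path.parent / meta["binary"], dtype="<f8")
    data = data.reshape(meta["n_channels"], meta["n_samples"])
    channels = [
        ContactChannel(level=c["level"], sub=c["sub"], mni=tuple(c["mni"]) if c["mni"] else None)
        for c in meta["channels"]
    ]
    mask = _runs_to_mask(meta.get("good_mask_runs"), meta["n_samples"])
    return LfpRecording(
        patient_id=meta["patient"],
        dataset_id=meta.get("dataset", "unknown"),
        hemisphere=meta["hemisphere"],
        condition=meta["condition"],
        sample_rate=meta["sample_rate"],
        data=data,
        channels=channels,
        good_mask=mask,
    )


def read_edf(path: str | Path, **labels) -> LfpRecording:
    """Ingest an EDF file via MNE (optional dependency) as ring channels 1..n."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("EDF ingestion requires the optional 'mne' package") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads volts; convert to microvolts
    channels = [ContactChannel(level=i + 1) for i in range(data.shape[0])]
    return LfpRecording(
        sample_rate=float(raw.info["sfreq"]), data=data, channels=channels, **labels
    )


def _mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    """Good-segment mask as [start, stop) index runs of *bad* samples."""
    bad = ~np.asarray(mask, dtype=bool)
    if not bad.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    return [[int(s), int(e)] for s, e in zip(edges[::2], edges[1::2])]


def _runs_to_mask(runs: list[list[int]] | None, n: int) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    for start, stop in runs or []:
        mask[start:stop] = False
    return mask
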