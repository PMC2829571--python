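"""Core containers and plain-text I/O.

A recording is a pair of synchronized acceleration channels measured at the
neck, just below the thyroid cartilage: anterior-posterior (A-P, anterior
positive) and superior-inferior (S-I, superior positive).  A swallow segment
is one segmented, preprocessed swallow cut out of such a recording.

All sample intervals in this package are 0-based and half-open: ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical stimulus labels, ordered by viscosity (thin to thick)
STIMULI = ("water", "barium", "nectar", "honey")
#: the two drinking tasks: four sips with the cup removed between sips
#: ("discrete") versus four consecutive sips ("sequential")
TASKS = ("discrete", "sequential")


class DegenerateInputError(ValueError):
    """A computation received an input it is undefined for (e.g. a constant
    signal where a variance-normalised quantity is required)."""


class InsufficientDataError(ValueError):
    """Not enough complete observations to run a statistical procedure."""


@dataclass
class RecordingMeta:
    """Provenance labels for one recording."""

    participant: str
    stimulus: str
    task: str
    repetition: int
    sampling_rate_hz: float
    baseline: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMeta":
        return cls(**d)


@dataclass
class DualAxisRecording:
    """Two synchronized acceleration channels plus sampling rate and metadata.

    Parameters
    ----------
    ap, si
        Anterior-posterior and superior-inferior samples (equal length).
    sampling_rate
        Sampling rate in Hz.
    meta
        Optional provenance labels.
    """

    ap: np.ndarray
    si: np.ndarray
    sampling_rate: float
    meta: RecordingMeta | None = None

    def __post_init__(self) -> None:
        self.ap = np.asarray(self.ap, dtype=float)
        self.si = np.asarray(self.si, dtype=float)
        if self.ap.ndim != 1 or self.si.ndim != 1:
            raise ValueError("channels must be 1-D sample arrays")
        if len(self.ap) != len(self.si) or len(self.ap) == 0:
            raise ValueError("channels must have equal, non-zero length")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n(self) -> int:
        return len(self.ap)

    @property
    def duration_s(self) -> float:
        return (self.n - 1) / self.sampling_rate


@dataclass
class GroundTruth:
    """Latent truth attached to a synthetic recording (for validation only).

    ``swallow_boundaries`` are 0-based half-open ``(start, end)`` sample pairs,
    disjoint and sorted.  ``latent_regularity`` is the generator's relative
    broadband-noise amplitude for this recording (lower = more regular signal).
    """

    swallow_boundaries: list[tuple[int, int]] = field(default_factory=list)
    latent_durations: list[float] = field(default_factory=list)
    latent_regularity: float = float("nan")

    def validate(self, n_samples: int) -> None:
        prev_end = 0
        for start, end in self.swallow_boundaries:
            if not (0 <= start < end <= n_samples):
                raise ValueError(f"boundary ({start}, {end}) outside recording")
            if start < prev_end:
                raise ValueError("boundaries overlap or are unsorted")
            prev_end = end


@dataclass
class SwallowSegment:
    """One segmented, preprocessed swallow: paired A-P (X) and S-I (Y) windows."""

    X: np.ndarray
    Y: np.ndarray
    sampling_rate: float
    participant: str = ""
    stimulus: str = ""
    task: str = ""
    repetition: int = 0
    swallow_index: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if len(self.X) != len(self.Y) or len(self.X) < 2:
            raise ValueError("X and Y must have equal length >= 2")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def ids(self) -> tuple:
        return (self.participant, self.stimulus, self.task,
                self.repetition, self.swallow_index)


# ---------------------------------------------------------------------------
# plain-text I/O: two-column CSV per recording + sidecar JSON, ground-truth CSV
# ---------------------------------------------------------------------------

def save_recording(rec: DualAxisRecording, csv_path: str | Path) -> Path:
    """Write a recording as a two-column CSV (``ap``, ``si``) with a sidecar
    JSON carrying the metadata. Returns the CSV path."""
    csv_path = Path(csv_path)
    pd.DataFrame({"ap": rec.ap, "si": rec.si}).to_csv(csv_path, index=False)
    if rec.meta is not None:
        sidecar = csv_path.with_suffix(".json")
        sidecar.write_text(json.dumps(rec.meta.to_dict(), indent=1))
    return csv_path


def load_recording(csv_path: str | Path) -> DualAxisRecording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = csv_path.with_suffix(".json")
    meta = None
    sampling_rate = None
    if sidecar.exists():
        meta = RecordingMeta.from_dict(json.loads(sidecar.read_text()))
        sampling_rate = meta.sampling_rate_hz
    if sampling_rate is None:
        raise ValueError(f"no sidecar JSON with sampling rate for {csv_path}")
    return DualAxisRecording(df["ap"].to_numpy(), df["si"].to_numpy(),
                             sampling_rate, meta)


def save_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    rows = [{"start_sample": s, "end_sample": e, "swallow_index": i}
            for i, (s, e) in enumerate(gt.swallow_boundaries)]
    pd.DataFrame(rows, columns=["start_sample", "end_sample", "swallow_index"]
                 ).to_csv(path, index=False)
    return path


def load_boundaries(path: str | Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path)
    df = df.sort_values("swallow_index")
    return [(int(s), int(e)) for s, e in zip(df["start_sample"], df["end_sample"])]


def save_segment(seg: SwallowSegment, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    pd.DataFrame({"ap": seg.X, "si": seg.Y}).to_csv(csv_path, index=False)
    return csv_path
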