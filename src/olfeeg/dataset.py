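"""Domain types for epoched olfactory-EEG trials.

The whole pipeline operates on :class:`EEGTrialSet`: a homogeneous collection
of epoched multi-channel trials, each tagged with a subject identifier, a
diagnostic label (AD / MCI / Healthy) and the odor presented on that trial
(lemon or rose).  Subject identity drives the leave-one-subject-out protocol,
so every subject must carry exactly one label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import DataError

__all__ = ["Label", "Odor", "EEGTrial", "EEGTrialSet", "Violation", "validate_trialset"]

DEFAULT_CHANNELS = ("Fp1", "Fz", "Cz", "Pz")


class Label(enum.IntEnum):
    """Diagnostic class.  AD is index 0 on purpose: every tie-break in the
    evaluation protocol resolves toward AD, and ``argmax`` picking the lowest
    index on exact ties implements that rule for free."""

    AD = 0
    MCI = 1
    HEALTHY = 2


class Odor(enum.Enum):
    LEMON = "lemon"
    ROSE = "rose"


@dataclass
class EEGTrial:
    """One epoched trial: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    subject_id: str
    label: Label
    odor: Odor
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError(f"trial data must be 2-D (channels x samples), got {self.data.shape}")
        if self.data.shape[0] < 1:
            raise DataError("trial needs at least one channel")
        if self.data.shape[1] < 16:
            raise DataError(f"trial needs >= 16 samples, got {self.data.shape[1]}")
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EEGTrialSet:
    """Ordered, shape-homogeneous collection of trials."""

    trials: list[EEGTrial]
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[EEGTrial]:
        return iter(self.trials)

    def __getitem__(self, i: int) -> EEGTrial:
        return self.trials[i]

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def n_samples(self) -> int:
        return self.trials[0].n_samples

    @property
    def fs(self) -> float:
        return self.trials[0].fs

    @property
    def subject_ids(self) -> list[str]:
        """Distinct subject ids in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.subject_id, None)
        return list(seen)

    def subject_label(self, subject_id: str) -> Label:
        for t in self.trials:
            if t.subject_id == subject_id:
                return t.label
        raise KeyError(subject_id)

    def data_tensor(self) -> np.ndarray:
        """Stack all trials into a (n_trials, channels, samples) array."""
        return np.stack([t.data for t in self.trials])

    def subset(self, indices: "np.ndarray | list[int]") -> "EEGTrialSet":
        return EEGTrialSet([self.trials[i] for i in indices], list(self.channel_names))

    def filter_odor(self, odor: Odor) -> "EEGTrialSet":
        return EEGTrialSet([t for t in self.trials if t.odor == odor], list(self.channel_names))

    def labels(self) -> np.ndarray:
        return np.array([int(t.label) for t in self.trials])


@dataclass(frozen=True)
class Violation:
    """One structured invariant breach found by :func:`validate_trialset`."""

    kind: str
    message: str
    trial_index: int | None = None
    subject_id: str | None = None


def validate_trialset(ts: EEGTrialSet) -> list[Violation]:
    """Check every :class:`EEGTrialSet` invariant; report, never raise.

    Returns an empty list iff the set is well formed, otherwise one
    :class:`Violation` per breach (non-finite samples, heterogeneous shapes
    or sampling rates, a subject appearing under two labels, channel-name
    count mismatch, empty set).
    """
    out: list[Violation] = []
    if not ts.trials:
        return [Violation("empty", "trial set contains no trials")]
    ref = ts.trials[0]
    subject_labels: dict[str, Label] = {}
    for i, t in enumerate(ts.trials):
        if not np.all(np.isfinite(t.data)):
            out.append(Violation("nonfinite", f"trial {i} contains NaN/Inf", trial_index=i))
        if t.data.shape != ref.data.shape:
            out.append(
                Violation(
                    "shape",
                    f"trial {i} shape {t.data.shape} != {ref.data.shape}",
                    trial_index=i,
                )
            )
        if t.fs != ref.fs:
            out.append(Violation("fs", f"trial {i} fs {t.fs} != {ref.fs}", trial_index=i))
        prev = subject_labels.setdefault(t.subject_id, t.label)
        if prev != t.label:
            out.append(
                Violation(
                    "label_conflict",
                    f"subject {t.subject_id!r} appears with labels "
                    f"{prev.name} and {t.label.name}",
                    trial_index=i,
                    subject_id=t.subject_id,
                )
            )
    if len(ts.channel_names) != ref.n_channels:
        out.append(
            Violation(
                "channel_names",
                f"{len(ts.channel_names)} channel names for {ref.n_channels} channels",
            )
        )
    return out
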