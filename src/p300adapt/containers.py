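"""Core domain containers for continuous EEG and stimulus-locked epochs.

Conventions used throughout the package:

* sample indices are 0-based; every window is half-open ``[start, end)``;
* signal amplitudes are in microvolts end-to-end;
* epochs are arrays of shape ``(n_epochs, n_times, n_channels)``;
* the canonical 10-electrode montage is ``CANONICAL_MONTAGE`` below, in that
  order (occipital, parietal row, then Fz/Cz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Electrode order every downstream stage assumes (posterior-dominant montage
#: centred on the parieto-occipital P300 generators).
CANONICAL_MONTAGE = ("O1", "Oz", "O2", "P7", "P3", "Pz", "P4", "P8", "Fz", "Cz")

TARGET = "target"
NONTARGET = "nontarget"


class ContractError(ValueError):
    """An operation was called in violation of its documented contract."""


class SchemaError(ValueError):
    """A stored container is missing a required dataset or attribute."""


class MontageError(ValueError):
    """Channel layout does not match the expected montage."""


@dataclass(frozen=True)
class EventMarker:
    """A stimulus onset: 0-based sample index plus target/non-target label."""

    sample_index: int
    label: str

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ContractError(f"event sample_index must be >= 0, got {self.sample_index}")
        if self.label not in (TARGET, NONTARGET):
            raise ContractError(f"event label must be 'target' or 'nontarget', got {self.label!r}")


@dataclass
class ContinuousRecording:
    """A continuous multichannel EEG recording in microvolts.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, n_channels)``.
    sampling_rate
        Sampling frequency in Hz.
    channel_names
        One unique name per channel, in storage order.
    subject_id
        Free-form subject identifier.
    events
        Stimulus markers; every ``sample_index`` must fall inside the
        recording.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_names: Sequence[str]
    subject_id: str = ""
    events: list[EventMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ContractError("samples must be 2-D (n_samples, n_channels)")
        self.channel_names = list(self.channel_names)
        if self.samples.shape[1] != len(self.channel_names):
            raise ContractError(
                f"{self.samples.shape[1]} channels in data but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ContractError("channel names must be unique")
        if not self.sampling_rate > 0:
            raise ContractError("sampling_rate must be > 0")
        for ev in self.events:
            if ev.sample_index >= self.n_samples:
                raise ContractError(
                    f"event at sample {ev.sample_index} outside recording of "
                    f"{self.n_samples} samples"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def reorder_channels(self, order: Sequence[str] = CANONICAL_MONTAGE) -> "ContinuousRecording":
        """Return a copy with channels permuted into ``order``.

        Raises :class:`MontageError` if any requested channel is missing.
        """
        missing = [ch for ch in order if ch not in self.channel_names]
        if missing:
            raise MontageError(f"channels missing from recording: {missing}")
        idx = [self.channel_names.index(ch) for ch in order]
        return ContinuousRecording(
            samples=self.samples[:, idx],
            sampling_rate=self.sampling_rate,
            channel_names=list(order),
            subject_id=self.subject_id,
            events=list(self.events),
        )


@dataclass
class EpochSet:
    """Fixed-length stimulus-locked epochs for one subject.

    ``epochs`` has shape ``(n_epochs, n_times, n_channels)`` in microvolts.
    ``labels`` is optional (absent for the unlabeled target domain during
    adaptation): 0 = non-target, 1 = target. ``baseline`` optionally carries
    the pre-stimulus segment consumed by baseline correction and is dropped
    afterwards.
    """

    epochs: np.ndarray
    times_ms: np.ndarray
    sampling_rate: float
    channel_names: Sequence[str]
    subject_id: str = ""
    domain_tag: str = "source"
    labels: Optional[np.ndarray] = None
    baseline: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ContractError("epochs must be 3-D (n_epochs, n_times, n_channels)")
        if self.times_ms.shape != (self.epochs.shape[1],):
            raise ContractError("times_ms length must equal n_times")
        if self.times_ms.size >= 2 and not np.all(np.diff(self.times_ms) > 0):
            raise ContractError("times_ms must be strictly increasing")
        self.channel_names = list(self.channel_names)
        if self.epochs.shape[2] != len(self.channel_names):
            raise ContractError("n_channels must equal len(channel_names)")
        if self.domain_tag not in ("source", "target"):
            raise ContractError("domain_tag must be 'source' or 'target'")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.epochs.shape[0],):
                raise ContractError("labels must have length n_epochs")
            if not np.isin(self.labels, (0, 1)).all():
                raise ContractError("labels must be 0 (nontarget) or 1 (target)")
        if self.baseline is not None:
            self.baseline = np.asarray(self.baseline, dtype=np.float64)
            if self.baseline.ndim != 3 or self.baseline.shape[0] != self.epochs.shape[0] or self.baseline.shape[2] != self.epochs.shape[2]:
                raise ContractError("baseline must be (n_epochs, n_baseline_times, n_channels)")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[2]

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def without_labels(self) -> "EpochSet":
        """Copy with labels stripped (unsupervised target-domain view)."""
        return replace(self, epochs=self.epochs.copy(), labels=None,
                       baseline=None if self.baseline is None else self.baseline.copy())

    def __eq__(self, other: object) -> bool:  # field-by-field, exact
        if not isinstance(other, EpochSet):
            return NotImplemented
        same_opt = (
            (self.labels is None) == (other.labels is None)
            and (self.baseline is None) == (other.baseline is None)
        )
        return (
            same_opt
            and np.array_equal(self.epochs, other.epochs)
            and np.array_equal(self.times_ms, other.times_ms)
            and self.sampling_rate == other.sampling_rate
            and list(self.channel_names) == list(other.channel_names)
            and self.subject_id == other.subject_id
            and self.domain_tag == other.domain_tag
            and (self.labels is None or np.array_equal(self.labels, other.labels))
            and (self.baseline is None or np.array_equal(self.baseline, other.baseline))
        )
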