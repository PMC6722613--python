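"""In-memory encoded dataset: stacked one-hot windows, length features,
labels and frequency levels for a list of splicing events."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import SplicingEvent
from .features import LengthNormStats, compute_length_stats, encode_event
from .models import CLASS_TO_INT, POSITIVE_CLASS

__all__ = ["EncodedDataset", "encode_events"]


@dataclass
class EncodedDataset:
    """Columnar, model-ready form of an event set.

    ``levels`` holds each event's relevant frequency (inclusion level for
    ES, alternative-site usage for ALT3/ALT5, 1.0 for CON) so test-time
    strata can be reconstructed without the original events.
    """

    event_ids: np.ndarray  # (n,) str
    acceptor: np.ndarray  # (n, 140, 4) float32
    donor: np.ndarray  # (n, 140, 4) float32
    lengths: np.ndarray  # (n, 3) float32
    labels: np.ndarray  # (n,) str class names
    levels: np.ndarray  # (n,) float

    def __len__(self) -> int:
        return len(self.event_ids)

    def subset(self, idx) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(
            event_ids=self.event_ids[idx],
            acceptor=self.acceptor[idx],
            donor=self.donor[idx],
            lengths=self.lengths[idx],
            labels=self.labels[idx],
            levels=self.levels[idx],
        )

    def batch(self) -> dict:
        return {"acceptor": self.acceptor, "donor": self.donor, "lengths": self.lengths}

    def task_subset(self, task: str) -> "EncodedDataset":
        """Restrict to the classes a task discriminates (all four for DSC)."""
        if task == "DSC":
            return self
        pos = POSITIVE_CLASS[task]
        return self.subset(np.flatnonzero((self.labels == "CON") | (self.labels == pos)))

    def task_targets(self, task: str) -> np.ndarray:
        """Integer targets: 0/1 for binary tasks, class index for DSC."""
        if task == "DSC":
            return np.array([CLASS_TO_INT[c] for c in self.labels], dtype=np.int64)
        pos = POSITIVE_CLASS[task]
        return (self.labels == pos).astype(np.int64)


def _relevant_level(e: SplicingEvent) -> float:
    if e.as_class == "ES":
        return e.incl_level
    if e.as_class == "ALT3":
        return e.usage3_level
    if e.as_class == "ALT5":
        return e.usage5_level
    return 1.0


def encode_events(
    events, genome, stats: LengthNormStats | None = None
) -> tuple[EncodedDataset, LengthNormStats]:
    """Featurize classified events against a genome accessor.

    When *stats* is None, length-normalization statistics are computed from
    the events themselves (the usual case for self-contained datasets);
    externally supplied genome-wide statistics may be passed instead.
    """
    if stats is None:
        stats = compute_length_stats(events)
    samples = [encode_event(e, genome, stats) for e in events]
    return (
        EncodedDataset(
            event_ids=np.array([s.event_id for s in samples]),
            acceptor=np.stack([s.acceptor_mat for s in samples]),
            donor=np.stack([s.donor_mat for s in samples]),
            lengths=np.stack([s.lengths for s in samples]),
            labels=np.array([s.label for s in samples]),
            levels=np.array([_relevant_level(e) for e in events]),
        ),
        stats,
    )
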