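"""Junction-window extraction, one-hot encoding and length features.

Each event contributes two fixed-width sequence windows: 70 nt on either
side of the acceptor (3'ss, intron|exon) junction and of the donor (5'ss,
exon|intron) junction, i.e. 2 x 140 nt in total.  Windows are pure genomic
context around the junction point — they are *not* clamped at the exon
boundary, so for exons shorter than 140 nt the two windows overlap.  On the
minus strand both windows are reverse-complemented so they read 5'->3' in
transcript orientation and acceptor/donor roles follow the transcript, not
the reference.

Length features are the upstream-intron, exon and downstream-intron lengths
(L1, L2, L3), z-normalized with exon and intron statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .events import SplicingEvent

__all__ = [
    "WINDOW_FLANK",
    "WINDOW_LEN",
    "BASE_ORDER",
    "JunctionWindows",
    "LengthNormStats",
    "EncodedSample",
    "ExtractionError",
    "EncodingError",
    "extract_junction_windows",
    "one_hot_encode",
    "decode_one_hot",
    "reverse_complement",
    "compute_length_stats",
    "length_features",
    "windows_to_fasta",
]

WINDOW_FLANK = 70
WINDOW_LEN = 2 * WINDOW_FLANK  # 140 nt per junction
BASE_ORDER = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


class ExtractionError(ValueError):
    """Window extraction failed (chromosome bounds or unknown sequence)."""


class EncodingError(ValueError):
    """Sequence cannot be one-hot encoded (length or alphabet)."""


@dataclass(frozen=True)
class JunctionWindows:
    """The 140-nt acceptor and donor windows of one event, transcript-oriented."""

    acceptor_seq: str
    donor_seq: str

    def __post_init__(self) -> None:
        if len(self.acceptor_seq) != WINDOW_LEN or len(self.donor_seq) != WINDOW_LEN:
            raise ValueError(f"junction windows must be exactly {WINDOW_LEN} nt")


@dataclass(frozen=True)
class LengthNormStats:
    """Mean/sd of exon and intron lengths used to z-normalize L1, L2, L3."""

    exon_mean: float
    exon_sd: float
    intron_mean: float
    intron_sd: float

    def __post_init__(self) -> None:
        if self.exon_sd <= 0 or self.intron_sd <= 0:
            raise ValueError("length standard deviations must be > 0")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "exon_mean": self.exon_mean,
                    "exon_sd": self.exon_sd,
                    "intron_mean": self.intron_mean,
                    "intron_sd": self.intron_sd,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path) -> "LengthNormStats":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class EncodedSample:
    """Model-ready representation of one event: two one-hot matrices plus
    the normalized (L1, L2, L3) length triple and the class label."""

    event_id: str
    acceptor_mat: np.ndarray  # (140, 4) float32
    donor_mat: np.ndarray  # (140, 4) float32
    lengths: np.ndarray  # (3,) float32
    label: str


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """0-based half-open fetch from a pyfaidx.Fasta or any mapping of
    chromosome name to sliceable sequence."""
    try:
        record = genome[chrom]
    except KeyError as exc:
        raise ExtractionError(f"unknown chromosome {chrom!r}") from exc
    if start < 0 or end > len(record):
        raise ExtractionError(
            f"window [{start},{end}) exceeds bounds of {chrom} (len {len(record)})"
        )
    seq = record[start:end]
    return str(seq).upper()


def extract_junction_windows(e: SplicingEvent, genome) -> JunctionWindows:
    """Extract the +/-70 nt acceptor and donor windows for one event.

    On the plus strand the acceptor junction is ``exon_start`` and the donor
    junction ``exon_end``; on the minus strand the roles swap and both
    windows are reverse-complemented so the result is transcript-oriented
    with the junction between positions 70 and 71 in both cases.
    """
    if e.strand == "+":
        acceptor = _fetch(genome, e.chrom, e.exon_start - WINDOW_FLANK, e.exon_start + WINDOW_FLANK)
        donor = _fetch(genome, e.chrom, e.exon_end - WINDOW_FLANK, e.exon_end + WINDOW_FLANK)
    else:
        acceptor = reverse_complement(
            _fetch(genome, e.chrom, e.exon_end - WINDOW_FLANK, e.exon_end + WINDOW_FLANK)
        )
        donor = reverse_complement(
            _fetch(genome, e.chrom, e.exon_start - WINDOW_FLANK, e.exon_start + WINDOW_FLANK)
        )
    return JunctionWindows(acceptor_seq=acceptor, donor_seq=donor)


def one_hot_encode(seq: str, length: int = WINDOW_LEN) -> np.ndarray:
    """One-hot encode a DNA/RNA sequence into a (length, 4) binary matrix.

    Column order is A, C, G, T; U is a synonym for T; N encodes to an
    all-zero row.  Any other character, or a wrong length, raises
    :class:`EncodingError`.
    """
    if length is not None and len(seq) != length:
        raise EncodingError(f"expected {length} nt, got {len(seq)}")
    mat = np.zeros((len(seq), 4), dtype=np.float32)
    for i, base in enumerate(seq.upper()):
        if base == "N":
            continue
        idx = _BASE_INDEX.get(base)
        if idx is None:
            raise EncodingError(f"illegal character {base!r} at position {i}")
        mat[i, idx] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to N."""
    out = []
    for row in np.asarray(mat):
        if row.sum() == 0:
            out.append("N")
        else:
            out.append(BASE_ORDER[int(np.argmax(row))])
    return "".join(out)


def compute_length_stats(events) -> LengthNormStats:
    """Mean and sample sd of exon lengths, and of the pooled multiset of
    upstream+downstream intron lengths, over *events*."""
    exon_lens = np.array([e.exon_len for e in events], dtype=float)
    intron_lens = np.array(
        [e.upstream_intron_len for e in events] + [e.downstream_intron_len for e in events],
        dtype=float,
    )
    if exon_lens.size < 2 or intron_lens.size < 2:
        raise ValueError("need at least 2 exon and 2 intron lengths for stats")
    exon_sd = float(np.std(exon_lens, ddof=1))
    intron_sd = float(np.std(intron_lens, ddof=1))
    if exon_sd == 0 or intron_sd == 0:
        raise ValueError("degenerate length statistics (zero standard deviation)")
    return LengthNormStats(
        exon_mean=float(np.mean(exon_lens)),
        exon_sd=exon_sd,
        intron_mean=float(np.mean(intron_lens)),
        intron_sd=intron_sd,
    )


def length_features(e: SplicingEvent, s: LengthNormStats) -> np.ndarray:
    """z-normalized (L1, L2, L3) = (upstream intron, exon, downstream intron)."""
    return np.array(
        [
            (e.upstream_intron_len - s.intron_mean) / s.intron_sd,
            (e.exon_len - s.exon_mean) / s.exon_sd,
            (e.downstream_intron_len - s.intron_mean) / s.intron_sd,
        ],
        dtype=np.float32,
    )


def encode_event(e: SplicingEvent, genome, stats: LengthNormStats) -> EncodedSample:
    """Full featurization of one event: windows + one-hot + length triple."""
    w = extract_junction_windows(e, genome)
    return EncodedSample(
        event_id=e.event_id,
        acceptor_mat=one_hot_encode(w.acceptor_seq),
        donor_mat=one_hot_encode(w.donor_seq),
        lengths=length_features(e, stats),
        label=e.as_class,
    )


def windows_to_fasta(event_windows: dict[str, JunctionWindows], path) -> None:
    """Write windows as FASTA records named ``<event_id>|acceptor`` / ``|donor``."""
    with open(path, "w") as fh:
        for event_id, w in event_windows.items():
            fh.write(f">{event_id}|acceptor\n{w.acceptor_seq}\n")
            fh.write(f">{event_id}|donor\n{w.donor_seq}\n")
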