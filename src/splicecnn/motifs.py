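"""Turning learned first-layer convolution filters into sequence motifs.

Each first-layer filter is scanned over a set of one-hot encoded windows;
the filter's activation is computed at every full-width offset, and the
subsequences at offsets where the activation exceeds a fraction (default
one half) of the filter's global maximum are stacked into a position
frequency matrix (PFM).  PFMs normalize to position weight matrices (PWMs)
and export in MEME minimal motif format for comparison tools such as
TOMTOM.  Filters that are never strongly activated, or that collect fewer
than ``min_sites`` subsequences, are dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .features import BASE_ORDER

__all__ = [
    "PositionFrequencyMatrix",
    "kernels_to_pfms",
    "scan_filters",
    "pfm_to_pwm",
    "write_meme",
    "read_meme",
    "motif_similarity",
    "MotifMatch",
]


@dataclass
class PositionFrequencyMatrix:
    """Per-column base counts collected from a filter's activating sites."""

    motif_id: str
    counts: np.ndarray  # (width, 4) non-negative ints, columns A,C,G,T
    n_sites: int

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("PFM counts must be non-negative")
        sums = self.counts.sum(axis=1)
        if self.n_sites < 1 or not (sums == self.n_sites).all():
            raise ValueError("every PFM column must sum to n_sites >= 1")

    def consensus(self) -> str:
        return "".join(BASE_ORDER[i] for i in self.counts.argmax(axis=1))


def scan_filters(
    kernels: np.ndarray,
    bias: np.ndarray,
    sequences: np.ndarray,
    activation_fraction: float = 0.5,
    min_sites: int = 10,
    id_prefix: str = "filter",
) -> tuple[list[PositionFrequencyMatrix], list[tuple[str, str]]]:
    """Scan filters (n_filters, width, 4) over one-hot sequences (n, L, 4).

    Offsets are full-width only, so offset i corresponds to sequence
    positions [i, i+width).  Returns retained PFMs and a list of
    (motif_id, reason) for dropped filters.
    """
    kernels = np.asarray(kernels, dtype=np.float32)
    sequences = np.asarray(sequences, dtype=np.float32)
    nf, width, _ = kernels.shape
    windows = np.lib.stride_tricks.sliding_window_view(sequences, width, axis=1)
    # windows: (n, positions, 4, width); activation of every filter everywhere
    acts = np.einsum("npcw,fwc->npf", windows, kernels, optimize=True) + bias
    pfms: list[PositionFrequencyMatrix] = []
    dropped: list[tuple[str, str]] = []
    for f in range(nf):
        motif_id = f"{id_prefix}_{f:02d}"
        act = acts[:, :, f]
        a_max = float(act.max())
        if a_max <= 0:
            dropped.append((motif_id, "max activation <= 0"))
            continue
        si, sj = np.nonzero(act > activation_fraction * a_max)
        sites = windows[si, sj]  # (k, 4, width) one-hot slices
        # keep only fully determined sites (no N rows)
        full = (sites.sum(axis=1) > 0.5).all(axis=1)
        sites = sites[full]
        if sites.shape[0] < min_sites:
            dropped.append((motif_id, f"only {sites.shape[0]} sites (< {min_sites})"))
            continue
        counts = np.rint(sites.sum(axis=0).T).astype(np.int64)  # (width, 4)
        pfms.append(PositionFrequencyMatrix(motif_id, counts, int(sites.shape[0])))
    return pfms, dropped


def kernels_to_pfms(
    model,
    sequences_by_input: dict[str, np.ndarray],
    activation_fraction: float = 0.5,
    min_sites: int = 10,
) -> list[PositionFrequencyMatrix]:
    """Extract PFMs from every first-layer filter of a trained model.

    *sequences_by_input* maps each model input ("acceptor"/"donor") to the
    one-hot windows to scan — typically held-out test windows.
    """
    kernels = model.first_layer_kernels()
    pfms: list[PositionFrequencyMatrix] = []
    for name in model.spec.inputs:
        got, _ = scan_filters(
            kernels[name],
            kernels[name + "_bias"],
            sequences_by_input[name],
            activation_fraction=activation_fraction,
            min_sites=min_sites,
            id_prefix=f"{model.spec.task}|{name}",
        )
        pfms.extend(got)
    return pfms


def pfm_to_pwm(pfm: PositionFrequencyMatrix, pseudocount: float = 0.0) -> np.ndarray:
    """Normalize counts to per-column probabilities with a pseudocount."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    return (pfm.counts + pseudocount) / (pfm.n_sites + 4.0 * pseudocount)


def write_meme(
    motifs: list[tuple[str, np.ndarray, int]],
    path,
    alphabet: str = "DNA",
    background: np.ndarray | None = None,
) -> None:
    """Write PWMs in MEME minimal motif format.

    *motifs* is a list of (motif_id, (width, 4) probability matrix, nsites).
    The RNA alphabet relabels the T column as U; probabilities are written
    with six decimals and each column must sum to 1 within 1e-6.
    """
    if alphabet not in ("DNA", "RNA"):
        raise ValueError("alphabet must be DNA or RNA")
    letters = "ACGT" if alphabet == "DNA" else "ACGU"
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {letters}\n\n")
        if alphabet == "DNA":
            fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{l} {b:.6f}" for l, b in zip(letters, bg)) + "\n\n")
        for motif_id, pwm, nsites in motifs:
            pwm = np.asarray(pwm, dtype=float)
            if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"motif {motif_id}: columns must sum to 1")
            fh.write(f"MOTIF {motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.shape[0]} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in pwm:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[tuple[str, np.ndarray, int]]:
    """Parse a MEME minimal motif file back into (id, pwm, nsites) tuples."""
    motifs: list[tuple[str, np.ndarray, int]] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            motif_id = line.split(None, 1)[1].split()[0]
            i += 1
            header = lines[i].strip()
            m = re.search(r"w=\s*(\d+)", header)
            w = int(m.group(1))
            m = re.search(r"nsites=\s*(\d+)", header)
            nsites = int(m.group(1)) if m else 0
            rows = []
            for j in range(w):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            motifs.append((motif_id, np.array(rows), nsites))
            i += 1 + w
        else:
            i += 1
    return motifs


class MotifMatch(NamedTuple):
    offset: int
    correlation: float
    orientation: str  # "+" or "-" (reverse complement)


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-column Pearson correlation of two aligned (k, 4) slices."""
    corrs = []
    for col_a, col_b in zip(a, b):
        sa, sb = col_a.std(), col_b.std()
        if sa == 0 or sb == 0:
            corrs.append(0.0)
        else:
            corrs.append(float(np.corrcoef(col_a, col_b)[0, 1]))
    return float(np.mean(corrs))


def reverse_complement_pwm(pwm: np.ndarray) -> np.ndarray:
    """Reverse the positions and swap A<->T, C<->G columns."""
    return pwm[::-1, ::-1]


def motif_similarity(pwm_a: np.ndarray, pwm_b: np.ndarray, min_overlap: int = 4,
                     dna: bool = True) -> MotifMatch:
    """Best ungapped alignment of two PWMs by mean column-wise Pearson
    correlation, considering all offsets with at least *min_overlap*
    overlapping columns and (for DNA) both orientations.

    The offset is the position of ``pwm_b``'s first column relative to
    ``pwm_a``'s (negative when b starts before a).
    """
    a = np.asarray(pwm_a, dtype=float)
    wa, wb = a.shape[0], np.asarray(pwm_b).shape[0]
    if wa < min_overlap or wb < min_overlap:
        raise ValueError(f"PWMs must have at least {min_overlap} columns")
    best: MotifMatch | None = None
    orientations = [("+", np.asarray(pwm_b, dtype=float))]
    if dna:
        orientations.append(("-", reverse_complement_pwm(np.asarray(pwm_b, dtype=float))))
    for orient, b in orientations:
        for off in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a, hi_a = max(0, off), min(wa, off + wb)
            if hi_a - lo_a < min_overlap:
                continue
            sl_a = a[lo_a:hi_a]
            sl_b = b[lo_a - off : hi_a - off]
            c = _column_corr(sl_a, sl_b)
            if best is None or c > best.correlation:
                best = MotifMatch(offset=off, correlation=c, orientation=orient)
    if best is None:
        raise ValueError("no alignment with sufficient overlap")
    return best
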