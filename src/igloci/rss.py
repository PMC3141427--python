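"""Recombination signal sequence (RSS) modelling and scanning.

An RSS is a conserved heptamer, a spacer of ~12 or ~23 bp, and a conserved
nonamer.  The heptamer always abuts the coding segment.  On the forward
strand, an RSS lying 3' of a coding segment reads heptamer-spacer-nonamer
left to right; an RSS lying 5' of a coding segment is the reverse
complement of that pattern, so its forward-strand spelling is
revcomp(nonamer)-spacer-revcomp(heptamer).

Scanning is consensus + Hamming distance with per-element mismatch caps,
exactly one cap for the heptamer and one for the nonamer.  N never matches
anything, on either side of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqio import Interval, NucSequence, normalize_residues, revcomp

#: canonical vertebrate RSS consensus elements
HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "TATTATTGT"

DOWNSTREAM = "downstream_of_coding"
UPSTREAM = "upstream_of_coding"


@dataclass(frozen=True)
class RssModel:
    """Consensus sequences, spacer class and mismatch tolerances for one scan.

    The nonamer consensus and its default tolerance of 2 mismatches follow
    the canonical teleost nonamer; the heptamer consensus is the canonical
    vertebrate CACAGTG with a default tolerance of 1 mismatch (the heptamer
    is the better-conserved element).  ``spacer_slack`` widens the accepted
    spacer length symmetrically; 0 enforces the exact spacer class.
    """

    heptamer_consensus: str = HEPTAMER_CONSENSUS
    nonamer_consensus: str = NONAMER_CONSENSUS
    spacer_class: int = 23
    spacer_slack: int = 1
    heptamer_max_mm: int = 1
    nonamer_max_mm: int = 2

    def __post_init__(self) -> None:
        hept = normalize_residues(self.heptamer_consensus, context="heptamer consensus")
        nona = normalize_residues(self.nonamer_consensus, context="nonamer consensus")
        if len(hept) != 7 or len(nona) != 9:
            raise ValueError("heptamer must be 7 nt and nonamer 9 nt")
        if self.spacer_class not in (12, 23):
            raise ValueError("spacer_class must be 12 or 23")
        if not (0 <= self.heptamer_max_mm <= 7 and 0 <= self.nonamer_max_mm <= 9):
            raise ValueError("mismatch caps out of range")
        if self.spacer_slack < 0:
            raise ValueError("spacer_slack must be >= 0")

    def spacer_lengths(self) -> range:
        return range(
            max(0, self.spacer_class - self.spacer_slack),
            self.spacer_class + self.spacer_slack + 1,
        )


@dataclass(frozen=True)
class RssHit:
    """One heptamer/spacer/nonamer match.

    ``orientation`` is relative to a hypothetical forward-strand coding
    segment: a '+' motif match (pattern as written) is an RSS downstream of
    coding; a '-' match is an RSS upstream of coding.
    """

    heptamer: Interval
    nonamer: Interval
    spacer_len: int
    orientation: str
    heptamer_mm: int
    nonamer_mm: int

    @property
    def total_mm(self) -> int:
        return self.heptamer_mm + self.nonamer_mm

    @property
    def strand(self) -> str:
        return self.heptamer.strand


def _encode(seq: str, n_code: int) -> np.ndarray:
    """Byte-encode a sequence; N is remapped so it can never match."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = n_code
    return arr


def hamming_scan(seq: str, motif: str, max_mm: int) -> list[tuple[int, int]]:
    """All windows of ``seq`` within ``max_mm`` Hamming distance of ``motif``.

    Returns ascending (position, mismatches) pairs.  N counts as a mismatch
    on either side.  A motif longer than the sequence yields an empty list.
    """
    if len(motif) > len(seq) or not motif:
        return []
    a = _encode(seq, 1)
    m = _encode(motif, 2)
    windows = sliding_window_view(a, len(m))
    mism = (windows != m).sum(axis=1)
    hits = np.nonzero(mism <= max_mm)[0]
    return [(int(i), int(mism[i])) for i in hits]


def _scan_plus(seq: str, seq_id: str, model: RssModel) -> list[RssHit]:
    """Forward-pattern hits (heptamer-spacer-nonamer as written)."""
    hept = hamming_scan(seq, model.heptamer_consensus, model.heptamer_max_mm)
    nona = dict(hamming_scan(seq, model.nonamer_consensus, model.nonamer_max_mm))
    hits = []
    for hpos, hmm in hept:
        for spacer in model.spacer_lengths():
            npos = hpos + 7 + spacer
            nmm = nona.get(npos)
            if nmm is not None and npos + 9 <= len(seq):
                hits.append(
                    RssHit(
                        heptamer=Interval(seq_id, hpos, hpos + 7, "+"),
                        nonamer=Interval(seq_id, npos, npos + 9, "+"),
                        spacer_len=spacer,
                        orientation=DOWNSTREAM,
                        heptamer_mm=hmm,
                        nonamer_mm=nmm,
                    )
                )
    return hits


def _flip_hit(hit: RssHit, length: int, seq_id: str) -> RssHit:
    """Map a hit found on the reverse complement back to forward coordinates."""

    def flip(iv: Interval) -> Interval:
        return Interval(seq_id, length - iv.end, length - iv.start, "-")

    return RssHit(
        heptamer=flip(hit.heptamer),
        nonamer=flip(hit.nonamer),
        spacer_len=hit.spacer_len,
        orientation=UPSTREAM,
        heptamer_mm=hit.heptamer_mm,
        nonamer_mm=hit.nonamer_mm,
    )


def scan_rss(seq: NucSequence, model: RssModel, strand: str = "both") -> list[RssHit]:
    """Exhaustive RSS scan over positions, spacer slack, and requested strands.

    strand '+' reports motif matches spelled heptamer-spacer-nonamer on the
    forward sequence (RSS downstream of a forward coding segment); strand '-'
    reports reverse-complement matches (RSS upstream of a forward coding
    segment, or downstream of a minus-strand one).  Overlapping hits are all
    reported; callers do any tie-breaking.
    """
    if strand not in ("+", "-", "both"):
        raise ValueError(f"invalid strand {strand!r}")
    hits: list[RssHit] = []
    if strand in ("+", "both"):
        hits.extend(_scan_plus(seq.residues, seq.id, model))
    if strand in ("-", "both"):
        rc = revcomp(seq.residues)
        hits.extend(
            _flip_hit(h, len(seq), seq.id) for h in _scan_plus(rc, seq.id, model)
        )
    hits.sort(key=lambda h: (h.heptamer.start, h.heptamer.strand, h.spacer_len))
    return hits
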