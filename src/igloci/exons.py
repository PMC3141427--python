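"""CH exon mapping by reference homology, orthology naming, zone partitioning.

Constant-region (CH) exons are located by comparing the germline sequence
against labeled reference exons (e.g. stickleback Cmu/Cdelta exons), named
after the reference they best match (orthology naming, so repeated copies
in duplicated zones share one label), and grouped into "zones": tandem
duplicated blocks each carrying D/JH segments and a CH exon battery.

Labels use ASCII spellings of the field's exon names: Cmu1..Cmu4 (IgM
domains), Cdelta1..Cdelta7 (IgD domains), TM1/TM2 (transmembrane and
cytoplasmic exons), SEC_TAIL (the IgM secretory tail, genomically
contiguous with Cmu4), and EX0 (the non-coding exon 3' of the JH cluster).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align

from .segments import SegmentCall
from .seqio import Interval, NucSequence, normalize_residues, read_fasta, revcomp

CMU_LABELS = ("Cmu1", "Cmu2", "Cmu3", "Cmu4")
CDELTA_LABELS = tuple(f"Cdelta{i}" for i in range(1, 8))
LABEL_VOCAB = CMU_LABELS + CDELTA_LABELS + ("TM1", "TM2", "SEC_TAIL", "EX0")
CH_LABELS = frozenset(CMU_LABELS) | frozenset(CDELTA_LABELS) | {"TM1", "TM2", "SEC_TAIL"}


@dataclass(frozen=True)
class ReferenceExon:
    """A labeled reference exon used for mapping and orthology naming."""

    label: str
    species_tag: str
    residues: str

    def __post_init__(self) -> None:
        if self.label not in LABEL_VOCAB:
            raise ValueError(f"unknown exon label {self.label!r}")
        normalize_residues(self.residues, context=f"reference {self.label}")


def read_reference_exons(path: str | Path) -> list[ReferenceExon]:
    """Read reference exons from FASTA with ids formatted ``LABEL|species``."""
    refs = []
    for rec in read_fasta(path):
        label, _, species = rec.id.partition("|")
        refs.append(ReferenceExon(label, species or "unknown", rec.residues))
    return refs


@dataclass
class ExonAnnotation:
    """A located CH (or exon-0) copy on the germline sequence."""

    label: str
    interval: Interval
    identity: float
    splice_ok: bool
    zone_id: int | None = None

    @property
    def strand(self) -> str:
        return self.interval.strand


# ------------------------------------------------------------- exon mapping


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _identity(a: str, b: str) -> float:
    """Ungapped identity over equal-length strings; N matches nothing."""
    x = np.frombuffer(a.encode(), np.uint8)
    y = np.frombuffer(b.encode(), np.uint8)
    n = min(len(x), len(y))
    if n == 0:
        return 0.0
    eq = (x[:n] == y[:n]) & (x[:n] != ord("N"))
    return float(eq.mean())


def _snap(seq: str, pos: int, signal: str, before: bool, snap_max: int) -> tuple[int, bool]:
    """Snap a boundary to the nearest position with a splice signal.

    ``before=True`` looks for ``signal`` immediately 5' of the boundary
    (acceptor AG), else immediately 3' (donor GT).  Returns (position,
    found); the original position is kept when no signal is within
    ``snap_max`` nt.
    """
    for delta in sorted(range(-snap_max, snap_max + 1), key=abs):
        p = pos + delta
        if before:
            if p >= 2 and seq[p - 2 : p] == signal:
                return p, True
        else:
            if p + 2 <= len(seq) and seq[p : p + 2] == signal:
                return p, True
    return pos, False


def _map_plus(
    seq: str,
    seq_id: str,
    refs: list[ReferenceExon],
    min_identity: float,
    snap_max: int,
    k: int,
    min_seed_votes: int,
) -> list[ExonAnnotation]:
    index = _kmer_index(seq, k)
    out: list[ExonAnnotation] = []
    for ref in refs:
        L = len(ref.residues)
        if L < k:
            continue
        votes: Counter[int] = Counter()
        for rpos in range(L - k + 1):
            for spos in index.get(ref.residues[rpos : rpos + k], ()):
                votes[spos - rpos] += 1
        for d, n_votes in votes.items():
            if n_votes < min_seed_votes or d < 0 or d + L > len(seq):
                continue
            ident = _identity(seq[d : d + L], ref.residues)
            if ident < min_identity:
                continue
            start, ok5 = _snap(seq, d, "AG", True, snap_max)
            end, ok3 = _snap(seq, d + L, "GT", False, snap_max)
            if end <= start:
                continue
            out.append(
                ExonAnnotation(
                    label=ref.label,
                    interval=Interval(seq_id, start, end, "+"),
                    identity=ident,
                    splice_ok=ok5 and ok3,
                )
            )
    return out


def map_ch_exons(
    genomic: NucSequence,
    refs: list[ReferenceExon],
    *,
    min_identity: float = 0.70,
    snap_max: int = 6,
    k: int = 12,
    min_seed_votes: int = 2,
    strand: str = "both",
) -> list[ExonAnnotation]:
    """Locate all genomic copies of each reference exon.

    Candidate placements are seeded by shared exact k-mers on one diagonal
    and accepted on full-reference ungapped identity >= ``min_identity``.
    Boundaries are snapped to the nearest AG (5') / GT (3') within
    ``snap_max`` nt when present.  Every copy of every label is reported;
    duplicated zones yield repeated labels.
    """
    if not refs:
        return []
    annos: list[ExonAnnotation] = []
    if strand in ("+", "both"):
        annos.extend(
            _map_plus(genomic.residues, genomic.id, refs, min_identity, snap_max, k, min_seed_votes)
        )
    if strand in ("-", "both"):
        rc = revcomp(genomic.residues)
        n = len(genomic)
        for a in _map_plus(rc, genomic.id, refs, min_identity, snap_max, k, min_seed_votes):
            a.interval = Interval(
                genomic.id, n - a.interval.end, n - a.interval.start, "-"
            )
            annos.append(a)
    # dedupe identical placements found via multiple seeds; keep best per locus/label
    best: dict[tuple[str, int, int, str], ExonAnnotation] = {}
    for a in annos:
        key = (a.label, a.interval.start, a.interval.end, a.interval.strand)
        if key not in best or a.identity > best[key].identity:
            best[key] = a
    result = list(best.values())
    result.sort(key=lambda a: (a.interval.start, a.label))
    return result


# ---------------------------------------------------------- orthology naming


def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def name_exon_orthology(
    exon_seq: str,
    refs: list[ReferenceExon],
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[str, float]:
    """Name an exon after its best-scoring reference label.

    Returns (label, margin) where margin is the score gap to the best
    competing label; an exact tie yields ("ambiguous", 0).
    """
    if not exon_seq:
        raise ValueError("empty exon sequence")
    labels = {r.label for r in refs}
    if len(labels) < 2:
        raise ValueError("orthology naming requires references for >= 2 labels")
    aligner = _aligner(match, mismatch, gap)
    best_by_label: dict[str, float] = {}
    for ref in refs:
        score = aligner.score(exon_seq, ref.residues)
        if score > best_by_label.get(ref.label, float("-inf")):
            best_by_label[ref.label] = score
    ranked = sorted(best_by_label.items(), key=lambda kv: (-kv[1], kv[0]))
    margin = ranked[0][1] - ranked[1][1]
    if margin == 0:
        return "ambiguous", 0.0
    return ranked[0][0], float(margin)


# ------------------------------------------------------------------- zones


@dataclass
class Zone:
    """A contiguous VH-free cluster of D/JH/CH annotations; the unit of duplication."""

    zone_id: int
    interval: Interval
    members: list = field(default_factory=list)
    functional: bool = True

    def labels(self) -> list[str]:
        return [m.label for m in self.members if isinstance(m, ExonAnnotation)]


def _zone_functional(labels: list[str]) -> bool:
    """Heuristic functional flag: a complete Cmu1..4 set or a complete Cdelta chain."""
    lab = set(labels)
    complete_mu = all(x in lab for x in CMU_LABELS)
    n_delta = len(lab & set(CDELTA_LABELS))
    complete_delta = "Cdelta1" in lab and n_delta >= 4 and {"TM1", "TM2"} <= lab
    return complete_mu or complete_delta


def partition_zones(
    segment_calls: list[SegmentCall],
    exon_annotations: list[ExonAnnotation],
    *,
    zone_gap_max: int = 15_000,
) -> list[Zone]:
    """Partition annotations into zones.

    Boundaries open at any VH call and at any gap larger than
    ``zone_gap_max`` between consecutive non-VH annotations.  Each maximal
    VH-free run containing at least one CH exon becomes a zone; zone ids
    are assigned in genomic order and written back onto the member exon
    annotations.
    """
    items: list = sorted(
        [c for c in segment_calls] + [a for a in exon_annotations],
        key=lambda x: (x.interval.start if isinstance(x, ExonAnnotation) else x.exon.start),
    )

    def start_of(x):
        return x.interval.start if isinstance(x, ExonAnnotation) else x.exon.start

    def end_of(x):
        return x.interval.end if isinstance(x, ExonAnnotation) else x.exon.end

    runs: list[list] = [[]]
    prev_end: int | None = None
    for item in items:
        is_vh = isinstance(item, SegmentCall) and item.kind == "VH"
        if is_vh:
            if runs[-1]:
                runs.append([])
            prev_end = None
            continue
        if prev_end is not None and start_of(item) - prev_end > zone_gap_max:
            if runs[-1]:
                runs.append([])
        runs[-1].append(item)
        prev_end = max(prev_end or 0, end_of(item))

    zones: list[Zone] = []
    for run in runs:
        ch = [
            m for m in run
            if isinstance(m, ExonAnnotation) and m.label in CH_LABELS
        ]
        if not ch:
            continue
        seq_id = run[0].interval.seq_id if isinstance(run[0], ExonAnnotation) else run[0].exon.seq_id
        zone = Zone(
            zone_id=len(zones) + 1,
            interval=Interval(seq_id, min(map(start_of, run)), max(map(end_of, run))),
            members=run,
            functional=_zone_functional(
                [m.label for m in run if isinstance(m, ExonAnnotation)]
            ),
        )
        for m in run:
            if isinstance(m, ExonAnnotation):
                m.zone_id = zone.zone_id
        zones.append(zone)
    return zones
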