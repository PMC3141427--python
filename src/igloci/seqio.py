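"""Sequence and annotation I/O with fixed coordinate conventions.

All coordinates inside the package are 0-based half-open on the forward
strand; minus-strand features store forward coordinates and are
reverse-complemented on extraction.  GFF3 output converts to the standard
1-based inclusive convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: feature types allowed in GFF3 output
GFF_TYPES = ("V_gene_segment", "D_gene_segment", "J_gene_segment", "exon", "region")


class InputError(ValueError):
    """Invalid user-supplied input (bad file, bad alphabet, bad coordinates)."""


def normalize_residues(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, convert U to T, and reject any non-{A,C,G,T,N} character."""
    s = raw.upper().replace("U", "T")
    for pos, ch in enumerate(s):
        if ch not in VALID_ALPHABET:
            raise InputError(
                f"invalid character {ch!r} at position {pos} in {context}"
            )
    return s


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on the forward strand of ``seq_id``."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Interval":
        return Interval(self.seq_id, self.start + offset, self.end + offset, self.strand)


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N; any other character is an error."""
    for ch in set(seq) - VALID_ALPHABET:
        raise InputError(f"invalid character {ch!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def extract(seq: NucSequence, interval: Interval) -> str:
    """Extract interval sequence, reverse-complementing minus-strand features."""
    if interval.end > len(seq):
        raise InputError(
            f"interval [{interval.start}, {interval.end}) out of bounds for "
            f"{seq.id} (length {len(seq)})"
        )
    sub = seq.residues[interval.start : interval.end]
    return revcomp(sub) if interval.strand == "-" else sub


def map_back(start: int, end: int, length: int) -> tuple[int, int]:
    """Map a [start, end) interval on a reverse complement back to forward coordinates."""
    return length - end, length - start


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a FASTA file into normalized :class:`NucSequence` records.

    Duplicate ids are a hard error; an empty file yields an empty list with
    a warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = normalize_residues(str(rec.seq), context=f"record {rec.id!r}")
        records.append(NucSequence(rec.id, residues))
    if not records:
        warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
    return records


def write_fasta(seqs: Iterable[NucSequence], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass
class GffFeature:
    """One GFF3 feature row (internal coordinates, converted on write)."""

    ftype: str
    interval: Interval
    attributes: dict[str, str] = field(default_factory=dict)
    score: float | None = None
    source: str = "igloci"

    def __post_init__(self) -> None:
        if self.ftype not in GFF_TYPES:
            raise InputError(f"feature type {self.ftype!r} not in {GFF_TYPES}")


def _esc(value: str) -> str:
    return str(value).replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff3(
    features: Sequence[GffFeature],
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
) -> None:
    """Write sorted GFF3 (1-based inclusive coordinates).

    ``seq_lengths`` enables bounds checking and ``##sequence-region`` pragmas.
    """
    if seq_lengths:
        for f in features:
            length = seq_lengths.get(f.interval.seq_id)
            if length is not None and f.interval.end > length:
                raise InputError(
                    f"feature [{f.interval.start}, {f.interval.end}) out of bounds "
                    f"for {f.interval.seq_id} (length {length})"
                )
    ordered = sorted(features, key=lambda f: (f.interval.seq_id, f.interval.start, f.interval.end))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seq_lengths:
            for sid, length in sorted(seq_lengths.items()):
                fh.write(f"##sequence-region {sid} 1 {length}\n")
        for f in ordered:
            attrs = ";".join(f"{k}={_esc(v)}" for k, v in f.attributes.items()) or "."
            score = "." if f.score is None else f"{f.score:g}"
            fh.write(
                "\t".join(
                    [
                        f.interval.seq_id,
                        f.source,
                        f.ftype,
                        str(f.interval.start + 1),
                        str(f.interval.end),
                        score,
                        f.interval.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GffFeature]:
    """Parse GFF3 written by :func:`write_gff3` back to internal coordinates."""
    features: list[GffFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise InputError(f"malformed GFF3 line: {line!r}")
            seqid, source, ftype, start, end, score, strand, _, attrs = cols
            attributes: dict[str, str] = {}
            if attrs != ".":
                for pair in attrs.split(";"):
                    if not pair:
                        continue
                    key, _, value = pair.partition("=")
                    attributes[key] = (
                        value.replace("%3B", ";").replace("%3D", "=").replace("%2C", ",")
                    )
            features.append(
                GffFeature(
                    ftype=ftype,
                    interval=Interval(seqid, int(start) - 1, int(end), strand),
                    attributes=attributes,
                    score=None if score == "." else float(score),
                    source=source,
                )
            )
    return features
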