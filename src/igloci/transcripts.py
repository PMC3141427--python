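"""Transcript-to-locus classification.

Each transcript (EST) is decomposed into a colinear chain of CH-exon copy
matches, assigned to its genomic zone of origin through diagnostic
nucleotides (positions where homologous exon copies in different zones
differ), and classified into an isoform:

* ``IGM_SEC``      secreted IgM: Cmu1-Cmu4 plus the secretory tail.
* ``IGM_TM_SHORT`` the short membrane IgM: only Cmu1-Cmu2 spliced to
                   TM1/TM2 (the splice joins the end of Cmu2 to TM1).
* ``IGD_TM_CHIMERIC`` membrane IgD: Cmu1 spliced onto a Cdelta chain
                   (no Cdelta5) ending in TM1/TM2.
* ``STERILE``      no rearranged VH (often exon 0 spliced to Cmu1) and/or
                   stop codons in all reading frames.
* ``UNCLASSIFIED`` anything else, including transcripts with no match.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .exons import ExonAnnotation
from .segments import STOP_CODONS
from .seqio import Interval, NucSequence, extract

ISOFORM_CLASSES = ("IGM_SEC", "IGM_TM_SHORT", "IGD_TM_CHIMERIC", "STERILE", "UNCLASSIFIED")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")


@dataclass(frozen=True)
class ExonCopy:
    """One genomic copy of a labeled exon, in its reading orientation."""

    label: str
    zone_id: int | None
    seq: str
    interval: Interval


def build_exon_catalog(
    genomic: NucSequence, annotations: list[ExonAnnotation]
) -> list[ExonCopy]:
    """Extract strand-aware sequences for every exon annotation."""
    return [
        ExonCopy(a.label, a.zone_id, extract(genomic, a.interval), a.interval)
        for a in annotations
    ]


@dataclass(frozen=True)
class ChainLink:
    label: str
    zone_id: int | None
    identity: float
    est_start: int
    est_end: int


@dataclass
class TranscriptModel:
    est_id: str
    exon_chain: list[ChainLink] = field(default_factory=list)
    has_vh: bool = False
    uses_exon0: bool = False
    stops_all_frames: bool = False
    isoform: str = "UNCLASSIFIED"
    zone_vote: tuple[int | str, int] = ("ambiguous", 0)

    def chain_labels(self) -> list[str]:
        return [link.label for link in self.exon_chain]


# ----------------------------------------------------------------- chaining


def _ungapped_identity(a: str, b: str) -> float:
    x = np.frombuffer(a.encode(), np.uint8)
    y = np.frombuffer(b.encode(), np.uint8)
    n = min(len(x), len(y))
    if n == 0:
        return 0.0
    return float(((x[:n] == y[:n]) & (x[:n] != ord("N"))).mean())


def chain_exons(
    est: NucSequence,
    catalog: list[ExonCopy],
    *,
    min_identity: float = 0.90,
    k: int = 12,
    vh_min_prefix: int = 50,
    vh_min_orf: int = 150,
    vh_end_slack: int = 150,
) -> TranscriptModel:
    """Chain catalog exon copies onto the EST and test the prefix for VH.

    The chain is the highest-total-identity selection of non-overlapping
    copy matches, colinear in EST coordinates (weighted interval
    scheduling).  An unmatched prefix of >= ``vh_min_prefix`` nt before the
    first chained exon is declared a VH if it contains a stop-free open
    reading frame of >= ``vh_min_orf`` nt ending within ``vh_end_slack`` nt
    of the junction (rearranged VH exons do not match germline intervals,
    so an ORF test is used instead of alignment).
    """
    model = TranscriptModel(est_id=est.id)
    cands: list[tuple[int, int, float, ExonCopy]] = []
    # index the EST once
    est_index: dict[str, list[int]] = {}
    for i in range(len(est.residues) - k + 1):
        est_index.setdefault(est.residues[i : i + k], []).append(i)
    for copy in catalog:
        L = len(copy.seq)
        if L < k:
            continue
        votes: Counter[int] = Counter()
        for rpos in range(0, L - k + 1):
            for epos in est_index.get(copy.seq[rpos : rpos + k], ()):
                votes[epos - rpos] += 1
        for d in votes:
            if d < 0 or d + L > len(est.residues):
                continue
            ident = _ungapped_identity(est.residues[d : d + L], copy.seq)
            if ident >= min_identity:
                cands.append((d, d + L, ident, copy))
    if not cands:
        return model
    # weighted interval scheduling on EST coordinates, maximizing total identity
    cands.sort(key=lambda c: c[1])
    n = len(cands)
    best: list[float] = [0.0] * (n + 1)
    take: list[bool] = [False] * n
    prev_idx: list[int] = [0] * n
    ends = [c[1] for c in cands]
    import bisect

    for i, (s, e, ident, _copy) in enumerate(cands):
        j = bisect.bisect_right(ends, s, 0, i)
        prev_idx[i] = j
        if best[j] + ident > best[i]:
            best[i + 1] = best[j] + ident
            take[i] = True
        else:
            best[i + 1] = best[i]
    chain: list[tuple[int, int, float, ExonCopy]] = []
    i = n
    while i > 0:
        if take[i - 1] and best[i] != best[i - 1]:
            chain.append(cands[i - 1])
            i = prev_idx[i - 1]
        else:
            i -= 1
    chain.reverse()
    model.exon_chain = [
        ChainLink(c.label, c.zone_id, ident, s, e) for (s, e, ident, c) in chain
    ]
    model.uses_exon0 = any(link.label == "EX0" for link in model.exon_chain)
    prefix = est.residues[: model.exon_chain[0].est_start]
    if len(prefix) >= vh_min_prefix:
        model.has_vh = _prefix_has_orf(prefix, vh_min_orf, vh_end_slack)
    return model


def _prefix_has_orf(prefix: str, min_orf: int, end_slack: int) -> bool:
    """Any maximal stop-free codon run >= min_orf nt ending near the prefix end."""
    n = len(prefix)
    for frame in range(3):
        run_start = frame
        p = frame
        while p + 3 <= n + 3:
            codon = prefix[p : p + 3]
            if len(codon) < 3 or codon in STOP_CODONS:
                run_len = p - run_start
                if run_len >= min_orf and n - p <= end_slack:
                    return True
                run_start = p + 3
            p += 3
    return False


# ------------------------------------------------------------- zone voting


def assign_zone(
    model: TranscriptModel,
    est: NucSequence,
    catalog: list[ExonCopy],
) -> tuple[int | str, int]:
    """Vote the transcript's zone of origin from diagnostic nucleotides.

    For each chained exon the EST segment is compared with every zone's
    copy of that label (minimum mismatches when a zone holds several
    copies).  Zones missing a copy of any chained label are disqualified.
    The lowest-total-mismatch zone wins iff it beats the runner-up by at
    least one site; the margin is the diagnostic-site count.
    """
    links = model.exon_chain
    if not links:
        return ("ambiguous", 0)
    zones = sorted({c.zone_id for c in catalog if c.zone_id is not None})
    by_label: dict[str, dict[int, list[ExonCopy]]] = {}
    for c in catalog:
        if c.zone_id is not None:
            by_label.setdefault(c.label, {}).setdefault(c.zone_id, []).append(c)
    totals: dict[int, int] = {}
    for z in zones:
        total = 0
        ok = True
        for link in links:
            copies = by_label.get(link.label, {}).get(z)
            if not copies:
                ok = False
                break
            seg = est.residues[link.est_start : link.est_end]
            total += min(_mismatches(seg, c.seq) for c in copies)
        if ok:
            totals[z] = total
    if not totals:
        return ("ambiguous", 0)
    ranked = sorted(totals.items(), key=lambda kv: (kv[1], kv[0]))
    if len(ranked) == 1:
        return (ranked[0][0], 0)
    margin = ranked[1][1] - ranked[0][1]
    if margin < 1:
        return ("ambiguous", margin)
    return (ranked[0][0], margin)


def _mismatches(a: str, b: str) -> int:
    x = np.frombuffer(a.encode(), np.uint8)
    y = np.frombuffer(b.encode(), np.uint8)
    n = min(len(x), len(y))
    return int(((x[:n] != y[:n]) | (x[:n] == ord("N"))).sum()) + abs(len(x) - len(y))


# ------------------------------------------------------------ classification


def classify_isoform(model: TranscriptModel) -> str:
    """Apply the isoform rules in order; see module docstring."""
    if not model.exon_chain:
        return "UNCLASSIFIED"
    if not model.has_vh or model.stops_all_frames:
        return "STERILE"
    core = [l for l in model.chain_labels() if l != "EX0"]
    if core == ["Cmu1", "Cmu2", "TM1", "TM2"]:
        return "IGM_TM_SHORT"
    if core in (["Cmu1", "Cmu2", "Cmu3", "Cmu4"],
                ["Cmu1", "Cmu2", "Cmu3", "Cmu4", "SEC_TAIL"]):
        return "IGM_SEC"
    if (
        len(core) >= 4
        and core[0] == "Cmu1"
        and core[-2:] == ["TM1", "TM2"]
        and all(l.startswith("Cdelta") for l in core[1:-2])
        and len(core) > 4
    ):
        return "IGD_TM_CHIMERIC"
    return "UNCLASSIFIED"


def orf_stop_analysis(
    est: NucSequence, limit: int | None = None
) -> tuple[dict[int, list[int]], bool]:
    """Stop-codon positions per forward frame; all-frames flag up to ``limit``.

    ``limit`` is normally the start of the last chained exon; a frame
    "has a stop" when a stop codon starts before it.
    """
    seq = est.residues
    if limit is None:
        limit = len(seq)
    stops: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for frame in range(3):
        for p in range(frame, len(seq) - 2, 3):
            if seq[p : p + 3] in STOP_CODONS:
                stops[frame].append(p)
    all_frames = all(any(p < limit for p in stops[f]) for f in range(3))
    return stops, all_frames


def classify_transcript(
    est: NucSequence,
    catalog: list[ExonCopy],
    **chain_kwargs,
) -> TranscriptModel:
    """Full per-transcript analysis: chain, stop screen, zone vote, isoform."""
    model = chain_exons(est, catalog, **chain_kwargs)
    if model.exon_chain:
        limit = model.exon_chain[-1].est_start
        _, model.stops_all_frames = orf_stop_analysis(est, limit)
        model.zone_vote = assign_zone(model, est, catalog)
    model.isoform = classify_isoform(model)
    return model


# ------------------------------------------------------- protein features


@dataclass(frozen=True)
class ProteinFeatures:
    """Cysteine positions and N-glycosylation sequons (N-X-S/T, X != P)."""

    cys_positions: tuple[int, ...]
    nglyc_sites: tuple[int, ...]


def protein_features(aa_seq: str) -> ProteinFeatures:
    """Report cysteines and N-glycosylation motifs in an amino-acid sequence."""
    for pos, ch in enumerate(aa_seq):
        if ch not in AA_ALPHABET:
            raise ValueError(f"invalid amino acid {ch!r} at position {pos}")
    cys = tuple(i for i, ch in enumerate(aa_seq) if ch == "C")
    nglyc = tuple(
        i
        for i in range(len(aa_seq) - 2)
        if aa_seq[i] == "N" and aa_seq[i + 1] != "P" and aa_seq[i + 2] in ("S", "T")
    )
    return ProteinFeatures(cys, nglyc)


# --------------------------------------------------------- in-silico PCR


def predict_amplicon(
    template: NucSequence,
    fwd_primer: str,
    rev_primer: str,
    max_mm: int = 0,
) -> list[tuple[Interval, int]]:
    """Predict PCR products on a template.

    A product is any forward-primer site paired with a downstream
    reverse-primer site (the reverse primer matches the template's reverse
    complement, i.e. its reverse complement appears in the template), each
    within ``max_mm`` mismatches.  Product length runs from the forward
    primer's 5' end to the reverse primer's 5' end inclusive.
    """
    from .rss import hamming_scan
    from .seqio import revcomp

    fwd_sites = hamming_scan(template.residues, fwd_primer.upper(), max_mm)
    rev_sites = hamming_scan(template.residues, revcomp(rev_primer.upper()), max_mm)
    products = []
    for i, _ in fwd_sites:
        for j, _ in rev_sites:
            if j >= i:
                end = j + len(rev_primer)
                products.append((Interval(template.id, i, end, "+"), end - i))
    products.sort(key=lambda p: (p[0].start, p[0].end))
    return products
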