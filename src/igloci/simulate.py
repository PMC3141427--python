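"""Synthetic IGH locus and transcript generation with planted truth.

The generator emulates the architecture of a duplicated teleost IGH locus:
several tandem "zones", each carrying a D cluster, a JH cluster, an
optional non-coding exon 0 (100 bp, stops in all three frames) 3' of the
JH cluster, the IgM exon battery (Cmu1-Cmu4 with a contiguous secretory
tail, then TM1/TM2), and an IgD battery (Cdelta1-4, 6, 7 by default - no
Cdelta5 - then TM1/TM2).  VH cassettes sit in arrays between zones.  Zones
are copies of one master sequence, diverged by per-base substitution, so
homologous copies carry zone-diagnostic nucleotides; one zone can be
"disorganized" (most cassettes dropped) and one inverted in place.

Transcripts are generated by VDJ joining (with junctional trimming and N
addition, rejection-sampled to be productive, i.e. in frame and stop-free)
followed by class-specific splicing, mirroring the four splicing patterns
seen in teleost IgM/IgD EST collections.

Every planted feature is recorded in a machine-readable truth set and
re-verified by direct string inspection before the locus is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exons import CDELTA_LABELS, CMU_LABELS, ReferenceExon, _zone_functional
from .rss import HEPTAMER_CONSENSUS, NONAMER_CONSENSUS
from .segments import STOP_CODONS, has_stop_in_frame
from .seqio import Interval, NucSequence, revcomp

BASES = np.array(list("ACGT"))

#: splice-blocking pad planted 5' of each VH acceptor: stop codons in all
#: three frames and no AG dinucleotide, so the planted acceptor is the only
#: viable ORF start for the exon
VH_STOP_PAD = "TTAATTAATTAA"

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

DEFAULT_CDELTA = ("Cdelta1", "Cdelta2", "Cdelta3", "Cdelta4", "Cdelta6", "Cdelta7")

DEFAULT_MIX = {
    "IGM_SEC": 0.40,
    "IGM_TM_SHORT": 0.25,
    "IGD_TM_CHIMERIC": 0.20,
    "STERILE": 0.15,
}


@dataclass(frozen=True)
class ZoneSpec:
    n_d: int = 7
    n_jh: int = 7
    cdelta_labels: tuple[str, ...] = DEFAULT_CDELTA
    include_exon0: bool = True
    inverted: bool = False
    disorganized: bool = False


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated locus; the seed is mandatory."""

    seed: int
    n_zones: int = 5
    zones: tuple[ZoneSpec, ...] | None = None
    n_vh_between_zones: int = 10
    zone_divergence: float = 0.02  # expected pairwise divergence between zone copies
    motif_mutation_rate: float = 0.0
    background_gc: float = 0.45
    intergenic_len: tuple[int, int] = (60, 150)
    ch_exon_len: int = 300
    vh_exon_len: int = 294
    jh_len: int = 48
    d_len: int = 16
    tm1_len: int = 150
    tm2_len: int = 99
    sec_tail_len: int = 60
    block_gap: int = 800  # gap between the IgM and IgD exon batteries

    def __post_init__(self) -> None:
        for rate in (self.zone_divergence, self.motif_mutation_rate, self.background_gc):
            if not (0 <= rate <= 1):
                raise ValueError("rates must be in [0, 1]")
        if self.n_zones < 1 or self.n_vh_between_zones < 0:
            raise ValueError("counts must be positive")
        lo, hi = self.intergenic_len
        if lo < 10 or hi < lo:
            raise ValueError("intergenic_len range too small for cassette assembly")

    def zone_specs(self) -> tuple[ZoneSpec, ...]:
        if self.zones is not None:
            if len(self.zones) != self.n_zones:
                raise ValueError("len(zones) must equal n_zones")
            return self.zones
        return tuple(ZoneSpec() for _ in range(self.n_zones))

    @classmethod
    def paper_layout(cls, seed: int, **overrides) -> "SimConfig":
        """The five-zone layout used throughout: exon 0 in zones 1-3 only,
        zone 3 disorganized, zone 5 inverted."""
        zones = (
            ZoneSpec(include_exon0=True),
            ZoneSpec(include_exon0=True),
            ZoneSpec(include_exon0=True, disorganized=True),
            ZoneSpec(include_exon0=False),
            ZoneSpec(include_exon0=False, inverted=True),
        )
        return cls(seed=seed, n_zones=5, zones=zones, **overrides)


@dataclass(frozen=True)
class TruthFeature:
    """One planted feature in locus coordinates (0-based half-open, forward)."""

    kind: str  # VH | D | JH | exon | zone
    label: str
    start: int
    end: int
    strand: str = "+"
    zone_id: int | None = None
    gene: str | None = None  # mu | delta for TM disambiguation


@dataclass(frozen=True)
class TruthZone:
    zone_id: int
    start: int
    end: int
    inverted: bool
    disorganized: bool
    functional: bool
    has_exon0: bool


@dataclass
class TruthSet:
    """A simulated locus plus machine-readable planted truth."""

    locus: NucSequence
    features: list[TruthFeature]
    zones: list[TruthZone]
    config: SimConfig
    masters: dict[str, str]  # exon label -> master sequence (incl. Cdelta5)
    vh_masters: list[str]
    jh_masters: list[str]
    d_masters: list[str]

    def reference_exons(self, species_tag: str = "synthetic") -> list[ReferenceExon]:
        """Labeled reference exons (master sequences), including Cdelta5 so
        its absence from the locus is observable."""
        refs = []
        for key, seq in sorted(self.masters.items()):
            if key.startswith("TM"):
                label, gene = key.split("_")
                refs.append(ReferenceExon(label, f"{species_tag}_{gene}", seq))
            else:
                refs.append(ReferenceExon(key, species_tag, seq))
        return refs

    def jh_refs(self) -> list[NucSequence]:
        return [NucSequence(f"JHref{i + 1}", s) for i, s in enumerate(self.jh_masters)]

    def features_of(self, kind: str, zone_id: int | None = None) -> list[TruthFeature]:
        return [
            f
            for f in self.features
            if f.kind == kind and (zone_id is None or f.zone_id == zone_id)
        ]

    def feature_seq(self, f: TruthFeature) -> str:
        sub = self.locus.residues[f.start : f.end]
        return revcomp(sub) if f.strand == "-" else sub

    def zone_exon_seq(self, zone_id: int, label: str, gene: str | None = None) -> str:
        for f in self.features:
            if (
                f.kind == "exon"
                and f.zone_id == zone_id
                and f.label == label
                and (gene is None or f.gene == gene)
            ):
                return self.feature_seq(f)
        raise KeyError(f"zone {zone_id} has no {label} ({gene})")


# ---------------------------------------------------------------- primitives


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """A stop-free (frame 0) coding sequence; length must be a multiple of 3."""
    assert length % 3 == 0
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=length // 3)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def _make_exon0(rng: np.random.Generator, gc: float) -> tuple[str, set[int]]:
    """100 bp with a planted stop codon in each frame; returns protected positions."""
    s = list(_random_seq(rng, 100, gc))
    protected = set()
    for pos in (12, 25, 41):  # frames 0, 1, 2
        s[pos : pos + 3] = "TAA"
        protected.update(range(pos, pos + 3))
    return "".join(s), protected


@dataclass
class _Part:
    """One assembly unit of the master zone with part-relative bookkeeping."""

    seq: str
    tag: str  # spacer | D | JH | EX0 | exon:<label>
    features: list[TruthFeature] = field(default_factory=list)  # part-relative
    protected: set[int] = field(default_factory=set)
    coding: tuple[int, int] | None = None  # frame-anchored stop-free region


def _rss_down(spacer: str) -> str:
    """RSS 3' of a forward coding segment: heptamer-spacer-nonamer."""
    return HEPTAMER_CONSENSUS + spacer + NONAMER_CONSENSUS


def _rss_up(spacer: str) -> str:
    """RSS 5' of a forward coding segment (reverse-complement spelling)."""
    return revcomp(NONAMER_CONSENSUS) + spacer + revcomp(HEPTAMER_CONSENSUS)


def _protect(n0: int, *spans: tuple[int, int]) -> set[int]:
    out = set()
    for s, e in spans:
        out.update(range(n0 + s, n0 + e))
    return out


class _MasterBuilder:
    """Builds the master-zone part list; spacers are shared across zones."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.gc = cfg.background_gc

    def spacer(self, lo: int | None = None, hi: int | None = None) -> _Part:
        lo = lo if lo is not None else self.cfg.intergenic_len[0]
        hi = hi if hi is not None else self.cfg.intergenic_len[1]
        return _Part(_random_seq(self.rng, int(self.rng.integers(lo, hi + 1)), self.gc), "spacer")

    def d_cassette(self, seq: str, label: str) -> _Part:
        sp5 = _random_seq(self.rng, 12, self.gc)
        sp3 = _random_seq(self.rng, 12, self.gc)
        up = _rss_up(sp5)
        down = _rss_down(sp3)
        full = up + seq + down
        d0 = len(up)
        prot = _protect(0, (0, 9), (len(up) - 7, len(up)))
        prot |= _protect(d0 + len(seq), (0, 7), (7 + 12, 7 + 12 + 9))
        return _Part(
            full,
            "D",
            [TruthFeature("D", label, d0, d0 + len(seq))],
            prot,
        )

    def jh_cassette(self, seq: str, label: str) -> _Part:
        sp = _random_seq(self.rng, 23, self.gc)
        up = _rss_up(sp)
        full = up + seq + "GTA"
        j0 = len(up)
        prot = _protect(0, (0, 9), (len(up) - 7, len(up)))
        prot |= _protect(j0 + len(seq), (0, 3))  # the GTA end anchor
        return _Part(full, "JH", [TruthFeature("JH", label, j0, j0 + len(seq))], prot)

    def exon_cassette(
        self, seq: str, label: str, gene: str | None, *, acceptor: bool = True,
        donor: bool = True, coding: bool = True, extra_protected: set[int] | None = None,
    ) -> _Part:
        pre = "AG" if acceptor else ""
        post = "GT" if donor else ""
        full = pre + seq + post
        e0 = len(pre)
        prot = set()
        if acceptor:
            prot |= {0, 1}
        if donor:
            prot |= {len(full) - 2, len(full) - 1}
        if extra_protected:
            prot |= {e0 + p for p in extra_protected}
        return _Part(
            full,
            f"exon:{label}",
            [TruthFeature("exon", label, e0, e0 + len(seq), gene=gene)],
            prot,
            coding=(e0, e0 + len(seq)) if coding else None,
        )


def _build_master_parts(cfg: SimConfig, rng: np.random.Generator, masters, jh_masters, d_masters):
    b = _MasterBuilder(cfg, rng)
    parts: list[_Part] = []

    def add(part: _Part) -> None:
        parts.append(part)

    for i, d in enumerate(d_masters):
        add(b.spacer())
        add(b.d_cassette(d, f"D{i + 1}"))
    for i, j in enumerate(jh_masters):
        add(b.spacer())
        add(b.jh_cassette(j, f"JH{i + 1}"))
    ex0_seq, ex0_prot = _make_exon0(rng, cfg.background_gc)
    add(b.spacer())
    add(b.exon_cassette(ex0_seq, "EX0", None, coding=False, extra_protected=ex0_prot))
    for label in CMU_LABELS[:3]:
        add(b.spacer())
        add(b.exon_cassette(masters[label], label, "mu"))
    # Cmu4 and the secretory tail are genomically contiguous (one composite
    # cassette: AG + Cmu4 + SEC_TAIL + GT)
    add(b.spacer())
    cmu4 = b.exon_cassette(masters["Cmu4"], "Cmu4", "mu", donor=False)
    tail_rel = len(cmu4.seq)
    cmu4.seq += masters["SEC_TAIL"] + "GT"
    cmu4.features.append(
        TruthFeature("exon", "SEC_TAIL", tail_rel, tail_rel + cfg.sec_tail_len, gene="mu")
    )
    cmu4.protected |= {len(cmu4.seq) - 2, len(cmu4.seq) - 1}
    add(cmu4)
    for label in ("TM1", "TM2"):
        add(b.spacer())
        add(b.exon_cassette(masters[f"{label}_mu"], label, "mu"))
    add(b.spacer(cfg.block_gap, cfg.block_gap + 50))
    for label in DEFAULT_CDELTA:
        add(b.spacer())
        add(b.exon_cassette(masters[label], label, "delta"))
    for label in ("TM1", "TM2"):
        add(b.spacer())
        add(b.exon_cassette(masters[f"{label}_delta"], label, "delta"))
    add(b.spacer())
    return parts


def _mutate_copy(
    seq: list[str],
    protected: set[int],
    coding: list[tuple[int, int]],
    rate: float,
    motif_rate: float,
    rng: np.random.Generator,
) -> None:
    """Per-base substitution avoiding motif positions and coding-frame stops.

    Motif/splice/anchor positions mutate at ``motif_rate`` (default 0);
    mutations that would write a stop codon into an exon's coding frame are
    redirected to a safe base (purifying selection on functional copies).
    """
    n = len(seq)
    if rate <= 0 and motif_rate <= 0:
        return
    coding_of: dict[int, int] = {}
    for s, e in coding:
        for p in range(s, e):
            coding_of[p] = s
    draws = rng.random(n)
    for pos in np.nonzero(draws < max(rate, motif_rate))[0]:
        pos = int(pos)
        is_motif = pos in protected
        threshold = motif_rate if is_motif else rate
        if draws[pos] >= threshold:
            continue
        choices = [b for b in "ACGT" if b != seq[pos]]
        rng.shuffle(choices)
        anchor = coding_of.get(pos)
        for base in choices:
            if anchor is not None:
                c0 = anchor + 3 * ((pos - anchor) // 3)
                codon = seq[c0] + seq[c0 + 1] + seq[c0 + 2]
                codon = codon[: pos - c0] + base + codon[pos - c0 + 1 :]
                if codon in STOP_CODONS:
                    continue
            seq[pos] = base
            break


def _assemble_zone(
    parts: list[_Part],
    spec: ZoneSpec,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, list[TruthFeature]]:
    """Select parts for one zone, diverge the copy, and orient it."""
    selected: list[_Part] = []
    forced_drop = {"exon:Cmu3", "exon:Cdelta1"} if spec.disorganized else set()
    d_kept = j_kept = 0
    for part in parts:
        if part.tag == "spacer":
            selected.append(part)
            continue
        if part.tag == "D":
            if d_kept >= spec.n_d or (spec.disorganized and rng.random() < 0.7):
                continue
            d_kept += 1
        elif part.tag == "JH":
            if j_kept >= spec.n_jh or (spec.disorganized and rng.random() < 0.7):
                continue
            j_kept += 1
        elif part.tag.startswith("exon:"):
            label = part.tag.split(":", 1)[1]
            if label == "EX0" and not spec.include_exon0:
                continue
            if label in CDELTA_LABELS and label not in spec.cdelta_labels:
                continue
            if part.tag in forced_drop:
                continue
            if spec.disorganized and part.tag != "exon:Cmu1" and rng.random() < 0.7:
                continue
        selected.append(part)

    chars: list[str] = []
    feats: list[TruthFeature] = []
    protected: set[int] = set()
    coding: list[tuple[int, int]] = []
    offset = 0
    for part in selected:
        chars.extend(part.seq)
        for f in part.features:
            feats.append(replace(f, start=f.start + offset, end=f.end + offset))
        protected |= {p + offset for p in part.protected}
        if part.coding is not None:
            coding.append((part.coding[0] + offset, part.coding[1] + offset))
        offset += len(part.seq)

    # per-copy substitution at half the pairwise divergence
    _mutate_copy(chars, protected, coding, cfg.zone_divergence / 2,
                 cfg.motif_mutation_rate, rng)
    zone_seq = "".join(chars)
    if spec.inverted:
        n = len(zone_seq)
        zone_seq = revcomp(zone_seq)
        feats = [
            replace(f, start=n - f.end, end=n - f.start, strand="-") for f in feats
        ]
        feats.sort(key=lambda f: f.start)
    return zone_seq, feats


def _vh_cassette(cfg: SimConfig, rng: np.random.Generator, vh_seq: str) -> tuple[str, int]:
    """Leader context + AG + VH exon + 23-spacer RSS; returns (seq, exon offset)."""
    lead = _random_seq(rng, int(rng.integers(*cfg.intergenic_len)), cfg.background_gc)
    sp = _random_seq(rng, 23, cfg.background_gc)
    prefix = lead + VH_STOP_PAD + "AG"
    seq = prefix + vh_seq + _rss_down(sp)
    return seq, len(prefix)


# -------------------------------------------------------------- simulation


def simulate_locus(config: SimConfig) -> TruthSet:
    """Generate a locus and its planted truth; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    specs = config.zone_specs()

    masters: dict[str, str] = {}
    for label in CMU_LABELS + CDELTA_LABELS:
        masters[label] = _random_orf(rng, config.ch_exon_len)
    masters["SEC_TAIL"] = _random_orf(rng, config.sec_tail_len)
    for gene in ("mu", "delta"):
        masters[f"TM1_{gene}"] = _random_orf(rng, config.tm1_len)
        masters[f"TM2_{gene}"] = _random_orf(rng, config.tm2_len)
    max_d = max(s.n_d for s in specs)
    max_jh = max(s.n_jh for s in specs)
    d_masters = [_random_seq(rng, config.d_len, config.background_gc) for _ in range(max_d)]
    jh_masters = [_random_orf(rng, config.jh_len) for _ in range(max_jh)]
    n_v_total = config.n_vh_between_zones * max(0, config.n_zones - 1)
    vh_masters = [_random_orf(rng, config.vh_exon_len) for _ in range(n_v_total)]

    parts = _build_master_parts(config, rng, masters, jh_masters, d_masters)
    # the shared EX0 copy in the master parts is the locus EX0 master
    for part in parts:
        if part.tag == "exon:EX0":
            masters["EX0"] = part.seq[2:-2]

    chars: list[str] = []
    features: list[TruthFeature] = []
    zones: list[TruthZone] = []
    vh_iter = iter(vh_masters)

    def append(seq: str) -> int:
        start = len(chars)
        chars.extend(seq)
        return start

    append(_random_seq(rng, 200, config.background_gc))
    for zi, spec in enumerate(specs, start=1):
        zone_seq, zone_feats = _assemble_zone(parts, spec, config, rng)
        z0 = append(zone_seq)
        feats = [replace(f, start=f.start + z0, end=f.end + z0, zone_id=zi)
                 for f in zone_feats]
        features.extend(feats)
        labels = [f.label for f in feats if f.kind == "exon" and f.label != "EX0"]
        zones.append(
            TruthZone(
                zone_id=zi,
                start=z0,
                end=z0 + len(zone_seq),
                inverted=spec.inverted,
                disorganized=spec.disorganized,
                functional=_zone_functional(labels),
                has_exon0=any(f.label == "EX0" for f in feats),
            )
        )
        if zi < len(specs):
            for _ in range(config.n_vh_between_zones):
                vh_seq = next(vh_iter)
                cassette, e0 = _vh_cassette(config, rng, vh_seq)
                c0 = append(cassette)
                features.append(
                    TruthFeature("VH", f"VH{c0}", c0 + e0, c0 + e0 + len(vh_seq))
                )
    append(_random_seq(rng, 200, config.background_gc))

    locus = NucSequence("synthetic_igh_locus", "".join(chars))
    features.sort(key=lambda f: f.start)
    truth = TruthSet(
        locus=locus,
        features=features,
        zones=zones,
        config=config,
        masters=masters,
        vh_masters=vh_masters,
        jh_masters=jh_masters,
        d_masters=d_masters,
    )
    if config.motif_mutation_rate == 0:
        _verify_truth(truth)
    return truth


def _verify_truth(truth: TruthSet) -> None:
    """Planted-motif invariants re-checked by direct string inspection."""
    seq = truth.locus.residues
    for f in truth.features:
        assert 0 <= f.start < f.end <= len(seq), "feature out of bounds"
        if f.kind == "VH":
            assert seq[f.start - 2 : f.start] == "AG"
            assert seq[f.end : f.end + 7] == HEPTAMER_CONSENSUS
            assert seq[f.end + 7 + 23 : f.end + 7 + 23 + 9] == NONAMER_CONSENSUS
            assert not has_stop_in_frame(seq, f.start, f.end)
        elif f.kind == "JH":
            s = truth.feature_seq(f)
            ctx = seq if f.strand == "+" else revcomp(seq)
            start = f.start if f.strand == "+" else len(seq) - f.end
            assert ctx[start + len(s) : start + len(s) + 3] == "GTA"
            assert ctx[start - 7 : start] == revcomp(HEPTAMER_CONSENSUS)
        elif f.kind == "exon" and f.label == "EX0":
            assert f.end - f.start == 100, "exon 0 must be 100 bp"
            s = truth.feature_seq(f)
            for frame in range(3):
                assert any(
                    s[p : p + 3] in STOP_CODONS for p in range(frame, 98, 3)
                ), "exon 0 must carry a stop in every frame"


# ----------------------------------------------------------- transcripts


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for pos in np.nonzero(rng.random(len(chars)) < rate)[0]:
        choices = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


def _productive_vdj(
    truth: TruthSet, zone_id: int, rng: np.random.Generator
) -> str:
    """VDJ join with 0-5 nt trims and 0-8 nt N additions per junction,
    rejection-sampled until in frame and stop-free (productive selection)."""
    v = truth.vh_masters[int(rng.integers(0, len(truth.vh_masters)))]
    d_feats = truth.features_of("D", zone_id)
    j_feats = truth.features_of("JH", zone_id)
    d = truth.feature_seq(d_feats[int(rng.integers(0, len(d_feats)))])
    j = truth.feature_seq(j_feats[int(rng.integers(0, len(j_feats)))])
    for _ in range(500):
        t_v, t_d5, t_d3, t_j = (int(x) for x in rng.integers(0, 6, size=4))
        n1, n2 = (int(x) for x in rng.integers(0, 9, size=2))
        mid = d[t_d5 : len(d) - t_d3]
        prefix = (
            v[: len(v) - t_v]
            + _random_seq(rng, n1, 0.5)
            + mid
            + _random_seq(rng, n2, 0.5)
            + j[t_j:]
        )
        if len(prefix) % 3 == 0 and not has_stop_in_frame(prefix, 0, len(prefix)):
            return prefix
    raise RuntimeError("could not sample a productive VDJ junction")


def _splice(truth: TruthSet, zone_id: int, chain: list[tuple[str, str | None]]) -> str:
    return "".join(truth.zone_exon_seq(zone_id, label, gene) for label, gene in chain)


_IGM_SEC_CHAIN = [("Cmu1", "mu"), ("Cmu2", "mu"), ("Cmu3", "mu"),
                  ("Cmu4", "mu"), ("SEC_TAIL", "mu")]
_IGM_TM_CHAIN = [("Cmu1", "mu"), ("Cmu2", "mu"), ("TM1", "mu"), ("TM2", "mu")]


def _igd_chain(truth: TruthSet, zone_id: int) -> list[tuple[str, str | None]]:
    present = {
        f.label
        for f in truth.features
        if f.kind == "exon" and f.zone_id == zone_id and f.gene == "delta"
    }
    deltas = [l for l in CDELTA_LABELS if l in present]
    return [("Cmu1", "mu")] + [(l, "delta") for l in deltas] + [
        ("TM1", "delta"), ("TM2", "delta")
    ]


def simulate_transcripts(
    truth: TruthSet,
    mix: dict[str, float] | None = None,
    n: int = 500,
    error_rate: float = 0.0,
    seed: int = 0,
    exon0_sterile_fraction: float = 0.7,
) -> tuple[list[NucSequence], pd.DataFrame]:
    """Draw transcripts from the functional zones with planted class labels.

    Returns the transcript sequences and a label table (est_id, isoform,
    zone_id, has_vh, uses_exon0).
    """
    mix = dict(mix or DEFAULT_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("isoform proportions must sum to 1")
    rng = np.random.default_rng(seed)
    functional = [z.zone_id for z in truth.zones if z.functional]
    if not functional:
        raise ValueError("no functional zones to transcribe from")
    exon0_zones = [
        z.zone_id for z in truth.zones if z.functional and z.has_exon0
    ]
    classes = list(mix)
    probs = np.array([mix[c] for c in classes])
    ests: list[NucSequence] = []
    rows: list[dict] = []
    for i in range(n):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        uses_exon0 = False
        if cls == "STERILE" and exon0_zones and rng.random() < exon0_sterile_fraction:
            uses_exon0 = True
            zone = exon0_zones[int(rng.integers(0, len(exon0_zones)))]
        else:
            zone = functional[int(rng.integers(0, len(functional)))]
        if cls == "IGM_SEC":
            seq = _productive_vdj(truth, zone, rng) + _splice(truth, zone, _IGM_SEC_CHAIN)
        elif cls == "IGM_TM_SHORT":
            seq = _productive_vdj(truth, zone, rng) + _splice(truth, zone, _IGM_TM_CHAIN)
        elif cls == "IGD_TM_CHIMERIC":
            seq = _productive_vdj(truth, zone, rng) + _splice(
                truth, zone, _igd_chain(truth, zone)
            )
        elif cls == "STERILE":
            body = _splice(truth, zone, _IGM_SEC_CHAIN)
            seq = (truth.zone_exon_seq(zone, "EX0") + body) if uses_exon0 else body
        else:
            raise ValueError(f"unknown isoform class {cls!r}")
        seq = _apply_errors(seq, error_rate, rng)
        est_id = f"EST{i + 1:05d}"
        ests.append(NucSequence(est_id, seq))
        rows.append(
            {
                "est_id": est_id,
                "isoform": cls,
                "zone_id": zone,
                "has_vh": cls != "STERILE",
                "uses_exon0": uses_exon0,
            }
        )
    return ests, pd.DataFrame(rows)


def truth_gff_features(truth: TruthSet):
    """Truth features as GFF rows (for `igloci simulate` output)."""
    from .seqio import GffFeature

    type_of = {"VH": "V_gene_segment", "D": "D_gene_segment", "JH": "J_gene_segment",
               "exon": "exon"}
    rows = []
    for f in truth.features:
        attrs = {"label": f.label}
        if f.zone_id is not None:
            attrs["zone"] = str(f.zone_id)
        if f.gene:
            attrs["gene"] = f.gene
        rows.append(
            GffFeature(
                type_of[f.kind],
                Interval(truth.locus.id, f.start, f.end, f.strand),
                attrs,
            )
        )
    for z in truth.zones:
        rows.append(
            GffFeature(
                "region",
                Interval(truth.locus.id, z.start, z.end),
                {
                    "label": f"zone{z.zone_id}",
                    "functional": str(z.functional).lower(),
                },
            )
        )
    return rows
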