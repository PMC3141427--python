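"""End-to-end orchestration: annotate a germline locus, classify transcripts.

``annotate_locus`` chains RSS scanning, VH/D/JH calling, CH-exon mapping
and zone partitioning; ``classify_transcripts`` maps ESTs onto the
annotated exon catalog.  File-based wrappers (``run_annotate`` /
``run_classify``) read FASTA and write GFF3/TSV plus a JSON manifest of
every parameter actually used, so a run is reproducible from its outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .exons import (ExonAnnotation, Zone, map_ch_exons, partition_zones,
                    read_reference_exons)
from .rss import RssModel
from .segments import SegmentCall, call_d, call_jh, call_vh
from .seqio import (GffFeature, NucSequence, read_fasta, write_gff3)
from .transcripts import (ISOFORM_CLASSES, TranscriptModel, build_exon_catalog,
                          classify_transcript)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Paths, parameter overrides and outputs for one pipeline run."""

    genome: str
    ch_refs: str | None = None
    jh_refs: str | None = None
    ests: str | None = None
    outdir: str = "igloci_out"
    seed: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class AnnotationResult:
    genomic: NucSequence
    vh_calls: list[SegmentCall]
    d_calls: list[SegmentCall]
    jh_calls: list[SegmentCall]
    exon_annotations: list[ExonAnnotation]
    zones: list[Zone]

    @property
    def segment_calls(self) -> list[SegmentCall]:
        return self.vh_calls + self.d_calls + self.jh_calls


def annotate_locus(
    genomic: NucSequence,
    ch_refs,
    jh_refs: list[NucSequence],
    **params,
) -> AnnotationResult:
    """Run the full annotation stack on one germline sequence.

    ``params`` may override: vh_orf_min/vh_orf_max/vh_rss_gap_max,
    d_min/d_max, exon_min_identity, zone_gap_max, rss model tolerances
    (hept_mm, nona_mm, spacer_slack).
    """
    hept_mm = params.get("hept_mm", 1)
    nona_mm = params.get("nona_mm", 2)
    slack = params.get("spacer_slack", 1)
    model23 = RssModel(spacer_class=23, heptamer_max_mm=hept_mm,
                       nonamer_max_mm=nona_mm, spacer_slack=slack)
    model12 = RssModel(spacer_class=12, heptamer_max_mm=hept_mm,
                       nonamer_max_mm=nona_mm, spacer_slack=slack)
    try:
        vh = call_vh(
            genomic, model23,
            orf_min=params.get("vh_orf_min", 240),
            orf_max=params.get("vh_orf_max", 360),
            rss_gap_max=params.get("vh_rss_gap_max", 10),
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("segment_caller:call_vh", str(exc)) from exc
    try:
        d = call_d(genomic, model12,
                   d_min=params.get("d_min", 5), d_max=params.get("d_max", 40))
    except Exception as exc:  # pragma: no cover
        raise StageError("segment_caller:call_d", str(exc)) from exc
    try:
        jh = call_jh(genomic, jh_refs, model23) if jh_refs else []
    except Exception as exc:
        raise StageError("segment_caller:call_jh", str(exc)) from exc
    try:
        exons = map_ch_exons(
            genomic, ch_refs,
            min_identity=params.get("exon_min_identity", 0.70),
            snap_max=params.get("snap_max", 6),
        )
    except Exception as exc:  # pragma: no cover
        raise StageError("exon_mapper:map_ch_exons", str(exc)) from exc
    zones = partition_zones(
        vh + d + jh, exons, zone_gap_max=params.get("zone_gap_max", 15_000)
    )
    return AnnotationResult(genomic, vh, d, jh, exons, zones)


def classify_transcripts(
    ests: list[NucSequence],
    result: AnnotationResult,
    **params,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Classify each EST against the annotated exon catalog."""
    catalog = build_exon_catalog(result.genomic, result.exon_annotations)
    models = [
        classify_transcript(
            est, catalog,
            min_identity=params.get("est_exon_min_identity", 0.90),
        )
        for est in ests
    ]
    rows = [
        {
            "est_id": m.est_id,
            "isoform": m.isoform,
            "zone": m.zone_vote[0],
            "n_diagnostic_sites": m.zone_vote[1],
            "has_vh": m.has_vh,
            "uses_exon0": m.uses_exon0,
            "stops_all_frames": m.stops_all_frames,
            "chain": ",".join(m.chain_labels()),
        }
        for m in models
    ]
    return models, pd.DataFrame(rows)


def summarize_counts(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Zone-by-isoform contingency table; marginals conserve the EST count."""
    df = transcripts.copy()
    df["zone"] = df["zone"].astype(str)
    zone_cols = sorted(
        {z for z in df["zone"] if z not in ("ambiguous",)},
        key=lambda z: (not z.isdigit(), int(z) if z.isdigit() else 0, z),
    )
    table = pd.DataFrame(0, index=list(ISOFORM_CLASSES), columns=zone_cols + ["ambiguous"])
    for _, row in df.iterrows():
        table.loc[row["isoform"], row["zone"]] += 1
    assert int(table.to_numpy().sum()) == len(df), "count table must conserve ESTs"
    return table


# ------------------------------------------------------------ file wrappers


def _annotation_gff(result: AnnotationResult) -> list[GffFeature]:
    type_of = {"VH": "V_gene_segment", "D": "D_gene_segment", "JH": "J_gene_segment"}
    feats = []
    for c in result.segment_calls:
        attrs = {"label": c.label, "evidence": f"{c.evidence_score:g}"}
        if c.boundary_uncertain:
            attrs["boundary_uncertain"] = "true"
        feats.append(GffFeature(type_of[c.kind], c.exon, attrs))
    for a in result.exon_annotations:
        attrs = {"label": a.label, "identity": f"{a.identity:.4f}",
                 "splice_ok": str(a.splice_ok).lower()}
        if a.zone_id is not None:
            attrs["zone"] = str(a.zone_id)
        feats.append(GffFeature("exon", a.interval, attrs))
    for z in result.zones:
        feats.append(
            GffFeature("region", z.interval,
                       {"label": f"zone{z.zone_id}",
                        "functional": str(z.functional).lower()})
        )
    return feats


def zones_table(result: AnnotationResult) -> pd.DataFrame:
    rows = []
    for z in result.zones:
        in_zone = lambda c: z.interval.start <= c.exon.start < z.interval.end  # noqa: E731
        rows.append(
            {
                "zone_id": z.zone_id,
                "seq_id": z.interval.seq_id,
                "start": z.interval.start + 1,
                "end": z.interval.end,
                "n_d": sum(1 for c in result.d_calls if in_zone(c)),
                "n_jh": sum(1 for c in result.jh_calls if in_zone(c)),
                "exons": ",".join(z.labels()),
                "functional": z.functional,
            }
        )
    return pd.DataFrame(rows)


def _load_genome(path: str) -> NucSequence:
    seqs = read_fasta(path)
    if not seqs:
        raise StageError("seq_io", f"empty genome file: {path}")
    if len(seqs) > 1:
        raise StageError(
            "seq_io", "annotate expects a single genomic sequence per run"
        )
    return seqs[0]


def run_annotate(config: RunConfig) -> AnnotationResult:
    """File-level annotation: writes locus.gff3, zones.tsv and a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomic = _load_genome(config.genome)
    if not config.ch_refs:
        raise StageError("seq_io", "annotate requires CH reference exons (--refs)")
    ch_refs = read_reference_exons(config.ch_refs)
    jh_refs = read_fasta(config.jh_refs) if config.jh_refs else []
    result = annotate_locus(genomic, ch_refs, jh_refs, **config.params)
    write_gff3(_annotation_gff(result), outdir / "locus.gff3",
               {genomic.id: len(genomic)})
    zones_table(result).to_csv(outdir / "zones.tsv", sep="\t", index=False)
    _write_manifest(outdir, "annotate", config)
    return result


def run_classify(config: RunConfig, result: AnnotationResult | None = None) -> pd.DataFrame:
    """File-level classification: writes transcripts.tsv (and counts.tsv)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result is None:
        result = run_annotate(config)
    if not config.ests:
        raise StageError("seq_io", "classify requires an EST FASTA (--ests)")
    ests = read_fasta(config.ests)
    _, table = classify_transcripts(ests, result, **config.params)
    table.to_csv(outdir / "transcripts.tsv", sep="\t", index=False)
    summarize_counts(table).to_csv(outdir / "counts.tsv", sep="\t")
    _write_manifest(outdir, "classify", config)
    return table


def _write_manifest(outdir: Path, stage: str, config: RunConfig) -> None:
    manifest = {
        "igloci_version": __version__,
        "stage": stage,
        "genome": config.genome,
        "ch_refs": config.ch_refs,
        "jh_refs": config.jh_refs,
        "ests": config.ests,
        "seed": config.seed,
        "params": config.params,
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
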