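# Methods

This note documents the models, rules and numerical choices behind
`igloci`, what the synthetic data does and does not emulate, and the known
limitations.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open on the forward strand;
minus-strand features keep forward coordinates and are reverse-complemented
on extraction. GFF3 output is 1-based inclusive. Input sequences are
normalized to uppercase {A,C,G,T,N} (U→T); any other character is a hard
error rather than being silently skipped. `N` never matches anything in any
identity or mismatch computation, on either side of a comparison — a
conservative choice for gap-ridden assemblies, where runs of N should not
manufacture homology.

## RSS model

A recombination signal sequence is modelled as consensus heptamer
(`CACAGTG`), a spacer of class 12 or 23 bp, and consensus nonamer
(`TATTATTGT`), with independent Hamming-mismatch caps per element
(defaults: heptamer ≤ 1, nonamer ≤ 2 — the heptamer is the
better-conserved element; the nonamer tolerance of up to two mismatches is
the standard permissive setting for teleost loci). The spacer is allowed a
symmetric slack of ±1 bp by default (0 gives the strict fixed-spacer
reading; spacers do drift by a base in real loci). Scanning is exhaustive
over positions, spacer lengths and strands; overlapping hits are all
reported and tie-breaking is left to callers. A motif match spelled
heptamer→nonamer on the forward strand is an RSS downstream of a
forward-strand coding segment; the reverse-complement spelling is an RSS
upstream of one. No position-weight-matrix or information-content scoring
is attempted: the consensus+Hamming model is the method being implemented.

## Segment calling

**VH.** A call requires (i) an open reading frame of 240–360 nt with no
stop codon in the frame anchored at the exon start (typical teleost VH
exons are ~300 nt; both bounds configurable), (ii) the dinucleotide `AG`
immediately 5' of the exon (the leader-intron splice acceptor), and
(iii) a 23-spacer RSS whose heptamer begins within 0–10 nt of the exon 3'
end. Detection of the full leader exon is not required: the acceptor-only
reading keeps the rule assembly-friendly and is the weakest commitment
consistent with the splice-site criterion. Overlapping candidates are
resolved by lowest total RSS mismatches, then leftmost start, then longest
ORF.

**D.** A D segment is an interval of 5–40 nt flanked by an upstream and a
downstream 12-spacer RSS (the 12/23 rule pairs 12-RSS D flanks with the
23-RSS V and J partners). The flanking architecture is exactly
strand-symmetric — the reverse complement of 5'RSS+D+3'RSS is again a
valid 5'RSS+D'+3'RSS — so a D segment's orientation is undecidable from
its RSSs alone and calls are reported on the forward strand by convention
(biologically, D segments can in fact recombine in either orientation).

**JH.** Candidates are diagonal runs of windowed homology (window 30 nt,
identity ≥ 60%) against user-supplied reference JH sequences. The 5'
boundary is placed immediately after the heptamer of the nearest upstream
RSS within 60 nt; the 3' boundary immediately before the first `GTA` at or
after the run end (≤ 30 nt away), the GT being the splice donor. The 5'
RSS anchor is required — it is constitutive of what a JH segment is — but
a missing `GTA` only sets `boundary_uncertain`. Two guards handle the
permissiveness of the 60% threshold on genome-scale input: homology runs
shorter than 36 nt are ignored (a single chance window is 30 nt), and
anchored candidates longer than 80 nt are rejected (JH exons are short).

**Self-audit.** Every caller re-verifies each emitted call by direct
string inspection (acceptor/`GTA` anchors present, ORFs stop-free, RSS
mismatch counts recomputed against the consensus) and raises on any
discrepancy. Calling is deterministic: identical input and parameters give
byte-identical GFF3.

## Dot plots and duplication detection

A cell (i, j) is lit when windows a[i:i+w) and b[j:j+w) share at least
⌈w·t⌉ matching bases — the integer threshold removes float-comparison
ambiguity (18/30 at 60%; 26/30 at 85%). The match set is exhaustive; two
exact strategies are chosen by shape (per-window vectorized comparison
when one sequence is short, per-diagonal cumulative window sums
otherwise). Lit cells on one diagonal are merged into runs; `max_gap`
defaults to 0 (strictly contiguous) and is configurable. Duplication
detection fixes window 30 / 85%, excludes the trivial main diagonal in
self-comparisons, and also scans against the reverse complement so
inverted duplications are reported with `orientation="reverse"`. Gapped
alignment is deliberately out of scope: the diagonal-run model is the
analysis being reproduced.

## CH exon mapping and orthology naming

Genomic copies of each labeled reference exon are found by exact-12-mer
diagonal seeding (≥ 2 seeds on one diagonal) followed by full-length
ungapped identity against the reference, accepted at ≥ 70% — below the
~98% identity of recently duplicated copies, above random. The k-mer
seeding is effectively lossless above ~90% identity and fades below ~80%;
for diverged single-copy exons the threshold, not the seeding, is the
operative limit. Boundaries snap to the nearest `AG` (5') / `GT` (3')
within 6 nt when present; `splice_ok` records whether both signals were
found (the secretory tail legitimately lacks a 5' acceptor — it is
genomically contiguous with Cμ4). Multiple copies of one label are all
reported.

Orthology naming aligns an exon against every reference (global
Needleman–Wunsch, match +1 / mismatch −1 / gap −2 — simple fixed scores
keep results reproducible) and returns the best label plus the score
margin to the best competing label; an exact tie returns "ambiguous".
Naming is invariant to reference order.

## Zones

Zone boundaries open at every VH call and at gaps > 15 kb between
consecutive non-VH annotations (intra-zone IgM→IgD distances are a few
kb; inter-feature gaps beyond 15 kb indicate a new region). Each maximal
VH-free run containing at least one CH exon is a zone. The `functional`
flag is a documented heuristic: a zone is functional if it carries a
complete Cμ1–Cμ4 set or a complete Cδ chain (Cδ1 present, ≥ 4 distinct Cδ
exons, TM1+TM2). Zones are reported per input sequence and never merged
across sequences — cross-scaffold integration is an assembly question the
package does not decide.

## Transcript classification

Exon-copy matches on an EST are found by exact-12-mer seeding and ungapped
identity ≥ 0.90 (transcripts are same-species copies of genomic exons;
at this threshold the chaining tolerates a few percent of sequencing
error). The chain is the maximum-total-identity colinear selection
(weighted interval scheduling). A ≥ 50-nt unmatched prefix before the
first chained exon is tested for VH content with an ORF rule — any
stop-free frame run of ≥ 150 nt ending within 150 nt of the junction —
because rearranged VH exons do not match germline intervals; exon-0
content is recognized by ordinary chaining of the EX0 copy.

Zone assignment counts mismatches between each chained EST segment and
every zone's copy of that exon (minimum over copies when a zone holds
several); zones missing any chained label are disqualified; the
lowest-total zone wins iff it beats the runner-up by at least one
diagnostic site, and the margin is reported. Votes aggregate over all
chained exons rather than Cμ1 alone — more sites, same principle.

Isoform rules are applied in order: (1) STERILE if the transcript has no
VH or has a stop codon in all three frames before the last chained exon's
start; (2) IGM_TM_SHORT for the chain Cμ1–Cμ2–TM1–TM2; (3) IGM_SEC for
Cμ1–Cμ4 (± secretory tail) with no TM exon; (4) IGD_TM_CHIMERIC for Cμ1
followed by ≥ 1 Cδ exon and ending TM1–TM2, with no Cδ5 required and
repeated Cδ labels tolerated; (5) UNCLASSIFIED otherwise. Stop-codon
screening covers the forward frames only (ESTs are oriented). Protein
feature reporting uses the standard genetic code; glycosylation sequons
are N-X-S/T with X ≠ P.

In-silico PCR reports every forward-primer site paired with every
downstream reverse-primer site (reverse primer matched against the
template's reverse complement), each within the mismatch cap (default 0);
product length runs from forward 5' end to reverse 5' end inclusive.

## Synthetic data: what it emulates, and what it does not

The default layout mirrors the target architecture: five tandem zones,
each organized zone with 7 D and 7 JH cassettes, exon 0 (100 bp with a
planted stop codon in every frame) 3' of the JH cluster in zones 1–3
only, the IgM battery (Cμ1–Cμ4, contiguous secretory tail, TM1/TM2) and
the IgD battery (Cδ1–Cδ4, Cδ6, Cδ7, TM1/TM2 — no Cδ5, though a Cδ5
*reference* exists so its genomic absence is observable), ten VH
cassettes between consecutive zones, zone 3 disorganized (each cassette
dropped with probability 0.7, Cμ1 always kept, one Cμ and Cδ1 forcibly
dropped so the zone cannot satisfy the functional heuristic), and zone 5
inverted in place. Exon sequences are generated stop-free random ORFs
(~300 nt for CH domains) rather than real sequences, so tests need no
downloads; real references can be supplied to every public function.

Zones are copies of one master sequence with i.i.d. substitutions;
`zone_divergence` is the expected *pairwise* divergence between copies
(each copy mutates at half that rate from the master), so the default
0.02 yields ~98% inter-zone identity, matching the "recent duplication"
regime the method targets. Two biological filters shape the mutations:
motif positions (RSS elements, splice dinucleotides, the JH `GTA`, exon-0
stops) are only mutated at the separate `motif_mutation_rate` (default 0),
and substitutions that would write a stop codon into an exon's coding
frame are redirected — purifying selection on functional copies. Each VH
cassette carries a 12-nt pad (`TTAATTAATTAA`: stop codons in all frames,
no AG) directly 5' of its acceptor, the sequence-level signature of a
leader-intron end that makes the planted acceptor the unique viable ORF
start.

Transcripts draw a source zone uniformly among functional zones and join
a random VH master to a zone D and JH with 0–5 nt trims and 0–8 nt N
additions per junction, rejection-sampled until the prefix is in frame
and stop-free — modelling the selection for productive rearrangements
that shapes real expressed repertoires. Sterile transcripts carry exon 0
spliced to the CH chain (70%) or a bare VH-less CH chain (30%), matching
the observation that not all VH-less messages carry exon 0. Sequencing
error is i.i.d. substitution at a configurable rate (default 0).

Not emulated: indels, transition/transversion bias, repeat families
beyond the planted duplications, read-level sequencing artifacts,
assembly gaps, and realistic VH family structure. Passing tests therefore
demonstrate correctness of the rules and bookkeeping under clean
substitution-only divergence — not robustness to assembly error, which on
real data should be assessed with the `boundary_uncertain`/`splice_ok`
flags and the audit trail.

## Problem sizes and determinism

The default simulated locus is ~60 kb (five ~9-kb zones, four 10-cassette
VH arrays); transcript experiments use 500 ESTs. These sizes exercise
every code path, including both dot-plot strategies, while keeping the
whole suite and the acceptance script fast. All generators require an
explicit seed and are deterministic given it; the pipeline itself is
seed-free and deterministic. `scripts/acceptance.py` derives all its
sub-seeds from the single `--seed` argument.

## Known limitations

* JH calling depends on reference JH sequences; there is no ab-initio JH
  model, and the hard length cap (80 nt) would truncate unusually long JH
  exons.
* D-segment strand is reported as '+' by convention (see above); inverted
  D segments are found but not labelled as inverted.
* Zone assignment compares equal-length copy prefixes; it does not model
  length polymorphism between zone copies (none is generated).
* The `functional` zone flag and the EST VH-ORF test are heuristics,
  documented as such; both have configurable thresholds.
* Short-read data, gapped alignment, phylogenetic tree building and IMGT
  nomenclature registration are out of scope.
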