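"""RSS model and scanner tests, including the independent brute-force oracle."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igloci.rss import (DOWNSTREAM, HEPTAMER_CONSENSUS, NONAMER_CONSENSUS,
                        RssModel, hamming_scan, scan_rss)
from igloci.seqio import NucSequence, revcomp

from conftest import random_seq


def oracle_hamming(seq: str, motif: str, max_mm: int):
    """Independent enumeration: every window, character-by-character."""
    out = []
    for i in range(len(seq) - len(motif) + 1):
        mm = sum(
            1
            for a, b in zip(seq[i : i + len(motif)], motif)
            if a != b or a == "N" or b == "N"
        )
        if mm <= max_mm:
            out.append((i, mm))
    return out


def oracle_scan(seq: str, model: RssModel):
    """Exhaustive double loop over heptamer starts, spacers and strands.

    Returns {(heptamer_start, strand, spacer, orientation, hept_mm, nona_mm)}.
    """
    hits = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        n = len(s)
        for h in range(n - 7 + 1):
            hm = sum(1 for a, b in zip(s[h : h + 7], model.heptamer_consensus)
                     if a != b or a == "N")
            if hm > model.heptamer_max_mm:
                continue
            for spacer in model.spacer_lengths():
                p = h + 7 + spacer
                if p + 9 > n:
                    continue
                nm = sum(1 for a, b in zip(s[p : p + 9], model.nonamer_consensus)
                         if a != b or a == "N")
                if nm <= model.nonamer_max_mm:
                    if strand == "+":
                        hits.add((h, "+", spacer, hm, nm))
                    else:
                        hits.add((n - h - 7, "-", spacer, hm, nm))
    return hits


def as_tuples(hits):
    return {
        (h.heptamer.start, h.heptamer.strand, h.spacer_len, h.heptamer_mm, h.nonamer_mm)
        for h in hits
    }


class TestHammingScan:
    def test_exact_identity_match(self):
        assert hamming_scan("TATTATTGT", "TATTATTGT", 0) == [(0, 0)]

    def test_single_mismatch_window(self):
        # brute force over all 4 windows of the 12-mer gives only (0, 1)
        assert hamming_scan("TATTACTGTAAA", "TATTATTGT", 2) == [(0, 1)]

    def test_n_counts_as_mismatch(self):
        assert hamming_scan("NNNNNNNNN", "TATTATTGT", 2) == []

    def test_motif_longer_than_sequence_is_empty(self):
        assert hamming_scan("ACG", "ACGT", 1) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_oracle_on_random_sequence(self, rng, seed):
        import numpy as np

        r = np.random.default_rng(seed)
        seq = random_seq(r, 2000)
        motif = random_seq(r, 9)
        for max_mm in (0, 2, 4):
            assert hamming_scan(seq, motif, max_mm) == oracle_hamming(seq, motif, max_mm)


class TestScanRss:
    def test_planted_canonical_23_rss(self, rng):
        spacer = random_seq(rng, 23)
        seq = NucSequence("s", HEPTAMER_CONSENSUS + spacer + NONAMER_CONSENSUS)
        hits = scan_rss(seq, RssModel(spacer_class=23, spacer_slack=0), "+")
        assert len(hits) == 1
        (h,) = hits
        assert (h.heptamer_mm, h.nonamer_mm, h.spacer_len) == (0, 0, 23)
        assert h.orientation == DOWNSTREAM

    def test_nonamer_over_mismatch_cap_is_rejected(self, rng):
        spacer = random_seq(rng, 23)
        broken = "GCG" + NONAMER_CONSENSUS[3:]  # 3 substitutions
        assert sum(a != b for a, b in zip(broken, NONAMER_CONSENSUS)) == 3
        seq = NucSequence("s", HEPTAMER_CONSENSUS + spacer + broken)
        assert scan_rss(seq, RssModel(spacer_class=23, nonamer_max_mm=2), "+") == []

    @pytest.mark.parametrize("spacer_class", [12, 23])
    def test_agrees_with_exhaustive_oracle(self, spacer_class):
        import numpy as np

        r = np.random.default_rng(101 + spacer_class)
        seq = random_seq(r, 10_000)
        model = RssModel(spacer_class=spacer_class, heptamer_max_mm=2, nonamer_max_mm=3)
        hits = scan_rss(NucSequence("s", seq), model, "both")
        assert as_tuples(hits) == oracle_scan(seq, model)

    def test_strand_symmetry(self):
        import numpy as np

        r = np.random.default_rng(55)
        seq = random_seq(r, 5000)
        model = RssModel(spacer_class=12, heptamer_max_mm=2, nonamer_max_mm=3)
        minus = scan_rss(NucSequence("s", seq), model, "-")
        plus_on_rc = scan_rss(NucSequence("s", revcomp(seq)), model, "+")
        mapped = {
            (len(seq) - h.heptamer.end, h.spacer_len, h.heptamer_mm, h.nonamer_mm)
            for h in plus_on_rc
        }
        got = {
            (h.heptamer.start, h.spacer_len, h.heptamer_mm, h.nonamer_mm)
            for h in minus
        }
        assert got == mapped

    def test_monotone_in_tolerances(self):
        import numpy as np

        r = np.random.default_rng(77)
        seq = NucSequence("s", random_seq(r, 8000))
        base = RssModel(spacer_class=23, heptamer_max_mm=1, nonamer_max_mm=2,
                        spacer_slack=0)
        loose = RssModel(spacer_class=23, heptamer_max_mm=2, nonamer_max_mm=3,
                         spacer_slack=1)
        assert as_tuples(scan_rss(seq, base, "both")) <= as_tuples(
            scan_rss(seq, loose, "both")
        )

    def test_expected_hit_count_on_random_sequence(self):
        """Hit count within 3 sigma of the binomial expectation (oracle-derived)."""
        import math

        import numpy as np

        # exact per-position probabilities for <=1 hept mm and <=2 nona mm
        p_hept = (1 + 7 * 3) / 4**7
        p_nona = (1 + 9 * 3 + 36 * 9) / 4**9
        n = 200_000
        model = RssModel(spacer_class=23, spacer_slack=0)
        r = np.random.default_rng(13)
        seq = NucSequence("s", random_seq(r, n))
        hits = scan_rss(seq, model, "+")
        mean = n * p_hept * p_nona
        sigma = math.sqrt(mean)
        assert abs(len(hits) - mean) <= 3 * sigma + 1


def test_model_validation():
    with pytest.raises(ValueError):
        RssModel(spacer_class=15)
    with pytest.raises(ValueError):
        RssModel(heptamer_consensus="CACA")
    with pytest.raises(ValueError):
        RssModel(nonamer_max_mm=10)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGT", min_size=60, max_size=120), st.integers(0, 3))
def test_hamming_scan_windows_verify_by_inspection(seq, max_mm):
    motif = NONAMER_CONSENSUS
    for pos, mm in hamming_scan(seq, motif, max_mm):
        direct = sum(a != b for a, b in zip(seq[pos : pos + 9], motif))
        assert direct == mm <= max_mm
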