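"""Dot-plot engine tests: windowed identity, run merging, duplication detection."""

import numpy as np
import pytest

from igloci.dotplot import (DiagonalRun, DotParams, coverage_of,
                            detect_duplications, dot_matches, merge_diagonals)
from igloci.seqio import NucSequence, revcomp

from conftest import random_seq


def oracle_matches(a: str, b: str, w: int, min_identity: float):
    """Independent O(|a||b|w) double loop with an explicit match count."""
    import math

    thr = math.ceil(round(w * min_identity, 9))
    out = {}
    for i in range(len(a) - w + 1):
        for j in range(len(b) - w + 1):
            m = sum(
                1
                for x, y in zip(a[i : i + w], b[j : j + w])
                if x == y and x != "N"
            )
            if m >= thr:
                out[(i, j)] = m / w
    return out


def oracle_components(cells, max_gap):
    """Union-find over same-diagonal cells within max_gap."""
    cells = sorted(cells)
    parent = {c: c for c in cells}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for (i1, j1) in cells:
        for (i2, j2) in cells:
            if i1 - j1 == i2 - j2 and 0 < i2 - i1 <= max_gap + 1:
                parent[find((i2, j2))] = find((i1, j1))
    groups = {}
    for c in cells:
        groups.setdefault(find(c), []).append(c)
    return {frozenset(g) for g in groups.values()}


def test_identity_threshold_is_integer_match_count():
    assert DotParams(30, 0.60).min_matches == 18
    assert DotParams(30, 0.85).min_matches == 26
    assert DotParams(30, 1.0).min_matches == 30


def test_self_comparison_lights_full_diagonal(rng):
    a = NucSequence("a", random_seq(rng, 100))
    matches = dot_matches(a, a, DotParams(30, 0.85))
    diag = {(i, i) for i in range(71)}
    assert diag <= set(matches)
    assert all(matches[c] == 1.0 for c in diag)


def test_three_substitutions_in_one_window_retained_at_85(rng):
    a = random_seq(rng, 100)
    b = list(a)
    for pos in (40, 50, 60):  # 3 substitutions inside window [40, 70)
        b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
    matches = dot_matches(
        NucSequence("a", a), NucSequence("b", "".join(b)), DotParams(30, 0.85)
    )
    assert (40, 40) in matches
    assert matches[(40, 40)] == pytest.approx(27 / 30)


def test_short_sequence_warns_and_returns_empty(rng):
    with pytest.warns(UserWarning):
        assert dot_matches(
            NucSequence("a", "ACGT"), NucSequence("b", "ACGT"), DotParams(30, 0.6)
        ) == {}


@pytest.mark.parametrize("seed", range(4))
@pytest.mark.parametrize("min_identity", [0.60, 0.85])
def test_matches_agree_with_brute_force_oracle(seed, min_identity):
    r = np.random.default_rng(seed)
    a = random_seq(r, 200)
    # half related, half unrelated so both regimes are exercised
    b = list(random_seq(r, 200))
    b[50:150] = a[30:130]
    b = "".join(b)
    params = DotParams(30, min_identity)
    got = dot_matches(NucSequence("a", a), NucSequence("b", b), params)
    exp = oracle_matches(a, b, 30, min_identity)
    assert set(got) == set(exp)
    for cell in got:
        assert got[cell] == pytest.approx(exp[cell])


def test_matches_are_symmetric(rng):
    a = NucSequence("a", random_seq(rng, 150))
    b = NucSequence("b", random_seq(rng, 150))
    params = DotParams(10, 0.6)
    ab = dot_matches(a, b, params)
    ba = dot_matches(b, a, params)
    assert {(j, i) for (i, j) in ab} == set(ba)


def test_lowering_identity_never_removes_a_cell(rng):
    a = NucSequence("a", random_seq(rng, 300))
    b = NucSequence("b", random_seq(rng, 300))
    strict = dot_matches(a, b, DotParams(12, 0.9))
    loose = dot_matches(a, b, DotParams(12, 0.7))
    assert set(strict) <= set(loose)


class TestMergeDiagonals:
    def test_contiguous_diagonal_merges_to_one_run(self):
        cells = {(i, i + 5): 1.0 for i in range(10, 30)}
        runs = merge_diagonals(cells, 0, window=30)
        assert len(runs) == 1
        assert runs[0] == DiagonalRun(10, 15, 30 + 19, 1.0)

    def test_gap_beyond_max_gap_splits_runs(self):
        cells = {(0, 0): 1.0, (10, 10): 1.0}
        assert len(merge_diagonals(cells, 5, window=30)) == 2
        assert len(merge_diagonals(cells, 9, window=30)) == 1

    @pytest.mark.parametrize("max_gap", [0, 2, 7])
    def test_equals_union_find_oracle(self, max_gap):
        r = np.random.default_rng(42 + max_gap)
        cells = {
            (int(i), int(j)): 1.0
            for i, j in zip(r.integers(0, 40, 120), r.integers(0, 40, 120))
        }
        runs = merge_diagonals(cells, max_gap, window=5)
        got = set()
        for run in runs:
            d = run.a_start - run.b_start
            members = frozenset(
                (i, i - d)
                for i in range(run.a_start, run.a_start + run.length - 5 + 1)
                if (i, i - d) in cells
            )
            got.add(members)
        assert got == oracle_components(set(cells), max_gap)
        # each cell belongs to exactly one run
        assert sum(len(g) for g in got) == len(cells)


class TestDetectDuplications:
    def test_mutated_copy_found_with_high_coverage(self):
        r = np.random.default_rng(3)
        z = random_seq(r, 3000)
        copy = list(z)
        for pos in np.nonzero(r.random(3000) < 0.02)[0]:
            copy[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[pos]]
        runs = detect_duplications(
            NucSequence("z", z), NucSequence("c", "".join(copy))
        )
        assert runs
        assert coverage_of(runs, 0, 3000) >= 0.90

    def test_self_comparison_excludes_main_diagonal(self, rng):
        a = NucSequence("a", random_seq(rng, 2000))
        assert detect_duplications(a) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_unrelated_sequences_have_no_long_runs(self, seed):
        r = np.random.default_rng(900 + seed)
        a = NucSequence("a", random_seq(r, 5000))
        b = NucSequence("b", random_seq(r, 5000))
        runs = detect_duplications(a, b)
        assert all(run.length < 60 for run in runs)

    def test_inverted_duplication_found_in_reverse_orientation(self):
        r = np.random.default_rng(8)
        z = random_seq(r, 1500)
        host = random_seq(r, 500) + revcomp(z) + random_seq(r, 500)
        runs = detect_duplications(NucSequence("z", z), NucSequence("h", host))
        rev = [x for x in runs if x.orientation == "reverse"]
        assert rev and max(x.length for x in rev) >= 1400
        assert all(x.length < 60 for x in runs if x.orientation == "forward")
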