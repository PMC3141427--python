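"""Windowed-identity dot plots and diagonal-run duplication detection.

A dot-plot cell (i, j) is lit when the two windows a[i:i+w) and b[j:j+w)
agree at or above a fixed identity fraction.  Runs of lit cells parallel to
the main diagonal are ungapped local duplications; reverse-orientation runs
are found by scanning against the reverse complement.  This windowed model
deliberately has no gaps: it reproduces what a dot-plot reader sees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .rss import _encode
from .seqio import NucSequence, revcomp

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class DotParams:
    """Window length (nt) and minimum identity fraction for a dot plot."""

    window: int = 30
    min_identity: float = 0.85

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")

    @property
    def min_matches(self) -> int:
        """Identity threshold as an integer match count, ceil(w * t)."""
        return math.ceil(round(self.window * self.min_identity, 9))


#: duplication-detection parameters: window 30, 85% identity
DUPLICATION_PARAMS = DotParams(window=30, min_identity=0.85)
#: homology-search parameters for JH / cDNA comparisons: window 30, 60% identity
HOMOLOGY_PARAMS = DotParams(window=30, min_identity=0.60)


@dataclass(frozen=True)
class DiagonalRun:
    """A maximal run of lit cells on one diagonal."""

    a_start: int
    b_start: int
    length: int
    mean_identity: float
    orientation: str = FORWARD

    @property
    def a_end(self) -> int:
        return self.a_start + self.length

    @property
    def b_end(self) -> int:
        return self.b_start + self.length


def _matches_by_short_windows(
    a: np.ndarray, b: np.ndarray, w: int, thr: int, swap: bool
) -> dict[tuple[int, int], float]:
    """Outer loop over the shorter sequence's windows, vectorized over the longer."""
    out: dict[tuple[int, int], float] = {}
    windows = sliding_window_view(a, w)
    for j in range(len(b) - w + 1):
        counts = (windows == b[j : j + w]).sum(axis=1)
        for i in np.nonzero(counts >= thr)[0]:
            key = (int(j), int(i)) if swap else (int(i), int(j))
            out[key] = counts[i] / w
    return out


def _matches_by_diagonals(
    a: np.ndarray, b: np.ndarray, w: int, thr: int
) -> dict[tuple[int, int], float]:
    """Per-diagonal cumulative-sum window counts; exact, O(nm) total work."""
    la, lb = len(a), len(b)
    out: dict[tuple[int, int], float] = {}
    for d in range(-(lb - w), la - w + 1):
        i0 = max(0, d)
        i1 = min(la, lb + d)
        if i1 - i0 < w:
            continue
        eq = (a[i0:i1] == b[i0 - d : i1 - d]).astype(np.int32)
        counts = np.convolve(eq, np.ones(w, dtype=np.int32), mode="valid")
        for k in np.nonzero(counts >= thr)[0]:
            i = i0 + int(k)
            out[(i, i - d)] = counts[k] / w
    return out


def dot_matches(
    a: NucSequence, b: NucSequence, params: DotParams
) -> dict[tuple[int, int], float]:
    """Exhaustive windowed-identity match set.

    Returns {(i, j): identity} for every window pair at or above the
    threshold.  Sequences shorter than the window yield an empty set with a
    warning.
    """
    w = params.window
    if len(a) < w or len(b) < w:
        warnings.warn("sequence shorter than dot-plot window; empty match set", stacklevel=2)
        return {}
    ca = _encode(a.residues, 1)
    cb = _encode(b.residues, 2)  # distinct N codes: N never matches N
    thr = params.min_matches
    # pick the cheaper exact strategy
    if min(len(a), len(b)) - w + 1 <= 64:
        if len(b) <= len(a):
            return _matches_by_short_windows(ca, cb, w, thr, swap=False)
        return _matches_by_short_windows(cb, ca, w, thr, swap=True)
    return _matches_by_diagonals(ca, cb, w, thr)


def merge_diagonals(
    matches: dict[tuple[int, int], float],
    max_gap: int = 0,
    *,
    window: int,
) -> list[DiagonalRun]:
    """Merge lit cells on the same diagonal into maximal runs.

    Cells with the same i - j offset whose starts differ by at most
    ``max_gap + 1`` join one run.  Runs are sorted by length descending.
    """
    by_diag: dict[int, list[tuple[int, float]]] = {}
    for (i, j), ident in matches.items():
        by_diag.setdefault(i - j, []).append((i, ident))
    runs: list[DiagonalRun] = []
    for d, cells in by_diag.items():
        cells.sort()
        start_i = cells[0][0]
        idents = [cells[0][1]]
        prev_i = start_i
        for i, ident in cells[1:]:
            if i - prev_i > max_gap + 1:
                runs.append(
                    DiagonalRun(start_i, start_i - d, prev_i - start_i + window,
                                float(np.mean(idents)))
                )
                start_i, idents = i, []
            idents.append(ident)
            prev_i = i
        runs.append(
            DiagonalRun(start_i, start_i - d, prev_i - start_i + window,
                        float(np.mean(idents)))
        )
    runs.sort(key=lambda r: (-r.length, r.a_start, r.b_start))
    return runs


def detect_duplications(
    a: NucSequence,
    b: NucSequence | None = None,
    params: DotParams = DUPLICATION_PARAMS,
    max_gap: int = 0,
    both_orientations: bool = True,
) -> list[DiagonalRun]:
    """Duplication runs between two sequences (window 30, 85% by default).

    For a self-comparison (``b`` omitted or identical to ``a``) the trivial
    main diagonal is excluded.  Reverse-orientation duplications are found
    by scanning against the reverse complement; their b-coordinates are
    reported on the forward strand of ``b``.
    """
    self_cmp = b is None or (b.id == a.id and b.residues == a.residues)
    if b is None:
        b = a
    w = params.window
    fwd = dot_matches(a, b, params)
    if self_cmp:
        fwd = {ij: v for ij, v in fwd.items() if ij[0] != ij[1]}
    runs = merge_diagonals(fwd, max_gap, window=w)
    if both_orientations:
        brc = NucSequence(b.id + "|rc", revcomp(b.residues))
        rev = dot_matches(a, brc, params)
        for run in merge_diagonals(rev, max_gap, window=w):
            # map the rc window-start back to a forward-strand window start
            b_fwd = len(b) - run.b_start - run.length
            runs.append(
                DiagonalRun(run.a_start, b_fwd, run.length, run.mean_identity, REVERSE)
            )
    runs.sort(key=lambda r: (-r.length, r.a_start, r.b_start))
    return runs


def coverage_of(runs: list[DiagonalRun], start: int, end: int, axis: str = "a") -> float:
    """Fraction of [start, end) covered by run footprints on one axis."""
    if end <= start:
        return 0.0
    mask = np.zeros(end - start, dtype=bool)
    for r in runs:
        lo = (r.a_start if axis == "a" else r.b_start) - start
        hi = lo + r.length
        lo, hi = max(lo, 0), min(hi, end - start)
        if hi > lo:
            mask[lo:hi] = True
    return float(mask.mean())


def render_dotplot(
    matches: dict[tuple[int, int], float], path: str, title: str = ""
) -> None:
    """Save a scatter rendering of a match set to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if matches:
        ii, jj = zip(*matches.keys())
        ax.scatter(ii, jj, s=1, c="black", marker=".")
    ax.set_xlabel("sequence a (nt)")
    ax.set_ylabel("sequence b (nt)")
    if title:
        ax.set_title(title)
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
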