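"""Shared fixtures: one simulated locus + annotation reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from igloci.pipeline import annotate_locus, classify_transcripts
from igloci.simulate import SimConfig, simulate_locus, simulate_transcripts

LOCUS_SEED = 7
TRANSCRIPT_SEED = 42
N_TRANSCRIPTS = 500


@pytest.fixture(scope="session")
def truth():
    """Default five-zone locus: exon 0 in zones 1-3, zone 3 disorganized,
    zone 5 inverted, 2% inter-zone divergence."""
    return simulate_locus(SimConfig.paper_layout(seed=LOCUS_SEED))


@pytest.fixture(scope="session")
def annotation(truth):
    return annotate_locus(truth.locus, truth.reference_exons(), truth.jh_refs())


@pytest.fixture(scope="session")
def classified(truth, annotation):
    """(merged prediction/truth table, models) for 500 error-free transcripts."""
    ests, labels = simulate_transcripts(
        truth, n=N_TRANSCRIPTS, error_rate=0.0, seed=TRANSCRIPT_SEED
    )
    models, table = classify_transcripts(ests, annotation)
    merged = table.merge(labels, on="est_id", suffixes=("_pred", "_true"))
    return merged, models


@pytest.fixture(scope="session")
def truth_identical():
    """Same layout with zero inter-zone divergence (identical zone copies)."""
    return simulate_locus(SimConfig.paper_layout(seed=LOCUS_SEED, zone_divergence=0.0))


@pytest.fixture(scope="session")
def annotation_identical(truth_identical):
    return annotate_locus(
        truth_identical.locus,
        truth_identical.reference_exons(),
        truth_identical.jh_refs(),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20110615)


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
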