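"""Transcript chaining, zone voting, isoform rules, ORF/protein utilities."""

import numpy as np
import pytest

from igloci.seqio import NucSequence
from igloci.transcripts import (ChainLink, TranscriptModel,
                                assign_zone, build_exon_catalog, chain_exons,
                                classify_isoform, classify_transcript,
                                orf_stop_analysis, predict_amplicon,
                                protein_features)

from conftest import random_seq


@pytest.fixture(scope="module")
def catalog(truth, annotation):
    return build_exon_catalog(truth.locus, annotation.exon_annotations)


def _model(labels, has_vh=True, stops=False):
    chain = [ChainLink(l, 1, 1.0, i * 100, (i + 1) * 100) for i, l in enumerate(labels)]
    return TranscriptModel("t", chain, has_vh=has_vh, stops_all_frames=stops)


class TestChainExons:
    def test_error_free_igm_sec_chains_at_identity_one(self, truth, catalog):
        zone = 1
        seq = "".join(
            truth.zone_exon_seq(zone, lab, "mu")
            for lab in ("Cmu1", "Cmu2", "Cmu3", "Cmu4", "SEC_TAIL")
        )
        model = chain_exons(NucSequence("t", seq), catalog)
        assert model.chain_labels() == ["Cmu1", "Cmu2", "Cmu3", "Cmu4", "SEC_TAIL"]
        assert all(link.identity == 1.0 for link in model.exon_chain)
        assert not model.has_vh  # no prefix at all

    def test_exon0_transcript_sets_uses_exon0_not_vh(self, truth, catalog):
        seq = truth.zone_exon_seq(1, "EX0") + truth.zone_exon_seq(1, "Cmu1", "mu")
        model = chain_exons(NucSequence("t", seq), catalog)
        assert model.uses_exon0 and not model.has_vh
        assert model.chain_labels()[0] == "EX0"

    def test_random_est_yields_empty_chain(self, rng, catalog):
        model = chain_exons(NucSequence("t", random_seq(rng, 1500)), catalog)
        assert model.exon_chain == [] and model.isoform == "UNCLASSIFIED"

    def test_vh_prefix_detected_by_orf(self, truth, catalog):
        from igloci.simulate import _productive_vdj

        rng = np.random.default_rng(123)
        prefix = _productive_vdj(truth, 2, rng)
        seq = prefix + "".join(
            truth.zone_exon_seq(2, lab, "mu") for lab in ("Cmu1", "Cmu2")
        ) + truth.zone_exon_seq(2, "TM1", "mu") + truth.zone_exon_seq(2, "TM2", "mu")
        model = chain_exons(NucSequence("t", seq), catalog)
        assert model.has_vh
        assert model.chain_labels() == ["Cmu1", "Cmu2", "TM1", "TM2"]


class TestAssignZone:
    def test_zone_vote_correct_with_margin_at_two_percent_divergence(
        self, truth, catalog
    ):
        for zone in (1, 2, 4):
            seq = "".join(
                truth.zone_exon_seq(zone, lab, "mu") for lab in ("Cmu1", "Cmu2")
            )
            model = chain_exons(NucSequence("t", seq), catalog)
            voted, margin = assign_zone(model, NucSequence("t", seq), catalog)
            assert voted == zone and margin >= 1

    def test_identical_copies_vote_ambiguous(self, truth_identical, annotation_identical):
        cat0 = build_exon_catalog(
            truth_identical.locus, annotation_identical.exon_annotations
        )
        seq = truth_identical.zone_exon_seq(1, "Cmu1", "mu")
        model = chain_exons(NucSequence("t", seq), cat0)
        voted, margin = assign_zone(model, NucSequence("t", seq), cat0)
        assert voted == "ambiguous" and margin == 0

    def test_winner_never_has_more_mismatches_than_runner_up(self, truth, catalog):
        # audit the vote on a handful of mixed transcripts
        from igloci.transcripts import _mismatches

        for zone in (1, 2):
            seq = truth.zone_exon_seq(zone, "Cmu1", "mu")
            est = NucSequence("t", seq)
            model = chain_exons(est, catalog)
            voted, _ = assign_zone(model, est, catalog)
            link = model.exon_chain[0]
            seg = est.residues[link.est_start : link.est_end]
            mm = {
                c.zone_id: _mismatches(seg, c.seq)
                for c in catalog
                if c.label == "Cmu1" and c.zone_id is not None
            }
            assert mm[voted] == min(mm.values())


class TestClassifyIsoform:
    def test_secreted_igm_chain(self):
        m = _model(["Cmu1", "Cmu2", "Cmu3", "Cmu4", "SEC_TAIL"])
        assert classify_isoform(m) == "IGM_SEC"

    def test_short_transmembrane_igm_chain(self):
        assert classify_isoform(_model(["Cmu1", "Cmu2", "TM1", "TM2"])) == "IGM_TM_SHORT"

    def test_sterile_exon0_chain(self):
        m = _model(["EX0", "Cmu1", "Cmu2"], has_vh=False, stops=True)
        assert classify_isoform(m) == "STERILE"

    def test_chimeric_igd_chain_without_cdelta5(self):
        labels = ["Cmu1", "Cdelta1", "Cdelta2", "Cdelta3", "Cdelta4", "Cdelta6",
                  "Cdelta7", "TM1", "TM2"]
        assert classify_isoform(_model(labels)) == "IGD_TM_CHIMERIC"

    def test_unexpected_chain_is_unclassified(self):
        assert classify_isoform(_model(["Cmu2", "Cmu3"])) == "UNCLASSIFIED"

    def test_empty_chain_is_unclassified(self):
        assert classify_isoform(TranscriptModel("t")) == "UNCLASSIFIED"


class TestOrfStopAnalysis:
    def test_hand_enumerated_nine_mer(self):
        # TAA TAG TGA in frame 0; frames 1/2 have no complete stop codon
        stops, all_frames = orf_stop_analysis(NucSequence("t", "TAATAGTGA"))
        assert stops[0] == [0, 3, 6]
        assert stops[1] == [] and stops[2] == []
        assert all_frames is False

    def test_exon0_transcript_stops_in_all_frames(self, truth, catalog):
        est = NucSequence(
            "t", truth.zone_exon_seq(1, "EX0") + truth.zone_exon_seq(1, "Cmu1", "mu")
        )
        model = classify_transcript(est, catalog)
        assert model.stops_all_frames and model.isoform == "STERILE"

    def test_stop_free_orf_is_false(self):
        from igloci.simulate import _random_orf

        orf = _random_orf(np.random.default_rng(4), 300)
        _, all_frames = orf_stop_analysis(NucSequence("t", orf))
        assert all_frames is False


class TestProteinFeatures:
    @pytest.mark.parametrize(
        "aa,cys,nglyc",
        [("NAS", (), (0,)), ("NPS", (), ()), ("CNCT", (0, 2), (1,))],
    )
    def test_motif_examples(self, aa, cys, nglyc):
        feats = protein_features(aa)
        assert feats.cys_positions == cys
        assert feats.nglyc_sites == nglyc

    def test_invalid_residue_is_an_error(self):
        with pytest.raises(ValueError):
            protein_features("MB")


class TestPredictAmplicon:
    FWD = "CATTGACTTTCTCATGGACTCAGGGC"  # Cmu1-sense primer
    REV = "GGACTGTTGGAGGATTCATGTCTCACA"  # Cdelta6-antisense primer

    def test_planted_product_has_expected_length(self, rng):
        from igloci.seqio import revcomp

        insert = random_seq(rng, 100)
        template = NucSequence("t", self.FWD + insert + revcomp(self.REV))
        products = predict_amplicon(template, self.FWD, self.REV)
        assert len(products) == 1
        assert products[0][1] == len(self.FWD) + 100 + len(self.REV)

    def test_absent_primers_give_no_product(self, rng):
        template = NucSequence("t", random_seq(rng, 500))
        assert predict_amplicon(template, self.FWD, self.REV) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_exhaustive_pair_oracle(self, seed):
        from igloci.seqio import revcomp

        r = np.random.default_rng(300 + seed)
        fwd, rev = random_seq(r, 6), random_seq(r, 6)
        template = random_seq(r, 800)
        got = {(iv.start, iv.end) for iv, _ in
               predict_amplicon(NucSequence("t", template), fwd, rev, max_mm=1)}
        exp = set()
        rc = revcomp(rev)
        for i in range(len(template) - 6 + 1):
            if sum(a != b for a, b in zip(template[i : i + 6], fwd)) > 1:
                continue
            for j in range(len(template) - 6 + 1):
                if j < i:
                    continue
                if sum(a != b for a, b in zip(template[j : j + 6], rc)) > 1:
                    continue
                exp.add((i, j + 6))
        assert got == exp


def test_chimeric_igd_transcript_end_to_end(truth, catalog):
    from igloci.simulate import _igd_chain, _productive_vdj, _splice

    rng = np.random.default_rng(9)
    seq = _productive_vdj(truth, 4, rng) + _splice(truth, 4, _igd_chain(truth, 4))
    model = classify_transcript(NucSequence("t", seq), catalog)
    assert model.isoform == "IGD_TM_CHIMERIC"
    assert "Cdelta5" not in model.chain_labels()
    assert model.zone_vote[0] == 4
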