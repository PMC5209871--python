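import numpy as np
import pytest

from lipevol.align import AlignParams
from lipevol.io_core import ProteinRecord
from lipevol.screen import (
    ScreenConfig,
    extract_lid,
    find_motifs,
    predict_signal_peptide,
    screen_candidates,
)
from lipevol.simdata import SimulationConfig, make_screening_fixture, simulate_family


class TestFindMotifs:
    def test_canonical_motif_pair(self):
        hits = find_motifs("AAGGGFAAAGESAGAA")
        assert hits.oxyanion == [(2, "GGGF")]
        assert hits.catalytic == [(9, "GESAG")]

    def test_alternate_forms_matched(self):
        hits = find_motifs("AAGGGLAAAGQSAGAA")
        assert hits.oxyanion == [(2, "GGGL")]
        assert hits.catalytic == [(9, "GQSAG")]

    def test_no_hits(self):
        hits = find_motifs("AAAAAA")
        assert hits.oxyanion == [] and hits.catalytic == []

    def test_matched_text_equals_slice(self):
        seq = "GGGFGGGFAAGESAG"
        hits = find_motifs(seq)
        for pos, text in hits.oxyanion + hits.catalytic:
            assert seq[pos : pos + len(text)] == text


class TestSignalPeptide:
    def test_hydrophobic_start_detected(self):
        rec = "M" + "K" + "L" * 10 + "DQNSTDQNST" * 4
        call = predict_signal_peptide(rec)
        assert call.present
        assert call.cleavage_guess is not None
        assert call.cleavage_guess <= 40

    def test_polar_start_rejected(self):
        rec = "M" + "D" * 10 + "LLLQNSTDQN" * 4
        assert not predict_signal_peptide(rec).present

    def test_must_start_with_methionine(self):
        rec = "K" + "L" * 12 + "DQNSTDQNST" * 4
        assert not predict_signal_peptide(rec).present

    def test_short_sequence_flagged(self):
        call = predict_signal_peptide("MLLLLLLLLL")
        assert not call.present and call.reason == "too_short"

    def test_recall_on_simulated_positives(self):
        """>= 95% of simulated signal-bearing sequences are called."""
        hits = 0
        total = 0
        for seed in range(25):
            fam = simulate_family(
                SimulationConfig(n_leaves=8, seed=seed)
            )
            for rec in fam.extant:
                total += 1
                if predict_signal_peptide(rec).present:
                    hits += 1
        assert total == 200
        assert hits / total >= 0.95


@pytest.fixture(scope="module")
def reference():
    seq = "M" + "L" * 14 + "GGGF" + "A" * 10 + "WIVNDYKQES" * 3 + "GESAG" + "A" * 10
    lid_start = len("M" + "L" * 14 + "GGGF" + "A" * 10)
    return ProteinRecord("ref", seq, {"lid": (lid_start, lid_start + 30)})


@pytest.fixture(scope="module")
def fixture():
    return make_screening_fixture(4, 4, seed=2)


class TestExtractLid:
    def test_identical_candidate_recovers_lid_verbatim(self, reference):
        lid = extract_lid(reference, reference)
        start, end = reference.features["lid"]
        assert lid.residues == reference.sequence[start:end]
        assert lid.interval == (start, end)

    def test_deleted_lid_yields_zero_length(self, reference):
        start, end = reference.features["lid"]
        candidate = ProteinRecord(
            "del", reference.sequence[:start] + reference.sequence[end:]
        )
        lid = extract_lid(candidate, reference)
        assert lid.length == 0 and lid.interval is None

    def test_recovered_interval_overlaps_truth_on_simulated_families(self):
        """Median Jaccard overlap >= 0.8 against simulated lid truth."""
        scores = []
        params = AlignParams()
        for seed in range(12):
            fam = simulate_family(
                SimulationConfig(n_leaves=4, seed=seed + 400)
            )
            reference = ProteinRecord(
                "ref",
                fam.true_ancestors[fam.root_label],
                {"lid": fam.config.lid_interval},
            )
            for rec in fam.extant:
                if "lid" not in rec.features:
                    continue
                truth = set(range(*rec.features["lid"]))
                got = extract_lid(rec, reference, params)
                if got.interval is None:
                    scores.append(0.0)
                    continue
                found = set(range(*got.interval))
                scores.append(len(truth & found) / len(truth | found))
        assert np.median(scores) >= 0.8


class TestScreenCandidates:
    def test_planted_positives_accepted(self, fixture):
        report = screen_candidates(fixture.records, fixture.reference)
        planted = {rid for rid, true in fixture.labels.items() if true}
        assert set(report.accepted_ids) == planted
        for row in report.rows:
            assert (row.decision == "accepted") == (not row.reasons)

    def test_short_lid_rejected_with_reason(self, fixture):
        pos = next(r for r in fixture.records if r.id.startswith("pos"))
        report = screen_candidates(
            [pos], fixture.reference, ScreenConfig(min_lid=10_000)
        )
        assert report.rows[0].decision == "rejected"
        assert "lid_too_short" in report.rows[0].reasons

    def test_low_identity_rejected_with_reason(self, fixture):
        pos = next(r for r in fixture.records if r.id.startswith("pos"))
        report = screen_candidates(
            [pos], fixture.reference, ScreenConfig(min_identity=1.01)
        )
        assert "low_identity" in report.rows[0].reasons

    def test_order_independence(self, fixture):
        r1 = screen_candidates(fixture.records, fixture.reference)
        r2 = screen_candidates(
            list(reversed(fixture.records)), fixture.reference
        )
        d1 = {row.id: row.decision for row in r1.rows}
        d2 = {row.id: row.decision for row in r2.rows}
        assert d1 == d2 and r1.summary == r2.summary

    def test_raising_min_lid_is_monotone(self, fixture):
        accepted = []
        for min_lid in (0, 20, 30, 10_000):
            report = screen_candidates(
                fixture.records,
                fixture.reference,
                ScreenConfig(min_lid=min_lid),
            )
            accepted.append(len(report.accepted_ids))
        assert accepted == sorted(accepted, reverse=True)

    def test_external_signal_flags_override_heuristic(self, fixture):
        pos = next(r for r in fixture.records if r.id.startswith("pos"))
        report = screen_candidates(
            [pos],
            fixture.reference,
            ScreenConfig(signal_flags={pos.id: False}),
        )
        assert "no_signal_peptide" in report.rows[0].reasons

    def test_summary_counts_consistent(self, fixture):
        report = screen_candidates(fixture.records, fixture.reference)
        assert report.summary["n_candidates"] == len(fixture.records)
        assert (
            report.summary["n_accepted"] + report.summary["n_rejected"]
            == report.summary["n_candidates"]
        )
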