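"""Onset detection: epoching, channel voting, latency scoring, patient reports."""

import numpy as np
import pytest

from ictal.io import CHB_SAMPLING_RATE_HZ, EegRecord
from ictal.onset import (
    EpochDecision,
    OnsetConfig,
    OnsetDetector,
    detect_onset,
    epoch_matrix,
    evaluate_patient,
    train_test_split_counts,
    vote,
)
from ictal.synthdata import SynthSpec, generate_chb_like, generate_chb_patient


def make_decisions(declared_epochs, n_epochs=60, n_channels=23):
    out = []
    for k in range(n_epochs):
        votes = np.zeros(n_channels, dtype=bool)
        if k in declared_epochs:
            votes[:] = True
        out.append(EpochDecision(k, votes))
    return out


@pytest.fixture(scope="module")
def record():
    return generate_chb_like(
        SynthSpec(
            mode="chb_record", seed=4, n_channels=23,
            sampling_rate_hz=CHB_SAMPLING_RATE_HZ, duration_s=10.0,
        )
    )


class TestEpochMatrix:

    def test_shape_epochs_by_channels_by_twenty(self, record):
        mat = epoch_matrix(record)
        assert mat.shape == (10, 23, 20)

    def test_single_channel_record_accepted(self):
        rec = generate_chb_like(
            SynthSpec(mode="chb_record", seed=9, n_channels=1,
                      sampling_rate_hz=256.0, duration_s=5.0)
        )
        assert epoch_matrix(rec).shape == (5, 1, 20)

    def test_truncation_is_causal(self, record):
        full = epoch_matrix(record)
        short = EegRecord(
            samples=record.samples[:, : 5 * 256],
            sampling_rate_hz=record.sampling_rate_hz,
            channel_labels=record.channel_labels,
        )
        np.testing.assert_array_equal(epoch_matrix(short), full[:5])

    def test_subsecond_record_rejected(self):
        rec = EegRecord(samples=np.ones((2, 100)), sampling_rate_hz=256.0)
        with pytest.raises(ValueError, match="shorter than one epoch"):
            epoch_matrix(rec)


class TestVote:
    def test_boundary_enumeration_over_23_channels(self):
        # independent oracle: direct fraction comparison for every k
        for k in range(24):
            votes = [1] * k + [0] * (23 - k)
            assert vote(votes) == (k / 23 >= 0.6)

    def test_fourteen_of_23_declares_thirteen_does_not(self):
        assert vote([1] * 14 + [0] * 9) is True
        assert vote([1] * 13 + [0] * 10) is False

    def test_unanimous_and_empty_votes(self):
        assert vote(np.ones(23)) is True
        assert vote(np.zeros(23)) is False
        with pytest.raises(ValueError, match="zero channels"):
            vote(np.array([]))

    def test_monotone_in_positive_votes(self):
        votes = np.zeros(23, dtype=int)
        declared = []
        for k in range(24):
            declared.append(vote(votes))
            if k < 23:
                votes[k] = 1
        # once declared, adding positive votes never undeclares
        first_true = declared.index(True)
        assert all(declared[first_true:])

    def test_single_channel_vote_is_that_channel(self):
        assert vote([1]) is True
        assert vote([0]) is False


class TestDetectOnset:
    def test_declaration_at_onset_gives_zero_latency(self):
        decs = make_decisions(declared_epochs=set(range(20, 35)))
        ev = detect_onset(decs, 20.0, (20.0, 35.0))
        assert ev.detected and ev.latency_s == 0.0

    def test_three_epoch_delay_gives_three_seconds(self):
        decs = make_decisions(declared_epochs=set(range(23, 35)))
        ev = detect_onset(decs, 20.0, (20.0, 35.0))
        assert ev.latency_s == 3.0

    def test_no_declaration_means_undetected(self):
        decs = make_decisions(declared_epochs=set())
        ev = detect_onset(decs, 20.0, (20.0, 35.0))
        assert not ev.detected and ev.latency_s is None and ev.detected_onset_s is None

    def test_declarations_before_onset_do_not_count(self):
        decs = make_decisions(declared_epochs={5, 6, 25})
        ev = detect_onset(decs, 20.0, (20.0, 35.0))
        assert ev.latency_s == 5.0

    def test_earlier_annotation_increases_latency_linearly(self):
        decs = make_decisions(declared_epochs={30})
        base = detect_onset(decs, 25.0, (25.0, 40.0)).latency_s
        for k in (1, 3, 5):
            shifted = detect_onset(decs, 25.0 - k, (25.0 - k, 40.0)).latency_s
            assert shifted == base + k

    def test_annotation_outside_record_rejected(self):
        decs = make_decisions(declared_epochs=set(), n_epochs=30)
        with pytest.raises(ValueError, match="outside"):
            detect_onset(decs, 99.0, (99.0, 120.0))


class TestSplitRule:
    @pytest.mark.parametrize("n,expected", [
        (16, (10, 6)),
        (3, (2, 1)),
        (7, (5, 2)),
        (40, (24, 16)),
        (18, (11, 7)),
        (10, (6, 4)),
    ])
    def test_sixty_percent_ceiling_rule(self, n, expected):
        assert train_test_split_counts(n) == expected

    def test_at_least_one_test_seizure(self):
        with pytest.raises(ValueError):
            train_test_split_counts(1)
        assert train_test_split_counts(2) == (1, 1)


class TestPatientEvaluation:
    def test_unmistakable_seizures_are_all_detected_quickly(self, chb_patient):
        report = evaluate_patient(chb_patient, patient_id="p01",
                                  config=OnsetConfig(seed=3))
        assert report.n_train_seizures == 3 and report.n_test_seizures == 2
        assert report.sensitivity_pct == 100.0
        assert report.mean_latency_s <= 1.0
        assert 0.0 <= report.false_detection_pct <= 100.0

    def test_fixed_seed_gives_identical_report(self, chb_patient):
        r1 = evaluate_patient(chb_patient, patient_id="p01", config=OnsetConfig(seed=3))
        r2 = evaluate_patient(chb_patient, patient_id="p01", config=OnsetConfig(seed=3))
        assert r1.to_json() == r2.to_json()

    def test_explicit_train_count_override(self, chb_patient):
        report = evaluate_patient(
            chb_patient, patient_id="p01",
            config=OnsetConfig(seed=3, n_train_seizures=4),
        )
        assert report.n_train_seizures == 4 and report.n_test_seizures == 1

    def test_single_seizure_patient_rejected(self):
        records = generate_chb_patient("p9", n_seizures=1, seed=5)
        with pytest.raises(ValueError, match="at least 2"):
            OnsetDetector(records).fit()

    def test_mismatched_channel_counts_rejected(self):
        a = generate_chb_like(SynthSpec(mode="chb_record", seed=1, n_channels=4,
                                        sampling_rate_hz=256.0, duration_s=5.0))
        b = generate_chb_like(SynthSpec(mode="chb_record", seed=2, n_channels=5,
                                        sampling_rate_hz=256.0, duration_s=5.0))
        with pytest.raises(ValueError, match="channel count"):
            OnsetDetector([a, b])

    def test_report_json_carries_per_seizure_latencies(self, chb_patient):
        report = evaluate_patient(chb_patient, patient_id="p01",
                                  config=OnsetConfig(seed=3))
        d = report.to_dict()
        assert len(d["seizures"]) == report.n_test_seizures
        for s in d["seizures"]:
            assert s["detected"] is True
            assert s["latency_s"] >= 0.0

    def test_annotation_sidecar_attachment(self, chb_patient):
        bare = [
            EegRecord(samples=r.samples, sampling_rate_hz=r.sampling_rate_hz,
                      channel_labels=r.channel_labels, record_id=r.record_id)
            for r in chb_patient
        ]
        sidecar = {r.record_id: list(r.annotations) for r in chb_patient if r.annotations}
        report = evaluate_patient(bare, sidecar, patient_id="p01",
                                  config=OnsetConfig(seed=3))
        assert report.sensitivity_pct == 100.0
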