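"""RBAC ledger semantics: registration, validated submission, quorum,
audit accounting, replay determinism and fuzzed invariants."""

import hashlib

import numpy as np
import pytest

from fedistill.trust_ledger import (
    REASON_ALREADY_REGISTERED, REASON_INVALID_ROLE, REASON_METADATA_MISMATCH,
    REASON_NOT_REGISTERED, REASON_ROUND_MISMATCH, REASON_STALE_TIMESTAMP,
    REASON_UNAUTHORIZED_ROLE, Ledger, SubmissionMetadata, canonical_payload,
    scripted_integrity_session,
)

PAYLOAD = canonical_payload(np.array([[0.8, 0.2], [0.25, 0.75]]))


def _meta(sender, ledger, declared=0.8, payload=PAYLOAD, round=None, ts=None):
    return SubmissionMetadata(
        sender=sender, round=ledger.current_round if round is None else round,
        declared_accuracy=declared,
        timestamp=ledger._clock + 1 if ts is None else ts, payload=payload)


@pytest.fixture()
def ledger():
    led = Ledger(quorum=2)
    led.register_client("0xprov", "model_provider")
    for i in range(3):
        led.register_client(f"0xval{i}", "validator")
    led.register_client("0xagg", "aggregator")
    return led


class TestRegistration:
    def test_fresh_address_accepted(self):
        led = Ledger()
        rec = led.register_client("0xa", "model_provider")
        assert rec.status == "accepted" and led.registered["0xa"] == "model_provider"

    def test_duplicate_registration_rejected(self):
        led = Ledger()
        led.register_client("0xa", "validator")
        rec = led.register_client("0xa", "validator")
        assert rec.status == "rejected" and rec.reason == REASON_ALREADY_REGISTERED

    def test_unknown_role_rejected(self):
        led = Ledger()
        rec = led.register_client("0xa", "admin")
        assert rec.status == "rejected" and rec.reason == REASON_INVALID_ROLE
        assert "0xa" not in led.registered


class TestSubmission:
    def test_unregistered_sender_rejected_with_contract_reason(self, ledger):
        rec = ledger.submit_model_update(_meta("0xintruder", ledger), 0.8)
        assert rec.status == "rejected"
        assert rec.reason == "Client not registered"

    def test_happy_path_logs_sha256_digest(self, ledger):
        rec = ledger.submit_model_update(_meta("0xprov", ledger), 0.8)
        assert rec.status == "accepted"
        assert rec.payload_hash == hashlib.sha256(PAYLOAD).hexdigest()
        assert len(rec.payload_hash) == 64
        assert all(c in "0123456789abcdef" for c in rec.payload_hash)

    def test_rejection_reason_is_first_failing_check(self, ledger):
        # wrong role comes before round / metadata problems
        rec = ledger.submit_model_update(
            _meta("0xval0", ledger, declared=0.99, round=5), 0.1)
        assert rec.reason == REASON_UNAUTHORIZED_ROLE
        rec = ledger.submit_model_update(_meta("0xprov", ledger, round=5), 0.8)
        assert rec.reason == REASON_ROUND_MISMATCH

    def test_inflated_accuracy_is_a_metadata_mismatch(self, ledger):
        rec = ledger.submit_model_update(_meta("0xprov", ledger, declared=0.99), 0.70)
        assert rec.status == "rejected" and rec.reason == REASON_METADATA_MISMATCH

    def test_stale_timestamp_replay_rejected(self, ledger):
        first = ledger.submit_model_update(_meta("0xprov", ledger, ts=100), 0.8)
        assert first.status == "accepted"
        rec = ledger.submit_model_update(_meta("0xprov", ledger, ts=100), 0.8)
        assert rec.reason == REASON_STALE_TIMESTAMP

    def test_malformed_payload_rejected(self, ledger):
        bad = b'{"probs":[["0.9","0.5"]]}'  # rows do not sum to 1
        rec = ledger.submit_model_update(_meta("0xprov", ledger, payload=bad), 0.8)
        assert rec.status == "rejected" and rec.reason == "malformed payload"

    def test_accuracy_within_tolerance_accepted(self, ledger):
        rec = ledger.submit_model_update(_meta("0xprov", ledger, declared=0.8),
                                         0.8 + 5e-7, tolerance=1e-6)
        assert rec.status == "accepted"


class TestQuorum:
    def _accepted_update(self, ledger):
        return ledger.submit_model_update(_meta("0xprov", ledger), 0.8)

    def test_below_quorum_not_eligible(self, ledger):
        rec = self._accepted_update(ledger)
        ledger.validator_approve(rec.index, "0xval0")
        assert not ledger.is_aggregation_eligible(rec.index)

    def test_at_quorum_eligible(self, ledger):
        rec = self._accepted_update(ledger)
        ledger.validator_approve(rec.index, "0xval0")
        ledger.validator_approve(rec.index, "0xval1")
        assert ledger.is_aggregation_eligible(rec.index)

    def test_duplicate_validator_counts_once(self, ledger):
        rec = self._accepted_update(ledger)
        ledger.validator_approve(rec.index, "0xval0")
        ledger.validator_approve(rec.index, "0xval0")
        assert not ledger.is_aggregation_eligible(rec.index)

    def test_non_validator_approval_rejected(self, ledger):
        rec = self._accepted_update(ledger)
        out = ledger.validator_approve(rec.index, "0xprov")
        assert out.status == "rejected"
        assert not ledger.is_aggregation_eligible(rec.index)


class TestAudit:
    def test_scripted_session_reproduces_integrity_accounting(self):
        report = scripted_integrity_session().audit_report()
        assert report["total"] == 212
        assert report["valid"] == 201
        assert report["rejected"] == 11
        assert report["rejection_rate"] == 5.19
        assert report["valid_success_rate"] == 100.0
        by = report["rejected_by_reason"]
        assert by["Client not registered"] == 6
        assert by[REASON_METADATA_MISMATCH] == 3
        assert by[REASON_INVALID_ROLE] == 2

    def test_empty_log_is_all_zero(self):
        report = Ledger().audit_report()
        assert report["total"] == report["valid"] == report["rejected"] == 0

    def test_reason_counts_sum_to_rejected(self, ledger):
        ledger.submit_model_update(_meta("0xghost", ledger), 0.5)
        ledger.register_client("0xprov", "model_provider")
        report = ledger.audit_report()
        assert sum(report["rejected_by_reason"].values()) == report["rejected"]
        assert report["valid"] + report["rejected"] == report["total"]


class TestReplayAndIntegrity:
    def test_identical_sequences_give_byte_identical_logs(self, tmp_path):
        logs = []
        for _ in range(2):
            led = scripted_integrity_session()
            path = tmp_path / f"log{_}.jsonl"
            led.write_log(path)
            logs.append(path.read_bytes())
        assert logs[0] == logs[1]

    def test_log_round_trip_preserves_records(self, tmp_path):
        led = scripted_integrity_session()
        path = tmp_path / "log.jsonl"
        led.write_log(path)
        records = Ledger.read_log(path)
        assert records == led.log
        assert Ledger.audit_from_log(records) == led.audit_report()

    def test_single_byte_tamper_changes_digest(self):
        tampered = bytearray(PAYLOAD)
        tampered[10] ^= 1
        assert hashlib.sha256(PAYLOAD).hexdigest() \
            != hashlib.sha256(bytes(tampered)).hexdigest()

    def test_fuzzed_sequences_preserve_log_invariants(self):
        rng = np.random.default_rng(99)
        addresses = [f"0x{i}" for i in range(8)]
        roles = ["model_provider", "validator", "aggregator", "admin"]
        for trial in range(50):
            led = Ledger(quorum=2)
            for _ in range(30):
                op = rng.integers(0, 4)
                addr = addresses[rng.integers(0, len(addresses))]
                if op == 0:
                    led.register_client(addr, roles[rng.integers(0, len(roles))])
                elif op == 1:
                    led.submit_model_update(
                        _meta(addr, led, declared=round(float(rng.random()), 3)),
                        recomputed_accuracy=round(float(rng.random()), 3))
                elif op == 2:
                    led.validator_approve(int(rng.integers(0, 30)), addr)
                else:
                    led.query(addr)
            # invariants: dense increasing indices, conservation, RBAC
            indices = [r.index for r in led.log]
            assert indices == list(range(len(led.log)))
            report = led.audit_report()
            assert report["valid"] + report["rejected"] == report["total"]
            for rec in led.log:
                if rec.kind == "model_update" and rec.status == "accepted":
                    assert led.registered.get(rec.sender) == "model_provider"
                if rec.status == "rejected":
                    assert rec.reason
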