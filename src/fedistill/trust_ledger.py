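"""Deterministic in-process permissioned-ledger simulator.

Models the access-control semantics of a role-based smart contract:
client registration, role assignment, validated model-update submission
with SHA-256 payload hashing, multi-validator quorum approval, authorized
queries, and audit analytics over the append-only transaction log.

This is a desk-scale simulator of the contract's *semantics* — which
submissions are accepted, which are rejected and why, and what the audit
trail records — not a chain client: there is no EVM, consensus or gas
accounting.  Every failure is recorded as a rejected transaction rather
than raised, mirroring how a contract reverts with a reason string.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

ROLES = ("model_provider", "validator", "aggregator")
KINDS = ("register", "assign_role", "model_update", "aggregate", "query", "approve")

# Canonical rejection reasons (first failing check wins, in contract order).
REASON_NOT_REGISTERED = "Client not registered"
REASON_ALREADY_REGISTERED = "already registered"
REASON_INVALID_ROLE = "invalid role"
REASON_UNAUTHORIZED_ROLE = "unauthorized role"
REASON_ROUND_MISMATCH = "round mismatch"
REASON_STALE_TIMESTAMP = "stale timestamp"
REASON_METADATA_MISMATCH = "metadata mismatch"
REASON_MALFORMED_PAYLOAD = "malformed payload"
REASON_NOT_VALIDATOR = "not a validator"
REASON_UNKNOWN_TX = "unknown transaction"


@dataclass(frozen=True)
class TransactionRecord:
    index: int
    kind: str
    sender: str
    status: str                      # "accepted" | "rejected"
    reason: str = ""
    payload_hash: str = ""
    round: int = -1
    declared_accuracy: float | None = None
    timestamp: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        if d["declared_accuracy"] is not None:
            d["declared_accuracy"] = repr(float(d["declared_accuracy"]))
        return json.dumps(d, sort_keys=True, separators=(",", ":"))


@dataclass
class SubmissionMetadata:
    sender: str
    round: int
    declared_accuracy: float
    timestamp: int
    payload: bytes

    def __post_init__(self) -> None:
        if not (0.0 <= self.declared_accuracy <= 1.0):
            raise ValueError("declared_accuracy must lie in [0, 1]")


def canonical_payload(probs: np.ndarray) -> bytes:
    """Platform-stable byte serialization of a soft-label matrix.

    JSON with sorted keys and ``repr`` float formatting, so the SHA-256
    digest is identical across runs and machines for identical doubles.
    """
    rows = [[repr(float(p)) for p in row] for row in np.asarray(probs, dtype=float)]
    return json.dumps({"probs": rows}, sort_keys=True,
                      separators=(",", ":")).encode("ascii")


class Ledger:
    """Append-only RBAC transaction log with quorum-gated aggregation.

    The six exposed contract functions are ``register_client``,
    ``assign_role``, ``submit_model_update``, ``validator_approve``,
    ``mark_aggregated`` and ``query``.
    """

    def __init__(self, quorum: int = 2):
        if quorum < 1:
            raise ValueError("quorum must be >= 1")
        self.registered: dict[str, str] = {}
        self.log: list[TransactionRecord] = []
        self.current_round: int = 0
        self.quorum: int = quorum
        self._clock: int = 0
        self._approvals: dict[int, set[str]] = {}
        self._last_accepted_ts: dict[str, int] = {}

    # -- internal -----------------------------------------------------------

    def _append(self, kind: str, sender: str, accepted: bool, reason: str = "",
                payload_hash: str = "", round: int = -1,
                declared_accuracy: float | None = None) -> TransactionRecord:
        self._clock += 1
        rec = TransactionRecord(
            index=len(self.log), kind=kind, sender=sender,
            status="accepted" if accepted else "rejected",
            reason="" if accepted else reason, payload_hash=payload_hash,
            round=round, declared_accuracy=declared_accuracy,
            timestamp=self._clock)
        self.log.append(rec)
        return rec

    # -- contract functions -------------------------------------------------

    @property
    def validator_set(self) -> set[str]:
        return {a for a, r in self.registered.items() if r == "validator"}

    def register_client(self, address: str, role: str) -> TransactionRecord:
        if role not in ROLES:
            return self._append("register", address, False, REASON_INVALID_ROLE)
        if address in self.registered:
            return self._append("register", address, False, REASON_ALREADY_REGISTERED)
        self.registered[address] = role
        return self._append("register", address, True)

    def assign_role(self, address: str, role: str) -> TransactionRecord:
        if address not in self.registered:
            return self._append("assign_role", address, False, REASON_NOT_REGISTERED)
        if role not in ROLES:
            return self._append("assign_role", address, False, REASON_INVALID_ROLE)
        self.registered[address] = role
        return self._append("assign_role", address, True)

    def submit_model_update(self, meta: SubmissionMetadata,
                            recomputed_accuracy: float,
                            tolerance: float = 1e-6) -> TransactionRecord:
        """Validate a soft-label submission; checks run in contract order:
        identity -> role -> round -> timestamp -> metadata -> payload."""
        kw = dict(round=meta.round, declared_accuracy=meta.declared_accuracy)
        if meta.sender not in self.registered:
            return self._append("model_update", meta.sender, False,
                                REASON_NOT_REGISTERED, **kw)
        if self.registered[meta.sender] != "model_provider":
            return self._append("model_update", meta.sender, False,
                                REASON_UNAUTHORIZED_ROLE, **kw)
        if meta.round != self.current_round:
            return self._append("model_update", meta.sender, False,
                                REASON_ROUND_MISMATCH, **kw)
        if meta.timestamp <= self._last_accepted_ts.get(meta.sender, -1):
            return self._append("model_update", meta.sender, False,
                                REASON_STALE_TIMESTAMP, **kw)
        if abs(meta.declared_accuracy - recomputed_accuracy) > tolerance:
            return self._append("model_update", meta.sender, False,
                                REASON_METADATA_MISMATCH, **kw)
        if not self._payload_valid(meta.payload):
            return self._append("model_update", meta.sender, False,
                                REASON_MALFORMED_PAYLOAD, **kw)
        digest = hashlib.sha256(meta.payload).hexdigest()
        self._last_accepted_ts[meta.sender] = meta.timestamp
        rec = self._append("model_update", meta.sender, True,
                           payload_hash=digest, **kw)
        self._approvals[rec.index] = set()
        return rec

    @staticmethod
    def _payload_valid(payload: bytes) -> bool:
        try:
            rows = json.loads(payload.decode("ascii"))["probs"]
            probs = np.asarray([[float(v) for v in row] for row in rows], dtype=float)
        except (ValueError, KeyError, TypeError, UnicodeDecodeError):
            return False
        if probs.ndim != 2 or probs.size == 0:
            return False
        return bool((probs >= -1e-12).all()
                    and np.abs(probs.sum(axis=1) - 1.0).max() <= 1e-9)

    def validator_approve(self, tx_index: int, validator_address: str) -> TransactionRecord:
        if validator_address not in self.registered \
                or self.registered[validator_address] != "validator":
            return self._append("approve", validator_address, False, REASON_NOT_VALIDATOR)
        if tx_index not in self._approvals:
            return self._append("approve", validator_address, False, REASON_UNKNOWN_TX)
        self._approvals[tx_index].add(validator_address)  # set semantics: once each
        return self._append("approve", validator_address, True)

    def is_aggregation_eligible(self, tx_index: int) -> bool:
        return len(self._approvals.get(tx_index, set())) >= self.quorum

    def mark_aggregated(self, sender: str, round: int) -> TransactionRecord:
        if sender not in self.registered:
            return self._append("aggregate", sender, False, REASON_NOT_REGISTERED,
                                round=round)
        if self.registered[sender] != "aggregator":
            return self._append("aggregate", sender, False, REASON_UNAUTHORIZED_ROLE,
                                round=round)
        rec = self._append("aggregate", sender, True, round=round)
        self.current_round = round + 1
        return rec

    def query(self, sender: str) -> TransactionRecord:
        """Read access to the audit trail; unregistered addresses are refused."""
        if sender not in self.registered:
            return self._append("query", sender, False, REASON_NOT_REGISTERED)
        return self._append("query", sender, True)

    # -- analytics and persistence ------------------------------------------

    def audit_report(self) -> dict:
        """Integrity accounting derived solely from the log."""
        total = len(self.log)
        rejected = [r for r in self.log if r.status == "rejected"]
        by_reason: dict[str, int] = {}
        for r in rejected:
            by_reason[r.reason] = by_reason.get(r.reason, 0) + 1
        n_rej = len(rejected)
        return {
            "total": total,
            "valid": total - n_rej,
            "rejected": n_rej,
            "rejected_by_reason": by_reason,
            "rejection_rate": round(100.0 * n_rej / total, 2) if total else 0.0,
            "valid_success_rate": 100.0 if total else 0.0,
        }

    def write_log(self, path: str | Path) -> None:
        Path(path).write_text("".join(rec.to_json() + "\n" for rec in self.log))

    @staticmethod
    def read_log(path: str | Path) -> list[TransactionRecord]:
        records = []
        for line in Path(path).read_text().splitlines():
            d = json.loads(line)
            if d.get("declared_accuracy") is not None:
                d["declared_accuracy"] = float(d["declared_accuracy"])
            records.append(TransactionRecord(**d))
        return records

    @staticmethod
    def audit_from_log(records: list[TransactionRecord]) -> dict:
        ledger = Ledger.__new__(Ledger)
        ledger.log = list(records)
        return Ledger.audit_report(ledger)


def scripted_integrity_session(quorum: int = 2) -> Ledger:
    """Replay a deterministic 212-transaction contract session.

    The session registers 5 model providers, 1 aggregator and 3 validators,
    then runs multi-round submission/approval/aggregation traffic with
    exactly three kinds of violation mixed in: 6 unauthorized queries from
    unregistered addresses, 3 malicious submissions whose declared accuracy
    contradicts the recomputed one, and 2 invalid-role updates — 201
    accepted and 11 rejected transactions in total.
    """
    ledger = Ledger(quorum=quorum)
    providers = [f"0xprovider{i}" for i in range(1, 6)]
    validators = [f"0xvalidator{i}" for i in range(1, 4)]
    aggregator = "0xaggregator"
    for addr in providers:
        ledger.register_client(addr, "model_provider")
    for addr in validators:
        ledger.register_client(addr, "validator")
    ledger.register_client(aggregator, "aggregator")                # 9 accepted

    payload = canonical_payload(np.array([[0.8, 0.2], [0.3, 0.7]]))
    accepted_updates: list[int] = []

    def submit(addr: str, declared: float, recomputed: float) -> TransactionRecord:
        meta = SubmissionMetadata(sender=addr, round=ledger.current_round,
                                  declared_accuracy=declared,
                                  timestamp=ledger._clock + 1, payload=payload)
        return ledger.submit_model_update(meta, recomputed_accuracy=recomputed)

    # 12 clean rounds: 5 submissions + 10 approvals + 1 aggregation each = 192
    for rnd in range(12):
        for addr in providers:
            rec = submit(addr, 0.8, 0.8)
            accepted_updates.append(rec.index)
        for tx in accepted_updates[-5:]:
            for v in validators[:2]:
                ledger.validator_approve(tx, v)
        ledger.mark_aggregated(aggregator, rnd)

    # Violations interleaved with legitimate queries.
    for i in range(6):                                              # unauthorized
        ledger.query(f"0xintruder{i}")
    for i in range(3):                                              # malicious
        submit(providers[i], declared=0.99, recomputed=0.70)
    ledger.register_client("0xnewcomer", "admin")                   # invalid role
    ledger.assign_role(providers[0], "superuser")                   # invalid role
    return ledger
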