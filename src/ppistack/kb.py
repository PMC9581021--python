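"""Annotation knowledge base.

Per-protein annotation records (GO terms by branch, domains, pathways,
amino-acid sequence) are canonicalized, content-hashed and kept in an
:class:`AnnotationStore` so that feature generation over the same proteins
in later experiments reuses prior work instead of re-ingesting.

Records travel as flat JSON objects (one per protein, JSON-lines on disk)
with keys ``id, go_bp, go_mf, go_cc, domains, pathways, sequence``.
Set-valued fields are arrays; order never matters because the content hash
is computed over a canonical serialization with sorted members.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

logger = logging.getLogger(__name__)

#: Fixed field order of the canonical serialization. Changing this changes
#: every content hash, so it is part of the on-disk format contract.
CANONICAL_FIELDS = ("id", "go_bp", "go_mf", "go_cc", "domains", "pathways", "sequence")

SET_FIELDS = ("go_bp", "go_mf", "go_cc", "domains", "pathways")


class MissingAccessionError(ValueError):
    """Raised when a raw record carries no usable accession."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein's processed annotations.

    ``content_hash`` is a SHA-256 hex digest of the canonical serialization
    (fixed field order, lexicographically sorted set members, UTF-8); it is
    deterministic across processes and insensitive to input ordering.
    """

    id: str
    go_bp: frozenset[str] = frozenset()
    go_mf: frozenset[str] = frozenset()
    go_cc: frozenset[str] = frozenset()
    domains: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()
    sequence: str = ""
    content_hash: str = ""

    def canonical_serialization(self) -> str:
        payload = {
            "id": self.id,
            "go_bp": sorted(self.go_bp),
            "go_mf": sorted(self.go_mf),
            "go_cc": sorted(self.go_cc),
            "domains": sorted(self.domains),
            "pathways": sorted(self.pathways),
            "sequence": self.sequence,
        }
        return json.dumps(payload, separators=(",", ":"), sort_keys=False)

    def to_json(self) -> dict:
        return {
            "id": self.id,
            "go_bp": sorted(self.go_bp),
            "go_mf": sorted(self.go_mf),
            "go_cc": sorted(self.go_cc),
            "domains": sorted(self.domains),
            "pathways": sorted(self.pathways),
            "sequence": self.sequence,
        }


def compute_content_hash(record: ProteinRecord) -> str:
    """SHA-256 hex digest of the record's canonical serialization."""
    return hashlib.sha256(record.canonical_serialization().encode("utf-8")).hexdigest()


def canonicalize(raw: Mapping) -> ProteinRecord:
    """Build a canonical :class:`ProteinRecord` from a raw mapping.

    Unknown keys are ignored; absent annotation fields become empty sets.
    Raises :class:`MissingAccessionError` if no accession is present.
    """
    accession = raw.get("id") or raw.get("accession")
    if not accession or not str(accession).strip():
        raise MissingAccessionError(
            f"record without accession rejected: {dict(raw)!r}"
        )
    kwargs = {}
    for name in SET_FIELDS:
        value = raw.get(name) or ()
        if isinstance(value, str):  # tolerate a single bare identifier
            value = (value,)
        kwargs[name] = frozenset(str(v) for v in value)
    record = ProteinRecord(
        id=str(accession).strip(),
        sequence=str(raw.get("sequence") or ""),
        **kwargs,
    )
    object.__setattr__(record, "content_hash", compute_content_hash(record))
    return record


def is_stale(local_hash: str, remote_hash: str) -> bool:
    """True iff the two content digests differ (record needs re-ingest)."""
    return local_hash != remote_hash


@dataclass
class AnnotationStore:
    """In-memory map accession -> :class:`ProteinRecord` with provenance.

    Ingesting an identical record is a no-op (observable through the
    provenance timestamps, which the workflow uses to verify reuse).
    """

    records: dict[str, ProteinRecord] = field(default_factory=dict)
    provenance: dict[str, tuple[str, float]] = field(default_factory=dict)
    ingest_count: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def ingest_record(self, raw: Mapping, source: str = "local") -> ProteinRecord:
        """Canonicalize ``raw`` and store it; idempotent on identical content."""
        record = canonicalize(raw)
        existing = self.records.get(record.id)
        if existing is not None and existing.content_hash == record.content_hash:
            return existing
        self.records[record.id] = record
        self.provenance[record.id] = (source, time.time())
        self.ingest_count += 1
        return record

    def ingest_many(self, raws: Iterable[Mapping], source: str = "local") -> int:
        n = 0
        for raw in raws:
            self.ingest_record(raw, source=source)
            n += 1
        return n

    def get(self, accession: str) -> Optional[ProteinRecord]:
        """The record for ``accession``, or None as an explicit absent marker.

        Absence is distinct from a record with empty annotation sets:
        downstream scorers log missing inputs instead of silently scoring
        empty sets.
        """
        return self.records.get(accession)

    def query_features(self, accession: str) -> Optional[ProteinRecord]:
        record = self.records.get(accession)
        if record is None:
            logger.warning("annotation missing for accession %s", accession)
        return record

    # -- persistence: directory of <accession>.json plus an index file -----

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index = {}
        for accession, record in sorted(self.records.items()):
            (directory / f"{accession}.json").write_text(
                json.dumps(record.to_json(), indent=1)
            )
            index[accession] = record.content_hash
        (directory / "index.json").write_text(json.dumps(index, indent=1, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "AnnotationStore":
        directory = Path(directory)
        store = cls()
        index_path = directory / "index.json"
        index = json.loads(index_path.read_text()) if index_path.exists() else {}
        for accession in sorted(index):
            raw = json.loads((directory / f"{accession}.json").read_text())
            record = store.ingest_record(raw, source=str(directory))
            if record.content_hash != index[accession]:
                logger.warning(
                    "stored hash mismatch for %s: stale on-disk index", accession
                )
        return store


def read_records_jsonl(path: str | Path) -> Iterator[dict]:
    """Yield raw record dicts from a JSON-lines annotation file."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc


def write_records_jsonl(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for record in records:
            handle.write(json.dumps(record.to_json()) + "\n")
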