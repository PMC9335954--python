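"""Versioned, append-only persistence of patient phenotype records.

Each save writes a *full snapshot* of the patient's annotation set as a new,
immutable record version — the analogue of a structured data element in a
clinical chart.  Snapshots make the "all terms at once, across encounters"
view trivial, while per-encounter changes are still recoverable by diffing
consecutive versions.

On disk the store is one directory per patient with one canonical-JSON file
per version (zero-padded filenames), so the history is inspectable with
ordinary shell tools and append-only by construction.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import NamedTuple

from .annotation import (AnnotationCart, CartDiff, PhenotypeAnnotation, blocking_issues,
                         diff_carts, iso_utc, validate_cart)
from .errors import (RecordSchemaError, RecordVersionError, StoreConflictError,
                     StoreLookupError, ValidationBlockedError)
from .ontology import Ontology

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class PatientPhenotypeRecord:
    patient_id: str
    record_version: int
    saved_at: str  # ISO 8601 UTC
    ontology_version: str
    annotations: tuple[PhenotypeAnnotation, ...]


def serialize_record(record: PatientPhenotypeRecord) -> str:
    """Canonical JSON: UTF-8 text, sorted keys, no insignificant whitespace.

    Canonical form means structurally equal records serialize to identical
    bytes, and serialize∘parse∘serialize is a fixpoint — byte equality can
    stand in for record equality downstream.
    """
    payload = {
        "patient_id": record.patient_id,
        "record_version": record.record_version,
        "saved_at": record.saved_at,
        "ontology_version": record.ontology_version,
        "schema_version": SCHEMA_VERSION,
        "terms": [
            {
                "id": a.term_id,
                "name": a.term_name,
                "negated": a.negated,
                "comment": a.comment,
                "added_at": a.added_at,
            }
            for a in record.annotations
        ],
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


_REQUIRED_KEYS = ("patient_id", "record_version", "saved_at",
                  "ontology_version", "schema_version", "terms")
_REQUIRED_TERM_KEYS = ("id", "name", "negated", "comment", "added_at")


def parse_record(payload: str) -> PatientPhenotypeRecord:
    """Inverse of :func:`serialize_record`, with schema checking."""
    try:
        data = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise RecordSchemaError(f"payload is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise RecordSchemaError("payload must be a JSON object")
    for key in _REQUIRED_KEYS:
        if key not in data:
            raise RecordSchemaError(f"payload is missing required key {key!r}")
    if data["schema_version"] != SCHEMA_VERSION:
        raise RecordVersionError(
            f"unsupported schema_version {data['schema_version']!r}; "
            f"expected {SCHEMA_VERSION!r}")
    annotations = []
    for i, term in enumerate(data["terms"]):
        for key in _REQUIRED_TERM_KEYS:
            if key not in term:
                raise RecordSchemaError(f"terms[{i}] is missing required key {key!r}")
        annotations.append(PhenotypeAnnotation(
            term_id=term["id"],
            term_name=term["name"],
            negated=bool(term["negated"]),
            comment=term["comment"],
            added_at=term["added_at"],
            ontology_version=data["ontology_version"],
        ))
    return PatientPhenotypeRecord(
        patient_id=data["patient_id"],
        record_version=int(data["record_version"]),
        saved_at=data["saved_at"],
        ontology_version=data["ontology_version"],
        annotations=tuple(annotations),
    )


class HistoryEntry(NamedTuple):
    record_version: int
    saved_at: str
    term_count: int
    diff: CartDiff  # vs the previous version (vs empty for version 1)


def _encode_patient_dir(patient_id: str) -> str:
    # patient ids are opaque text; keep directory names filesystem-safe
    return re.sub(r"[^A-Za-z0-9._-]", lambda m: f"%{ord(m.group(0)):02X}", patient_id)


class RecordStore:
    """Directory-backed, append-only store of per-patient record histories."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _patient_dir(self, patient_id: str) -> Path:
        return self.root / _encode_patient_dir(patient_id)

    def _version_path(self, patient_id: str, version: int) -> Path:
        return self._patient_dir(patient_id) / f"{version:06d}.json"

    def versions(self, patient_id: str) -> list[int]:
        pdir = self._patient_dir(patient_id)
        if not pdir.is_dir():
            return []
        out = []
        for name in os.listdir(pdir):
            if name.endswith(".json") and name[:-5].isdigit():
                out.append(int(name[:-5]))
        return sorted(out)

    def save_record(self, cart: AnnotationCart, ontology: Ontology,
                    now: datetime | None = None) -> PatientPhenotypeRecord:
        """Append a new full-snapshot record for the cart's patient.

        The cart must pass validation with no blocking issues.  The new
        record gets version ``latest + 1`` (1 for a first save); a version
        collision with a concurrent writer raises rather than silently
        letting the last writer win.
        """
        issues = blocking_issues(validate_cart(cart, ontology))
        if issues:
            raise ValidationBlockedError(issues)
        existing = self.versions(cart.patient_id)
        version = (existing[-1] if existing else 0) + 1
        record = PatientPhenotypeRecord(
            patient_id=cart.patient_id,
            record_version=version,
            saved_at=iso_utc(now if now is not None else datetime.now(timezone.utc)),
            ontology_version=ontology.version_label,
            annotations=tuple(cart.items),
        )
        pdir = self._patient_dir(cart.patient_id)
        pdir.mkdir(parents=True, exist_ok=True)
        path = self._version_path(cart.patient_id, version)
        try:
            # O_EXCL makes the version claim atomic: a concurrent save of the
            # same version number fails instead of overwriting.
            with open(path, "x", encoding="utf-8") as fh:
                fh.write(serialize_record(record))
        except FileExistsError:
            raise StoreConflictError(
                f"record version {version} for patient {cart.patient_id!r} "
                "was saved concurrently") from None
        return record

    def load_record(self, patient_id: str,
                    version: int | None = None) -> PatientPhenotypeRecord:
        """Load one record; omit *version* for the latest snapshot."""
        versions = self.versions(patient_id)
        if not versions:
            raise StoreLookupError(f"no records for patient {patient_id!r}")
        if version is None:
            version = versions[-1]
        elif version not in versions:
            raise StoreLookupError(
                f"patient {patient_id!r} has no record version {version}")
        path = self._version_path(patient_id, version)
        return parse_record(path.read_text(encoding="utf-8"))

    def history(self, patient_id: str) -> list[HistoryEntry]:
        """Chronological history with per-version diffs vs the predecessor."""
        versions = self.versions(patient_id)
        if not versions:
            raise StoreLookupError(f"no records for patient {patient_id!r}")
        entries: list[HistoryEntry] = []
        previous: tuple[PhenotypeAnnotation, ...] = ()
        for version in versions:
            record = self.load_record(patient_id, version)
            entries.append(HistoryEntry(
                record_version=record.record_version,
                saved_at=record.saved_at,
                term_count=len(record.annotations),
                diff=diff_carts(previous, record.annotations),
            ))
            previous = record.annotations
        return entries
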