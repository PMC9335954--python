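"""The annotation "shopping cart": a working set of phenotype terms.

A clinician assembles phenotype annotations one term at a time — each with
an optional negation flag (the phenotype was explicitly absent) and a free
text comment (e.g. linked genes) — before committing the set to the patient
record.  The cart enforces one entry per term, resolves legacy identifiers
to current primary terms on entry, and snapshots the term name and ontology
version at add time so saved records stay interpretable as the ontology
evolves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime, timezone
from typing import Iterable, NamedTuple

from .errors import ObsoleteTermError, TermLookupError
from .ontology import Ontology, ResolutionStatus


def iso_utc(moment: datetime) -> str:
    """Render a timestamp as UTC ISO 8601 with seconds precision."""
    if moment.tzinfo is None:
        moment = moment.replace(tzinfo=timezone.utc)
    return moment.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass(frozen=True)
class PhenotypeAnnotation:
    term_id: str
    term_name: str          # snapshot at add time
    negated: bool = False
    comment: str | None = None
    added_at: str = ""      # ISO 8601 UTC
    ontology_version: str = ""


@dataclass(frozen=True)
class AnnotationCart:
    """An ordered, duplicate-free working set for one patient."""

    patient_id: str
    items: tuple[PhenotypeAnnotation, ...] = ()

    def term_ids(self) -> list[str]:
        return [a.term_id for a in self.items]

    def get(self, term_id: str) -> PhenotypeAnnotation | None:
        for item in self.items:
            if item.term_id == term_id:
                return item
        return None


@dataclass(frozen=True, order=True)
class ValidationIssue:
    kind: str  # unknown | obsolete | duplicate | redundant_ancestor
    term_id: str
    message: str


#: Issue kinds that block saving.  Redundancy (having both a term and one of
#: its ancestors) is deliberate clinical practice at times, so it only warns.
BLOCKING_KINDS = frozenset({"unknown", "obsolete", "duplicate"})


def add_term(cart: AnnotationCart, ontology: Ontology, term_id: str, *,
             negated: bool = False, comment: str | None = None,
             now: datetime | None = None) -> AnnotationCart:
    """Add (or update) a term in the cart.

    Alternate ids are accepted and stored under their primary id.  Obsolete
    ids are rejected; if a unique replacement exists the error suggests it,
    but the replacement is never substituted silently.  Re-adding a present
    term updates its negation/comment in place, preserving cart order.
    """
    resolution = ontology.resolve(term_id)
    if resolution.status is ResolutionStatus.UNKNOWN:
        raise TermLookupError(f"unknown term: {term_id}")
    if resolution.status is ResolutionStatus.OBSOLETE_UNREPLACED:
        raise ObsoleteTermError(term_id)
    if resolution.status is ResolutionStatus.OBSOLETE_REPLACED:
        raise ObsoleteTermError(term_id, replacement=resolution.primary)
    primary = resolution.primary
    term = ontology.terms[primary]
    stamp = iso_utc(now if now is not None else datetime.now(timezone.utc))
    annotation = PhenotypeAnnotation(
        term_id=primary,
        term_name=term.name,
        negated=negated,
        comment=comment,
        added_at=stamp,
        ontology_version=ontology.version_label,
    )
    items = list(cart.items)
    for i, existing in enumerate(items):
        if existing.term_id == primary:
            items[i] = annotation
            return replace(cart, items=tuple(items))
    items.append(annotation)
    return replace(cart, items=tuple(items))


class RemoveResult(NamedTuple):
    cart: AnnotationCart
    removed: bool  # False means the id was absent (warning, not an error)


def remove_term(cart: AnnotationCart, term_id: str) -> RemoveResult:
    """Remove a term; removing an absent id is a warning-flagged no-op."""
    items = [a for a in cart.items if a.term_id != term_id]
    if len(items) == len(cart.items):
        return RemoveResult(cart, False)
    return RemoveResult(replace(cart, items=tuple(items)), True)


def validate_cart(cart: AnnotationCart, ontology: Ontology) -> list[ValidationIssue]:
    """Quality-gate a cart before saving.

    Reports unknown, obsolete and duplicate term ids (blocking) and
    redundant ancestors — the cart holding both a term and one of its
    proper ancestors (warning only).  Issues are sorted by (kind, term id).
    """
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    active: list[str] = []
    for item in cart.items:
        if item.term_id in seen:
            issues.append(ValidationIssue("duplicate", item.term_id,
                                          f"{item.term_id} appears more than once"))
            continue
        seen.add(item.term_id)
        term = ontology.terms.get(item.term_id)
        if term is None:
            hint = ""
            if item.term_id in ontology.alt_index:
                hint = f" (alternate id of {ontology.alt_index[item.term_id]})"
            issues.append(ValidationIssue("unknown", item.term_id,
                                          f"{item.term_id} is not a primary term{hint}"))
        elif term.obsolete:
            issues.append(ValidationIssue("obsolete", item.term_id,
                                          f"{item.term_id} is obsolete"))
        else:
            active.append(item.term_id)
    active_set = set(active)
    for term_id in active:
        ancestors = ontology.ancestors(term_id)
        for anc in sorted(ancestors & active_set):
            issues.append(ValidationIssue(
                "redundant_ancestor", anc,
                f"{anc} is an ancestor of {term_id}, which is also in the cart"))
    # one issue per redundant ancestor, even if several descendants imply it
    deduped: dict[tuple[str, str], ValidationIssue] = {}
    for issue in issues:
        deduped.setdefault((issue.kind, issue.term_id), issue)
    return sorted(deduped.values(), key=lambda i: (i.kind, i.term_id))


def blocking_issues(issues: Iterable[ValidationIssue]) -> list[ValidationIssue]:
    return [i for i in issues if i.kind in BLOCKING_KINDS]


class CartDiff(NamedTuple):
    added: set[str]
    removed: set[str]
    modified: set[str]


def diff_carts(old: Iterable[PhenotypeAnnotation],
               new: Iterable[PhenotypeAnnotation]) -> CartDiff:
    """Set-wise difference between two annotation lists.

    ``modified`` holds term ids present in both whose negation flag or
    comment changed; timestamps are ignored.  The three sets are pairwise
    disjoint.
    """
    old_by_id = {a.term_id: a for a in old}
    new_by_id = {a.term_id: a for a in new}
    added = set(new_by_id) - set(old_by_id)
    removed = set(old_by_id) - set(new_by_id)
    modified = {
        tid for tid in set(old_by_id) & set(new_by_id)
        if (old_by_id[tid].negated, old_by_id[tid].comment)
        != (new_by_id[tid].negated, new_by_id[tid].comment)
    }
    return CartDiff(added=added, removed=removed, modified=modified)
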