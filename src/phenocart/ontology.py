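"""Parse an OBO-format ontology into an indexed in-memory DAG.

The Human Phenotype Ontology (HPO) and its siblings are distributed as OBO
flat files: a header followed by ``[Term]`` stanzas of ``tag: value`` lines.
This module parses the term-level subset of that format (names, definitions,
synonyms with scope, ``is_a`` parents, ``alt_id`` merges, obsolescence with
``replaced_by``/``consider``) and builds the indexes the rest of the package
needs: identifier resolution through alternate and obsolete ids, transitive
hierarchy traversal, per-term detail assembly, and ranked autocomplete
search.

The parser is prefix-agnostic: any ``PREFIX:digits`` CURIE works, so test
ontologies can use a toy prefix while production input is ``hpo.obo``.
"""

from __future__ import annotations

import graphlib
import re
import warnings
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple, TextIO

from .errors import GeneTableError, OboParseError, OntologyCycleError, TermLookupError

TERM_ID_RE = re.compile(r"^[A-Za-z]+:[0-9]+$")

SYNONYM_SCOPES = ("exact", "broad", "narrow", "related")


def is_term_id(value: str) -> bool:
    """True if *value* is a well-formed ``PREFIX:digits`` CURIE."""
    return bool(TERM_ID_RE.match(value))


def normalize_label(label: str) -> str:
    """Lowercase and collapse internal whitespace; punctuation is retained.

    This is the single normalization used by both autocomplete search and
    the dictionary-extraction index, so the two stay comparable.
    """
    return " ".join(label.split()).lower()


@dataclass(frozen=True)
class Synonym:
    label: str
    scope: str = "related"

    def __post_init__(self):
        if not self.label.strip():
            raise ValueError("synonym label must be non-empty")
        if self.scope not in SYNONYM_SCOPES:
            raise ValueError(f"unknown synonym scope {self.scope!r}")


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    name: str
    definition: str | None = None
    synonyms: tuple[Synonym, ...] = ()
    alt_ids: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()
    obsolete: bool = False
    replaced_by: tuple[str, ...] = ()
    consider: tuple[str, ...] = ()


class ResolutionStatus(str, Enum):
    PRIMARY = "primary"
    ALT = "alt"
    OBSOLETE_REPLACED = "obsolete_replaced"
    OBSOLETE_UNREPLACED = "obsolete_unreplaced"
    UNKNOWN = "unknown"


class Resolution(NamedTuple):
    primary: str
    status: ResolutionStatus


@dataclass(frozen=True)
class GeneAssociation:
    term_id: str
    gene_symbol: str
    gene_id: str = ""


@dataclass(frozen=True)
class TermDetails:
    id: str
    name: str
    definition: str | None
    synonyms: tuple[Synonym, ...]
    superclasses: tuple[tuple[str, str], ...]
    subclasses: tuple[tuple[str, str], ...]
    genes: tuple[str, ...]


class MatchKind(str, Enum):
    """Autocomplete tiers, best first."""

    NAME_PREFIX = "name_prefix"
    SYNONYM_PREFIX = "synonym_prefix"
    NAME_SUBSTRING = "name_substring"
    SYNONYM_SUBSTRING = "synonym_substring"


_TIER_ORDER = {
    MatchKind.NAME_PREFIX: 0,
    MatchKind.SYNONYM_PREFIX: 1,
    MatchKind.NAME_SUBSTRING: 2,
    MatchKind.SYNONYM_SUBSTRING: 3,
}


@dataclass(frozen=True)
class SearchHit:
    term_id: str
    matched_label: str
    match_kind: MatchKind
    rank: int


@dataclass
class Ontology:
    """A parsed ontology with its traversal and resolution indexes."""

    version_label: str = ""
    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    alt_index: dict[str, str] = field(default_factory=dict)
    children_index: dict[str, list[str]] = field(default_factory=dict)

    # ---- resolution -------------------------------------------------

    def resolve(self, term_id: str) -> Resolution:
        """Map any identifier to its current primary term.

        Alternate ids (merged terms) map to their primary; obsolete terms
        with exactly one ``replaced_by`` map to the replacement.  Unknown
        ids are echoed back with status ``unknown`` rather than raising, so
        resolution is total.  Resolution is idempotent: resolving the
        returned primary yields status ``primary``.
        """
        term = self.terms.get(term_id)
        if term is not None:
            if not term.obsolete:
                return Resolution(term_id, ResolutionStatus.PRIMARY)
            if len(term.replaced_by) == 1:
                return Resolution(term.replaced_by[0], ResolutionStatus.OBSOLETE_REPLACED)
            # zero or several candidate replacements: never guess
            return Resolution(term_id, ResolutionStatus.OBSOLETE_UNREPLACED)
        primary = self.alt_index.get(term_id)
        if primary is not None:
            return Resolution(primary, ResolutionStatus.ALT)
        return Resolution(term_id, ResolutionStatus.UNKNOWN)

    def _require_active(self, term_id: str) -> OntologyTerm:
        term = self.terms.get(term_id)
        if term is None or term.obsolete:
            raise TermLookupError(f"unknown or obsolete term: {term_id}")
        return term

    # ---- traversal --------------------------------------------------

    def ancestors(self, term_id: str, include_self: bool = False) -> set[str]:
        """Transitive closure over ``is_a`` parents."""
        return self._closure(term_id, include_self, lambda t: self.terms[t].parents)

    def descendants(self, term_id: str, include_self: bool = False) -> set[str]:
        """Transitive closure over the inverted ``is_a`` relation."""
        return self._closure(term_id, include_self, lambda t: self.children_index.get(t, ()))

    def _closure(self, term_id, include_self, step) -> set[str]:
        self._require_active(term_id)
        seen: set[str] = set()
        queue = deque(step(term_id))
        while queue:
            cur = queue.popleft()
            if cur in seen:
                continue
            seen.add(cur)
            queue.extend(step(cur))
        if include_self:
            seen.add(term_id)
        else:
            seen.discard(term_id)
        return seen

    # ---- details ----------------------------------------------------

    def term_details(self, term_id: str, genes: Iterable[GeneAssociation] = ()) -> TermDetails:
        """Assemble the Details-pane view of one term.

        Superclasses and subclasses are *direct* relations only, and the
        gene list contains only genes directly associated with this term —
        propagation up the hierarchy is the ranking module's job.
        """
        term = self._require_active(term_id)
        supers = sorted((p, self.terms[p].name) for p in term.parents)
        subs = sorted((c, self.terms[c].name) for c in self.children_index.get(term_id, ()))
        direct = sorted({a.gene_symbol for a in genes if a.term_id == term_id})
        return TermDetails(
            id=term_id,
            name=term.name,
            definition=term.definition,
            synonyms=term.synonyms,
            superclasses=tuple(supers),
            subclasses=tuple(subs),
            genes=tuple(direct),
        )

    # ---- search -----------------------------------------------------

    def search(self, query: str, limit: int = 20) -> list[SearchHit]:
        """Ranked autocomplete over names and synonyms.

        Matching is case-insensitive on whitespace-normalized labels.
        Tiers: name prefix, synonym prefix, name substring, synonym
        substring; within a tier shorter matched labels come first, then
        term id.  Each term appears once, at its best tier; obsolete terms
        are excluded.
        """
        if limit < 1:
            raise ValueError("limit must be >= 1")
        q = normalize_label(query)
        if not q:
            return []
        best: dict[str, tuple[int, int, str, str]] = {}
        for term in self.terms.values():
            if term.obsolete:
                continue
            labels = [(term.name, True)] + [(s.label, False) for s in term.synonyms]
            for label, is_name in labels:
                norm = normalize_label(label)
                pos = norm.find(q)
                if pos < 0:
                    continue
                if pos == 0:
                    kind = MatchKind.NAME_PREFIX if is_name else MatchKind.SYNONYM_PREFIX
                else:
                    kind = MatchKind.NAME_SUBSTRING if is_name else MatchKind.SYNONYM_SUBSTRING
                key = (_TIER_ORDER[kind], len(norm), norm, label)
                cur = best.get(term.id)
                if cur is None or key < cur:
                    best[term.id] = key
        ordered = sorted(best.items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0]))
        hits = []
        for rank, (term_id, (tier, _len, _norm, label)) in enumerate(ordered[:limit], start=1):
            kind = [k for k, v in _TIER_ORDER.items() if v == tier][0]
            hits.append(SearchHit(term_id=term_id, matched_label=label, match_kind=kind, rank=rank))
        return hits


# ---------------------------------------------------------------------------
# OBO parsing


_SYN_RE = re.compile(r'^"(?P<label>(?:[^"\\]|\\.)*)"\s*(?P<scope>EXACT|BROAD|NARROW|RELATED)?')
_DEF_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


def _unescape(text: str) -> str:
    return re.sub(r"\\(.)", r"\1", text)


def _split_stanzas(lines: Iterable[str]):
    """Yield (stanza_type or None for header, list of (tag, value))."""
    stanza_type: str | None = None
    current: list[tuple[str, str]] = []
    for raw in lines:
        stripped = raw.rstrip("\n").strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            yield stanza_type, current
            stanza_type = stripped[1:-1]
            current = []
            continue
        if not stripped or stripped.startswith("!"):
            continue
        if ":" not in stripped:
            continue  # tolerate stray lines; unrecognized content is ignored
        tag, value = stripped.split(":", 1)
        current.append((tag.strip(), value.strip()))
    yield stanza_type, current


def _strip_comment(value: str) -> str:
    """Drop an OBO trailing ``! comment`` from a tag value."""
    return value.split("!", 1)[0].strip()


def parse_obo(source: TextIO | str) -> Ontology:
    """Parse OBO flat-file text into a fully indexed :class:`Ontology`.

    Recognized term tags: ``id``, ``name``, ``def``, ``synonym``, ``is_a``,
    ``alt_id``, ``is_obsolete``, ``replaced_by``, ``consider``; recognized
    header tag: ``data-version``.  Anything else is ignored, so the parser
    copes with production ``hpo.obo`` content.  Stanza order never affects
    the result.

    Raises :class:`OboParseError` for a stanza with no id or a duplicate
    primary id, and :class:`OntologyCycleError` (listing one cycle) if the
    ``is_a`` graph over non-obsolete terms is cyclic.
    """
    if isinstance(source, str):
        lines: Iterable[str] = source.splitlines()
    else:
        lines = source

    version_label = ""
    terms: dict[str, OntologyTerm] = {}
    ordinal = 0

    for stanza_type, tags in _split_stanzas(lines):
        if stanza_type is None:
            for tag, value in tags:
                if tag == "data-version":
                    version_label = _strip_comment(value)
            continue
        if stanza_type != "Term":
            continue
        ordinal += 1
        data: dict[str, list[str]] = {}
        for tag, value in tags:
            data.setdefault(tag, []).append(value)
        if "id" not in data:
            raise OboParseError(f"[Term] stanza #{ordinal} has no id tag")
        term_id = _strip_comment(data["id"][0])
        if term_id in terms:
            raise OboParseError(f"duplicate primary id {term_id} (stanza #{ordinal})")
        obsolete = any(v.lower().startswith("true") for v in data.get("is_obsolete", []))
        name = _strip_comment(data["name"][0]) if "name" in data else ""
        if not name and not obsolete:
            raise OboParseError(f"non-obsolete term {term_id} has no name (stanza #{ordinal})")
        definition = None
        if "def" in data:
            m = _DEF_RE.match(data["def"][0])
            if m:
                definition = _unescape(m.group("text"))
        synonyms = []
        for value in data.get("synonym", []):
            m = _SYN_RE.match(value)
            if not m:
                continue
            scope = (m.group("scope") or "related").lower()
            label = _unescape(m.group("label")).strip()
            if label:
                synonyms.append(Synonym(label=label, scope=scope))
        parents = tuple(
            p for p in (_strip_comment(v) for v in data.get("is_a", [])) if p and p != term_id
        )
        terms[term_id] = OntologyTerm(
            id=term_id,
            name=name,
            definition=definition,
            synonyms=tuple(synonyms),
            alt_ids=tuple(_strip_comment(v) for v in data.get("alt_id", [])),
            parents=parents,
            obsolete=obsolete,
            replaced_by=tuple(_strip_comment(v) for v in data.get("replaced_by", [])),
            consider=tuple(_strip_comment(v) for v in data.get("consider", [])),
        )

    # indexes
    alt_index: dict[str, str] = {}
    children_index: dict[str, list[str]] = {}
    for term in terms.values():
        for alt in term.alt_ids:
            if alt not in terms:
                alt_index[alt] = term.id
        if term.obsolete:
            continue
        for parent in term.parents:
            children_index.setdefault(parent, []).append(term.id)
    for kids in children_index.values():
        kids.sort()

    # acyclicity over non-obsolete terms; later traversals rely on this
    graph = {
        t.id: [p for p in t.parents if p in terms and not terms[p].obsolete]
        for t in terms.values()
        if not t.obsolete
    }
    sorter = graphlib.TopologicalSorter(graph)
    try:
        sorter.prepare()
    except graphlib.CycleError as exc:
        raise OntologyCycleError(list(exc.args[1])) from exc

    return Ontology(version_label=version_label, terms=terms,
                    alt_index=alt_index, children_index=children_index)


# ---------------------------------------------------------------------------
# Gene-association table


def load_gene_associations(source: TextIO | str, ontology: Ontology) -> list[GeneAssociation]:
    """Load a ``term_id <tab> gene_symbol <tab> gene_id`` table.

    A header line is detected by its first field not being a CURIE.  Term
    ids are passed through :meth:`Ontology.resolve`, so rows referencing
    alternate or replaced ids are stored under the current primary term;
    rows with unknown ids are dropped and counted in a single warning.
    """
    if isinstance(source, str):
        lines: Iterable[str] = source.splitlines()
    else:
        lines = source
    out: list[GeneAssociation] = []
    dropped = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if lineno == 1 and fields and not is_term_id(fields[0]):
            continue  # header
        if len(fields) not in (2, 3):
            raise GeneTableError(
                f"line {lineno}: expected 2-3 tab-separated columns, got {len(fields)}"
            )
        term_id, gene_symbol = fields[0].strip(), fields[1].strip()
        gene_id = fields[2].strip() if len(fields) == 3 else ""
        resolution = ontology.resolve(term_id)
        if resolution.status is ResolutionStatus.UNKNOWN:
            dropped += 1
            continue
        out.append(GeneAssociation(term_id=resolution.primary,
                                   gene_symbol=gene_symbol, gene_id=gene_id))
    if dropped:
        warnings.warn(f"dropped {dropped} association row(s) with unknown term ids",
                      stacklevel=2)
    return out
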