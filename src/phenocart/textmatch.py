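"""Dictionary-based phenotype concept extraction from free text.

This is the post-hoc comparison arm of the package: instead of structured
point-of-care capture, terms are recovered from note text by multi-pattern
dictionary matching — an Aho-Corasick automaton over every non-obsolete
term name and exact-scope synonym, deliberately "basic": no stemming, no
abbreviation expansion, no negation-scope detection.  Copy-paste style
corruption operators (suffix truncation such as "limb" → "lim", character
deletion, adjacent transposition) let tests and the demo quantify how small
free-text errors silently lose terms that structured capture retains.

Matching is case-insensitive on a whitespace-collapsed projection of the
text, constrained to word boundaries, with longest-match-wins overlap
resolution; offsets in results always refer to the original text.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .errors import CorruptionError
from .ontology import Ontology, normalize_label


class _AhoCorasick:
    """Multi-pattern matcher: trie + BFS failure links + output merging."""

    def __init__(self, patterns: Iterable[str]):
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[str]] = [[]]
        self._fail: list[int] = [0]
        for pattern in patterns:
            self._insert(pattern)
        self._build_failures()

    def _insert(self, pattern: str) -> None:
        state = 0
        for ch in pattern:
            nxt = self._goto[state].get(ch)
            if nxt is None:
                nxt = len(self._goto)
                self._goto[state][ch] = nxt
                self._goto.append({})
                self._out.append([])
                self._fail.append(0)
            state = nxt
        self._out[state].append(pattern)

    def _build_failures(self) -> None:
        queue: deque[int] = deque()
        for state in self._goto[0].values():
            queue.append(state)
        while queue:
            state = queue.popleft()
            for ch, nxt in self._goto[state].items():
                queue.append(nxt)
                fall = self._fail[state]
                while fall and ch not in self._goto[fall]:
                    fall = self._fail[fall]
                self._fail[nxt] = self._goto[fall].get(ch, 0)
                if self._fail[nxt] == nxt:
                    self._fail[nxt] = 0
                self._out[nxt] = self._out[nxt] + self._out[self._fail[nxt]]

    def iter_matches(self, text: str):
        """Yield ``(end_exclusive, pattern)`` for every occurrence."""
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(ch, 0)
            for pattern in self._out[state]:
                yield i + 1, pattern


@dataclass(frozen=True)
class Match:
    term_id: str
    surface: str  # text as it appeared in the note
    start: int    # 0-based, half-open character offsets into the original text
    end: int
    label: str    # normalized dictionary form that matched


class DictionaryIndex:
    """Surface-form dictionary over an ontology, ready for extraction."""

    def __init__(self, entries: dict[str, frozenset[str]]):
        self.entries = entries
        self._automaton = _AhoCorasick(entries.keys())

    def __len__(self) -> int:
        return len(self.entries)


def build_dictionary(ontology: Ontology) -> DictionaryIndex:
    """Index every non-obsolete term's name and exact-scope synonyms.

    Broad/narrow/related synonyms are excluded to keep the free-text arm
    conservative; forms are normalized identically to autocomplete search,
    and a form shared by several terms maps to all of them.
    """
    entries: dict[str, set[str]] = {}
    for term in ontology.terms.values():
        if term.obsolete:
            continue
        forms = [term.name] + [s.label for s in term.synonyms if s.scope == "exact"]
        for form in forms:
            norm = normalize_label(form)
            if norm:
                entries.setdefault(norm, set()).add(term.id)
    return DictionaryIndex({form: frozenset(ids) for form, ids in entries.items()})


def _normalize_with_offsets(text: str) -> tuple[str, list[int], list[int]]:
    """Whitespace-collapsed lowercase projection plus offset maps.

    Returns ``(norm, starts, ends)`` where ``starts[i]``/``ends[i]`` bound
    the original-text span that normalized character *i* came from.
    """
    chars: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            j = i
            while j < n and text[j].isspace():
                j += 1
            if chars and j < n:  # inner run → single space; edges dropped
                chars.append(" ")
                starts.append(i)
                ends.append(j)
            i = j
        else:
            low = ch.lower()
            chars.append(low if len(low) == 1 else ch)
            starts.append(i)
            ends.append(i + 1)
            i += 1
    return "".join(chars), starts, ends


def extract_terms(index: DictionaryIndex, text: str) -> list[Match]:
    """All dictionary matches in *text*, word-bounded and non-overlapping.

    Overlaps resolve longest-match-first, ties to the leftmost span; a form
    mapping to several terms emits one :class:`Match` per term id at the
    same span.  Results are sorted by start offset, then term id.
    """
    norm, starts, ends = _normalize_with_offsets(text)
    candidates: list[tuple[int, int, str]] = []  # (start_n, end_n, form)
    for end_n, form in index._automaton.iter_matches(norm):
        start_n = end_n - len(form)
        before_ok = start_n == 0 or not norm[start_n - 1].isalnum()
        after_ok = end_n == len(norm) or not norm[end_n].isalnum()
        if before_ok and after_ok:
            candidates.append((start_n, end_n, form))

    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    chosen: list[tuple[int, int, str]] = []
    occupied: list[tuple[int, int]] = []
    for start_n, end_n, form in candidates:
        if any(start_n < e and s < end_n for s, e in occupied):
            continue
        occupied.append((start_n, end_n))
        chosen.append((start_n, end_n, form))

    matches: list[Match] = []
    for start_n, end_n, form in chosen:
        start, end = starts[start_n], ends[end_n - 1]
        for term_id in sorted(index.entries[form]):
            matches.append(Match(term_id=term_id, surface=text[start:end],
                                 start=start, end=end, label=form))
    matches.sort(key=lambda m: (m.start, m.term_id))
    return matches


def matches_to_tsv(matches: Iterable[Match]) -> str:
    """Match report as ``term_id⇥start⇥end⇥surface`` lines with a header."""
    lines = ["term_id\tstart\tend\tsurface"]
    for m in matches:
        lines.append(f"{m.term_id}\t{m.start}\t{m.end}\t{m.surface}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Copy-paste corruption operators

CORRUPTION_KINDS = ("truncate_suffix", "delete_char", "transpose_adjacent")


@dataclass(frozen=True)
class CorruptionOp:
    kind: str
    target_mention_index: int
    parameter: int | None = None  # chars to truncate / position; None → seeded pick


class AppliedOp(NamedTuple):
    op: CorruptionOp
    before: str
    after: str


def _apply_op(op: CorruptionOp, segment: str, rng: random.Random) -> str:
    if len(segment) < 2:
        raise CorruptionError(f"mention {op.target_mention_index} too short to corrupt")
    if op.kind == "truncate_suffix":
        k = op.parameter if op.parameter is not None else 1
        if not 1 <= k < len(segment):
            raise CorruptionError(f"cannot truncate {k} chars from {segment!r}")
        return segment[:-k]
    if op.kind == "delete_char":
        pos = op.parameter if op.parameter is not None else rng.randrange(len(segment))
        if not 0 <= pos < len(segment):
            raise CorruptionError(f"delete position {pos} outside {segment!r}")
        return segment[:pos] + segment[pos + 1:]
    if op.kind == "transpose_adjacent":
        pos = op.parameter if op.parameter is not None else rng.randrange(len(segment) - 1)
        if not 0 <= pos < len(segment) - 1:
            raise CorruptionError(f"transpose position {pos} outside {segment!r}")
        return segment[:pos] + segment[pos + 1] + segment[pos] + segment[pos + 2:]
    raise CorruptionError(f"unknown corruption kind {op.kind!r}")


def corrupt_text(text: str, mentions: Sequence[tuple[int, int]],
                 ops: Sequence[CorruptionOp], seed: int = 0
                 ) -> tuple[str, list[AppliedOp]]:
    """Apply copy-paste-style corruptions to ground-truth mention spans.

    Each op edits exactly one mention's span; text outside the targeted
    mentions is untouched.  Deterministic for a given seed and op list; the
    returned log records each mention's before/after strings.
    """
    rng = random.Random(seed)
    for op in ops:
        if not 0 <= op.target_mention_index < len(mentions):
            raise CorruptionError(
                f"op targets mention {op.target_mention_index}, "
                f"but only {len(mentions)} mentions exist")
    log: list[AppliedOp] = []
    # edit from the rightmost mention down so earlier offsets stay valid
    by_mention: dict[int, list[CorruptionOp]] = {}
    for op in ops:
        by_mention.setdefault(op.target_mention_index, []).append(op)
    for idx in sorted(by_mention, key=lambda i: mentions[i][0], reverse=True):
        start, end = mentions[idx]
        segment = text[start:end]
        for op in by_mention[idx]:
            before = segment
            segment = _apply_op(op, segment, rng)
            log.append(AppliedOp(op=op, before=before, after=segment))
        text = text[:start] + segment + text[end:]
    log.sort(key=lambda a: a.op.target_mention_index)
    return text, log


class CaptureReport(NamedTuple):
    retained: set[str]
    lost: set[str]
    spurious: set[str]


def compare_capture(structured: set[str], extracted: Iterable[Match]) -> CaptureReport:
    """Compare a structured term set with a free-text extraction result.

    ``lost`` is what structured capture has but extraction missed;
    ``spurious`` is what extraction found that was never structurally
    recorded; ``retained`` is the intersection.
    """
    extracted_ids = {m.term_id for m in extracted}
    return CaptureReport(
        retained=structured & extracted_ids,
        lost=structured - extracted_ids,
        spurious=extracted_ids - structured,
    )
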