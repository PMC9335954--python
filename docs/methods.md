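# Methods

## Scope and model

`phenocart` models point-of-care structured phenotyping as four stages —
browse, select, persist, reuse — and contrasts it with a free-text
pipeline in which the same terms are pasted into a note and recovered by
dictionary matching. The package's claim is mechanical, not statistical:
structured capture is lossless by construction, while text-mediated
capture loses any term whose surface form is perturbed, and the loss
propagates to phenotype-driven gene ranking.

## Ontology handling

The OBO parser covers the term-level subset that phenotype work actually
touches: `id`, `name`, `def`, `synonym` (with scope; missing scope
defaults to `related`), `is_a`, `alt_id`, `is_obsolete`, `replaced_by`,
`consider`, plus the header `data-version`, which becomes the ontology's
version label and is stamped into every annotation and record.
Unrecognized tags are ignored so production `hp.obo` files parse. The
parser enforces: every stanza has an `id` (errors name the stanza
ordinal), primary ids are unique, and the `is_a` graph over non-obsolete
terms is acyclic (checked at parse time with a topological sort, so
traversals may assume a DAG and need no cycle guards).

Identifier resolution is total and idempotent: alternate ids map to their
primary term, an obsolete term with exactly one `replaced_by` maps to its
replacement, an obsolete term with zero or several candidates is reported
as unreplaced — a replacement is never guessed — and unknown ids echo
back with an `unknown` status rather than raising.

Autocomplete search ranks case-insensitively on whitespace-collapsed
labels in four tiers — name prefix, synonym prefix, name substring,
synonym substring — with shorter matched labels first within a tier and
term id as the final tie-break, so results are fully deterministic. Each
term appears once, at its best tier. Obsolete terms are not searchable:
surfacing retired vocabulary at the point of care is precisely the
failure mode structured capture is meant to avoid. These ranking rules
are this package's own contract; they were chosen for determinism and
testability, not inherited from any particular production system.

## Cart and record semantics

Annotations snapshot the term name and ontology version at add time, so a
saved record remains interpretable after the ontology moves on. Re-adding
a present term updates its negation/comment in place (cart semantics;
erroring would block clinicians), and holding both a term and one of its
proper ancestors is a warning, not an error, because choosing a more or
less specific term is legitimate clinical judgment.

Negation is a structured boolean *and* the comment stays free text: the
boolean makes downstream exports computable (the Phenopacket `excluded`
flag), while the comment preserves free-form use such as linked genes.

The store writes one full snapshot per save — not deltas — because the
primary consumer wants the complete cross-encounter term set at once;
encounter-level changes are recovered by diffing consecutive snapshots.
Records are immutable; versions are exactly 1..n per patient; a version
collision between concurrent writers raises a conflict (the file is
created with `O_EXCL`, so the last writer cannot silently win). The JSON
payload is canonical — UTF-8, sorted keys, no insignificant whitespace,
explicit `schema_version: "1.0"` — so structural equality and byte
equality coincide and future schema migration has a hook.

## Extraction arm

The dictionary holds every non-obsolete term name and *exact*-scope
synonyms only; broad/narrow/related synonyms are excluded to keep the
free-text arm conservative (near-synonym inflation would overstate its
recall). Matching runs an Aho-Corasick automaton (trie plus BFS failure
links, implemented in-package and verified against a quadratic naive-scan
oracle) over a normalized projection of the text — lowercased, internal
whitespace collapsed — with offsets mapped back to the original.
Matches must sit on word boundaries (adjacent characters non-alphanumeric
or text edge: `lim` must not match inside `climb`), overlaps resolve
longest-match-first then leftmost, and a surface form shared by several
terms yields one match per term at the same span.

Corruption operators edit exactly one ground-truth mention span each —
suffix truncation (the canonical `limb` → `lim` slip), single-character
deletion, adjacent transposition — deterministically for a given seed,
with a before/after log. Text outside the targeted mentions is never
touched, so "corrupting k mentions loses exactly k terms" is a testable
conservation law whenever the corrupted forms leave the dictionary.

## Gene ranking

The ranker is a deliberately transparent information-content baseline,
not a re-implementation of any knowledgebase-backed production ranker
(whose output depends on an external, versioned knowledgebase and is not
reproducible at desk scale). Associations propagate up `is_a` paths:
gene g is associated with term t iff g is directly annotated to t or any
descendant. With n_t of N genes reaching t, IC(t) = −ln(n_t/N), which is
monotone non-decreasing from root to leaf; terms reached by no gene get
the smoothed −ln(1/(N+1)) — rarer than anything observed but finite.
score(g) = Σ IC(t) over the patient terms associated with g; ties rank
by gene symbol. The scorer surface is pluggable so an external ranker can
be swapped in behind the same interface.

## Demonstration design

`run_demo` (and `phenocart demo`) generates a 40-term ontology
(edge probability 0.08, single root by construction) and a 25-gene corpus
with 3 associations per gene — sizes chosen so the corpus is competitive
enough for rank movement to be visible while the whole demonstration runs
in milliseconds. The causal gene is the one with the most direct
annotations; the patient's k terms are its direct terms topped up with
random others; corruptions target only mentions of causal-gene-associated
terms. That targeting yields a directional guarantee: every gene
associated with a dropped term loses exactly IC(t), and unassociated
genes lose nothing, so the causal gene's rank after corruption is ≥ its
structured rank — deterministically, on every seed. The demo verifies
each corruption actually removes its term from the extraction (trying
truncation first, then the other operators) so the retained count is
exactly k − m.

## Synthetic data and what it does not show

The note generator embeds each term's canonical name or an exact synonym
verbatim, separated by filler drawn from a fixed sentence bank containing
no dictionary surface forms, and records exact mention spans. This makes
recall on uncorrupted notes exactly 100% by construction — which is the
point: the comparison isolates the effect of transcription errors, with
extraction's baseline handicap removed. Real clinical text is harsher to
dictionary NLP (inflection, abbreviation, negation scope, discontinuous
mentions), so passing tests here bound the *best case* for the free-text
arm; they say nothing about its performance on real notes, where losses
would only grow. Likewise the random ontologies use synthetic
pronounceable vocabularies, which understate the surface-form ambiguity
of real terminologies.

## Numerical and procedural choices

- Timestamps are injected (`now` parameter) and rendered as UTC ISO 8601
  with seconds precision, for reproducible records in tests.
- IC comparisons in tests use a 1e-12 absolute slack for float rounding;
  the ranker itself does no thresholding.
- RTF output escapes `\`, `{`, `}` and encodes non-ASCII as `\uN?`, so
  arbitrary comments cannot unbalance the document; the `\row` control
  word count is annotation count + 1 by contract.
- Empty or whitespace-only search queries return an empty result rather
  than erroring; empty records render header-only tables and empty
  feature lists.
- The store encodes patient ids into filesystem-safe directory names by
  percent-escaping; record filenames are zero-padded versions so
  lexicographic and numeric order agree.

## Known limitations

- OBO support is the term-level subset above; OWL, non-`is_a`
  relationships, and full OBO 1.4 grammar are out of scope.
- The Phenopacket export targets structural validity of the emitted
  subset, not full schema conformance.
- Extraction has no negation detection: a negated mention in text is
  extracted as present, a real hazard of the free-text pipeline that the
  structured arm's negation flag avoids.
- Character offset mapping assumes one-to-one lowercasing; locale edge
  cases (e.g. dotted İ) fall back to the original character.
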