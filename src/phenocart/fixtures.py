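"""Deterministic generators for test-scale inputs.

Everything the package consumes — OBO ontologies, gene–phenotype tables,
clinical note text with known term mentions — can be generated here, so the
whole workflow builds and tests without downloading production data.  All
generators are pure functions of their parameters and seed.

The canonical seven-term ontology (a tiny caricature of the HPO: a root,
a limb branch, a seizure branch, one merged id and one obsolete term) is
the shared fixture the package's documented examples use.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import FixtureError
from .ontology import Ontology

CANONICAL_OBO = """\
format-version: 1.2
data-version: toy/2021-01-01

[Term]
id: T:0000001
name: Phenotypic abnormality
def: "A phenotypic abnormality." []

[Term]
id: T:0000010
name: Abnormal limb morphology
def: "Any structural anomaly of a limb." []
synonym: "Limb abnormality" EXACT []
is_a: T:0000001 ! Phenotypic abnormality

[Term]
id: T:0000011
name: Polydactyly
def: "More digits than normal." []
is_a: T:0000010 ! Abnormal limb morphology

[Term]
id: T:0000012
name: Syndactyly
def: "Webbed or fused digits." []
alt_id: T:0000099
is_a: T:0000010 ! Abnormal limb morphology

[Term]
id: T:0000020
name: Seizure
def: "A sudden surge of abnormal electrical activity in the brain." []
synonym: "Epileptic seizure" EXACT []
is_a: T:0000001 ! Phenotypic abnormality

[Term]
id: T:0000021
name: Febrile seizure
def: "A seizure associated with fever." []
is_a: T:0000020 ! Seizure

[Term]
id: T:0000030
name: obsolete Convulsion
is_obsolete: true
replaced_by: T:0000020
"""

CANONICAL_GENE_TABLE = """\
term_id\tgene_symbol\tgene_id
T:0000011\tGENE1\t101
T:0000012\tGENE1\t101
T:0000020\tGENE2\t102
T:0000021\tGENE3\t103
T:0000010\tGENE3\t103
"""


def canonical_fixture() -> str:
    """The fixed seven-term toy ontology as OBO text (byte-identical per call)."""
    return CANONICAL_OBO


def canonical_gene_table() -> str:
    """The fixed three-gene association table matching the canonical ontology."""
    return CANONICAL_GENE_TABLE


_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def _pronounceable(rng: random.Random, n_syllables: int) -> str:
    return "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
                   for _ in range(n_syllables))


def _unique_word(rng: random.Random, used: set[str]) -> str:
    while True:
        word = _pronounceable(rng, rng.randint(2, 4))
        if word not in used:
            used.add(word)
            return word


def random_ontology(n_terms: int, edge_prob: float, seed: int) -> str:
    """A random single-rooted DAG ontology as OBO text.

    Acyclicity is guaranteed by construction: ``is_a`` edges only point
    from higher- to lower-indexed terms, and every non-root term draws at
    least one parent, so term 1 is the unique root.  Roughly a third of
    terms get an exact synonym.  Deterministic per seed.
    """
    if n_terms < 2:
        raise FixtureError("n_terms must be >= 2")
    if not 0 < edge_prob < 1:
        raise FixtureError("edge_prob must be in (0, 1)")
    rng = random.Random(seed)
    used: set[str] = set()
    lines = ["format-version: 1.2", f"data-version: random/seed-{seed}", ""]
    for i in range(1, n_terms + 1):
        term_id = f"T:{i:07d}"
        name = _unique_word(rng, used).capitalize()
        lines.append("[Term]")
        lines.append(f"id: {term_id}")
        lines.append(f"name: {name}")
        if rng.random() < 0.3:
            lines.append(f'synonym: "{_unique_word(rng, used).capitalize()}" EXACT []')
        if i > 1:
            parents = [j for j in range(1, i) if rng.random() < edge_prob]
            if not parents:
                parents = [rng.randint(1, i - 1)]
            for j in parents:
                lines.append(f"is_a: T:{j:07d}")
        lines.append("")
    return "\n".join(lines)


def random_gene_table(ontology: Ontology, n_genes: int, assoc_per_gene: int,
                      seed: int) -> str:
    """A random gene–term TSV over an ontology's non-obsolete terms.

    Each gene draws ``assoc_per_gene`` distinct terms uniformly without
    replacement; deterministic per seed.
    """
    if n_genes < 1:
        raise FixtureError("n_genes must be >= 1")
    terms = sorted(t.id for t in ontology.terms.values() if not t.obsolete)
    if assoc_per_gene > len(terms):
        raise FixtureError(
            f"assoc_per_gene={assoc_per_gene} exceeds term count {len(terms)}")
    rng = random.Random(seed)
    lines = ["term_id\tgene_symbol\tgene_id"]
    for g in range(1, n_genes + 1):
        symbol = f"GENE{g:03d}"
        for term_id in sorted(rng.sample(terms, assoc_per_gene)):
            lines.append(f"{term_id}\t{symbol}\t{1000 + g}")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SyntheticNote:
    text: str
    mentions: tuple[tuple[str, int, int, str], ...]  # (term_id, start, end, surface)
    seed: int


# Neutral connective sentences; none contains a dictionary surface form of
# the canonical fixture, and random-ontology vocabularies cannot collide
# with plain English by construction.
_FILLER_BANK = (
    "The patient was evaluated in clinic.",
    "Vital signs were within normal ranges.",
    "Family history was reviewed in detail.",
    "Growth parameters were documented.",
    "Follow-up was arranged in three months.",
    "Prior records were obtained and reviewed.",
    "The visit was attended by both parents.",
    "Laboratory results are pending at this time.",
)

_LEAD_INS = (
    "Exam was notable for ",
    "The workup documented ",
    "On review, we noted ",
    "Findings included ",
)


def synthesize_note(ontology: Ontology, terms: list[str], filler_seed: int
                    ) -> SyntheticNote:
    """A clinical-note-like text embedding each term exactly once.

    Each term's canonical name (or, with a coin flip, one of its exact
    synonyms) appears verbatim once, surrounded by neutral filler, and the
    ground-truth character span of every mention is recorded.
    """
    rng = random.Random(filler_seed)
    pieces: list[str] = [rng.choice(_FILLER_BANK), " "]
    offset = sum(len(p) for p in pieces)
    mentions: list[tuple[str, int, int, str]] = []
    for term_id in terms:
        resolution = ontology.resolve(term_id)
        term = ontology.terms.get(resolution.primary)
        if term is None or term.obsolete:
            raise FixtureError(f"term {term_id} has no usable surface form")
        surfaces = [term.name] + [s.label for s in term.synonyms if s.scope == "exact"]
        surface = surfaces[0] if len(surfaces) == 1 or rng.random() < 0.5 \
            else rng.choice(surfaces[1:])
        lead = rng.choice(_LEAD_INS)
        pieces.append(lead)
        offset += len(lead)
        start = offset
        pieces.append(surface)
        offset += len(surface)
        mentions.append((resolution.primary, start, offset, surface))
        tail = ". " + rng.choice(_FILLER_BANK) + " "
        pieces.append(tail)
        offset += len(tail)
    text = "".join(pieces).rstrip()
    return SyntheticNote(text=text, mentions=tuple(mentions), seed=filler_seed)
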