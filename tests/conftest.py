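import random
from datetime import datetime, timezone

import pytest

import phenocart as pc

NOW = datetime(2021, 2, 1, 12, 0, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def ontology():
    return pc.parse_obo(pc.canonical_fixture())


@pytest.fixture(scope="session")
def associations(ontology):
    return pc.load_gene_associations(pc.canonical_gene_table(), ontology)


@pytest.fixture(scope="session")
def corpus(ontology, associations):
    return pc.build_corpus(ontology, associations)


@pytest.fixture(scope="session")
def dictionary(ontology):
    return pc.build_dictionary(ontology)


def make_cart(ontology, term_ids, patient="P1", **kwargs):
    cart = pc.AnnotationCart(patient_id=patient)
    for tid in term_ids:
        cart = pc.add_term(cart, ontology, tid, now=NOW, **kwargs)
    return cart


def random_record(rng: random.Random, ontology) -> pc.PatientPhenotypeRecord:
    """A record with randomized annotation content, incl. awkward comments."""
    nasty = ["", 'quotes "inside"', "tab\there", "new\nline", "back\\slash",
             "brace {x} y", "unicode é世", None]
    terms = [t for t in ontology.terms.values() if not t.obsolete]
    chosen = rng.sample(terms, rng.randint(0, len(terms)))
    annotations = tuple(
        pc.PhenotypeAnnotation(
            term_id=t.id, term_name=t.name, negated=rng.random() < 0.4,
            comment=rng.choice(nasty), added_at="2021-02-01T12:00:00Z",
            ontology_version=ontology.version_label)
        for t in chosen)
    return pc.PatientPhenotypeRecord(
        patient_id=f"P{rng.randint(1, 5)}", record_version=rng.randint(1, 9),
        saved_at="2021-02-01T12:00:00Z", ontology_version=ontology.version_label,
        annotations=annotations)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never share code with the package)

def closure_oracle(parent_map: dict[str, set[str]], start: str) -> set[str]:
    """Transitive closure by repeated one-step expansion to a fixpoint."""
    result: set[str] = set()
    frontier = set(parent_map.get(start, set()))
    while frontier:
        result |= frontier
        frontier = {p for t in frontier for p in parent_map.get(t, set())} - result
    return result


def search_oracle(ontology, query: str, limit: int):
    """Linear scan over every label applying the tier/tie rules directly."""
    def norm(s):
        return " ".join(s.split()).lower()

    q = norm(query)
    if not q:
        return []
    per_term = {}
    for term in ontology.terms.values():
        if term.obsolete:
            continue
        candidates = []
        for label, is_name in [(term.name, True)] + [
                (s.label, False) for s in term.synonyms]:
            n = norm(label)
            if q not in n:
                continue
            if n.startswith(q):
                tier = 0 if is_name else 1
            else:
                tier = 2 if is_name else 3
            candidates.append((tier, len(n), n, label))
        if candidates:
            per_term[term.id] = min(candidates)
    ordered = sorted(per_term.items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0]))
    return [(tid, key[3], key[0]) for tid, key in ordered[:limit]]


def extraction_oracle(index, text: str):
    """Quadratic scan: try every dictionary form at every position.

    Same normalization, word-boundary, and longest/leftmost overlap rules
    as the production matcher, implemented independently.
    """
    def norm_map(t):
        chars, starts, ends, i = [], [], [], 0
        while i < len(t):
            if t[i].isspace():
                j = i
                while j < len(t) and t[j].isspace():
                    j += 1
                if chars and j < len(t):
                    chars.append(" "); starts.append(i); ends.append(j)
                i = j
            else:
                low = t[i].lower()
                chars.append(low if len(low) == 1 else t[i])
                starts.append(i); ends.append(i + 1)
                i += 1
        return "".join(chars), starts, ends

    norm, starts, ends = norm_map(text)
    cands = []
    for form in index.entries:
        pos = 0
        while True:
            hit = norm.find(form, pos)
            if hit < 0:
                break
            end = hit + len(form)
            if ((hit == 0 or not norm[hit - 1].isalnum())
                    and (end == len(norm) or not norm[end].isalnum())):
                cands.append((hit, end, form))
            pos = hit + 1
    cands.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    chosen, taken = [], []
    for s, e, form in cands:
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append((s, e))
        chosen.append((s, e, form))
    out = []
    for s, e, form in chosen:
        for tid in sorted(index.entries[form]):
            out.append((tid, starts[s], ends[e - 1], form))
    return sorted(out)
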