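"""Dictionary extraction: automaton correctness, corruption, comparison."""

import random

import pytest

import phenocart as pc
from phenocart.errors import CorruptionError

from conftest import extraction_oracle


def random_text(rng, ontology, n_tokens=25):
    """Word soup mixing dictionary forms, fragments, and noise."""
    forms = [t.name for t in ontology.terms.values() if not t.obsolete]
    forms += [s.label for t in ontology.terms.values() if not t.obsolete
              for s in t.synonyms]
    vocab = forms + [f[:-1] for f in forms if len(f) > 3] + \
        ["the", "and", "noted", "x9", "..", "CLIMB"]
    words = []
    for _ in range(n_tokens):
        w = rng.choice(vocab)
        if rng.random() < 0.3:
            w = w.upper() if rng.random() < 0.5 else w.lower()
        words.append(w)
        words.append(rng.choice([" ", "  ", ", ", ". ", "\n"]))
    return "".join(words)


class TestDictionary:
    def test_canonical_fixture_has_eight_surface_forms(self, dictionary):
        assert len(dictionary) == 8  # 6 names + 2 exact synonyms

    def test_only_exact_synonyms_enter_the_dictionary(self):
        obo = ("[Term]\nid: A:1\nname: alpha\n"
               'synonym: "close" RELATED []\nsynonym: "same" EXACT []\n')
        index = pc.build_dictionary(pc.parse_obo(obo))
        assert set(index.entries) == {"alpha", "same"}

    def test_shared_synonym_maps_to_both_terms(self):
        obo = ('[Term]\nid: A:1\nname: alpha\nsynonym: "shared form" EXACT []\n\n'
               '[Term]\nid: A:2\nname: beta\nsynonym: "shared form" EXACT []\n')
        index = pc.build_dictionary(pc.parse_obo(obo))
        assert index.entries["shared form"] == {"A:1", "A:2"}

    def test_rebuild_is_term_order_insensitive(self):
        text = pc.canonical_fixture()
        header, _, body = text.partition("[Term]")
        stanzas = ("[Term]" + body).split("\n\n")
        random.Random(3).shuffle(stanzas)
        a = pc.build_dictionary(pc.parse_obo(text))
        b = pc.build_dictionary(pc.parse_obo(header + "\n\n".join(stanzas)))
        assert a.entries == b.entries


class TestExtraction:
    def test_longest_match_wins_over_contained_form(self, dictionary):
        matches = pc.extract_terms(dictionary, "patient has febrile seizure today")
        assert [(m.term_id, m.surface) for m in matches] == \
            [("T:0000021", "febrile seizure")]

    def test_synonym_is_matched(self, dictionary):
        matches = pc.extract_terms(dictionary, "Limb abnormality noted")
        assert [m.term_id for m in matches] == ["T:0000010"]
        assert matches[0].start == 0 and matches[0].end == len("Limb abnormality")

    def test_truncated_mention_is_silently_lost(self, dictionary):
        assert pc.extract_terms(dictionary, "lim abnormality noted") == []

    def test_word_boundaries_prevent_matches_inside_words(self):
        obo = "[Term]\nid: A:1\nname: lim\n"
        index = pc.build_dictionary(pc.parse_obo(obo))
        assert pc.extract_terms(index, "they climb walls") == []
        assert len(pc.extract_terms(index, "the lim, was seen")) == 1

    def test_whitespace_and_case_normalization(self, dictionary):
        matches = pc.extract_terms(dictionary, "FEBRILE\n   Seizure observed")
        assert [m.term_id for m in matches] == ["T:0000021"]
        surface = matches[0].surface
        assert surface.startswith("FEBRILE") and surface.endswith("Seizure")

    def test_ambiguous_form_emits_one_match_per_term(self):
        obo = ('[Term]\nid: A:1\nname: alpha\nsynonym: "shared form" EXACT []\n\n'
               '[Term]\nid: A:2\nname: beta\nsynonym: "shared form" EXACT []\n')
        index = pc.build_dictionary(pc.parse_obo(obo))
        matches = pc.extract_terms(index, "a shared form here")
        assert [(m.term_id, m.start, m.end) for m in matches] == \
            [("A:1", 2, 13), ("A:2", 2, 13)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_scan_oracle_on_random_texts(self, seed):
        rng = random.Random(seed)
        ont = pc.parse_obo(pc.random_ontology(25, 0.1, seed))
        index = pc.build_dictionary(ont)
        for _ in range(10):
            text = random_text(rng, ont)
            got = sorted((m.term_id, m.start, m.end, m.label)
                         for m in pc.extract_terms(index, text))
            assert got == extraction_oracle(index, text)

    def test_oracle_agreement_on_canonical_fixture_texts(self, ontology, dictionary):
        rng = random.Random(99)
        for _ in range(20):
            text = random_text(rng, ontology)
            got = sorted((m.term_id, m.start, m.end, m.label)
                         for m in pc.extract_terms(dictionary, text))
            assert got == extraction_oracle(dictionary, text)


class TestCorruption:
    def test_truncating_limb_to_lim(self):
        text = "limb pain noted"
        corrupted, log = pc.corrupt_text(
            text, [(0, 4)],
            [pc.CorruptionOp("truncate_suffix", 0, 1)], seed=0)
        assert corrupted == "lim pain noted"
        assert log[0].before == "limb" and log[0].after == "lim"

    def test_empty_op_list_is_identity(self):
        text = "anything at all"
        corrupted, log = pc.corrupt_text(text, [(0, 8)], [], seed=0)
        assert corrupted == text and log == []

    def test_out_of_range_target_raises(self):
        with pytest.raises(CorruptionError):
            pc.corrupt_text("abc def", [(0, 3)],
                            [pc.CorruptionOp("delete_char", 5, 0)], seed=0)

    def test_non_targeted_spans_are_untouched(self, ontology, dictionary):
        note = pc.synthesize_note(ontology, ["T:0000011", "T:0000021"], 4)
        spans = [(m[1], m[2]) for m in note.mentions]
        corrupted, _ = pc.corrupt_text(
            note.text, spans, [pc.CorruptionOp("delete_char", 0, 2)], seed=0)
        before = {m.term_id for m in pc.extract_terms(dictionary, note.text)}
        after = {m.term_id for m in pc.extract_terms(dictionary, corrupted)}
        assert before - after == {"T:0000011"}
        assert "T:0000021" in after

    def test_transpose_and_determinism(self):
        corrupted_a, _ = pc.corrupt_text(
            "word here", [(0, 4)],
            [pc.CorruptionOp("transpose_adjacent", 0, None)], seed=5)
        corrupted_b, _ = pc.corrupt_text(
            "word here", [(0, 4)],
            [pc.CorruptionOp("transpose_adjacent", 0, None)], seed=5)
        assert corrupted_a == corrupted_b != "word here"


class TestCompareCapture:
    def test_partition_of_structured_set(self):
        matches = [pc.Match("A:1", "a", 0, 1, "a"), pc.Match("A:3", "c", 2, 3, "c")]
        report = pc.compare_capture({"A:1", "A:2"}, matches)
        assert report.retained == {"A:1"}
        assert report.lost == {"A:2"}
        assert report.spurious == {"A:3"}
        assert len(report.retained) + len(report.lost) == 2

    def test_identical_sets_have_no_loss(self):
        matches = [pc.Match("A:1", "a", 0, 1, "a")]
        report = pc.compare_capture({"A:1"}, matches)
        assert report.lost == set() == report.spurious

    def test_full_recall_on_uncorrupted_synthetic_notes(self, ontology, dictionary):
        for seed in range(10):
            terms = ["T:0000011", "T:0000012", "T:0000020", "T:0000021", "T:0000010"]
            note = pc.synthesize_note(ontology, terms, seed)
            report = pc.compare_capture(
                set(terms), pc.extract_terms(dictionary, note.text))
            assert report.lost == set()

    def test_corrupting_k_mentions_loses_exactly_k(self, ontology, dictionary):
        terms = ["T:0000011", "T:0000012", "T:0000020", "T:0000021"]
        note = pc.synthesize_note(ontology, terms, 2)
        spans = [(m[1], m[2]) for m in note.mentions]
        for k in range(1, len(terms) + 1):
            ops = [pc.CorruptionOp("truncate_suffix", i, 2) for i in range(k)]
            corrupted, _ = pc.corrupt_text(note.text, spans, ops, seed=0)
            report = pc.compare_capture(
                set(terms), pc.extract_terms(dictionary, corrupted))
            assert len(report.retained) == len(terms) - k
            assert report.lost == {note.mentions[i][0] for i in range(k)}
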