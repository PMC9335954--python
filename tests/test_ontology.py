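"""Ontology parsing, identifier resolution, traversal, and search."""

import random

import pytest

import phenocart as pc
from phenocart.errors import OboParseError, OntologyCycleError, TermLookupError
from phenocart.ontology import MatchKind, ResolutionStatus

from conftest import closure_oracle, search_oracle


class TestParsing:
    def test_canonical_fixture_counts_and_version(self, ontology):
        assert len(ontology.terms) == 7
        assert sum(1 for t in ontology.terms.values() if not t.obsolete) == 6
        assert sum(1 for t in ontology.terms.values() if t.obsolete) == 1
        assert ontology.version_label == "toy/2021-01-01"

    def test_smallest_cycle_is_rejected(self):
        obo = ("[Term]\nid: A:1\nname: one\nis_a: A:2\n\n"
               "[Term]\nid: A:2\nname: two\nis_a: A:1\n")
        with pytest.raises(OntologyCycleError) as exc:
            pc.parse_obo(obo)
        assert set(exc.value.cycle) <= {"A:1", "A:2"}

    def test_stanza_without_id_names_its_ordinal(self):
        obo = "[Term]\nid: A:1\nname: one\n\n[Term]\nname: nameless\n"
        with pytest.raises(OboParseError, match="#2"):
            pc.parse_obo(obo)

    def test_duplicate_primary_id_rejected(self):
        obo = "[Term]\nid: A:1\nname: one\n\n[Term]\nid: A:1\nname: again\n"
        with pytest.raises(OboParseError, match="duplicate"):
            pc.parse_obo(obo)

    def test_parsing_is_stanza_order_insensitive(self):
        text = pc.canonical_fixture()
        header, _, body = text.partition("[Term]")
        stanzas = ("[Term]" + body).split("\n\n")
        for seed in range(5):
            shuffled = stanzas[:]
            random.Random(seed).shuffle(shuffled)
            reparsed = pc.parse_obo(header + "\n\n".join(shuffled))
            baseline = pc.parse_obo(text)
            assert reparsed.terms == baseline.terms
            assert reparsed.alt_index == baseline.alt_index
            assert reparsed.children_index == baseline.children_index
            assert reparsed.version_label == baseline.version_label

    def test_agrees_with_obonet_on_structure(self, ontology):
        """Independent parser cross-check on the canonical fixture."""
        import io

        import obonet

        graph = obonet.read_obo(io.StringIO(pc.canonical_fixture()))
        ours = {tid for tid, t in ontology.terms.items() if not t.obsolete}
        assert set(graph.nodes) == ours  # obonet drops obsolete terms
        theirs_edges = {(c, p) for c, p, k in graph.edges(keys=True) if k == "is_a"}
        ours_edges = {(t.id, p) for t in ontology.terms.values()
                      if not t.obsolete for p in t.parents}
        assert theirs_edges == ours_edges
        assert graph.graph["data-version"] == ontology.version_label


class TestResolve:
    @pytest.mark.parametrize("query,primary,status", [
        ("T:0000020", "T:0000020", ResolutionStatus.PRIMARY),
        ("T:0000099", "T:0000012", ResolutionStatus.ALT),
        ("T:0000030", "T:0000020", ResolutionStatus.OBSOLETE_REPLACED),
        ("T:9999999", "T:9999999", ResolutionStatus.UNKNOWN),
    ])
    def test_resolution_statuses(self, ontology, query, primary, status):
        assert ontology.resolve(query) == (primary, status)

    def test_resolution_is_idempotent_and_total(self, ontology):
        ids = list(ontology.terms) + list(ontology.alt_index) + ["X:0"]
        for tid in ids:
            first = ontology.resolve(tid)
            if first.status in (ResolutionStatus.PRIMARY, ResolutionStatus.ALT,
                                ResolutionStatus.OBSOLETE_REPLACED):
                assert ontology.resolve(first.primary).status is ResolutionStatus.PRIMARY

    def test_multiple_replacements_are_never_guessed(self):
        obo = ("[Term]\nid: A:1\nname: one\n\n[Term]\nid: A:2\nname: two\n\n"
               "[Term]\nid: A:3\nis_obsolete: true\n"
               "replaced_by: A:1\nreplaced_by: A:2\n")
        ont = pc.parse_obo(obo)
        assert ont.resolve("A:3") == ("A:3", ResolutionStatus.OBSOLETE_UNREPLACED)


class TestTraversal:
    def test_fixture_examples(self, ontology):
        assert ontology.ancestors("T:0000021") == {"T:0000020", "T:0000001"}
        assert ontology.ancestors("T:0000001") == set()
        assert ontology.descendants("T:0000010") == {"T:0000011", "T:0000012"}
        assert ontology.descendants("T:0000011") == set()

    def test_unknown_or_obsolete_id_raises(self, ontology):
        with pytest.raises(TermLookupError):
            ontology.ancestors("T:9999999")
        with pytest.raises(TermLookupError):
            ontology.descendants("T:0000030")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_closure_on_random_dags(self, seed):
        ont = pc.parse_obo(pc.random_ontology(50, 0.08, seed))
        parent_map = {t.id: set(t.parents) for t in ont.terms.values()}
        child_map: dict[str, set[str]] = {}
        for tid, parents in parent_map.items():
            for p in parents:
                child_map.setdefault(p, set()).add(tid)
        for tid in ont.terms:
            assert ont.ancestors(tid) == closure_oracle(parent_map, tid)
            assert ont.descendants(tid) == closure_oracle(child_map, tid)
            assert ont.ancestors(tid, include_self=True) == \
                closure_oracle(parent_map, tid) | {tid}

    def test_ancestor_descendant_mirror(self):
        for seed in range(5):
            ont = pc.parse_obo(pc.random_ontology(30, 0.1, seed))
            for tid in ont.terms:
                for anc in ont.ancestors(tid):
                    assert tid in ont.descendants(anc)


class TestTermDetails:
    def test_direct_relations_and_genes(self, ontology, associations):
        d = ontology.term_details("T:0000020", associations)
        assert d.superclasses == (("T:0000001", "Phenotypic abnormality"),)
        assert d.subclasses == (("T:0000021", "Febrile seizure"),)
        assert d.genes == ("GENE2",)

    def test_root_has_no_superclasses(self, ontology, associations):
        assert ontology.term_details("T:0000001", associations).superclasses == ()

    def test_gene_list_is_not_propagated(self, ontology, associations):
        # GENE1 annotates the children of T:0000010 but not the term itself
        assert ontology.term_details("T:0000010", associations).genes == ("GENE3",)


class TestSearch:
    def test_prefix_beats_substring(self, ontology):
        hits = ontology.search("seizure", 10)
        assert [(h.term_id, h.match_kind) for h in hits] == [
            ("T:0000020", MatchKind.NAME_PREFIX),
            ("T:0000021", MatchKind.NAME_SUBSTRING),
        ]
        assert [h.rank for h in hits] == [1, 2]

    def test_synonym_prefix_tier(self, ontology):
        hits = ontology.search("lim", 10)
        assert len(hits) == 1
        assert hits[0].term_id == "T:0000010"
        assert hits[0].matched_label == "Limb abnormality"
        assert hits[0].match_kind is MatchKind.SYNONYM_PREFIX

    def test_empty_query_returns_nothing(self, ontology):
        assert ontology.search("", 10) == []
        assert ontology.search("   ", 10) == []

    def test_obsolete_terms_are_not_searchable(self, ontology):
        assert all(h.term_id != "T:0000030" for h in ontology.search("convulsion", 10))

    def test_matches_linear_scan_oracle_on_random_queries(self):
        rng = random.Random(42)
        for seed in range(5):
            ont = pc.parse_obo(pc.random_ontology(30, 0.1, seed))
            labels = [t.name for t in ont.terms.values()] + [
                s.label for t in ont.terms.values() for s in t.synonyms]
            for _ in range(40):
                label = rng.choice(labels)
                a = rng.randrange(len(label))
                query = label[a:a + rng.randint(1, 6)]
                limit = rng.randint(1, 10)
                hits = ont.search(query, limit)
                expected = search_oracle(ont, query, limit)
                assert [(h.term_id, h.matched_label) for h in hits] == \
                    [(tid, lab) for tid, lab, _tier in expected]
                assert [h.rank for h in hits] == list(range(1, len(hits) + 1))


class TestGeneTable:
    def test_fixture_table_loads_fully(self, ontology, associations):
        assert len(associations) == 5

    def test_alt_id_rows_resolve_to_primary(self, ontology):
        table = "T:0000099\tGENEX\t9"
        assocs = pc.load_gene_associations(table, ontology)
        assert assocs == [pc.GeneAssociation("T:0000012", "GENEX", "9")]

    def test_unknown_rows_are_dropped_with_warning(self, ontology):
        table = "T:0000020\tGENEA\t1\nT:9999999\tGENEB\t2"
        with pytest.warns(UserWarning, match="dropped 1"):
            assocs = pc.load_gene_associations(table, ontology)
        assert [a.gene_symbol for a in assocs] == ["GENEA"]

    def test_malformed_row_names_line_number(self, ontology):
        from phenocart.errors import GeneTableError
        with pytest.raises(GeneTableError, match="line 2"):
            pc.load_gene_associations("T:0000020\tG\t1\nonly-one-field", ontology)
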