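# phenocart

Structured deep phenotyping at the point of care, as a library and CLI.

Clinical phenotype data is most useful downstream — for diagnosis, gene
prioritization, and cohort research — when it is captured as discrete
ontology terms rather than free text. The Human Phenotype Ontology (HPO)
provides the vocabulary: a DAG of terms like `HP:0001250` *Seizure* with
synonyms, definitions, and `is_a` parents. In practice, though, clinicians
often copy-paste term names into notes, and the terms are later recovered
by dictionary NLP — a pipeline in which a single slip (pasting `lim`
instead of `limb`) silently deletes a phenotype and can push the causal
gene far down a phenotype-driven ranking.

`phenocart` implements the structured alternative end to end, and the
comparison that motivates it:

- **ontology** — an OBO flat-file parser (prefix-agnostic, `hpo.obo`
  compatible subset) with identifier resolution through `alt_id` and
  `replaced_by`, transitive `is_a` traversal, per-term details, and tiered
  autocomplete search over names and synonyms.
- **annotation** — the "shopping cart": an ordered, duplicate-free working
  set of terms, each with a negation flag and a free-text comment, with
  validation (unknown/obsolete/duplicate block saving; a term plus its own
  ancestor only warns) and set-wise diffing between cart states.
- **store** — append-only, version-tagged persistence: each save writes a
  full snapshot as canonical JSON (sorted keys, no insignificant
  whitespace, explicit `schema_version`), so byte equality equals record
  equality and history reconstructs per-encounter changes by diffing.
- **export** — renderings of a saved record: a minimal RTF table for
  clinical notes, TSV for pipelines, a Phenopacket-style JSON subset
  (`excluded` mirrors negation), and note-template token expansion
  (every `.chophpo` in a note becomes the table).
- **textmatch** — the free-text arm: an Aho-Corasick automaton over all
  non-obsolete names and exact synonyms, case-insensitive,
  word-boundary-constrained, longest-match-wins; plus reproducible
  copy-paste corruption operators (suffix truncation, character deletion,
  adjacent transposition).
- **generank** — a transparent information-content ranker. Associations
  propagate up the ontology; a term's information content is
  IC(t) = −ln(n_t/N) where n_t of N genes are propagated-annotated to t
  (unannotated terms get the smoothed −ln(1/(N+1))); a gene's score for a
  patient is Σ IC(t) over the patient terms it is associated with, and
  ranks break ties by gene symbol.
- **fixtures** — deterministic generators for toy ontologies, gene tables,
  and synthetic notes with ground-truth mention spans, so everything runs
  with zero downloads.

## Worked example

The `demo` subcommand runs the whole comparison on a generated 40-term
ontology and 25-gene corpus: it seeds a causal gene, embeds 5 of its
phenotype terms in a synthetic note, corrupts 1 mention the way a
copy-paste slip would, then extracts terms from the corrupted note and
ranks genes under both capture arms.

```
$ phenocart demo --terms 5 --corruptions 1 --seed 1
Capture comparison (seed 1): 5 terms, 1 copy-paste corruption(s)
  causal gene: GENE001  (corpus of 25 genes)

                                structured   extracted
  terms retained                      5/5        4/5
  causal gene rank                       8          13
  terms lost to extraction: T:0000024
  corruption (truncate_suffix): 'Muzepa' -> 'Muzep'
```

Structured capture keeps all 5 terms and ranks the causal gene 8th of 25;
the free-text arm loses the one corrupted term (`Muzepa` → `Muzep` no
longer matches the dictionary) and the causal gene drops to rank 13. By
construction the dropped term is one the causal gene is annotated to, and
since scores are sums of non-negative per-term contributions, losing such
a term can never *improve* the causal gene's rank.

The same workflow is scriptable against the built-in toy ontology:

```
$ phenocart search seizure
1	T:0000020	Seizure	Seizure	name_prefix
2	T:0000021	Febrile seizure	Febrile seizure	name_substring
$ phenocart cart add P1 T:0000021 --comment "linked gene: GENE3"
$ phenocart save P1
$ phenocart export P1 --format phenopacket
```

Point `--ontology` at a downloaded `hp.obo` and `--genes` at an HPO
`genes_to_phenotype`-style TSV to run against the production ontology.

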