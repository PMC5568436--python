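# Methods

## The model

A Syntactically Analyzed Network (SAN) is built from a per-utterance
dependency analysis of one speaker's production. Under Dependency Grammar
every word of an utterance is the dependent of exactly one governor — another
word, or the notional root at position 0 — through a labeled relation. The
network conflates these analyses over a whole session: nodes are unique
canonical word forms, and a directed edge governor → dependent carries the
multiset of relation labels with which that ordered pair was produced,
together with its total count. Root attachments never become edges (the
network connects words to words only), and node occurrence counts record how
many times each word was produced.

The approach assumes the annotation is authored by a competent annotator (or
imported from an annotated corpus); the toolkit validates structural
well-formedness — single head, acyclicity, positions in range, labels in the
active scheme, one root per utterance — but it does not parse and it takes no
stance on whether the analysed unit is the word or the morpheme: whatever the
annotation tokenizes is the unit.

### Analysis conventions

- **DP-hypothesis** (default, configurable): the determiner governs the noun,
  so in *an apple* the edge is `an → apple`. `apply_dp_hypothesis_check`
  reports (advisorily) any arc where a determiner-labeled token depends on a
  noun instead.
- **Word unification**: variant spellings are merged through a
  `NormalizationMap` whose canonical forms must be fixed points (no chains),
  which makes unification idempotent. It is applied when annotations are
  read, so annotation files stay faithful to the transcription.
- **Default label scheme**: relations {subject, object, complement, modifier,
  attribute} plus the reserved `root`; categories default to conventional
  parts of speech, and a bilingual study can replace them with e.g.
  {English, Spanish, Proper name} for downstream node coloring.
- **Single root per utterance** by default; fragment-rich child speech can be
  accepted with `allow_multiple_roots=True`, which attaches each fragment
  head to root.

## Graph statistics

All distance and clustering metrics run on the **undirected simple
projection** of the directed labeled graph, with unit edge lengths. The
clustering of any tree is 0 and of any complete graph 1, and for trees
E = N − 1 — the internal consistency checks the test suite enforces.

- *C*: mean local clustering over all nodes; nodes of degree < 2 contribute 0.
- *L*: mean shortest-path length over unordered node pairs; defined only on a
  connected graph, so it is always computed on the **giant (weakly)
  connected component**. A disconnected input is refused with instructions to
  take the giant component, never silently reduced.
- Diameter: maximum shortest-path length, same domain as *L*.
- ⟨k⟩ = 2E/N and the node/edge ratio N/E, on the chosen scope.

### Edge-counting conventions

Network programs disagree on what an "edge" is when a word pair is linked by
several relations. Both conventions are provided and named explicitly:
`pair` (default) counts each connected ordered pair once; `labeled` counts
each distinct (governor, dependent, relation) triple. Hub degree uses the
`labeled` convention by default — a pair linked by both *subject* and
*object* contributes 2 directed edges — switchable to `simple`
(distinct-neighbor) mode. Relation-frequency tables likewise come in `token`
mode (every produced arc, computed from the annotation list) and `type` mode
(distinct labeled edges, computed from the network).

### Small-world flag

The summary flags a network as small-world when clustering substantially
exceeds the Erdős–Rényi expectation while the path length stays near the
random-graph scale: C > a·(⟨k⟩/N) and L ≤ b·(ln N / ln ⟨k⟩), with a = 4 and
b = 2 by default. The factors are configurable; the flag is descriptive
shorthand, not a statistical test. A ring lattice (high C, long L) is
correctly not flagged; a few rewired shortcuts flip the flag.

### Determinism and ties

Components are sorted by size descending with ties broken by the
lexicographically smallest member; hub rows sort by degree descending then
alphabetically; category conflicts on a node resolve by majority vote with a
lexicographic tie-break and a logged conflict. Exports serialize nodes and
edges in sorted order, so equal networks produce byte-identical files and the
CLI pipeline is reproducible run to run.

## Cleaning rules

CHAT transcription codes removed by default: bracketed codes (`[/]`, `[*]`,
…, including nested), the unintelligibility markers `xxx`/`yyy`/`www`,
pause marks `(.)`–`(...)`, bullet/timestamp spans, `&`- and `+`-prefixed
event/terminator codes, and edge punctuation (word-internal apostrophes are
kept). Literal removal patterns (e.g. a stray `*CHI:`) apply in listed order.
Case folding is on by default so *The*/*the* form one node. The exact default
code set is this package's own choice and is intentionally conservative;
cleaning is idempotent and total, and an utterance emptied by cleaning is
flagged and excluded from the network. Self-loop arcs — produced by a
repeated word depending on itself or by a unification collision (*da* → *the*
under a `the → da` arc) — are dropped with a logged warning, since dependency
grammar forbids self-dependency.

## The synthetic-data generator

Real corpora of this kind live in CHILDES and require manual expert
annotation, so the generator emulates only the *shape* of child speech that
the software contracts depend on, not developmental theory:

| parameter | default | rationale |
|---|---|---|
| `n_utterances` | 100 | a short recording session |
| `vocab_size` | 60 | small early productive vocabulary |
| `zipf_exponent` | 1.0 | classical word-frequency rank law |
| `utterance_length_range` | (1, 10) | short child utterances |
| `bilingual_fraction` | 0.0 | fraction of vocabulary tagged with the second-language category |
| `seed` | required for reproduction | single explicit PRNG, no global state |

Word forms are sampled i.i.d. from a Zipf-ranked pseudo-word vocabulary that
deliberately includes ñ and accented vowels, so every export path is
exercised against non-ASCII forms. Dependency trees are built by random
attachment — each token after the first attaches to a uniformly chosen
earlier token — which guarantees a valid single-rooted, single-head, acyclic
analysis by construction; relation labels are drawn uniformly from the
scheme. What the fixtures do **not** model: realistic grammar (no word-order
or category constraints on attachment), acquisition trajectories, speaker
errors, or the empirical relation-label distribution. Passing tests therefore
demonstrate software correctness (parsing, conflation, metrics, round-trips,
determinism) on child-speech-shaped data, not claims about real development.

The acceptance script runs the pipeline at 300 utterances over a 120-word
vocabulary — enough for a dense giant component with non-trivial clustering —
and the property tests use 100 random graphs of ≤ 40 nodes against
brute-force oracles (triangle counting, Floyd–Warshall, union–find), sizes at
which the oracles are exact and fast.

## Numerical and format choices

- Internal statistics keep full floating precision; rounding happens only in
  CSV presentation (C to 3 decimals, N/E to 6, ⟨k⟩ and L to 3, mirroring the
  usual summary-table layout).
- GraphML is the interchange format (importable by both Gephi and
  Cytoscape); multi-label edges join labels with `|`, and a
  `relation_counts` attribute (`label:count|…`) preserves per-label
  multiplicities so a write → read round trip is exact.
- The pairs format disambiguates repeated word forms within an utterance with
  a `#k` occurrence suffix, stripped before network construction; a
  single-word utterance is written as a bare-form line. Because the format
  orders words by first mention, round-tripping preserves the word multiset
  and labeled arc set, not the original token order.
- Strict UTF-8 everywhere; undecodable bytes fail loudly rather than being
  replaced.

## Known limitations

- The CHAT reader covers the dialect subset needed for corpus extraction;
  `%mor`/`%gra` tiers, overlap notation and audio alignment are ignored.
- No automatic parsing, no rendering/layout/coloring (downstream network
  programs do that from the exported attributes), no scale-free exponent
  fitting, and no null-model ensembles beyond the single Erdős–Rényi
  reference used by the small-world flag.
- Scripts other than Greco-Latin alphabets are handled only to the extent
  that the transcription is already romanized text.
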