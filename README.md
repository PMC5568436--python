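# sannet — syntactically analyzed networks from child-speech transcripts

`sannet` turns dependency-annotated speech transcripts into **Syntactically
Analyzed Networks (SANs)** — directed labeled graphs with unique word forms as
nodes and governor → dependent syntactic links as edges — and computes the
network statistics used to track typical, atypical and bilingual language
development: giant-component clustering coefficient *C*, characteristic path
length *L*, diameter, average degree ⟨k⟩ = 2E/N, node/edge ratio N/E,
relation-frequency tables and hub (highly connected word) rankings.

It is written for clinical linguists and language-acquisition researchers who
annotate CHILDES-style transcripts by hand (or import standard dependency
corpora) and analyze the resulting networks in Gephi or Cytoscape. Unlike
word-adjacency / co-occurrence networks, a SAN is built from an explicit
syntactic analysis of every utterance under Dependency Grammar: each word is
attached to exactly one governor by a labeled relation (subject, object,
complement, modifier, attribute). Analysis conventions are configurable; the
default follows the DP-hypothesis, under which the determiner governs the
noun — in *an apple*, the noun depends on the article, so the network edge is
`an → apple`.

## What the toolkit does

1. **`chat_io`** — read CHAT (`.cha`) transcripts, select one speaker tier
   (e.g. `*CHI`), strip transcription codes (`[/]`, `xxx`, `&=laughs`, …) and
   tokenize. UTF-8 throughout: ñ and accented characters are never corrupted.
2. **`annotation`** — represent per-utterance dependency analyses; read/write
   the three-column *pairs* format (`governor<TAB>relation<TAB>dependent`),
   import CoNLL-U, validate (single head, acyclic, labels in scheme), unify
   variant word forms (*mammma* → *mamma*, *da* → *the*).
3. **`network_builder`** — conflate utterances into a SAN; extract weakly
   connected components and the giant component.
4. **`graph_stats`** — summary statistics, relation frequencies (token or
   type counts), hub tables by directed degree, longitudinal tracking across
   sessions.
5. **`exporters`** — GraphML (Gephi/Cytoscape), SIF (Cytoscape), edge CSV,
   pairs, and CSV result tables.
6. **`fixtures`** — seeded synthetic corpora (Zipf-distributed vocabulary,
   random dependency trees over 1–10 tokens) and reference graphs with known
   closed-form metrics.
7. **`cli`** — the `san` command: `clean`, `validate`, `build`, `export`,
   `stats`, `hubs`, `relations`, `track`, `fixtures`, `run`.

## Worked example

```python
import sannet as s

scheme = s.LabelScheme()                      # subject/object/complement/modifier/attribute
unify  = s.NormalizationMap({"da": "the"})

pairs = "da\tmodifier\tdoggie\n\nsee\tobject\tthe\nthe\tmodifier\tdoggie\n"
annotations = s.read_pairs(pairs, scheme, normalization=unify)
san = s.build_san(annotations, scheme=scheme)
print(sorted(san.nodes))                      # ['doggie', 'see', 'the']
print(san.edges[("the", "doggie")].count)     # 2   (da was unified into the)

stats = s.summarize(san, scope="giant")
print(stats.n_nodes, stats.n_edges,
      round(stats.avg_degree_k, 3), round(stats.node_edge_ratio, 6))
# 3 2 1.333 1.5
```

The two annotated utterances (*da doggie*, *see the doggie*) collapse into a
three-word network: unification sends `da` to the node `the`, so the
`the → doggie` edge accumulates a count of 2, and the giant component has
N = 3 nodes, E = 2 edges, hence ⟨k⟩ = 2·2/3 ≈ 1.333 and N/E = 1.5. A
connected component with E = N − 1 is a tree, so its clustering coefficient
is 0 — the typical shape of the earliest child networks, before densification
raises *C* and the network becomes small-world (high *C*, low *L*).

From the shell, the same pipeline end to end:

```sh
san fixtures --n-utterances 40 --seed 17 --out-dir fx/
san validate fx/corpus.pairs --scheme fx/scheme.yml
san export fx/corpus.pairs --format graphml --out fx/network.graphml
san stats fx/network.graphml --scope giant
san hubs fx/network.graphml --min-degree 8
```

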