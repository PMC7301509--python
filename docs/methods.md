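# Methods

## Data model

The vocabulary is stored as five plain tables: MH details (id, preferred
name, tree numbers, categories, semantic types, UMLS concept ids,
publication count), the MH↔UMLS concept link table, SCR details, the
SCR→broader-MH relation, and the MH parent/child relation. MeSH concepts,
entry terms and qualifier records are outside the model: every stored
record is either a main heading or a supplementary concept record, and
"term" below means either. Multi-valued cells are `|`-joined and sorted;
rows are sorted on the first column, so serialization is byte-
deterministic. A JSON manifest records the schema version, the total
publication count N, and per-table row counts. An optional sixth table
(`NonMeshConcepts`) lists non-MeSH-synonymous UMLS concepts by preferred
name; it exists so the recursive recognition route can be exercised with
the built-in dictionary matcher alone.

Identifier lookups are case-sensitive; name lookups case-insensitive.
Tree numbers are kept verbatim as dotted strings. A top-level address
such as `C10` has no represented parent; its first character is the
category. An MH's category set is the set of first letters of its tree
numbers; an SCR, having none, inherits the union of its broader MHs'
categories — a convention required for the cross-category rule to apply
to rare-disease records at all.

The hierarchy is encoded twice — tree-number prefixes and the
parent/child table — and the generator guarantees the two agree; the test
suite exploits this by navigating one encoding with networkx as an oracle
for code that navigates the other.

## Synthetic vocabulary generator

The generator emulates the structural features the measures depend on:
a forest of categories, a DAG shape (some nodes carry a second parent and
hence extra tree numbers, propagated consistently to all descendants by
deriving every address from the parent DAG), SCRs attached to one or more
broader MHs, many-to-one CUI→MH links, one-to-one CUI→SCR links, and
skewed publication counts. Defaults: 2 categories, depth 4, branching 2
(30 MHs), 4 SCRs, 2 non-MeSH concepts, multi-parent rate 0.1, counts
drawn from a Zipf(a=2) law capped at 10^4 — many rarely indexed terms,
a few heavily indexed ones, as in real indexing data. N defaults to the
sum of per-term counts, which keeps every occurrence probability below 1
(positive IC everywhere) whenever at least two categories carry counts.

It does **not** emulate: real MeSH names and synonymy (names are
synthetic `adjective noun index` strings, so recognition tests probe
matching mechanics, not lexical coverage), abbreviations, qualifier
records, the real 16-category breadth, or realistic tree depths (real
MeSH reaches depth 13). Passing tests therefore demonstrate correctness
of the algorithms on MeSH-shaped structures, not recognition recall on
real clinical text.

## Information content

`IC(d) = -log10(freq(D(d))/N)` with `D(d)` inclusive of `d` itself.
Inclusion of the term's own count is a deliberate choice: with a strictly
proper descendant set a leaf's frequency would be 0 and its IC undefined;
the inclusive roll-up is the standard Resnik construction and makes IC
anti-monotone along every parent/child edge. An `include_self=False` flag
preserves the alternative reading. Base 10 is fixed so that
`10^(-IC(MICA))` equals `P(MICA)`, the quantity the Schlicker measure
needs. A roll-up of 0 is replaced by a pseudo-count of 1, making
never-indexed terms maximally (log10 N) rather than infinitely
informative. N is always supplied by the frequency table (dataset
manifest, counts TSV header, or the count fetcher) — never hard-coded.

The publication-count fetcher queries the PubMed MeSH field through the
NCBI esearch endpoint, retries transient failures, and caches to a JSON
file; it accepts an injected fetch function, and all tests run against
injected fixtures only.

## Similarity

All four IC measures reduce to `IC(MICA)`; the MICA is taken over the
*inclusive* ancestor sets (each term is its own ancestor), so
`MICA(d,d) = d`. Ties are broken by the smaller id for determinism. The
Wang measure likewise includes the self term with contribution ω^0 = 1,
and `n_a` is the minimum edge count over all tree-number chains.

Boundary conventions, chosen to keep the measurement model's two global
assertions — identity pairs score exactly 1, cross-category pairs exactly
0 — true for every measure:

- The cross-category short-circuit applies to **all five** measures,
  including Jiang–Conrath, whose raw form could otherwise be positive
  across categories when both ICs are small.
- The raw per-measure functions implement the formulas literally
  (`sim_resnik(d,d) = IC(d)`, `sim_rel(d,d) = 1 − P(d)`); the top-level
  `similarity()` dispatcher short-circuits an identical resolved MH pair
  to exactly 1.0 under every method. Users comparing annotation sets get
  the boundary behavior; users studying a raw formula can call it
  directly.
- Lin's 0/0 case (two terms of zero IC): 1 for the same term, 0
  otherwise.

The maximal-similarity rule for multi-tree-number terms: for the IC
measures the maximum over tree-number pairs provably equals the global
MICA computation (every common ancestor lies on some chain pair, and all
four formulas are monotone in IC(MICA)), so the dispatcher computes the
global form; a test verifies the equality against per-pair enumeration.
Wang scores depend on the whole ancestor chain (the SV normalizer
changes with the address), so the dispatcher enumerates tree-number pairs
explicitly and keeps the maximum, while `sim_wang` itself exposes the
whole-term form with contributions minimized over all chains.

SCR endpoints are replaced by their broader-MH sets before measuring;
SCR-vs-SCR similarity is the maximum over the cross product. An SCR with
an empty broader set cannot occur in a validated dataset.

## Recognition

Normalization lowercases, removes ASCII and typographic
apostrophes/backticks (dropping a possessive `s` left dangling, e.g.
`Paget's` → `paget`, while `Graves'` → `graves`), replaces remaining
punctuation by spaces and collapses whitespace; it is idempotent.
Tokens are whitespace-separated after normalization; there is no
stemming and no abbreviation expansion, so inputs like `IgG levels`
will not match — a known limitation of dictionary matching.

Matching is greedy leftmost-longest over normalized token windows,
capped at the longest stored name; annotations never overlap. Ties at
equal window length prefer MH over SCR, then the smaller id. The default
semantic-type filter is the 33-code disease-related list (`dsyn`, `neop`,
`fndg`, ...); an empty filter accepts everything. SCR hits optionally
expand to their broader MHs (`scr_expanded` route). Names of non-MeSH
concepts found in the text are re-submitted as free text up to a
recursion depth limit (default 2); cycles are broken by a visited-name
set, which also lets an embedded MH name win once the enclosing concept
name is excluded.

MetaMap is not re-implemented: the MMI adapter parses the documented
pipe-delimited fielded output, rescales scores from 0–1000 to [0,1],
resolves CUIs through the concept table, and routes unresolvable CUIs
through the recursive path on the row's preferred name. Multiple
candidate rows per phrase are all kept; callers filter by score.

## Numerical and procedural choices

- All similarity values are plain floats; no tolerance is applied
  internally — the exact-0 and exact-1 guarantees are by construction
  (short-circuits), not by rounding.
- The RRF dialect accepted by the builder: UTF-8, no quoting, one
  trailing `|` per line (a line ending in `|` always has it stripped as
  the trailing separator, so writers must close an empty final field
  with an extra `|`). Strict mode fails on bad arity with the line
  number; lenient mode skips with a log message.
- The on-disk store is TSV + JSON manifest rather than a binary columnar
  format: portability and diffability over compactness.
- Problem sizes in the test suite: oracle sweeps run on a ~240-term
  two-category DAG (1000 random pairs × 10 ω values for Wang; five
  generator seeds for the IC oracle), which exercises multi-parent
  addresses while keeping the whole suite in seconds.

## Known limitations

- IC table construction scans all tree numbers per term (quadratic in
  vocabulary size); fine up to a few thousand terms, and the realistic
  path for full MeSH would memoize prefix indexes.
- The recognizer is a dictionary matcher over preferred names only; real
  MeSH entry-term synonymy is out of the data model, so recall on real
  text depends on an upstream concept tagger (e.g. via the MMI adapter).
- Wang similarity between terms linked only through an ancestor outside
  their own categories is 0 by the category rule even though a shared
  multi-category ancestor could exist in principle.
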