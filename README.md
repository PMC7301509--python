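# meshsem

Recognition, normalization and semantic comparison of MeSH terms for
biomedical text mining.

MeSH (Medical Subject Headings) is the controlled vocabulary the National
Library of Medicine uses to index the biomedical literature. Annotating
free-text disease phenotypes with MeSH terms, and measuring how close two
annotations are, underpins phenotype harmonization, data integration and
systems-genetics analyses. Most similarity tools model only main headings
(MHs) — the descriptor component that carries hierarchical *tree numbers*
such as `C10.574.945` — and cannot handle supplementary concept records
(SCRs), the tree-number-less records that cover rare diseases like
"Bardet-Biedl syndrome 11". `meshsem` models both: SCRs are linked to one
or more broader MHs and are mapped onto the hierarchy through them.

The package provides:

- a five-table data model (MH details, MH↔UMLS concept links, SCR details,
  SCR→broader-MH relations, parent/child pairs) with a plain-TSV on-disk
  form, a builder for UMLS-style pipe-delimited source files, and a
  deterministic synthetic-vocabulary generator so everything is testable
  without licensed data;
- a dictionary recognizer that normalizes free text (case, apostrophes and
  backticks, punctuation) and finds leftmost-longest matches of preferred
  names, with SCR→MH expansion and recursive resolution of
  non-MeSH-synonymous UMLS concepts; an adapter parses MetaMap fielded
  (MMI) output, so an external NLP engine can supply candidate concepts;
- five semantic-similarity measures over the hierarchy.

## The measures

Information content is estimated from publication counts rolled up over
each term's descendants:

    P(d) = freq(D(d)) / N,    IC(d) = -log10 P(d)

where `D(d)` is the inclusive descendant set of `d` and `N` the total
number of indexed publications. With MICA the most informative common
ancestor of two terms:

    Sim_res(d1,d2) = IC(MICA)
    Sim_lin(d1,d2) = 2·IC(MICA) / (IC(d1)+IC(d2))
    Sim_jc (d1,d2) = 1 − min(1, IC(d1)+IC(d2) − 2·IC(MICA))
    Sim_rel(d1,d2) = Sim_lin(d1,d2) · (1 − 10^(−IC(MICA)))

The graph-based Wang measure gives each ancestor `a` of `d` a contribution
`S_d(a) = ω^(n_a)` (`n_a` = minimum edge count from `d` to `a`, ω = 0.6 by
default) and scores a pair by the contributions of shared ancestors:

    Sim_wang(d1,d2) = Σ_{t∈A(d1)∩A(d2)} (S_d1(t)+S_d2(t)) / (SV_d1+SV_d2)

Two MeSH-specific rules apply to every measure: terms whose tree numbers
lie in disjoint top-level categories (first letter, e.g. `C` diseases vs
`F` psychiatry and psychology) score exactly 0, and when multiple tree
numbers yield multiple values only the maximum is kept. SCR endpoints are
replaced by their broader MHs before measuring.

## Worked example

```
$ meshsem fixture --seed 1 --out demo/ds
demo/ds 30 MHs  4 SCRs

$ meshsem ic --dataset demo/ds --term D000003
mesh_ui ic
D000003 0.639849

$ meshsem sim --dataset demo/ds --method lin D000003 D000004
0.436545
$ meshsem sim --dataset demo/ds --method wang D000003 D000004
0.269663
$ meshsem sim --dataset demo/ds --method wang D000003 D000016
0
```

The fixture holds two categories (`C` and `F`). `D000003` ("acute
arthritis 003", tree number `C01.003`) and `D000004` ("atypical
encephalitis 004", `C01.002.004`) share only the category root, so their
Lin score reflects the root's low information content, and the Wang score
is (0.6+0.36)/(1.6+1.96) ≈ 0.2697 — the root contributes ω and ω² along
the two chains. `D000016` sits in category `F`, so every measure returns
exactly 0 against it. Recognition round-trips stored names:

```
$ echo "acute arthritis 003" | meshsem parse --dataset demo/ds
input   start  end  cui       mesh_ui  mesh_name            record_kind  route   score
acute arthritis 003  0  19  C1000003  D000003  acute arthritis 003  MH  direct  1
```

The library API mirrors the CLI: `generate_fixture`, `load_dataset`,
`build_ic_table`, `similarity`, `parse_text`, `parse_mmi_output`.

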