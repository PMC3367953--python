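# specieslink

Species recognition and gene–species assignment for biomedical text.

Gene normalization — mapping a gene mention such as *TP53* to a database
identifier — is impossible without knowing the organism, because homologous
genes share names across species. `specieslink` solves the species half of
that problem: it detects organism names in titles and abstracts, normalizes
them to NCBI Taxonomy identifiers (human → 9606), and links each
pre-tagged gene mention to a species. Gene mention recognition itself is
out of scope; gene spans are inputs (PubTator-style TSV).

It is aimed at text-mining pipelines that need a fast, deterministic,
dictionary-plus-rules species module with no model downloads.

## Method

Species mentions come from case-insensitive, token-boundary-anchored
dictionary lookup over a pre-filtered species lexicon (vernacular terms
like "porcine" included; strains like "E. coli K-12" matched whole),
augmented by two refinements:

* **cell-name rule** — a known cell line implies its organism when
  "cell(s)" co-occurs in the same noun phrase ("HeLa cancer cell" → human);
* **specificity inference** — a general term co-occurring with a specific
  name is re-labeled with the specific taxon ("Arabidopsis" next to
  "Arabidopsis thaliana" → 3702).

Each gene mention *g* is then assigned a tax id by a deterministic cascade;
the first rule that fires wins:

1. **prefix** — if *g* starts with a lowercase organism-abbreviation letter
   followed by an uppercase letter (hRrp46p → human, mSos1 → mouse);
2. **cooccurrence** — the species mention in *g*'s sentence, preferring the
   left context over the right and, per side, the smallest character gap;
3. **focus species** — argmax over species *s* of
   `w(s) = 2·#title-mentions(s) + #other-mentions(s)`, with ties broken by
   corpus-global species frequency (human > rat > mouse > …), never randomly;
4. **SRI fallback** — for documents with no species mention at all, a
   cue-word model over {human, mouse, yeast, fly} scoring
   `score(s) = Σ_w count(w)·max(0, P(w|s) − max_{s'≠s} P(w|s'))`
   ("cohort" → human, "ferment" → yeast).

An evaluator reports mention-level precision/recall/F (exact span + tax id)
and assignment accuracy with a per-rule breakdown, and a seeded synthetic
corpus generator plants documents whose correct answer is known by
construction for every cascade stage.

## Worked example

With a document `docs/ex1.txt`

```
A study of hRrp46p and the exosome.
In mouse tissue, the Rrp4 gene was upregulated. HeLa cells expressed Exo1.
```

and gene spans `genes.tsv` (`doc_id  start  end  surface  Gene`, offsets on
the title + space + abstract text):

```
ex1	11	18	hRrp46p	Gene
ex1	57	61	Rrp4	Gene
ex1	105	109	Exo1	Gene
```

running

```
specieslink tag --input docs --format text --genes genes.tsv \
    --output out.tsv --output-format tsv
```

prints `tagged 1 documents -> out.tsv` and writes

```
ex1	39	44	mouse	Species	10090	dictionary
ex1	84	88	HeLa	Species	9606	cell_line
ex1	11	18	hRrp46p	Gene	9606	prefix
ex1	57	61	Rrp4	Gene	10090	cooccurrence
ex1	105	109	Exo1	Gene	9606	cooccurrence
```

Reading: "mouse" was found by dictionary lookup (tax 10090) and "HeLa"
implies human via the cell-name rule. *hRrp46p* is assigned human by its
`h` prefix; *Rrp4* gets mouse from the species mention to its left in the
same sentence; *Exo1* gets human from the HeLa-derived mention in its
sentence. The same library surface is available programmatically
(`specieslink.pipeline.tag_document`), and `specieslink evaluate` scores
such output against a gold TSV.

Other subcommands: `build-lexicon` (filter raw name records by a taxid
whitelist, add curated terms), `train-sri`, `make-fixtures`.

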