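"""Deterministic synthetic corpus generation.

Every cascade stage needs documents with a known correct answer: genes
carrying an organism-prefix letter, genes next to species mentions (left,
right, nearest, cell-line-derived), genes resolvable only through the
document's focus species (including deliberate weighted ties), and
species-free documents carrying cue words for the SRI fallback.  The
generator plants exactly one gene per document from slot-filled sentence
templates, so offsets and the gold species are correct by construction and
a noise-free corpus must be recovered perfectly by the cascade.

Templates use slot filling only -- no free text generation -- which keeps
the output byte-reproducible from the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from specieslink.io_formats import GoldRecord, write_gold
from specieslink.lexicon import GlobalFrequencyTable, global_rank
from specieslink.preprocess import Document, build_document

#: (display surface, tax_id) pool used to fill species slots.
DEFAULT_SPECIES_POOL: tuple[tuple[str, int], ...] = (
    ("human", 9606),
    ("mouse", 10090),
    ("rat", 10116),
    ("zebrafish", 7955),
    ("Drosophila melanogaster", 7227),
    ("Saccharomyces cerevisiae", 4932),
    ("Arabidopsis thaliana", 3702),
    ("E. coli K-12", 83333),
    ("Sus scrofa", 9823),
    ("chicken", 9031),
)

#: Cell-line cues (display, tax_id); displays match the packaged cell lexicon.
CELL_LINE_POOL: tuple[tuple[str, int], ...] = (
    ("HeLa", 9606),
    ("3T3", 10090),
    ("PC12", 10116),
)

#: Cue words planted for the SRI fallback, per species.
CUE_WORDS: dict[int, tuple[str, ...]] = {
    9606: ("cohort", "patients", "clinical"),
    10090: ("littermates", "knockout", "weaning"),
    4932: ("ferment", "budding", "sporulation"),
    7227: ("ommatidia", "instar", "metamorphosis"),
}

#: Background vocabulary shared by all SRI labels (trains to weight zero).
SRI_BACKGROUND = (
    "gene expression analysis sequence protein measurement result method "
    "sample signal pathway regulation transcript assay replicate".split()
)

RULE_ORDER = ("prefix", "cooccurrence", "focus", "sri")

DEFAULT_QUOTAS = {"prefix": 0.1, "cooccurrence": 0.34, "focus": 0.36, "sri": 0.2}

_PREFIX_LETTERS = "hmrdzxy"


@dataclass
class FixtureConfig:
    """Generator parameters; the seed fully determines the output."""

    n_docs: int = 50
    seed: int = 0
    quotas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_QUOTAS))
    label_noise: float = 0.0
    species_pool: tuple[tuple[str, int], ...] = DEFAULT_SPECIES_POOL

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if not self.species_pool:
            raise ValueError("species pool must be non-empty")
        unknown = set(self.quotas) - set(RULE_ORDER)
        if unknown:
            raise ValueError(f"unknown rules in quotas: {sorted(unknown)}")
        if any(q < 0 for q in self.quotas.values()):
            raise ValueError("quotas must be nonnegative")
        if sum(self.quotas.values()) > 1.0 + 1e-9:
            raise ValueError("quotas must sum to at most 1")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "quotas" in data:
            data["quotas"] = dict(data["quotas"])
        return cls(**data)


@dataclass
class FixtureCorpus:
    """A generated corpus with everything the pipeline and scorer need."""

    documents: list[Document]
    raw_texts: dict[str, str]
    gene_spans: dict[str, list[tuple[int, int]]]
    gold: list[GoldRecord]
    rule_counts: dict[str, int]


def allocate_rule_counts(cfg: FixtureConfig) -> dict[str, int]:
    """Docs per rule: floor allocation, remainders by largest fraction.

    Quota mass not assigned to any rule goes to ``focus`` (the stage that
    dominates real corpora).
    """
    quotas = {r: cfg.quotas.get(r, 0.0) for r in RULE_ORDER}
    leftover_mass = 1.0 - sum(quotas.values())
    quotas["focus"] += leftover_mass
    raw = {r: cfg.n_docs * q for r, q in quotas.items()}
    counts = {r: int(raw[r]) for r in RULE_ORDER}
    remainder = cfg.n_docs - sum(counts.values())
    order = sorted(RULE_ORDER, key=lambda r: (-(raw[r] - counts[r]), RULE_ORDER.index(r)))
    for r in order[:remainder]:
        counts[r] += 1
    return counts


class _DocBuilder:
    """Accumulates title/abstract sentences while tracking the gene span in
    the joined title-space-abstract coordinate system."""

    def __init__(self) -> None:
        self._sections: dict[str, list[str]] = {"title": [], "abstract": []}
        self._pending_gene: Optional[tuple[str, int, tuple[int, int], str]] = None

    def sentence(self, section: str, *fragments: str | tuple[str, str]) -> None:
        parts: list[str] = []
        length = 0
        gene_local: Optional[tuple[int, int]] = None
        gene_text = ""
        for frag in fragments:
            if isinstance(frag, tuple):
                kind, text = frag
                if kind == "gene":
                    gene_local = (length, length + len(text))
                    gene_text = text
                parts.append(text)
                length += len(text)
            else:
                parts.append(frag)
                length += len(frag)
        self._sections[section].append("".join(parts))
        if gene_local is not None:
            # defer absolute offset computation to finish()
            self._pending_gene = (section, len(self._sections[section]) - 1,
                                  gene_local, gene_text)

    def finish(self, doc_id: str) -> tuple[Document, str, tuple[int, int]]:
        if self._pending_gene is None:
            raise ValueError("no gene planted in document")
        title = " ".join(self._sections["title"])
        abstract = " ".join(self._sections["abstract"])
        sections = [("title", title)]
        if abstract:
            sections.append(("abstract", abstract))
        doc = build_document(doc_id, sections)
        section, sent_idx, (ls, le), gene_text = self._pending_gene
        base = 0 if section == "title" else len(title) + 1
        for i in range(sent_idx):
            base += len(self._sections[section][i]) + 1
        span = (base + ls, base + le)
        raw = title + "\n" + abstract if abstract else title
        if doc.full_text[span[0]:span[1]] != gene_text:
            raise AssertionError(
                f"template offset bookkeeping broke for {doc_id}: expected "
                f"{gene_text!r}, got {doc.full_text[span[0]:span[1]]!r}"
            )
        return doc, raw, span


def _gene_name(rng: random.Random, prefix: Optional[str] = None) -> str:
    body = (rng.choice("BCDFGKLNPST") + rng.choice("abdeikl")
            + rng.choice("mnprst") + str(rng.randrange(1, 10)))
    return (prefix + body) if prefix else body


def generate_corpus(
    cfg: FixtureConfig,
    freq: Optional[GlobalFrequencyTable] = None,
    prefix_map: Optional[dict[str, int]] = None,
) -> FixtureCorpus:
    """Generate a corpus; the gold species of every gene is fixed by the
    template that planted it.

    ``freq`` is needed to pre-compute the winner of planted focus ties (it
    must be the same table the cascade will use); ``prefix_map`` maps
    prefix letters to tax_ids (defaults to the packaged map).
    """
    from specieslink.lexicon import default_frequency_table, default_prefix_map

    freq = freq or default_frequency_table()
    pmap = prefix_map or default_prefix_map().entries
    rng = random.Random(cfg.seed)
    counts = allocate_rule_counts(cfg)

    rule_of_doc: list[str] = []
    for rule in RULE_ORDER:
        rule_of_doc.extend([rule] * counts[rule])
    rng.shuffle(rule_of_doc)

    documents: list[Document] = []
    raw_texts: dict[str, str] = {}
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    gold: list[GoldRecord] = []

    for i, rule in enumerate(rule_of_doc):
        doc_id = f"doc{i:04d}"
        builder = _DocBuilder()
        if rule == "prefix":
            gold_tax = _plant_prefix(builder, rng, cfg, pmap)
        elif rule == "cooccurrence":
            gold_tax = _plant_cooccurrence(builder, rng, cfg, variant=i % 5)
        elif rule == "focus":
            gold_tax = _plant_focus(builder, rng, cfg, freq, variant=i % 3)
        else:
            gold_tax = _plant_sri(builder, rng)
        doc, raw, span = builder.finish(doc_id)
        if cfg.label_noise > 0.0 and rng.random() < cfg.label_noise:
            others = [t for _, t in cfg.species_pool if t != gold_tax]
            if others:
                gold_tax = rng.choice(others)
        documents.append(doc)
        raw_texts[doc_id] = raw
        gene_spans[doc_id] = [span]
        gold.append(GoldRecord(doc_id=doc_id, start=span[0], end=span[1],
                               surface=doc.full_text[span[0]:span[1]],
                               tax_id=gold_tax))
    return FixtureCorpus(documents=documents, raw_texts=raw_texts,
                         gene_spans=gene_spans, gold=gold, rule_counts=counts)


def _pick_two(rng: random.Random, pool: Sequence[tuple[str, int]]) -> tuple:
    a, b = rng.sample(list(pool), 2)
    return a, b


def _plant_prefix(builder, rng, cfg, pmap) -> int:
    letter = rng.choice([c for c in _PREFIX_LETTERS if c in pmap])
    gene = _gene_name(rng, prefix=letter)
    other, _ = _pick_two(rng, cfg.species_pool)
    builder.sentence("title", "Characterization of the ", ("gene", gene), " gene.")
    builder.sentence("abstract", "The ", ("gene", gene),
                     f" gene was isolated from a {other[0]} library.")
    builder.sentence("abstract", "Its regulatory region remains uncharted.")
    return pmap[letter]


def _plant_cooccurrence(builder, rng, cfg, variant: int) -> int:
    gene = _gene_name(rng)
    (sp_a, tax_a), (sp_b, tax_b) = _pick_two(rng, cfg.species_pool)
    builder.sentence("title", "Analysis of transcriptional regulation.")
    if variant == 0:  # single mention, left of the gene
        builder.sentence("abstract", f"In {sp_a} tissue, ", ("gene", gene),
                         " expression was elevated.")
        return tax_a
    if variant == 1:  # left beats right
        builder.sentence("abstract", f"In {sp_a} samples, ", ("gene", gene),
                         f" was compared with findings in {sp_b} models.")
        return tax_a
    if variant == 2:  # two on the left: nearest wins
        builder.sentence("abstract", f"Unlike {sp_b} models, {sp_a} tissue showed ",
                         ("gene", gene), " induction.")
        return tax_a
    if variant == 3:  # right side only
        builder.sentence("abstract", "The ", ("gene", gene),
                         f" gene was first described in {sp_a} embryos.")
        return tax_a
    cell, tax_c = CELL_LINE_POOL[rng.randrange(len(CELL_LINE_POOL))]
    builder.sentence("abstract", f"{cell} cells showed strong ", ("gene", gene),
                     " expression.")
    return tax_c


def _plant_focus(builder, rng, cfg, freq, variant: int) -> int:
    gene = _gene_name(rng)
    (sp_a, tax_a), (sp_b, tax_b) = _pick_two(rng, cfg.species_pool)
    if variant == 2:  # deliberate weighted tie: title x1 (=2) vs abstract x2
        builder.sentence("title", f"A comparative study of {sp_a}.")
        builder.sentence("abstract", f"Samples from {sp_b} were collected.")
        builder.sentence("abstract", f"Additional {sp_b} data were analyzed.")
        builder.sentence("abstract", "The ", ("gene", gene), " gene was profiled.")
        return global_rank(freq, {tax_a, tax_b})
    builder.sentence("title", f"Gene regulation in {sp_a}.")
    builder.sentence("abstract", f"Recent studies of {sp_a} biology have expanded rapidly.")
    builder.sentence("abstract", "The ", ("gene", gene), " gene remains poorly understood.")
    return tax_a


def _plant_sri(builder, rng) -> int:
    gene = _gene_name(rng)
    tax = rng.choice(sorted(CUE_WORDS))
    c1, c2, c3 = CUE_WORDS[tax]
    builder.sentence("title", "A study of the ", ("gene", gene), " gene.")
    builder.sentence("abstract", f"Measurements involving {c1} and {c2} procedures were recorded.")
    builder.sentence("abstract", f"Further {c3} observations were collected.")
    builder.sentence("abstract", "Levels of ", ("gene", gene), " were quantified.")
    return tax


# ---------------------------------------------------------------------------
# SRI training / evaluation corpora (token-level, no documents needed).

def make_sri_corpus(
    seed: int, n_per_species: int = 25, cues_per_doc: int = 3
) -> list[tuple[list[str], int]]:
    """Labeled token multisets: shared background plus label cue words."""
    rng = random.Random(seed)
    out: list[tuple[list[str], int]] = []
    for tax in sorted(CUE_WORDS):
        for _ in range(n_per_species):
            tokens = rng.choices(SRI_BACKGROUND, k=12)
            tokens += rng.choices(CUE_WORDS[tax], k=cues_per_doc)
            rng.shuffle(tokens)
            out.append((tokens, tax))
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# On-disk fixture corpora (text documents + PubTator gene spans + gold TSV).

def write_corpus(corpus: FixtureCorpus, outdir: str | Path) -> None:
    """Write raw texts, gene spans and gold records under ``outdir``."""
    out = Path(outdir)
    (out / "docs").mkdir(parents=True, exist_ok=True)
    for doc_id, raw in sorted(corpus.raw_texts.items()):
        (out / "docs" / f"{doc_id}.txt").write_text(raw + "\n", encoding="utf-8")
    gene_lines = []
    for doc_id in sorted(corpus.gene_spans):
        doc = next(d for d in corpus.documents if d.doc_id == doc_id)
        for start, end in corpus.gene_spans[doc_id]:
            gene_lines.append(f"{doc_id}\t{start}\t{end}\t"
                              f"{doc.full_text[start:end]}\tGene")
    (out / "genes.tsv").write_text("\n".join(gene_lines) + "\n", encoding="utf-8")
    write_gold(corpus.gold, out / "gold.tsv")
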