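"""Shared fixtures: packaged resources, a tiny lexicon, random-document
machinery for matcher/oracle comparison."""

from __future__ import annotations

import random

import pytest

from specieslink.lexicon import SpeciesLexicon, normalize_name
from specieslink.pipeline import Resources
from specieslink.preprocess import segment_document


@pytest.fixture(scope="session")
def resources() -> Resources:
    return Resources.default()


@pytest.fixture(scope="session")
def mini_lexicon() -> SpeciesLexicon:
    return SpeciesLexicon(
        entries={
            "human": 9606,
            "mouse": 10090,
            "rat": 10116,
            "e. coli k-12": 83333,
            "e. coli": 562,
            "sus scrofa": 9823,
            "porcine": 9823,
            "arabidopsis": 3701,
            "arabidopsis thaliana": 3702,
        },
        sources={},
    )


def make_doc(title: str, abstract: str = "", doc_id: str = "d0"):
    raw = title + ("\n" + abstract if abstract else "")
    return segment_document(raw, fmt="text", doc_id=doc_id)


# ---------------------------------------------------------------------------
# Brute-force matcher oracle: enumerate every substring, keep lexicon hits
# with clean token boundaries, then apply leftmost-longest selection.

_ASCII_ALNUM = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789")


def oracle_matches(text: str, lex: SpeciesLexicon) -> list[tuple[int, int, int]]:
    """Expected (start, end, tax_id) triples, independent of the regex path."""
    max_len = max((len(n) for n in lex.entries), default=0) + 8
    candidates: list[tuple[int, int, int]] = []
    n = len(text)
    for s in range(n):
        if text[s].isspace():
            continue
        if s > 0 and text[s - 1] in _ASCII_ALNUM:
            continue
        for e in range(s + 1, min(n, s + max_len) + 1):
            if text[e - 1].isspace():
                continue
            if e < n and text[e] in _ASCII_ALNUM:
                continue
            try:
                norm = normalize_name(text[s:e])
            except Exception:
                continue
            if norm in lex.entries:
                candidates.append((s, e, lex.entries[norm]))
    # leftmost-longest scan
    out: list[tuple[int, int, int]] = []
    pos = 0
    while True:
        viable = [c for c in candidates if c[0] >= pos]
        if not viable:
            break
        first = min(c[0] for c in viable)
        best = max((c for c in viable if c[0] == first), key=lambda c: c[1])
        out.append(best)
        pos = best[1]
    return out


_FILLER_WORDS = [
    "the", "analysis", "of", "xq1", "protein", "was", "tested", "in", "and",
    "with", "samples", "gene", "assay", "level", "zz9",
]


def random_document_text(rng: random.Random, lex: SpeciesLexicon) -> str:
    """~200-char strings with planted (and sometimes mangled) species names."""
    names = sorted(lex.entries)
    chunks: list[str] = []
    size = 0
    while size < 200:
        roll = rng.random()
        if roll < 0.35:
            name = rng.choice(names)
            # random case mutation and occasional doubled internal spaces
            word = "".join(c.upper() if rng.random() < 0.3 else c for c in name)
            if " " in word and rng.random() < 0.3:
                word = word.replace(" ", "  ", 1)
            chunks.append(word)
        elif roll < 0.45:
            # glue a name to alphanumerics: boundary must suppress the match
            chunks.append(rng.choice(names).replace(" ", "") + rng.choice("sx1"))
        else:
            chunks.append(rng.choice(_FILLER_WORDS))
        if rng.random() < 0.1:
            chunks.append(rng.choice([",", ".", ";", "(", ")"]))
        size = sum(len(c) + 1 for c in chunks)
    return " ".join(chunks)
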