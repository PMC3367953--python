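"""Species Represented Indicator (SRI): cue-word species inference.

Roughly 1 in 6 abstracts names no organism at all, yet its genes still need
a species.  The SRI model scores four common model organisms -- human
(9606), mouse (10090), yeast (4932), fly (7227) -- from words that are
strongly correlated with one of them ("cohort" with human studies,
"ferment" with yeast).

The coefficient used here is a one-vs-rest conditional-probability margin:

    weight(w, s) = max(0, P(w | s) - max_{s' != s} P(w | s'))

estimated from label-conditional relative token frequencies of a labeled
training corpus.  Words whose margin falls below a floor are dropped, so
the model stays sparse and cheap to apply.  Inference scores a document by
summing token-count-weighted margins per species; ties and all-zero scores
fall back to corpus-global frequency rank over the four organisms.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from specieslink.lexicon import GlobalFrequencyTable, LexiconError, global_rank

#: The fixed species domain of the indicator.
SRI_SPECIES = (9606, 10090, 4932, 7227)  # human, mouse, yeast, fly

DEFAULT_WEIGHT_FLOOR = 0.01

_TOKEN = re.compile(r"[a-z]+")


def _load_stopwords() -> frozenset[str]:
    path = resources.files("specieslink").joinpath("data", "stopwords.txt")
    words = Path(str(path)).read_text(encoding="utf-8").split()
    return frozenset(words)


_STOPWORDS: Optional[frozenset[str]] = None


def tokenize(text: str) -> list[str]:
    """Lowercase alphabetic tokens of length >= 3, stopwords removed."""
    global _STOPWORDS
    if _STOPWORDS is None:
        _STOPWORDS = _load_stopwords()
    return [t for t in _TOKEN.findall(text.lower())
            if len(t) >= 3 and t not in _STOPWORDS]


@dataclass
class SRIModel:
    """Sparse cue-word weights: (word, species tax_id) -> margin >= 0."""

    weights: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (word, species), w in self.weights.items():
            if species not in SRI_SPECIES:
                raise ValueError(
                    f"species {species} outside the SRI domain {SRI_SPECIES}"
                )
            if not (w >= 0.0 and w == w and w != float("inf")):
                raise ValueError(f"weight for ({word!r}, {species}) must be "
                                 f"finite and nonnegative, got {w!r}")

    def __len__(self) -> int:
        return len(self.weights)

    def save(self, path: str | Path) -> None:
        lines = [
            f"{word}\t{species}\t{weight:.6f}"
            for (word, species), weight in sorted(self.weights.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SRIModel":
        weights: dict[tuple[str, int], float] = {}
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), 1
        ):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise LexiconError(f"{path}:{lineno}: expected 3 fields")
            weights[(parts[0], int(parts[1]))] = float(parts[2])
        return cls(weights=weights)


def train_sri(
    labeled_docs: Sequence[tuple[Sequence[str], int]],
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
) -> SRIModel:
    """Estimate cue-word margins from (token sequence, species label) pairs.

    Labels must come from the four-species SRI domain and at least two
    distinct labels must be present (a margin needs a contrast class).
    """
    labels = {label for _, label in labeled_docs}
    bad = labels - set(SRI_SPECIES)
    if bad:
        raise ValueError(f"labels outside the SRI species domain: {sorted(bad)}")
    if len(labels) < 2:
        raise ValueError("training requires at least two distinct species labels")

    per_label: dict[int, Counter[str]] = {s: Counter() for s in labels}
    totals: dict[int, int] = {s: 0 for s in labels}
    for tokens, label in labeled_docs:
        per_label[label].update(tokens)
        totals[label] += len(tokens)

    def prob(word: str, s: int) -> float:
        return per_label[s][word] / totals[s] if totals[s] else 0.0

    vocab = set()
    for counter in per_label.values():
        vocab.update(counter)

    weights: dict[tuple[str, int], float] = {}
    for word in vocab:
        for s in labels:
            margin = prob(word, s) - max(prob(word, s2) for s2 in labels if s2 != s)
            if margin >= weight_floor:
                weights[(word, s)] = margin
    return SRIModel(weights=weights)


def sri_score(tokens: Iterable[str], model: SRIModel) -> dict[int, float]:
    """Per-species score: sum of token-count-weighted cue margins."""
    counts = Counter(tokens)
    scores = {s: 0.0 for s in SRI_SPECIES}
    for (word, species), weight in model.weights.items():
        if word in counts:
            scores[species] += counts[word] * weight
    return scores


def sri_infer(
    tokens: Iterable[str], model: SRIModel, freq: GlobalFrequencyTable
) -> int:
    """Infer the document species; ties and zero scores fall back to the
    corpus-global frequency rank over the four SRI organisms."""
    if not len(model):
        raise ValueError("SRI model is empty")
    scores = sri_score(tokens, model)
    top = max(scores.values())
    tied = {s for s, v in scores.items() if v == top}
    if top <= 0.0:
        tied = set(SRI_SPECIES)
    if len(tied) == 1:
        return next(iter(tied))
    return global_rank(freq, tied)


def default_sri_model() -> SRIModel:
    path = resources.files("specieslink").joinpath("data", "sri_model.tsv")
    return SRIModel.load(Path(str(path)))
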