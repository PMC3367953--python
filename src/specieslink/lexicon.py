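"""Species-name, cell-line, prefix and global-frequency tables.

Every downstream step (dictionary matching, the cell-name rule, the prefix
rule, tie-breaking) queries one of the four tables defined here.  All tables
serialize to plain tab-separated text so a lexicon round-trips losslessly.

The packaged species lexicon is a small, pre-filtered table intended for
testing and demonstration.  Production lexicons are built offline from
NCBI-Taxonomy-style ``names`` records with :func:`build_lexicon`, which
applies an Entrez-gene taxid whitelist and curated augmentations (common
vernacular terms such as "porcine" that formal terminologies lack).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

_WS_RUN = re.compile(r"\s+")

VALID_SOURCES = ("taxonomy", "curated", "cell-derived")


class LexiconError(ValueError):
    """Raised for invalid names, conflicting entries or malformed files."""


def normalize_name(raw: str) -> str:
    """Normalize a surface name: lowercase, collapse whitespace runs, strip.

    Idempotent; raises :class:`LexiconError` on empty/whitespace-only input.

    >>> normalize_name("E. Coli K-12")
    'e. coli k-12'
    """
    norm = _WS_RUN.sub(" ", raw.strip()).lower()
    if not norm:
        raise LexiconError(f"invalid name: empty after normalization ({raw!r})")
    return norm


@dataclass
class SpeciesLexicon:
    """Map from normalized species surface name to NCBI Taxonomy id.

    ``entries`` maps each normalized name to exactly one positive tax_id;
    ``sources`` records provenance per entry (taxonomy | curated |
    cell-derived).
    """

    entries: dict[str, int] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, tax_id in self.entries.items():
            _check_entry(name, tax_id)
        for name, src in self.sources.items():
            if src not in VALID_SOURCES:
                raise LexiconError(f"unknown source tag {src!r} for {name!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self.entries

    def lookup(self, name: str) -> Optional[int]:
        """Return the tax_id for a (not necessarily normalized) name."""
        try:
            return self.entries.get(normalize_name(name))
        except LexiconError:
            return None

    @property
    def tax_ids(self) -> set[int]:
        return set(self.entries.values())

    def save(self, path: str | Path) -> None:
        write_lexicon_tsv(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "SpeciesLexicon":
        return read_lexicon_tsv(path)


@dataclass
class CellLineLexicon:
    """Map from normalized cell-line name (e.g. "hela") to organism tax_id.

    Referenced tax_ids must exist in the companion species lexicon's tax_id
    set or in a declared ``extension`` set (cell lines from organisms that
    the species lexicon happens not to cover).
    """

    entries: dict[str, int] = field(default_factory=dict)
    extension: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, tax_id in self.entries.items():
            _check_entry(name, tax_id)

    def __len__(self) -> int:
        return len(self.entries)

    def validate_against(self, species: SpeciesLexicon) -> None:
        """Check the companion-lexicon invariant; raise on a dangling tax_id."""
        known = species.tax_ids | self.extension
        dangling = {t for t in self.entries.values() if t not in known}
        if dangling:
            raise LexiconError(
                f"cell-line tax_ids absent from species lexicon and extension "
                f"set: {sorted(dangling)}"
            )

    @classmethod
    def load(cls, path: str | Path, extension: Iterable[int] = ()) -> "CellLineLexicon":
        lex = read_lexicon_tsv(path)
        return cls(entries=dict(lex.entries), extension=set(extension))


@dataclass
class PrefixMap:
    """Single lowercase letter -> tax_id, for the gene-symbol prefix rule.

    The packaged default covers the common model organisms: h (human),
    m (mouse), r (rat), d (fly), z (zebrafish), x (Xenopus), y (yeast).
    Users may override or extend it with their own table.
    """

    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for letter, tax_id in self.entries.items():
            if not (len(letter) == 1 and "a" <= letter <= "z"):
                raise LexiconError(f"prefix key must be a single letter a-z: {letter!r}")
            if not (isinstance(tax_id, int) and tax_id > 0):
                raise LexiconError(f"invalid tax_id for prefix {letter!r}: {tax_id!r}")

    def get(self, letter: str) -> Optional[int]:
        return self.entries.get(letter)

    @classmethod
    def load(cls, path: str | Path) -> "PrefixMap":
        entries = {}
        for key, tax_id in _read_two_column_tsv(path):
            entries[key] = tax_id
        return cls(entries=entries)


@dataclass
class GlobalFrequencyTable:
    """Corpus-level species frequencies used for deterministic tie-breaking.

    Ordering is total: count descending, then tax_id ascending.  The
    packaged table is calibrated so that human outranks rat outranks mouse,
    matching the reported popularity ordering in the reference corpus the
    tie-break rule was derived from.
    """

    entries: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tax_id, count in self.entries.items():
            if not (isinstance(tax_id, int) and tax_id > 0):
                raise LexiconError(f"invalid tax_id {tax_id!r}")
            if not (isinstance(count, int) and count >= 0):
                raise LexiconError(f"negative count for tax_id {tax_id}")

    def count(self, tax_id: int) -> int:
        """Frequency of ``tax_id``; absent species count as 0."""
        return self.entries.get(tax_id, 0)

    def sort_key(self, tax_id: int) -> tuple[int, int]:
        """Key under which ``min`` picks the highest-ranked species."""
        return (-self.count(tax_id), tax_id)

    @classmethod
    def load(cls, path: str | Path) -> "GlobalFrequencyTable":
        entries = {}
        for key, count in _read_two_column_tsv(path):
            entries[int(key)] = count
        return cls(entries=entries)


def global_rank(table: GlobalFrequencyTable, candidates: Iterable[int]) -> int:
    """Pick the most frequent candidate; ties broken by ascending tax_id.

    Candidates absent from the table are treated as count 0.  Raises on an
    empty candidate set.
    """
    cands = set(candidates)
    if not cands:
        raise LexiconError("global_rank requires a non-empty candidate set")
    return min(cands, key=table.sort_key)


def build_lexicon(
    name_records: Sequence[tuple[str, int]],
    whitelist: Optional[Iterable[int]] = None,
    augmentations: Sequence[tuple[str, int]] = (),
) -> SpeciesLexicon:
    """Build a filtered species lexicon from raw name records.

    ``name_records`` are (surface, tax_id) pairs, typically from an NCBI
    Taxonomy names table.  When ``whitelist`` is given, records whose tax_id
    is not whitelisted are dropped (the offline analogue of removing species
    with no Entrez Gene records).  ``augmentations`` are curated (name,
    tax_id) pairs added unconditionally, bypassing the whitelist.

    Duplicate normalized names resolve by precedence: curated augmentation
    beats taxonomy record; among taxonomy records the lowest tax_id wins.
    Duplicates are logged as warnings.  Conflicting duplicates *within* the
    augmentations are a hard error.
    """
    wl = set(whitelist) if whitelist is not None else None
    entries: dict[str, int] = {}
    sources: dict[str, str] = {}

    for raw, tax_id in name_records:
        if tax_id <= 0:
            raise LexiconError(f"non-positive tax_id {tax_id} for {raw!r}")
        if wl is not None and tax_id not in wl:
            continue
        name = normalize_name(raw)
        if name in entries:
            keep = min(entries[name], tax_id)
            logger.warning(
                "duplicate lexicon name %r (tax %d vs %d); keeping %d",
                name, entries[name], tax_id, keep,
            )
            entries[name] = keep
        else:
            entries[name] = tax_id
            sources[name] = "taxonomy"

    aug_seen: dict[str, int] = {}
    for raw, tax_id in augmentations:
        if tax_id <= 0:
            raise LexiconError(f"non-positive tax_id {tax_id} for {raw!r}")
        name = normalize_name(raw)
        if name in aug_seen and aug_seen[name] != tax_id:
            raise LexiconError(
                f"conflicting augmentations for {name!r}: "
                f"{aug_seen[name]} vs {tax_id}"
            )
        aug_seen[name] = tax_id
        if name in entries and entries[name] != tax_id:
            logger.warning(
                "augmentation %r (tax %d) overrides taxonomy entry (tax %d)",
                name, tax_id, entries[name],
            )
        entries[name] = tax_id
        sources[name] = "curated"

    return SpeciesLexicon(entries=entries, sources=sources)


# ---------------------------------------------------------------------------
# TSV serialization: `name<TAB>tax_id<TAB>source`, UTF-8, '#' comments.

def read_lexicon_tsv(path: str | Path) -> SpeciesLexicon:
    entries: dict[str, int] = {}
    sources: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise LexiconError(f"{path}:{lineno}: expected 2-3 tab-separated fields")
        name = normalize_name(parts[0])
        try:
            tax_id = int(parts[1])
        except ValueError as exc:
            raise LexiconError(f"{path}:{lineno}: bad tax_id {parts[1]!r}") from exc
        source = parts[2] if len(parts) == 3 else "taxonomy"
        entries[name] = tax_id
        sources[name] = source
    return SpeciesLexicon(entries=entries, sources=sources)


def write_lexicon_tsv(lex: SpeciesLexicon, path: str | Path) -> None:
    lines = [
        f"{name}\t{tax_id}\t{lex.sources.get(name, 'taxonomy')}"
        for name, tax_id in sorted(lex.entries.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_whitelist(path: str | Path) -> set[int]:
    """Read a taxid whitelist: one integer per line, '#' comments."""
    out: set[int] = set()
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            out.add(int(line))
        except ValueError as exc:
            raise LexiconError(f"{path}:{lineno}: bad tax_id {line!r}") from exc
    return out


def read_hierarchy(path: str | Path) -> dict[int, int]:
    """Read a taxonomy-hierarchy table: `tax_id<TAB>parent_tax_id` lines."""
    out: dict[int, int] = {}
    for key, parent in _read_two_column_tsv(path):
        out[int(key)] = parent
    return out


def _read_two_column_tsv(path: str | Path) -> Iterable[tuple[str, int]]:
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconError(f"{path}:{lineno}: expected 2 tab-separated fields")
        try:
            yield parts[0], int(parts[1])
        except ValueError as exc:
            raise LexiconError(f"{path}:{lineno}: bad integer {parts[1]!r}") from exc


def _check_entry(name: str, tax_id: int) -> None:
    if not name or name != normalize_name(name):
        raise LexiconError(f"entry name not normalized: {name!r}")
    if not (isinstance(tax_id, int) and tax_id > 0):
        raise LexiconError(f"invalid tax_id {tax_id!r} for {name!r}")


# ---------------------------------------------------------------------------
# Packaged default resources.

def _data_path(filename: str) -> Path:
    return Path(str(resources.files("specieslink").joinpath("data", filename)))


def default_species_lexicon() -> SpeciesLexicon:
    return read_lexicon_tsv(_data_path("species.tsv"))


def default_cell_lexicon() -> CellLineLexicon:
    return CellLineLexicon.load(_data_path("cells.tsv"), extension={10029})


def default_prefix_map() -> PrefixMap:
    return PrefixMap.load(_data_path("prefixes.tsv"))


def default_frequency_table() -> GlobalFrequencyTable:
    return GlobalFrequencyTable.load(_data_path("frequency.tsv"))


def default_hierarchy() -> dict[int, int]:
    return read_hierarchy(_data_path("hierarchy.tsv"))
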