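"""Dictionary-based keyword tagging of abstracts.

Abstracts are represented downstream only through the typed keywords found
in them, so this module is the bridge from free text to count profiles.
The dictionary maps surface forms (possibly multi-word) to canonical term
IDs, each with one of eight keyword types.  Matching policy:

* case-insensitive;
* token-boundary anchored (``p5`` never matches inside ``p53``);
* hyphens are kept inside tokens (``S-phase`` is one token);
* longest match wins, scanning left to right, matches never overlap;
* a surface form shared by several term IDs credits *all* of them once
  per occurrence — ambiguity is preserved for the classifier to weigh.

The two "general biological" keyword types (``bio_term`` and ``bio_action``)
are always enabled; the other six types are user-selectable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: The eight keyword types of the typed dictionary.
KEYWORD_TYPES = (
    "gene_protein", "chemical", "disease", "drug", "symptom",
    "organism", "bio_term", "bio_action", "other_bio",
)

#: Types that can never be disabled.
ALWAYS_ENABLED = frozenset({"bio_term", "bio_action"})

_TOKEN_RE = re.compile(r"[A-Za-z0-9_]+(?:-[A-Za-z0-9_]+)*")


@dataclass(frozen=True)
class DictionaryEntry:
    surface_form: str
    term_id: str
    term_type: str

    def __post_init__(self):
        if not self.surface_form:
            raise ValueError("surface form must be non-empty")
        if self.term_type not in KEYWORD_TYPES:
            raise ValueError(f"unknown keyword type {self.term_type!r}")


@dataclass(frozen=True)
class TypeSelection:
    """Which keyword types are enabled; bio_term/bio_action are forced on."""

    enabled: frozenset = frozenset(KEYWORD_TYPES)

    def __post_init__(self):
        object.__setattr__(self, "enabled", frozenset(self.enabled) | ALWAYS_ENABLED)

    @classmethod
    def all(cls) -> "TypeSelection":
        return cls(frozenset(KEYWORD_TYPES))

    @classmethod
    def without(cls, *disabled: str) -> "TypeSelection":
        bad = set(disabled) & ALWAYS_ENABLED
        if bad:
            raise ValueError(f"types {sorted(bad)} are always used and cannot be disabled")
        return cls(frozenset(KEYWORD_TYPES) - set(disabled))


@dataclass
class KeywordProfile:
    """Typed-keyword counts of one abstract (term_id -> positive count)."""

    pmid: int
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())


def tokenize(text: str) -> list[str]:
    """Lower-cased word tokens; hyphens stay inside tokens."""
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(text)]


class KeywordMatcher:
    """Compiled dictionary supporting longest-match non-overlapping scans."""

    def __init__(self, index: dict[tuple, list[tuple[str, str]]], max_len: int):
        # token-tuple -> list of (term_id, term_type); max_len = longest form
        self._index = index
        self._max_len = max_len
        self.term_types = {tid: ttype
                           for hits in index.values() for tid, ttype in hits}

    def scan(self, text: str) -> dict[str, int]:
        """Count non-overlapping longest matches per term_id."""
        tokens = tokenize(text)
        counts: dict[str, int] = {}
        i, n = 0, len(tokens)
        while i < n:
            matched = 0
            for length in range(min(self._max_len, n - i), 0, -1):
                hits = self._index.get(tuple(tokens[i:i + length]))
                if hits:
                    for term_id, _ in hits:
                        counts[term_id] = counts.get(term_id, 0) + 1
                    matched = length
                    break
            i += matched or 1
        return counts


def compile_dictionary(entries: Iterable[DictionaryEntry]) -> KeywordMatcher:
    """Compile dictionary entries into a matcher.

    Duplicate (surface_form, term_id) pairs collapse with a warning; one
    surface form mapped to several term_ids keeps all mappings.
    """
    index: dict[tuple, list[tuple[str, str]]] = {}
    max_len = 0
    n_entries = 0
    for entry in entries:
        n_entries += 1
        key = tuple(tokenize(entry.surface_form))
        if not key:
            logger.warning("surface form %r tokenizes to nothing; skipped",
                           entry.surface_form)
            continue
        hits = index.setdefault(key, [])
        if any(tid == entry.term_id for tid, _ in hits):
            logger.warning("duplicate dictionary entry (%r, %s) collapsed",
                           entry.surface_form, entry.term_id)
            continue
        hits.append((entry.term_id, entry.term_type))
        max_len = max(max_len, len(key))
    if n_entries == 0:
        raise ValueError("cannot compile an empty dictionary")
    return KeywordMatcher(index, max_len)


def tag_text(record, matcher: KeywordMatcher,
             selection: TypeSelection | None = None) -> KeywordProfile:
    """Tag one abstract (title + body) into a keyword profile.

    Term IDs of disabled types are removed *after* matching, so disabling a
    type never changes how the remaining text is segmented.
    """
    selection = selection or TypeSelection.all()
    counts = matcher.scan(record.text)
    kept = {tid: c for tid, c in counts.items()
            if matcher.term_types.get(tid) in selection.enabled}
    return KeywordProfile(record.pmid, kept)


def read_dictionary(path: str | Path) -> list[DictionaryEntry]:
    """Read a dictionary TSV: ``surface_form<TAB>term_id<TAB>term_type``."""
    entries = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        surface, term_id, term_type = line.split("\t")[:3]
        entries.append(DictionaryEntry(surface, term_id, term_type))
    return entries


def load_pretagged(path: str | Path, selection: TypeSelection | None = None,
                   ) -> dict[int, KeywordProfile]:
    """Load pre-tagged profiles from ``pmid<TAB>term_id<TAB>type<TAB>count`` TSV.

    Interchangeable with :func:`tag_text` output; the type filter is applied
    at load time and rows with non-positive counts are rejected.
    """
    selection = selection or TypeSelection.all()
    profiles: dict[int, KeywordProfile] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        pmid_s, term_id, term_type, count_s = line.split("\t")[:4]
        pmid, count = int(pmid_s), int(count_s)
        if count <= 0:
            logger.warning("row %d: non-positive count %d for %s rejected",
                           lineno, count, term_id)
            continue
        prof = profiles.setdefault(pmid, KeywordProfile(pmid))
        if term_type in selection.enabled:
            prof.counts[term_id] = prof.counts.get(term_id, 0) + count
    return profiles


def write_pretagged(profiles: Mapping[int, KeywordProfile] | Sequence[KeywordProfile],
                    term_types: Mapping[str, str], path: str | Path) -> None:
    """Write profiles in the pre-tagged TSV format consumed by load_pretagged."""
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    with open(path, "w") as fh:
        for prof in profiles:
            for term_id in sorted(prof.counts):
                fh.write(f"{prof.pmid}\t{term_id}\t"
                         f"{term_types[term_id]}\t{prof.counts[term_id]}\n")
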