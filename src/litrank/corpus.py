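"""Input identifiers, gene-to-abstract expansion, and corpus fixtures.

A ranking job starts from up to three identifier lists: the "interesting"
set A, the "background" set B, and the query set C.  Lists may contain
Ensembl gene IDs (``ENSG…``), Entrez gene IDs, or PubMed IDs.  Numeric
Entrez gene IDs are indistinguishable from PubMed IDs by inspection, so the
identifier kind is always declared per list and never guessed.

Gene identifiers are expanded to the PubMed IDs linked to them (including
GeneRIF- and interaction-derived links); Ensembl IDs are first translated
to all matching Entrez IDs.  Duplicate PMIDs and overlaps between sets are
deliberately preserved — users rely on repetition to cope with imbalanced
inputs.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Medline

logger = logging.getLogger(__name__)

#: Hard cap on the size of any single input list (genes or abstracts).
INPUT_CAP = 25_000

_ENSG_RE = re.compile(r"^ENSG\d{6,}$")
_INT_RE = re.compile(r"^[0-9]+$")


class IdKind(str, Enum):
    """Declared kind of an input identifier list."""

    ensembl_gene = "ensembl_gene"
    entrez_gene = "entrez_gene"
    pubmed_id = "pubmed_id"
    pubmed_query = "pubmed_query"


class SetLabel(str, Enum):
    A = "A"
    B = "B"
    C = "C"


class UnusableSetError(ValueError):
    """An input set is empty after clean-up / expansion."""


class InputCapError(ValueError):
    """An input list exceeds the configured maximum size."""


@dataclass(frozen=True)
class InputIdentifier:
    """One cleaned input token with its declared kind."""

    raw_token: str
    id_kind: IdKind


@dataclass
class AbstractRecord:
    """One PubMed-style document.

    ``body`` may be empty: some PubMed entries contain only titles.
    ``keyword_counts`` is filled by the tagger (term_id -> positive count).
    """

    pmid: int
    title: str = ""
    body: str = ""
    keyword_counts: dict[str, int] | None = None

    @property
    def text(self) -> str:
        return (self.title + " " + self.body).strip()


@dataclass
class GeneLinkTable:
    """Gene-to-literature mapping tables.

    One Ensembl gene may map to several Entrez genes; all are retained.
    A gene may legitimately map to zero PMIDs.
    """

    entrez_to_pmids: dict[str, list[int]] = field(default_factory=dict)
    ensembl_to_entrez: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, entrez_path: str | Path | None = None,
                 ensembl_path: str | Path | None = None) -> "GeneLinkTable":
        """Load link tables from ``entrez<TAB>pmid`` and ``ensg<TAB>entrez`` files.

        Insertion order of the files defines the per-gene PMID order.
        """
        table = cls()
        if entrez_path is not None:
            for line in Path(entrez_path).read_text().splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                gene, pmid = line.split("\t")[:2]
                table.entrez_to_pmids.setdefault(gene.strip(), []).append(int(pmid))
        if ensembl_path is not None:
            for line in Path(ensembl_path).read_text().splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                ensg, entrez = line.split("\t")[:2]
                table.ensembl_to_entrez.setdefault(ensg.strip(), []).append(entrez.strip())
        return table


@dataclass
class DocumentSet:
    """An ordered PMID list for one of the sets A/B/C.

    Duplicates and cross-set overlaps are preserved, never removed.
    """

    label: SetLabel
    pmids: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pmids)


def _token_is_wellformed(token: str, kind: IdKind) -> bool:
    if kind is IdKind.ensembl_gene:
        return bool(_ENSG_RE.match(token))
    if kind in (IdKind.entrez_gene, IdKind.pubmed_id):
        return bool(_INT_RE.match(token)) and int(token) > 0
    return bool(token)  # pubmed_query: any non-empty string


def parse_identifier_list(tokens: Sequence[str], declared_kind: IdKind | str,
                          ) -> list[InputIdentifier]:
    """Clean up a raw token list into typed identifiers.

    Malformed tokens are dropped with a warning; the declared kind is
    authoritative for numeric tokens (an Entrez gene ID is never silently
    reinterpreted as a PubMed ID).

    Raises :class:`UnusableSetError` if nothing survives clean-up.
    """
    kind = IdKind(declared_kind)
    out: list[InputIdentifier] = []
    for raw in tokens:
        token = raw.strip()
        if _token_is_wellformed(token, kind):
            out.append(InputIdentifier(token, kind))
        else:
            logger.warning("dropping malformed %s token %r", kind.value, raw)
    if not out:
        raise UnusableSetError(
            f"no well-formed {kind.value} identifiers remain after clean-up")
    return out


def expand_to_abstracts(ids: Iterable[InputIdentifier], links: GeneLinkTable,
                        label: SetLabel | str = SetLabel.A) -> DocumentSet:
    """Expand identifiers to the ordered PMID list of a document set.

    Ensembl genes translate to *all* matching Entrez genes, each Entrez gene
    contributes *all* of its linked PMIDs (link-table order), and PubMed IDs
    pass through unchanged.  Genes with no mapping or no linked abstracts
    contribute nothing (logged).  Duplicates are retained.
    """
    pmids: list[int] = []
    for ident in ids:
        if ident.id_kind is IdKind.pubmed_id:
            pmids.append(int(ident.raw_token))
            continue
        if ident.id_kind is IdKind.ensembl_gene:
            entrez_ids = links.ensembl_to_entrez.get(ident.raw_token, [])
            if not entrez_ids:
                logger.warning("Ensembl gene %s has no Entrez mapping", ident.raw_token)
        elif ident.id_kind is IdKind.entrez_gene:
            entrez_ids = [ident.raw_token]
        else:
            raise ValueError(
                "pubmed_query identifiers must be resolved to PMIDs through a "
                "query fixture before expansion")
        for entrez in entrez_ids:
            linked = links.entrez_to_pmids.get(entrez, [])
            if not linked:
                logger.warning("Entrez gene %s has no linked abstracts", entrez)
            pmids.extend(linked)
    ds = DocumentSet(SetLabel(label), pmids)
    if not ds.pmids:
        raise UnusableSetError(f"set {ds.label.value} expanded to zero abstracts")
    return ds


def enforce_input_cap(items: DocumentSet | Sequence, cap: int = INPUT_CAP):
    """Refuse any input list larger than ``cap`` entries (genes or abstracts)."""
    n = len(items)
    if n > cap:
        raise InputCapError(
            f"input list has {n} entries, exceeding the maximum of {cap}; "
            "please reduce the corresponding list's size")
    return items


# ---------------------------------------------------------------------------
# Corpus fixtures: TSV / JSON / Medline text
# ---------------------------------------------------------------------------

def _index_records(records: Iterable[AbstractRecord]) -> dict[int, AbstractRecord]:
    out: dict[int, AbstractRecord] = {}
    for rec in records:
        if rec.pmid in out:
            logger.warning("duplicate PMID %d in corpus file; last record wins", rec.pmid)
        out[rec.pmid] = rec
    return out


def read_corpus(path: str | Path, format: str = "fixture_tsv",
                ) -> dict[int, AbstractRecord]:
    """Read an abstract corpus, indexed by PMID.

    Formats: ``fixture_tsv`` (``pmid<TAB>title<TAB>body``), ``fixture_json``
    (list of objects with the same fields), ``medline_text`` (PMID/TI/AB
    tagged records).  Title-only records are kept with an empty body.
    """
    path = Path(path)
    if format == "fixture_tsv":
        records = []
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            try:
                pmid = int(parts[0])
            except ValueError:
                logger.warning("skipping unparseable corpus row %d: %r", lineno, line[:60])
                continue
            title = parts[1] if len(parts) > 1 else ""
            body = parts[2] if len(parts) > 2 else ""
            records.append(AbstractRecord(pmid, title, body))
    elif format == "fixture_json":
        raw = json.loads(path.read_text())
        records = [AbstractRecord(int(r["pmid"]), r.get("title", ""), r.get("body", ""))
                   for r in raw]
    elif format == "medline_text":
        with open(path) as handle:
            records = [
                AbstractRecord(int(r["PMID"]), r.get("TI", ""), r.get("AB", ""))
                for r in Medline.parse(handle) if "PMID" in r
            ]
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    if not records:
        logger.warning("corpus file %s is empty", path)
    return _index_records(records)


def write_corpus(records: Mapping[int, AbstractRecord] | Iterable[AbstractRecord],
                 path: str | Path) -> None:
    """Write records as fixture TSV (``pmid<TAB>title<TAB>body``)."""
    if isinstance(records, Mapping):
        records = records.values()
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.pmid}\t{rec.title}\t{rec.body}\n")


def read_query_fixture(path: str | Path) -> dict[str, list[int]]:
    """Load a query -> PMID-list fixture (JSON object) for pubmed_query inputs.

    Live PubMed query execution is out of scope; queries are resolved only
    through this user-supplied table.
    """
    return {q: [int(p) for p in pmids]
            for q, pmids in json.loads(Path(path).read_text()).items()}
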