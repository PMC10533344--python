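"""Corpus ingestion: PubTator documents -> entity-annotated sentences.

The stages mirror a standard literature-mining front end:

1. :func:`parse_pubtator` reads PubTator-native blocks (``PMID|t|``,
   ``PMID|a|`` and tab-separated annotation lines).
2. :func:`map_disease_mentions` rewrites disease mentions to UMLS concepts
   through a user-supplied MeSH->CUI table and keeps only concepts of the
   neoplastic-process semantic type; gene mentions become
   :class:`~gexkb.schema.GeneEntity` records keyed by NCBI Gene id.
3. :func:`split_sentences` segments the text deterministically and rebases
   mention offsets to sentence-local coordinates.
4. :func:`expand_pairs` emits one :class:`EntityAnnotatedSentence` per
   (gene mention, cancer mention) combination in a sentence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from .schema import (
    NEOPLASTIC_PROCESS,
    CancerEntity,
    EntityAnnotatedSentence,
    GeneEntity,
    Mention,
    SchemaError,
)

__all__ = [
    "RawMention", "AnnotatedDocument", "ConceptMappingTable",
    "parse_pubtator", "write_pubtator", "map_disease_mentions",
    "split_sentences", "expand_pairs", "ingest_documents", "IngestReport",
]

logger = logging.getLogger(__name__)

_CUI_RE = re.compile(r"^C\d{7}$")

# End-of-sentence: terminal punctuation, whitespace, then an upper-case
# letter or digit.  Boundaries right after common abbreviations are ignored.
_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9])")
_ABBREV_END = re.compile(
    r"\b(?:e\.g|i\.e|et al|vs|cf|Fig|fig|Dr|No|approx)\.$"
)


def _abstract_spans(text: str) -> list[tuple[int, int]]:
    """Half-open sentence spans within ``text`` (deterministic rule-based)."""
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        if _ABBREV_END.search(text[: m.start()]):
            continue
        spans.append((start, m.start()))
        start = m.end()
    spans.append((start, len(text)))
    return spans


@dataclass(frozen=True)
class RawMention:
    """An annotation line before (genes) or after (diseases) concept mapping.

    ``kind`` is ``gene`` or ``disease`` on input; mapping replaces disease
    mentions by ``cancer`` mentions carrying a :class:`CancerEntity` and
    attaches a :class:`GeneEntity` to gene mentions.
    """

    kind: str
    identifier: str
    start: int
    end: int
    text: str
    entity: Optional[object] = None


@dataclass(frozen=True)
class AnnotatedDocument:
    """A PubTator document: title, abstract and entity mention spans.

    Offsets follow the PubTator convention: title mentions index into the
    title; abstract mentions index into ``title + " " + abstract``.
    """

    document_id: str
    title: str
    abstract: str
    mentions: tuple[RawMention, ...] = ()

    @property
    def full_text(self) -> str:
        return self.title + " " + self.abstract if self.abstract else self.title


class PubTatorError(ValueError):
    """Raised on a structurally unusable PubTator stream."""


def parse_pubtator(stream: Union[str, IO[str]]) -> list[AnnotatedDocument]:
    """Parse PubTator native format into documents.

    Malformed annotation lines (wrong field count, out-of-bounds offsets,
    surface-text mismatch, unparsable gene id) are skipped with a logged
    warning.  A block carrying annotation lines but no title line is an
    error.
    """
    if hasattr(stream, "read"):
        stream = stream.read()
    docs: list[AnnotatedDocument] = []
    for block in re.split(r"\n\s*\n", stream.strip()):
        if not block.strip():
            continue
        docs.append(_parse_block(block))
    return docs


def _parse_block(block: str) -> AnnotatedDocument:
    doc_id: Optional[str] = None
    title = ""
    abstract = ""
    ann_lines: list[str] = []
    for line in block.splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("|", 2)
        if len(parts) == 3 and parts[1] in ("t", "a"):
            doc_id = doc_id or parts[0]
            if parts[1] == "t":
                title = parts[2]
            else:
                abstract = parts[2]
        else:
            ann_lines.append(line)
    if not title:
        raise PubTatorError(
            f"document block has annotation lines but no title line: {block[:80]!r}"
        )
    doc = AnnotatedDocument(document_id=doc_id or "", title=title, abstract=abstract)
    mentions: list[RawMention] = []
    for line in ann_lines:
        fields = line.split("\t")
        if len(fields) < 6:
            logger.warning("skipping malformed annotation line: %r", line)
            continue
        _, start_s, end_s, text, mtype, identifier = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            logger.warning("skipping annotation with non-integer offsets: %r", line)
            continue
        kind = {"gene": "gene", "disease": "disease"}.get(mtype.lower())
        if kind is None:
            continue  # chemicals, species, ... are out of scope
        full = doc.full_text
        if not (0 <= start < end <= len(full)) or full[start:end] != text:
            logger.warning(
                "skipping annotation with mismatched span in %s: %r",
                doc.document_id, line,
            )
            continue
        mentions.append(RawMention(kind, identifier, start, end, text))
    return replace(doc, mentions=tuple(mentions))


def write_pubtator(docs: Iterable[AnnotatedDocument], stream: IO[str]) -> None:
    """Serialize documents back to PubTator native format."""
    for doc in docs:
        stream.write(f"{doc.document_id}|t|{doc.title}\n")
        if doc.abstract:
            stream.write(f"{doc.document_id}|a|{doc.abstract}\n")
        for m in doc.mentions:
            mtype = {"gene": "Gene", "disease": "Disease", "cancer": "Disease"}[m.kind]
            stream.write(
                f"{doc.document_id}\t{m.start}\t{m.end}\t{m.text}\t{mtype}\t{m.identifier}\n"
            )
        stream.write("\n")


class ConceptMappingTable:
    """MeSH identifier -> UMLS (CUI, semantic type) mapping, many-to-many."""

    def __init__(self, rows: Iterable[tuple[str, str, str]]):
        self._map: dict[str, list[tuple[str, str]]] = {}
        for mesh_id, cui, semtype in rows:
            mesh_id = self._norm(mesh_id)
            if not _CUI_RE.match(cui):
                raise SchemaError(f"malformed CUI {cui!r} in mapping table")
            self._map.setdefault(mesh_id, []).append((cui, semtype))

    @staticmethod
    def _norm(mesh_id: str) -> str:
        return mesh_id.split(":", 1)[1] if mesh_id.upper().startswith("MESH:") else mesh_id

    @classmethod
    def from_tsv(cls, source: Union[str, IO[str]]) -> "ConceptMappingTable":
        """Load a 3-column TSV (mesh_id, cui, semantic_type); header optional."""
        text = source.read() if hasattr(source, "read") else source
        rows: list[tuple[str, str, str]] = []
        for i, line in enumerate(text.splitlines()):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise SchemaError(f"mapping table line {i + 1} has <3 columns: {line!r}")
            if i == 0 and not _CUI_RE.match(fields[1]):
                continue  # header row
            rows.append((fields[0], fields[1], fields[2]))
        return cls(rows)

    def lookup(self, mesh_id: str) -> list[tuple[str, str]]:
        return list(self._map.get(self._norm(mesh_id), []))


@dataclass
class IngestReport:
    """Bookkeeping for dropped/expanded mentions during ingestion."""

    documents: int = 0
    gene_mentions: int = 0
    cancer_mentions: int = 0
    dropped_unmapped: int = 0
    dropped_non_neoplastic: int = 0
    dropped_bad_gene_id: int = 0
    dropped_cross_sentence: int = 0
    multi_cui_expansions: int = 0
    sentences: int = 0
    pair_records: int = 0


def map_disease_mentions(
    doc: AnnotatedDocument,
    table: ConceptMappingTable,
    neoplastic_code: str = NEOPLASTIC_PROCESS,
    report: Optional[IngestReport] = None,
) -> AnnotatedDocument:
    """Rewrite disease mentions to cancer concepts; attach gene entities.

    Each disease mention yields one ``cancer`` mention per mapped CUI whose
    semantic type equals ``neoplastic_code``; mentions with no surviving
    CUI are dropped (counted in ``report``, never fatal).  A MeSH id mapped
    to several neoplastic CUIs yields one mention per CUI.
    """
    report = report if report is not None else IngestReport()
    out: list[RawMention] = []
    for m in doc.mentions:
        if m.kind == "gene":
            try:
                gene = GeneEntity(gene_id=int(m.identifier), symbol=m.text)
            except (ValueError, SchemaError):
                report.dropped_bad_gene_id += 1
                logger.warning("dropping gene mention with bad id %r", m.identifier)
                continue
            out.append(replace(m, entity=gene))
            report.gene_mentions += 1
        elif m.kind == "disease":
            hits = table.lookup(m.identifier)
            if not hits:
                report.dropped_unmapped += 1
                continue
            kept = [
                (cui, st) for cui, st in hits if st == neoplastic_code
            ]
            if not kept:
                report.dropped_non_neoplastic += 1
                continue
            if len(kept) > 1:
                report.multi_cui_expansions += 1
            for cui, st in kept:
                entity = CancerEntity(cui=cui, preferred_name=m.text, semantic_type=st)
                out.append(replace(m, kind="cancer", identifier=cui, entity=entity))
                report.cancer_mentions += 1
        else:
            out.append(m)
    return replace(doc, mentions=tuple(out))


def _sentence_spans(doc: AnnotatedDocument) -> list[tuple[int, int]]:
    """Half-open spans of sentences within ``doc.full_text``.

    The title is always a single sentence; the abstract is segmented by the
    rule-based splitter.
    """
    spans = [(0, len(doc.title))]
    if doc.abstract:
        base = len(doc.title) + 1
        for start, end in _abstract_spans(doc.abstract):
            spans.append((base + start, base + end))
    return spans


def split_sentences(
    doc: AnnotatedDocument, report: Optional[IngestReport] = None
) -> list[tuple[str, list[RawMention]]]:
    """Segment the document; rebase mention offsets to sentence-local.

    Mentions crossing a sentence boundary are dropped with a warning,
    never truncated.
    """
    report = report if report is not None else IngestReport()
    full = doc.full_text
    out: list[tuple[str, list[RawMention]]] = []
    spans = _sentence_spans(doc)
    assigned: set[int] = set()
    for s_start, s_end in spans:
        text = full[s_start:s_end]
        local: list[RawMention] = []
        for i, m in enumerate(doc.mentions):
            if s_start <= m.start and m.end <= s_end:
                local.append(replace(m, start=m.start - s_start, end=m.end - s_start))
                assigned.add(i)
        out.append((text, local))
        report.sentences += 1
    for i, m in enumerate(doc.mentions):
        if i not in assigned:
            report.dropped_cross_sentence += 1
            logger.warning(
                "dropping mention %r crossing a sentence boundary in %s",
                m.text, doc.document_id,
            )
    return out


def expand_pairs(
    text: str,
    mentions: Sequence[RawMention],
    document_id: str,
    sentence_index: int = 0,
) -> list[EntityAnnotatedSentence]:
    """One record per (gene mention, cancer mention) pair — full product.

    Sentences lacking either a gene or a cancer mention yield nothing.
    """
    genes = [m for m in mentions if m.kind == "gene"]
    cancers = [m for m in mentions if m.kind == "cancer"]
    records: list[EntityAnnotatedSentence] = []
    for gi, g in enumerate(genes):
        for ci, c in enumerate(cancers):
            sid = f"{document_id}:{sentence_index}:g{gi}c{ci}"
            try:
                records.append(
                    EntityAnnotatedSentence(
                        sentence_id=sid,
                        document_id=document_id,
                        text=text,
                        gene_mention=Mention(g.entity, g.start, g.end),
                        cancer_mention=Mention(c.entity, c.start, c.end),
                    )
                )
            except SchemaError as exc:  # e.g. overlapping spans from noisy NER
                logger.warning("skipping pair %s: %s", sid, exc)
    return records


def ingest_documents(
    docs: Iterable[AnnotatedDocument],
    table: ConceptMappingTable,
    neoplastic_code: str = NEOPLASTIC_PROCESS,
) -> tuple[list[EntityAnnotatedSentence], IngestReport]:
    """Full front end: map concepts, split, expand pairs, with a report."""
    report = IngestReport()
    records: list[EntityAnnotatedSentence] = []
    for doc in docs:
        report.documents += 1
        mapped = map_disease_mentions(doc, table, neoplastic_code, report)
        for idx, (text, local) in enumerate(split_sentences(mapped, report)):
            records.extend(expand_pairs(text, local, mapped.document_id, idx))
    report.pair_records = len(records)
    return records, report
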