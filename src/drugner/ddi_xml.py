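"""Reader/writer for DDI-challenge-style XML corpora.

Documents contain ``<sentence>`` elements with a ``text`` attribute and
``<entity>`` children carrying ``charOffset`` (0-based, inclusive on both
ends, e.g. ``"0-9"``; discontinuous mentions use semicolon-separated
fragments, each annotated independently) and ``type`` attributes.  An
optional ``normId`` attribute carries the normalization identifier; the
original challenge schema has no such field, so it is read when present and
written only for entities that have one.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from xml.sax.saxutils import quoteattr

from .corpus import AnnotatedSentence, EntityAnnotation, annotate_sentence


class DDIParseError(ValueError):
    pass


def _parse_char_offset(raw: str) -> list[tuple[int, int]]:
    fragments = []
    for part in raw.split(";"):
        lo, _, hi = part.strip().partition("-")
        try:
            fragments.append((int(lo), int(hi)))
        except ValueError as exc:
            raise DDIParseError(f"malformed charOffset {raw!r}") from exc
    return fragments


def parse_ddi_xml(document: str) -> list[AnnotatedSentence]:
    """Parse DDI-style XML text into annotated sentences.

    Malformed XML raises :class:`DDIParseError` naming the line/column
    offset.  Entity offsets that cross token boundaries force token splits
    so boundaries always align (see :func:`drugner.corpus.annotate_sentence`).
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise DDIParseError(f"malformed XML at line/column {exc.position}: {exc}") from exc

    sentences: list[AnnotatedSentence] = []
    for sent_el in root.iter("sentence"):
        text = sent_el.get("text", "")
        entities: list[EntityAnnotation] = []
        for ent_el in sent_el.findall("entity"):
            offset = ent_el.get("charOffset")
            if offset is None:
                raise DDIParseError(
                    f"entity without charOffset in sentence {sent_el.get('id', '?')!r}"
                )
            entity_type = ent_el.get("type", "DRUG")
            norm_id = ent_el.get("normId")
            for lo, hi in _parse_char_offset(offset):
                entities.append(EntityAnnotation(lo, hi, entity_type, norm_id))
        sentences.append(
            annotate_sentence(text, entities, sentence_id=sent_el.get("id", ""))
        )
    return sentences


def write_ddi_xml(corpus: list[AnnotatedSentence], document_id: str = "synthetic") -> str:
    """Serialize sentences to DDI-style XML.

    Sentence text is the single-space join of token surfaces; entity
    character offsets are recomputed from token positions, so
    ``parse_ddi_xml(write_ddi_xml(c)) == c`` for any legal corpus.
    """
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', f'<document id={quoteattr(document_id)}>']
    for si, sentence in enumerate(corpus):
        sid = sentence.sentence_id or f"{document_id}.s{si}"
        text = sentence.text
        lines.append(f"  <sentence id={quoteattr(sid)} text={quoteattr(text)}>")
        starts = []
        pos = 0
        for token in sentence.tokens:
            starts.append(pos)
            pos += len(token.surface) + 1
        for ei, (ts, te, etype) in enumerate(sentence.entity_spans()):
            lo = starts[ts]
            hi = starts[te] + len(sentence.tokens[te].surface) - 1
            surface = text[lo : hi + 1]
            norm = sentence.norm_labels[ts]
            norm_attr = f" normId={quoteattr(norm)}" if norm != "NIL" else ""
            lines.append(
                f"    <entity id={quoteattr(f'{sid}.e{ei}')} charOffset=\"{lo}-{hi}\""
                f" type={quoteattr(etype)}{norm_attr} text={quoteattr(surface)}/>"
            )
        lines.append("  </sentence>")
    lines.append("</document>")
    return "\n".join(lines) + "\n"
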