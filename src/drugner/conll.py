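"""CoNLL-style token-per-line reader and writer.

Columns are tab-separated: surface, NER (BIO) label, optional
normalization label.  A blank line separates sentences.
"""

from __future__ import annotations

from .corpus import NIL, AnnotatedSentence, Token, repair_bio


def read_conll(text: str) -> list[AnnotatedSentence]:
    sentences: list[AnnotatedSentence] = []
    rows: list[list[str]] = []

    def flush() -> None:
        if not rows:
            return
        tokens = [Token(r[0]) for r in rows]
        ner = repair_bio([r[1] if len(r) > 1 else "O" for r in rows])
        norm = [r[2] if len(r) > 2 else NIL for r in rows]
        sentences.append(AnnotatedSentence(tokens, ner, norm))
        rows.clear()

    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            flush()
            continue
        rows.append(line.split("\t"))
    flush()
    return sentences


def write_conll(corpus: list[AnnotatedSentence], include_norm: bool = True) -> str:
    blocks = []
    for sentence in corpus:
        lines = []
        for token, ner, norm in zip(sentence.tokens, sentence.ner_labels, sentence.norm_labels):
            cols = [token.surface, ner] + ([norm] if include_norm else [])
            lines.append("\t".join(cols))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")
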