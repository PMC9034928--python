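"""Pretrained word-vector loading and embedding-table initialization.

Text format: an optional first header line ``count dim``, then one word per
line followed by ``dim`` whitespace-separated numbers.  Rows for words not
covered by the file are drawn uniformly from ``[-b, +b]``; the default
bound is the variance-preserving ``b = sqrt(3/dim)`` (the literal ``3/dim``
reading is available via ``bound="linear"``).  The padding row is zero.
"""

from __future__ import annotations

import io
from typing import Iterable, Literal

import numpy as np

from .alphabet import Alphabet


class VectorFormatError(ValueError):
    pass


def init_bound(dim: int, bound: Literal["sqrt", "linear"] = "sqrt") -> float:
    return float(np.sqrt(3.0 / dim)) if bound == "sqrt" else 3.0 / dim


def random_embedding(
    size: int, dim: int, rng: np.random.Generator, bound: Literal["sqrt", "linear"] = "sqrt"
) -> np.ndarray:
    """Uniformly initialized embedding table with a zero padding row."""
    b = init_bound(dim, bound)
    table = rng.uniform(-b, b, size=(size, dim))
    table[Alphabet.PAD_INDEX] = 0.0
    return table


def read_word_vectors(stream: Iterable[str] | str) -> tuple[dict[str, np.ndarray], int]:
    """Parse a word-vector text stream into ``{word: vector}`` plus dim."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    for lineno, line in enumerate(stream, start=1):
        parts = line.rstrip("\n").split()
        if not parts:
            continue
        if lineno == 1 and len(parts) == 2:
            try:  # "count dim" header
                int(parts[0]), int(parts[1])
                continue
            except ValueError:
                pass
        word, values = parts[0], parts[1:]
        try:
            vec = np.asarray([float(v) for v in values], dtype=float)
        except ValueError as exc:
            raise VectorFormatError(f"non-numeric value on line {lineno}") from exc
        if dim is None:
            dim = len(vec)
            if dim == 0:
                raise VectorFormatError(f"no vector values on line {lineno}")
        elif len(vec) != dim:
            raise VectorFormatError(
                f"dimensionality {len(vec)} on line {lineno} != {dim} seen earlier"
            )
        vectors[word] = vec
    return vectors, (dim or 0)


def load_word_vectors(
    stream: Iterable[str] | str,
    alphabet: Alphabet,
    dim: int | None = None,
    rng: np.random.Generator | None = None,
    bound: Literal["sqrt", "linear"] = "sqrt",
) -> np.ndarray:
    """Build an ``alphabet.size x dim`` embedding table from a vector file.

    In-alphabet words present in the file keep their file vectors; all other
    rows (unknown token included) are uniform random within the init bound;
    the padding row is zero.  ``dim`` is taken from the file when present.
    """
    vectors, file_dim = read_word_vectors(stream)
    if file_dim:
        if dim is not None and dim != file_dim:
            raise VectorFormatError(f"requested dim {dim} != file dim {file_dim}")
        dim = file_dim
    if dim is None:
        raise VectorFormatError("empty vector file and no dim given")
    rng = rng or np.random.default_rng(0)
    table = random_embedding(alphabet.size, dim, rng, bound)
    hits = 0
    for index in range(Alphabet.NUM_RESERVED, alphabet.size):
        vec = vectors.get(alphabet.instance(index))
        if vec is not None:
            table[index] = vec
            hits += 1
    return table
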