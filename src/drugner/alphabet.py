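"""Bijective instance <-> index mappings with reserved padding/unknown slots.

Every discrete channel of the model (words, characters, NER labels,
normalization labels, auxiliary features) is indexed through an
:class:`Alphabet`.  Index 0 is reserved for padding and index 1 for
unknown/out-of-vocabulary instances; learned instances start at index 2 in
first-occurrence order, which makes encoding deterministic given corpus
iteration order.
"""

from __future__ import annotations

from typing import Iterable, Iterator

PAD = "<PAD>"
UNK = "<UNK>"


class Alphabet:
    """A growable, freezable bijection between strings and dense indices."""

    PAD_INDEX = 0
    UNK_INDEX = 1
    NUM_RESERVED = 2

    def __init__(self, name: str = "", frozen: bool = False) -> None:
        self.name = name
        self.frozen = frozen
        self._instance_to_index: dict[str, int] = {PAD: self.PAD_INDEX, UNK: self.UNK_INDEX}
        self._index_to_instance: list[str] = [PAD, UNK]

    def __len__(self) -> int:
        return len(self._index_to_instance)

    def __contains__(self, instance: str) -> bool:
        return instance in self._instance_to_index

    def __iter__(self) -> Iterator[str]:
        return iter(self._index_to_instance[self.NUM_RESERVED:])

    @property
    def size(self) -> int:
        """Total number of indices, reserved entries included."""
        return len(self._index_to_instance)

    @property
    def num_learned(self) -> int:
        return len(self._index_to_instance) - self.NUM_RESERVED

    def instances(self) -> list[str]:
        """Learned instances in index order (reserved entries excluded)."""
        return list(self._index_to_instance[self.NUM_RESERVED:])

    def add(self, instance: str) -> int:
        if instance in self._instance_to_index:
            return self._instance_to_index[instance]
        if self.frozen:
            raise RuntimeError(f"alphabet {self.name!r} is frozen; cannot add {instance!r}")
        index = len(self._index_to_instance)
        self._instance_to_index[instance] = index
        self._index_to_instance.append(instance)
        return index

    def update(self, instances: Iterable[str]) -> None:
        for instance in instances:
            self.add(instance)

    def index(self, instance: str) -> int:
        """Look up an instance; grows the mapping unless frozen, in which
        case unseen instances map to the unknown index."""
        found = self._instance_to_index.get(instance)
        if found is not None:
            return found
        if self.frozen:
            return self.UNK_INDEX
        return self.add(instance)

    def instance(self, index: int) -> str:
        if not 0 <= index < len(self._index_to_instance):
            raise IndexError(f"index {index} out of range for alphabet {self.name!r}")
        return self._index_to_instance[index]

    def freeze(self) -> "Alphabet":
        self.frozen = True
        return self

    def to_dict(self) -> dict:
        return {"name": self.name, "frozen": self.frozen, "instances": self.instances()}

    @classmethod
    def from_dict(cls, payload: dict) -> "Alphabet":
        alphabet = cls(payload.get("name", ""))
        alphabet.update(payload["instances"])
        alphabet.frozen = bool(payload.get("frozen", False))
        return alphabet
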