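"""Language representation for the founder-effect simulator.

A language is a presence/absence vector over a master phoneme inventory.
Because every simulated language descends from one of a handful of ancestral
languages, and phoneme loss only ever clears bits, each language can be
stored compactly as a bit-string over its *ancestor's* initial phoneme list:
bit ``j`` of the compact string refers to the ``j``-th phoneme (in master
order) that the ancestor started with.  At analysis time the compact string
is expanded back to the full master-inventory space by looking up the
ancestor.

All bit-vectors are numpy ``uint8`` arrays of 0/1 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PhonemeInventory",
    "AncestralLanguage",
    "LanguageString",
    "compact_encode",
    "expand",
    "lose_random_phoneme",
]


def _as_bits(vec) -> np.ndarray:
    a = np.asarray(vec)
    if a.dtype == bool:
        a = a.astype(np.uint8)
    a = a.astype(np.uint8, copy=False)
    if a.ndim != 1 or not np.isin(a, (0, 1)).all():
        raise ValueError("presence vector must be 1-D with 0/1 entries")
    return a


@dataclass(frozen=True)
class PhonemeInventory:
    """Ordered master inventory of phoneme tokens.

    Positions are meaningful: every full-space presence vector in a run is
    indexed against this ordering.  Tokens are opaque strings (IPA symbols in
    real data, generated labels in simulations).
    """

    phonemes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.phonemes)) != len(self.phonemes):
            raise ValueError("phoneme identifiers must be unique")

    @property
    def nph(self) -> int:
        return len(self.phonemes)

    def index(self, token: str) -> int:
        return self.phonemes.index(token)

    @classmethod
    def generated(cls, nph: int = 908, prefix: str = "ph") -> "PhonemeInventory":
        """A synthetic master inventory of ``nph`` opaque tokens."""
        width = len(str(nph))
        return cls(tuple(f"{prefix}{i:0{width}d}" for i in range(nph)))

    @classmethod
    def from_file(cls, path) -> "PhonemeInventory":
        """Read one phoneme token per line; line number = position."""
        with open(path, "r", encoding="utf-8") as fh:
            toks = [line.strip() for line in fh if line.strip()]
        return cls(tuple(toks))

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tok in self.phonemes:
                fh.write(tok + "\n")


@dataclass(frozen=True)
class AncestralLanguage:
    """One of the initial languages seeded at the dispersal origin.

    ``full_mask`` is the presence vector over the master inventory;
    ``K`` (its popcount) is the ancestor's initial phoneme count and the
    length of every compact string that descends from it.
    """

    id: str
    full_mask: np.ndarray
    positions: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "full_mask", _as_bits(self.full_mask))
        self.full_mask.setflags(write=False)
        pos = np.flatnonzero(self.full_mask)
        if pos.size < 1:
            raise ValueError("an ancestral language needs at least one phoneme")
        object.__setattr__(self, "positions", pos)

    @property
    def K(self) -> int:
        return int(self.positions.size)

    @property
    def nph(self) -> int:
        return int(self.full_mask.size)


@dataclass(frozen=True, eq=False)
class LanguageString:
    """A tribe's language: ancestor label + compact presence bits.

    Bit ``j`` corresponds to the ``j``-th phoneme of the ancestor's initial
    inventory (master order).  Values are immutable; mutation returns a new
    string, so tribes that share a string diverge after independent loss.
    """

    ancestor_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", _as_bits(self.bits))
        self.bits.setflags(write=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LanguageString):
            return NotImplemented
        return (self.ancestor_id == other.ancestor_id
                and self.bits.size == other.bits.size
                and bool((self.bits == other.bits).all()))

    def __hash__(self) -> int:
        return hash((self.ancestor_id, self.bits.tobytes()))

    @property
    def phoneme_count(self) -> int:
        return int(self.bits.sum())


def compact_encode(full_mask, ancestor: AncestralLanguage) -> LanguageString:
    """Compress a full-space presence vector into ancestor-relative bits.

    Raises ``ValueError`` if ``full_mask`` contains a phoneme the ancestor
    never had (a corrupted lineage: loss can only clear bits).
    """
    m = _as_bits(full_mask)
    if m.size != ancestor.nph:
        raise ValueError("full_mask length does not match the master inventory")
    if np.any(m & ~ancestor.full_mask & 1):
        raise ValueError(
            "full_mask contains phonemes absent from the ancestor "
            f"{ancestor.id!r}; not a descendant"
        )
    return LanguageString(ancestor.id, m[ancestor.positions])


def expand(ls: LanguageString, ancestors: Mapping[str, AncestralLanguage] | Iterable[AncestralLanguage]) -> np.ndarray:
    """Expand a compact string to the full master-inventory space.

    Inverse of :func:`compact_encode`: positions the ancestor never had stay
    0; the ``j``-th set position of the ancestor's mask carries compact bit
    ``j``.
    """
    if not isinstance(ancestors, Mapping):
        ancestors = {a.id: a for a in ancestors}
    try:
        anc = ancestors[ls.ancestor_id]
    except KeyError:
        raise KeyError(f"unknown ancestor id {ls.ancestor_id!r}") from None
    if ls.bits.size != anc.K:
        raise ValueError("compact string length does not match ancestor K")
    full = np.zeros(anc.nph, dtype=np.uint8)
    full[anc.positions] = ls.bits
    return full


def lose_random_phoneme(ls: LanguageString, rng: np.random.Generator) -> LanguageString:
    """Clear one uniformly chosen set bit; a new string is returned.

    An empty string (no phonemes left) is returned unchanged: the model has
    no extinction rule, counts of zero are simply recorded as-is.
    """
    k = ls.phoneme_count
    if k == 0:
        return ls
    which = int(rng.integers(0, k))
    bits = ls.bits.copy()
    set_pos = np.flatnonzero(bits)
    bits[set_pos[which]] = 0
    return LanguageString(ls.ancestor_id, bits)
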