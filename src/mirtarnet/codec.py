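"""Sequence normalization, orientation, padding and integer encoding.

A model input is built from one miRNA and one candidate target site.  The
miRNA is reversed (5'->3' becomes 3'->5'), both sequences are right-padded
with ``N`` into fixed-width slots, the two slots are concatenated, and the
resulting string is mapped to integer codes over the five-letter alphabet
``{A, U, G, C, N}``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "AUGCN"
#: Fixed letter -> code map; stable across runs and serialized models.
LETTER_TO_CODE = {letter: i for i, letter in enumerate(ALPHABET)}
CODE_TO_LETTER = {i: letter for i, letter in enumerate(ALPHABET)}
PAD = "N"

_NORMALIZE = str.maketrans("atgcunT", "AUGCUNU")


class CodecError(ValueError):
    """Base class for sequence-encoding errors."""


class InvalidSymbolError(CodecError):
    def __init__(self, symbol: str, position: int):
        self.symbol = symbol
        self.position = position
        super().__init__(
            f"invalid symbol {symbol!r} at position {position} "
            f"(allowed: A/U/G/C/N and T, any case)"
        )


class OrientationError(CodecError):
    """Raised when a sequence already has the requested orientation."""


class SlotOverflowError(CodecError):
    """Raised when a sequence does not fit its fixed-width slot."""


class Orientation(enum.Enum):
    FIVE_TO_THREE = "5to3"
    THREE_TO_FIVE = "3to5"


@dataclass(frozen=True)
class RnaSequence:
    """An RNA string over {A,U,G,C,N} with an explicit strand orientation."""

    residues: str
    orientation: Orientation = Orientation.FIVE_TO_THREE

    def __post_init__(self):
        if not self.residues:
            raise CodecError("empty sequence")
        for pos, ch in enumerate(self.residues):
            if ch not in LETTER_TO_CODE:
                raise InvalidSymbolError(ch, pos)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class PairSchema:
    """Fixed slot widths for the concatenated miRNA + site model input."""

    mirna_slot_len: int
    site_slot_len: int

    def __post_init__(self):
        if self.mirna_slot_len <= 0 or self.site_slot_len <= 0:
            raise CodecError("slot lengths must be positive")

    @property
    def total_len(self) -> int:
        return self.mirna_slot_len + self.site_slot_len


#: 26-nt miRNA slot + 53-nt site slot -> inputs of length 79.
DEEPMIRTAR_SCHEMA = PairSchema(26, 53)
#: 26-nt miRNA slot + 40-nt (trimmed) site slot -> inputs of length 66.
MIRAW_SCHEMA = PairSchema(26, 40)

SCHEMAS = {"deepmirtar": DEEPMIRTAR_SCHEMA, "miraw": MIRAW_SCHEMA}


@dataclass(frozen=True)
class LabeledPair:
    """One miRNA:site example; both sequences are stored 5'->3'."""

    mirna: RnaSequence
    site: RnaSequence
    label: int
    pair_id: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise CodecError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class EncodedPair:
    """Integer-coded, fixed-length model input plus its class label."""

    codes: np.ndarray
    label: int
    pair_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "codes", np.asarray(self.codes, dtype=np.int64))


def normalize_sequence(raw: str) -> RnaSequence:
    """Uppercase, map T->U and validate the alphabet.

    Returns a 5'->3' :class:`RnaSequence`.  Raises
    :class:`InvalidSymbolError` naming the first offending character.
    """
    if not raw:
        raise CodecError("empty sequence")
    out = raw.translate(_NORMALIZE)
    for pos, ch in enumerate(out):
        if ch not in LETTER_TO_CODE:
            raise InvalidSymbolError(raw[pos], pos)
    return RnaSequence(out, Orientation.FIVE_TO_THREE)


def orient_mirna(mirna: RnaSequence) -> RnaSequence:
    """Reverse a 5'->3' miRNA into model orientation (3'->5')."""
    if mirna.orientation is not Orientation.FIVE_TO_THREE:
        raise OrientationError("miRNA is already 3'->5'; refusing to reverse twice")
    return RnaSequence(mirna.residues[::-1], Orientation.THREE_TO_FIVE)


def pad_sequence(seq: RnaSequence, slot_len: int) -> RnaSequence:
    """Right-pad with 'N' to ``slot_len``; error if the sequence is longer."""
    if len(seq) > slot_len:
        raise SlotOverflowError(
            f"sequence of length {len(seq)} exceeds slot of {slot_len}"
        )
    if len(seq) == slot_len:
        return seq
    return RnaSequence(seq.residues + PAD * (slot_len - len(seq)), seq.orientation)


def concatenate_pair(pair: LabeledPair, schema: PairSchema) -> RnaSequence:
    """Reversed-and-padded miRNA slot followed by the padded site slot."""
    mirna = pad_sequence(orient_mirna(pair.mirna), schema.mirna_slot_len)
    site = pad_sequence(pair.site, schema.site_slot_len)
    return RnaSequence(mirna.residues + site.residues, Orientation.FIVE_TO_THREE)


def encode(seq: RnaSequence) -> np.ndarray:
    """Map residues to integer codes (A=0, U=1, G=2, C=3, N=4)."""
    return np.fromiter(
        (LETTER_TO_CODE[ch] for ch in seq.residues), dtype=np.int64, count=len(seq)
    )


def decode(codes: np.ndarray) -> RnaSequence:
    """Inverse of :func:`encode`."""
    return RnaSequence("".join(CODE_TO_LETTER[int(c)] for c in codes))


def encode_pair(pair: LabeledPair, schema: PairSchema) -> EncodedPair:
    """Full pipeline: orient, pad, concatenate and integer-encode one pair."""
    return EncodedPair(encode(concatenate_pair(pair, schema)), pair.label, pair.pair_id)


def encode_dataset(
    pairs: list[LabeledPair], schema: PairSchema
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a pair list into an (N, total_len) code matrix and label vector."""
    if not pairs:
        raise CodecError("empty dataset")
    X = np.stack([encode_pair(p, schema).codes for p in pairs])
    y = np.array([p.label for p in pairs], dtype=np.float64)
    return X, y
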