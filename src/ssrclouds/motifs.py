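"""SSR motif families: canonicalization of 1-6 bp tandem-repeat motifs.

A microsatellite motif is an ambiguous name for a repeat: the run
``...AACAACAAC...`` can be read starting at any phase (AAC, ACA, CAA)
and on either strand (GTT, TGT, TTG).  All six strings describe the
same repeat, so motifs are collapsed into *motif families* -- the orbit
of a motif under cyclic rotation and reverse complement -- named by the
lexicographically smallest member.  A motif that is a whole-number
concatenation of a shorter motif (ATAT = (AT)x2) is reduced to its
primitive root before family assignment, so the families partition the
primitive motifs of lengths 1-6.  There are 501 such families.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

DNA_ALPHABET = "ACGT"
MAX_MOTIF_LEN = 6

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InvalidMotifError(ValueError):
    """Raised for motifs outside the {A,C,G,T} x length 1-6 domain."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def rotations(motif: str) -> set[str]:
    """All cyclic rotations (phases) of a motif."""
    return {motif[i:] + motif[:i] for i in range(len(motif))}


def primitive_root(motif: str) -> str:
    """Shortest string whose whole-number concatenation equals ``motif``.

    Checks every divisor length of the motif; a primitive motif is its
    own root.
    """
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return motif[:d]
    return motif


def is_primitive(motif: str) -> bool:
    return primitive_root(motif) == motif


@dataclass(frozen=True)
class MotifFamily:
    """Equivalence class of primitive motifs under rotation + revcomp."""

    canonical_id: str
    members: frozenset[str] = field(repr=False)

    @property
    def motif_length(self) -> int:
        return len(self.canonical_id)

    def __contains__(self, motif: str) -> bool:
        return motif in self.members


def _validate(motif: str) -> str:
    if not isinstance(motif, str) or not motif:
        raise InvalidMotifError("motif must be a non-empty DNA string")
    motif = motif.upper()
    if len(motif) > MAX_MOTIF_LEN:
        raise InvalidMotifError(
            f"motif {motif!r} longer than {MAX_MOTIF_LEN} bp"
        )
    if any(c not in DNA_ALPHABET for c in motif):
        raise InvalidMotifError(f"motif {motif!r} contains non-ACGT characters")
    return motif


@lru_cache(maxsize=None)
def family_members(motif: str) -> frozenset[str]:
    """Member set of the family containing ``motif``.

    The input is reduced to its primitive root; the family is the union
    of the root's rotations and the rotations of its reverse complement.
    """
    root = primitive_root(_validate(motif))
    return frozenset(rotations(root) | rotations(reverse_complement(root)))


@lru_cache(maxsize=None)
def family_of(motif: str) -> str:
    """Canonical family id (lexicographically smallest member) of a motif.

    Inputs related by rotation, reverse complement, or whole-multiple
    repetition map to the same id, e.g. ``family_of("CAA") ==
    family_of("GTT") == "AAC"`` and ``family_of("ATAT") == "AT"``.
    """
    return min(family_members(motif))


def get_family(motif: str) -> MotifFamily:
    members = family_members(motif)
    return MotifFamily(canonical_id=min(members), members=members)


def enumerate_families(max_len: int = MAX_MOTIF_LEN) -> list[MotifFamily]:
    """All motif families of primitive motifs with length <= ``max_len``.

    For max_len=6 this yields the full catalogue of 501 families.
    Families are returned sorted by (motif length, canonical id).
    """
    if not 1 <= max_len <= MAX_MOTIF_LEN:
        raise ValueError(f"max_len must be in 1..{MAX_MOTIF_LEN}, got {max_len}")
    seen: dict[str, MotifFamily] = {}
    for length in range(1, max_len + 1):
        for tup in itertools.product(DNA_ALPHABET, repeat=length):
            motif = "".join(tup)
            if not is_primitive(motif):
                continue
            cid = family_of(motif)
            if cid not in seen:
                seen[cid] = get_family(motif)
    return sorted(seen.values(), key=lambda f: (f.motif_length, f.canonical_id))
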