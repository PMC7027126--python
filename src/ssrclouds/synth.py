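"""Synthetic toy genomes with known SSR ground truth.

Fixtures emulate the two ingredients of real SSR neighbourhoods: a
background sequence with controllable base (or dinucleotide)
composition, and planted repeats -- perfect tandem runs of a chosen
family, optionally "decayed" by per-base substitutions and indels to
mimic the mutational degradation of ancient loci.  Every plant's exact
post-insertion coordinates and realized mutation counts are recorded in
a truth table, so recall/precision of the scanners and annotators can
be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import DNA_ALPHABET, family_members, family_of


class PlacementError(ValueError):
    """Raised when a genome cannot hold the requested plants."""


@dataclass
class PlantSpec:
    """One batch of planted repeats of a single family."""

    family: str
    perfect_length: int
    copies: int = 1
    decay_substitution_rate: float = 0.0
    decay_indel_rate: float = 0.0
    spacer_length: tuple[int, int] = (100, 300)  # uniform inclusive range

    def __post_init__(self):
        for r in (self.decay_substitution_rate, self.decay_indel_rate):
            if not 0 <= r <= 1:
                raise ValueError(f"decay rate {r} outside [0, 1]")
        self.family = family_of(self.family)


def make_background(
    length: int,
    base_frequencies: dict[str, float] | None = None,
    dinucleotide: np.ndarray | None = None,
    seed: int | None = None,
) -> str:
    """Random background sequence with no repeat structure beyond chance.

    Either i.i.d. draws from ``base_frequencies`` (default uniform) or
    an order-1 chain from a 4x4 ``dinucleotide`` transition matrix
    (rows = previous base, ACGT order).
    """
    rng = np.random.default_rng(seed)
    if dinucleotide is not None:
        dinucleotide = np.asarray(dinucleotide, dtype=float)
        if dinucleotide.shape != (4, 4) or not np.allclose(
            dinucleotide.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("dinucleotide matrix rows must each sum to 1")
        cum = np.cumsum(dinucleotide, axis=1)
        u = rng.random(length)
        out = bytearray(length)
        prev = int(rng.integers(4))
        for i in range(length):
            prev = int(np.searchsorted(cum[prev], u[i], side="right"))
            prev = min(prev, 3)
            out[i] = ord(DNA_ALPHABET[prev])
        return out.decode("ascii")
    if base_frequencies is None:
        base_frequencies = {b: 0.25 for b in DNA_ALPHABET}
    probs = np.array([base_frequencies.get(b, 0.0) for b in DNA_ALPHABET])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"base frequencies sum to {probs.sum()}, not 1")
    idx = rng.choice(4, size=length, p=probs)
    return "".join(DNA_ALPHABET[i] for i in idx)


def _decay(
    perfect: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> tuple[str, int, int, int]:
    """Apply per-base substitutions and indels; return (seq, nsub, nins, ndel)."""
    out: list[str] = []
    nsub = nins = ndel = 0
    for base in perfect:
        if indel_rate and rng.random() < indel_rate / 2:
            ndel += 1
            continue
        if sub_rate and rng.random() < sub_rate:
            base = rng.choice([b for b in DNA_ALPHABET if b != base])
            nsub += 1
        out.append(base)
        if indel_rate and rng.random() < indel_rate / 2:
            out.append(DNA_ALPHABET[rng.integers(4)])
            nins += 1
    return "".join(out), nsub, nins, ndel


def plant(
    genome: str,
    spec: PlantSpec,
    seed: int | None = None,
    chrom: str = "chr1",
) -> tuple[str, pd.DataFrame]:
    """Insert ``spec.copies`` (possibly decayed) repeats into a sequence.

    Insertion points are spaced by spacers drawn uniformly from
    ``spec.spacer_length``; insertions shift downstream coordinates and
    the truth table records final (post-indel, post-insertion)
    coordinates, so interval comparisons against annotations are exact.
    """
    rng = np.random.default_rng(seed)
    members = sorted(family_members(spec.family))
    cuts: list[int] = []
    pos = 0
    for _ in range(spec.copies):
        pos += int(rng.integers(spec.spacer_length[0], spec.spacer_length[1] + 1))
        cuts.append(pos)
    if cuts and cuts[-1] > len(genome):
        raise PlacementError(
            f"genome of {len(genome)} bp too short for {spec.copies} plants "
            f"with spacers {spec.spacer_length}"
        )
    pieces: list[str] = []
    records = []
    prev = 0
    offset = 0
    for cut in cuts:
        pieces.append(genome[prev:cut])
        motif = members[int(rng.integers(len(members)))]
        perfect = (motif * (spec.perfect_length // len(motif) + 1))[
            : spec.perfect_length
        ]
        seq, nsub, nins, ndel = _decay(
            perfect, spec.decay_substitution_rate, spec.decay_indel_rate, rng
        )
        start = cut + offset
        pieces.append(seq)
        records.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + len(seq),
                "family": spec.family,
                "perfect_length": spec.perfect_length,
                "n_sub": nsub,
                "n_ins": nins,
                "n_del": ndel,
            }
        )
        offset += len(seq)
        prev = cut
    pieces.append(genome[prev:])
    truth = pd.DataFrame(
        records,
        columns=[
            "chrom", "start", "end", "family", "perfect_length",
            "n_sub", "n_ins", "n_del",
        ],
    )
    return "".join(pieces), truth


def make_planted_genome(
    background_length: int,
    specs: list[PlantSpec],
    base_frequencies: dict[str, float] | None = None,
    seed: int | None = None,
    chrom: str = "chr1",
) -> tuple[dict[str, str], pd.DataFrame]:
    """Background plus a batch of plants per spec; returns (genome, truth).

    Spacers come from the same background generator, so they carry no
    family signal above chance.
    """
    rng = np.random.default_rng(seed)
    background = make_background(
        background_length, base_frequencies, seed=int(rng.integers(2**31))
    )
    order: list[PlantSpec] = []
    for spec in specs:
        order.extend([spec] * spec.copies)
    perm = rng.permutation(len(order))
    order = [order[i] for i in perm]

    pieces: list[str] = []
    records = []
    prev = 0
    offset = 0
    for spec in order:
        lo, hi = spec.spacer_length
        cut = prev + int(rng.integers(lo, hi + 1))
        if cut > len(background):
            raise PlacementError(
                f"background of {background_length} bp too short for "
                f"{len(order)} plants"
            )
        members = sorted(family_members(spec.family))
        motif = members[int(rng.integers(len(members)))]
        perfect = (motif * (spec.perfect_length // len(motif) + 1))[
            : spec.perfect_length
        ]
        decayed, nsub, nins, ndel = _decay(
            perfect, spec.decay_substitution_rate, spec.decay_indel_rate, rng
        )
        pieces.append(background[prev:cut])
        start = cut + offset
        pieces.append(decayed)
        records.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + len(decayed),
                "family": spec.family,
                "perfect_length": spec.perfect_length,
                "sub_rate": spec.decay_substitution_rate,
                "indel_rate": spec.decay_indel_rate,
                "n_sub": nsub,
                "n_ins": nins,
                "n_del": ndel,
            }
        )
        offset += len(decayed)
        prev = cut
    pieces.append(background[prev:])
    truth = pd.DataFrame(
        records,
        columns=[
            "chrom", "start", "end", "family", "perfect_length",
            "sub_rate", "indel_rate", "n_sub", "n_ins", "n_del",
        ],
    ).sort_values("start", ignore_index=True)
    return {chrom: "".join(pieces)}, truth
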