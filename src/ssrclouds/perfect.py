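"""Detection of perfect (uninterrupted) SSR loci.

A perfect locus is a maximal run of tandem copies of one motif-family
member -- no substitutions, indels, or phase shifts -- of at least
``min_length`` bp (default 12, the empirical slippage-threshold
length).  A trailing partial motif copy counts toward the length, so a
13 bp run of a trinucleotide motif (4 1/3 copies) is a 13 bp locus.
Runs are found per period with a shifted self-comparison of the
sequence: positions where ``seq[i] == seq[i+p]`` chain into regions of
exact period p.  N characters and contig ends break runs.

Loci of different families may overlap (a poly-A run inside an AAC run
is reported under both families); loci of the same family are disjoint
and separated by at least 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motifs import MAX_MOTIF_LEN, family_of, primitive_root


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class PerfectLocus:
    """Maximal perfect tandem-repeat interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    family: str
    repeat_phase: str  # first motif-length bases of the locus

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


_VALID = frozenset("ACGTN")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    return arr


def scan_perfect(
    seq: str,
    min_length: int = 12,
    families: set[str] | None = None,
    chrom: str = "seq",
    max_motif_len: int = MAX_MOTIF_LEN,
) -> list[PerfectLocus]:
    """All maximal perfect SSR loci >= ``min_length`` bp in ``seq``.

    Parameters
    ----------
    seq:
        DNA string; lowercase accepted (softmask ignored), N allowed and
        treated as a repeat breaker.
    min_length:
        Minimum locus length in bp; applies to all families.
    families:
        Optional restriction to a set of canonical family ids.
    """
    if not seq:
        raise InvalidSequenceError("empty sequence")
    seq = seq.upper()
    if set(seq) - _VALID:
        bad = sorted(set(seq) - _VALID)
        raise InvalidSequenceError(f"non-ACGTN characters in sequence: {bad}")

    arr = _encode(seq)
    valid = arr != b"N"
    n = len(seq)
    raw: dict[str, list[tuple[int, int, str]]] = {}

    for p in range(1, max_motif_len + 1):
        if n <= p:
            break
        match = (arr[:-p] == arr[p:]) & valid[:-p] & valid[p:]
        if not match.any():
            continue
        # maximal runs of True in `match`
        diff = np.diff(match.astype(np.int8))
        starts = list(np.flatnonzero(diff == 1) + 1)
        ends = list(np.flatnonzero(diff == -1) + 1)
        if match[0]:
            starts.insert(0, 0)
        if match[-1]:
            ends.append(len(match))
        for i, j in zip(starts, ends):
            i, j = int(i), int(j)
            length = (j - i) + p  # region [i, j+p) has exact period p
            if length < min_length:
                continue
            motif = seq[i : i + p]
            if "N" in motif:
                # a run shorter than the period leaves inner positions
                # unchecked by the shifted comparison
                continue
            if len(primitive_root(motif)) != p:
                # covered by the shorter-period scan of the same family
                continue
            fam = family_of(motif)
            if families is not None and fam not in families:
                continue
            raw.setdefault(fam, []).append((i, j + p, motif))

    out: list[PerfectLocus] = []
    for fam, cands in raw.items():
        cands.sort(key=lambda t: (t[0], -t[1]))
        kept: list[tuple[int, int, str]] = []
        for s, e, motif in cands:
            if kept and e <= kept[-1][1]:
                continue  # contained in an earlier same-family locus
            if kept and s <= kept[-1][1]:
                # overlapping/adjacent same-family runs (phase shift at the
                # junction) form a single locus: loci are distinct only when
                # separated by >= 1 bp
                ps, pe, pm = kept[-1]
                kept[-1] = (ps, e, pm)
            else:
                kept.append((s, e, motif))
        for s, e, motif in kept:
            out.append(PerfectLocus(chrom, s, e, fam, motif))
    out.sort(key=lambda l: (l.chrom, l.start, l.end, l.family))
    return out


def scan_genome(
    genome: dict[str, str],
    min_length: int = 12,
    families: set[str] | None = None,
) -> list[PerfectLocus]:
    """``scan_perfect`` over every record of a genome, sorted by position."""
    loci: list[PerfectLocus] = []
    for chrom in genome:
        loci.extend(
            scan_perfect(genome[chrom], min_length, families, chrom=chrom)
        )
    loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.family))
    return loci


def merge_same_family(
    loci: list[PerfectLocus], gap: int = 100
) -> list[tuple[str, int, int, str]]:
    """Union same-family loci separated by fewer than ``gap`` bp.

    Used before cloud training so that the flanks between two nearby
    loci of one family are not counted twice.  The "fewer than" is
    strict: a separation of exactly ``gap`` bp stays two intervals.
    Returns (chrom, start, end, family) tuples sorted by position.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for l in loci:
        groups.setdefault((l.chrom, l.family), []).append(l.interval)
    merged: list[tuple[str, int, int, str]] = []
    for (chrom, fam), ivs in groups.items():
        out: list[tuple[int, int]] = []
        for s, e in sorted(ivs):
            if out and s - out[-1][1] < gap:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged.extend((chrom, s, e, fam) for s, e in out)
    merged.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    return merged
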