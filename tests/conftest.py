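"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: the
orbit enumerator works on raw strings, the perfect-repeat oracle tests
every (start, period) pair by direct extension, and the cloud oracle
does a plain breadth-first search over the full Hamming graph.
"""

from __future__ import annotations

import itertools
from collections import deque

import pytest

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def brute_primitive_root(m: str) -> str:
    # classic doubling trick: the smallest period is where m re-occurs in m+m
    i = (m + m).find(m, 1)
    root = m[:i]
    return root if len(m) % i == 0 else m


def brute_family_members(m: str) -> frozenset[str]:
    root = brute_primitive_root(m)
    out = set()
    for s in (root, rc(root)):
        for i in range(len(s)):
            out.add(s[i:] + s[:i])
    return frozenset(out)


def brute_family_id(m: str) -> str:
    return min(brute_family_members(m))


def brute_enumerate_orbits(max_len: int) -> dict[str, frozenset[str]]:
    """Orbits of all primitive strings of length <= max_len under
    rotation + reverse complement."""
    orbits: dict[str, frozenset[str]] = {}
    for length in range(1, max_len + 1):
        for tup in itertools.product(BASES, repeat=length):
            s = "".join(tup)
            if brute_primitive_root(s) != s:
                continue
            members = brute_family_members(s)
            orbits[min(members)] = members
    return orbits


def brute_scan_perfect(seq: str, min_len: int = 12, max_p: int = 6):
    """Every maximal perfect tandem run, by direct extension from every
    (start, period) pair; same-family contained runs dropped,
    overlapping/adjacent same-family runs merged into one locus."""
    seq = seq.upper()
    n = len(seq)
    cands: dict[str, set[tuple[int, int]]] = {}
    for p in range(1, max_p + 1):
        for start in range(n - p):
            motif = seq[start : start + p]
            if any(c not in BASES for c in motif):
                continue
            if brute_primitive_root(motif) != motif:
                continue
            end = start + p
            while end < n and seq[end] in BASES and seq[end] == seq[end - p]:
                end += 1
            length = end - start
            if length < max(min_len, p + 1):
                continue
            if (
                start > 0
                and seq[start - 1] in BASES
                and seq[start - 1] == seq[start - 1 + p]
            ):
                continue  # not left-maximal for this period
            cands.setdefault(brute_family_id(motif), set()).add((start, end))
    result = []
    for fam, ivs in cands.items():
        kept: list[list[int]] = []
        for s, e in sorted(ivs, key=lambda t: (t[0], -t[1])):
            if kept and e <= kept[-1][1]:
                continue
            if kept and s <= kept[-1][1]:
                kept[-1][1] = e
            else:
                kept.append([s, e])
        result.extend((fam, s, e) for s, e in kept)
    return sorted(result)


def brute_cloud_bfs(
    seeds: set[str], counts: dict[str, int], threshold: float
) -> set[str]:
    """Plain BFS over the Hamming-1 graph restricted to strand-folded
    counts strictly above threshold (seeds admitted unconditionally)."""
    folded = {}
    for o, c in counts.items():
        folded[o] = c + (counts.get(rc(o), 0) if rc(o) != o else 0)
        folded.setdefault(rc(o), folded[o])
    eligible = {o for o, c in folded.items() if c > threshold}
    cloud = set(seeds)
    queue = deque(seeds)
    while queue:
        cur = queue.popleft()
        for i, ch in enumerate(cur):
            for b in BASES:
                if b == ch:
                    continue
                nb = cur[:i] + b + cur[i + 1 :]
                if nb in eligible and nb not in cloud:
                    cloud.add(nb)
                    queue.append(nb)
    return cloud


@pytest.fixture(scope="session")
def planted_polyA_genome():
    """~60 kb toy genome with 150 planted 30 bp poly-A runs, 10% decay."""
    from ssrclouds.synth import PlantSpec, make_planted_genome

    specs = [
        PlantSpec(
            "A", perfect_length=30, copies=150,
            decay_substitution_rate=0.1, spacer_length=(150, 350),
        )
    ]
    genome, truth = make_planted_genome(60_000, specs, seed=11)
    return genome, truth
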