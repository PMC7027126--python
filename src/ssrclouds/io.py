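"""Readers and writers: FASTA, BED, RepeatMasker ``.out``, config YAML.

All genomic intervals are 0-based half-open (BED convention); the
RepeatMasker reader converts from that format's 1-based inclusive
coordinates.  FASTA input may be gzipped; record names are the first
whitespace-delimited token and sequences are uppercased (softmasked
bases are kept, their count logged).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml
from Bio import SeqIO

logger = logging.getLogger("ssrclouds")


class ParseError(ValueError):
    pass


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> dict[str, str]:
    """Named sequences from a (possibly gzipped) FASTA file."""
    seqs: dict[str, str] = {}
    soft = 0
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            s = str(rec.seq)
            soft += sum(c.islower() for c in s)
            s = s.upper()
            if "U" in s:
                raise ParseError(
                    f"record {rec.id!r} contains U (RNA alphabet not supported)"
                )
            seqs[rec.id] = s
    if soft:
        logger.info("uppercased %d softmasked bases", soft)
    if not seqs:
        raise ParseError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_repeatmasker_out(path) -> list[tuple[str, int, int, str]]:
    """Mask intervals from a RepeatMasker ``.out`` table.

    Returns (chrom, start, end, repeat_class) with coordinates
    converted to 0-based half-open.  The standard 3 header lines (and
    blank lines) are skipped; unparseable rows are skipped with a
    logged warning count.
    """
    out: list[tuple[str, int, int, str]] = []
    skipped = 0
    with _open_text(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue  # header or malformed leading field
            try:
                chrom = parts[4]
                begin = int(parts[5])
                end = int(parts[6])
                repeat_class = parts[10] if len(parts) > 10 else "."
            except (IndexError, ValueError):
                skipped += 1
                continue
            if begin < 1 or end < begin:
                skipped += 1
                continue
            out.append((chrom, begin - 1, end, repeat_class))
    if skipped:
        logger.warning("skipped %d unparseable RepeatMasker rows", skipped)
    return out


def read_bed(path) -> list[tuple]:
    """BED intervals; extra columns are preserved as strings."""
    rows: list[tuple] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {ln}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ParseError(f"line {ln}: non-integer coordinates") from e
            if start > end:
                raise ParseError(f"line {ln}: start {start} > end {end}")
            rows.append((parts[0], start, end, *parts[3:]))
    return rows


def write_bed(rows, path, header_lines: list[str] | None = None) -> None:
    """Write BED rows; floats rendered to 6 significant digits."""
    with open(path, "w") as fh:
        for h in header_lines or []:
            fh.write(f"# {h}\n")
        for row in rows:
            cells = []
            for v in row:
                if isinstance(v, float):
                    cells.append(f"{v:.6g}")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def mask_to_dict(
    intervals: list[tuple],
) -> dict[str, list[tuple[int, int]]]:
    """Group (chrom, start, end, ...) rows into a chrom->intervals mapping."""
    d: dict[str, list[tuple[int, int]]] = {}
    for row in intervals:
        d.setdefault(row[0], []).append((row[1], row[2]))
    for c in d:
        d[c].sort()
    return d


def save_cloudset(cs, directory, counts: dict[str, int] | None = None) -> Path:
    """Write one plain-text cloud file: oligo, tier rank, training count.

    Tier rank is the most stringent tier containing the oligo; the
    training count column is the strand-folded flank count when
    ``counts`` is given, else 0 (perfect-repeat oligos need not occur
    in training flanks at all).
    """
    from .clouds import fold_counts

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    folded = fold_counts(counts) if counts else {}
    path = directory / f"{cs.family}.cloud.tsv"
    with open(path, "w") as fh:
        fh.write(f"# family: {cs.family}\n# k: {cs.k}\n")
        fh.write(f"# thresholds: {[t.core_threshold for t in cs.tiers]}\n")
        fh.write(f"# training_locus_count: {cs.training_locus_count}\n")
        fh.write(f"# flank_width: {cs.flank_width}\n")
        fh.write(f"# train_fraction: {cs.train_fraction}\n")
        fh.write(f"# seed: {cs.seed}\n")
        for oligo in sorted(cs.all_oligos):
            rank = cs.tier_of(oligo)
            perf = 1 if oligo in cs.perfect_oligos else 0
            fh.write(f"{oligo}\t{rank}\t{folded.get(oligo, 0)}\t{perf}\n")
    return path


def load_cloudset(path):
    """Read a cloud file written by :func:`save_cloudset`."""
    from .clouds import CloudSet, CloudTier

    meta: dict[str, str] = {}
    rows: list[tuple[str, int, int]] = []
    perfect: set[str] = set()
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, val = line[2:].partition(": ")
                meta[key] = val
                continue
            if not line:
                continue
            oligo, rank, count, perf = line.split("\t")
            rows.append((oligo, int(rank), int(count)))
            if perf == "1":
                perfect.add(oligo)
    thresholds = [float(x) for x in yaml.safe_load(meta.get("thresholds", "[]"))]
    n_tiers = max((r for _, r, _ in rows), default=len(thresholds)) or 1
    if len(thresholds) < n_tiers:
        thresholds = thresholds + [0.0] * (n_tiers - len(thresholds))
    tiers = []
    acc: set[str] = set()
    for rank in range(1, n_tiers + 1):
        acc |= {o for o, r, _ in rows if r == rank}
        tiers.append(
            CloudTier(
                stringency_rank=rank,
                core_threshold=thresholds[rank - 1],
                oligos=frozenset(acc),
            )
        )
    seed = meta.get("seed", "None")
    return CloudSet(
        family=meta["family"],
        k=int(meta["k"]),
        tiers=tiers,
        perfect_oligos=frozenset(perfect),
        training_locus_count=int(meta.get("training_locus_count", 0)),
        flank_width=int(meta.get("flank_width", 50)),
        train_fraction=float(meta.get("train_fraction", 0.9)),
        seed=None if seed == "None" else int(seed),
    )


def load_cloud_dir(directory) -> list:
    return [
        load_cloudset(p) for p in sorted(Path(directory).glob("*.cloud.tsv"))
    ]


@dataclass
class RunConfig:
    """The full parameter surface, defaulted to the published settings."""

    k: int = 16
    min_perfect_length: int = 12
    flank_width: int = 50
    train_fraction: float = 0.9
    train_merge_gap: int = 100
    min_training_loci: int = 100
    merge_dist: int = 5
    tier_fractions: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    tier_thresholds: list[float] | None = None  # overrides tier_fractions
    fdr_window: int = 1_000_000
    replicates: int = 15
    seed: int | None = None
    perfect_run_length: int = 12

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with _open_text(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        if "tier_fractions" in data:
            data["tier_fractions"] = tuple(data["tier_fractions"])
        return cls(**data)

    def with_overrides(self, **kwargs) -> "RunConfig":
        from dataclasses import replace

        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})

    def header_lines(self) -> list[str]:
        return [
            f"{f.name}: {getattr(self, f.name)}" for f in fields(self)
        ]
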