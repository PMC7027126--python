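"""False-positive and false-discovery rates from Markov-simulated nulls.

Cloud annotation of a genome that contains no real SSRs still produces
hits by chance, more often for relaxed tiers and short loci.  To
quantify this, null genomes are simulated window by window from an
order-1 Markov chain fitted to the (repeat-masked) source genome --
each base drawn conditional on the previous one from the window's
dinucleotide frequencies, with the marginal base distribution used at
window starts.  Annotating the null replicates with the same clouds
yields, per stringency tier, the cumulative fraction of simulated bp
annotated at each locus length or longer (the FPR table).  A real
locus's FDR is then the expected falsely annotated bp at its (tier,
longest consecutive same-tier stretch) -- conservatively computed over
the whole analyzed genome -- divided by the observed annotated bp at
that setting, capped at 1.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .annotate import CloudLocus

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class NullGenomeSpec:
    """Parameters of the null-genome simulation."""

    window: int = 1_000_000
    replicates: int = 15
    seed: int | None = None

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.window < 2:
            raise ValueError("window must be >= 2")


@dataclass
class WindowFrequencies:
    """Marginal and conditional base frequencies of one genome window."""

    chrom: str
    start: int
    end: int
    base_probs: np.ndarray  # shape (4,)
    transition_probs: np.ndarray  # shape (4, 4); row = previous base
    fallback: bool = False  # True when the window was fully masked


def _encode_bases(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def estimate_frequencies(
    genome: dict[str, str],
    mask: dict[str, list[tuple[int, int]]] | None = None,
    window: int = 1_000_000,
) -> list[WindowFrequencies]:
    """Per-window base and dinucleotide frequencies of a genome.

    Masked positions (perfect SSRs, transposable elements, ...) and Ns
    are excluded from counting, and a masked position also breaks the
    adjacency of the dinucleotide on either side, so the estimates
    describe the non-repetitive background.  A window with no usable
    bases inherits the genome-wide frequencies and is flagged.
    """
    tracks: list[WindowFrequencies] = []
    total_base = np.zeros(4)
    total_trans = np.zeros((4, 4))
    raw: list[tuple[str, int, int, np.ndarray, np.ndarray]] = []
    for chrom, seq in genome.items():
        codes = _encode_bases(seq.upper())
        usable = codes < 4
        if mask and chrom in mask:
            for s, e in mask[chrom]:
                usable[s:e] = False
        for ws in range(0, len(seq), window):
            we = min(ws + window, len(seq))
            c = codes[ws:we]
            u = usable[ws:we]
            base = np.bincount(c[u], minlength=5)[:4].astype(float)
            pair_ok = u[:-1] & u[1:]
            trans = np.zeros((4, 4))
            if pair_ok.any():
                pairs = c[:-1][pair_ok] * 4 + c[1:][pair_ok]
                trans = np.bincount(pairs, minlength=16).astype(float).reshape(4, 4)
            total_base += base
            total_trans += trans
            raw.append((chrom, ws, we, base, trans))

    def _norm(v: np.ndarray) -> np.ndarray:
        s = v.sum()
        return v / s if s > 0 else np.full_like(v, 0.25)

    g_base = _norm(total_base)
    g_trans = np.array([_norm(row) for row in total_trans])
    for chrom, ws, we, base, trans in raw:
        if base.sum() == 0:
            tracks.append(
                WindowFrequencies(chrom, ws, we, g_base, g_trans, fallback=True)
            )
            continue
        bp = _norm(base)
        tp = np.array(
            [_norm(row) if row.sum() > 0 else bp for row in trans]
        )
        tracks.append(WindowFrequencies(chrom, ws, we, bp, tp))
    return tracks


def _simulate_window(
    n: int, wf: WindowFrequencies, rng: np.random.Generator
) -> str:
    mcum = np.cumsum(wf.base_probs)
    tcum = np.cumsum(wf.transition_probs, axis=1)
    mcum[-1] = tcum[:, -1] = 1.0
    u = rng.random(n)
    rows = [tuple(r) for r in tcum]
    marg = tuple(mcum)

    def draw(cum, r):
        if r < cum[0]:
            return 0
        if r < cum[1]:
            return 1
        if r < cum[2]:
            return 2
        return 3

    out = bytearray(n)
    prev = draw(marg, u[0])
    out[0] = ord(_BASES[prev])
    for i in range(1, n):
        prev = draw(rows[prev], u[i])
        out[i] = ord(_BASES[prev])
    return out.decode("ascii")


def simulate_null_genome(
    tracks: list[WindowFrequencies],
    replicates: int = 15,
    seed: int | None = None,
) -> list[dict[str, str]]:
    """Simulate ``replicates`` same-shaped genomes from frequency tracks.

    Every source window is re-emitted at its own length from its own
    Markov chain; masked source positions are simulated like any other
    (the null genome is a same-length non-repetitive background, not a
    gapped one).  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    genomes: list[dict[str, str]] = []
    for rep in range(replicates):
        parts: dict[str, list[str]] = {}
        for wf in tracks:
            parts.setdefault(wf.chrom, []).append(
                _simulate_window(wf.end - wf.start, wf, rng)
            )
        genomes.append({c: "".join(ps) for c, ps in parts.items()})
    return genomes


class UndefinedRateError(ValueError):
    """Raised when an FPR table is requested over zero simulated bp."""


@dataclass
class FPRTable:
    """Cumulative false-positive rate per (stringency tier, locus length).

    ``rates[tier]`` is a list of (length, cumulative FPR) sorted by
    length: the fraction of simulated bp annotated at that tier within
    loci whose longest consecutive tier stretch is that length or
    longer.  Rates are non-increasing in length and non-decreasing as
    the tier relaxes (both hold by construction from nested tiers).
    """

    simulated_bp: int
    rates: dict[int, list[tuple[int, float]]] = field(repr=False)

    def fpr(self, tier: int, length: int) -> float:
        rows = self.rates.get(tier, [])
        if not rows:
            return 0.0
        lengths = [l for l, _ in rows]
        if length > lengths[-1]:
            return 0.0  # no null locus was ever this long
        i = bisect.bisect_right(lengths, length) - 1
        if i < 0:
            # shorter than everything observed: every null locus qualifies
            return rows[0][1]
        # exact length, or (absent length) the nearest shorter length's
        # larger, conservative rate
        return rows[i][1]

    def to_frame(self):
        import pandas as pd

        recs = [
            {"tier": t, "length": l, "cumulative_fpr": r}
            for t, rows in sorted(self.rates.items())
            for l, r in rows
        ]
        return pd.DataFrame(recs, columns=["tier", "length", "cumulative_fpr"])


def _tier_items(loci: list[CloudLocus], tier: int) -> list[tuple[int, int]]:
    """(longest tier stretch, tier-covered bp) per locus hit at that tier."""
    return [
        (l.longest_tier_stretch.get(tier, 0), l.tier_covered_bp.get(tier, 0))
        for l in loci
        if l.longest_tier_stretch.get(tier, 0) > 0
    ]


def _cumulative(items: list[tuple[int, int]]) -> list[tuple[int, float]]:
    """Map sorted unique lengths -> total bp in items of that length or more."""
    items = sorted(items)
    lengths = sorted({l for l, _ in items})
    out = []
    j = len(items)
    cum = 0
    for L in reversed(lengths):
        while j > 0 and items[j - 1][0] >= L:
            cum += items[j - 1][1]
            j -= 1
        out.append((L, cum))
    return out[::-1]


def build_fpr_table(
    null_loci: list[CloudLocus], simulated_bp: int
) -> FPRTable:
    """Cumulative FPR per (tier, length) from a null-genome annotation.

    A null locus contributes its bp covered at a given stringency,
    keyed by the longest stretch consecutively covered at that
    stringency (tiers are nested, so "at that stringency" includes all
    more stringent oligos).
    """
    if simulated_bp <= 0:
        raise UndefinedRateError("no simulated sequence analyzed")
    tiers = sorted(
        {t for l in null_loci for t in l.longest_tier_stretch}
    )
    rates: dict[int, list[tuple[int, float]]] = {}
    for t in tiers:
        rates[t] = [
            (L, bp / simulated_bp)
            for L, bp in _cumulative(_tier_items(null_loci, t))
        ]
    return FPRTable(simulated_bp=simulated_bp, rates=rates)


def assign_fdr(
    real_loci: list[CloudLocus],
    table: FPRTable,
    analyzed_bp: int,
) -> list[CloudLocus]:
    """Fill ``fdr`` on each locus from the null FPR table.

    A locus is keyed by its best tier and the longest consecutive
    stretch at that tier; its FDR is (FPR x analyzed bp) / observed
    cumulative annotated bp at that setting, capped at 1.  The expected
    false bp conservatively treats the entire analyzed genome as
    non-SSR.
    """
    obs_cum: dict[int, list[tuple[int, float]]] = {}
    for t in {l.best_tier for l in real_loci}:
        obs_cum[t] = _cumulative(_tier_items(real_loci, t))

    def observed(tier: int, length: int) -> float:
        rows = obs_cum.get(tier, [])
        lengths = [l for l, _ in rows]
        i = bisect.bisect_right(lengths, length) - 1
        if i < 0:
            return rows[0][1] if rows else 0.0
        return rows[i][1]

    for l in real_loci:
        t = l.best_tier
        length = l.longest_tier_stretch.get(t, 0)
        expected_false = table.fpr(t, length) * analyzed_bp
        obs = observed(t, length)
        l.fdr = min(1.0, expected_false / obs) if obs > 0 else 1.0
    return real_loci


def fdr_curve(
    loci: list[CloudLocus], cutoffs: list[float] | None = None
):
    """Total annotated bp retained at each maximum-FDR threshold."""
    import pandas as pd

    if cutoffs is None:
        cutoffs = [x / 100 for x in range(0, 101, 5)]
    rows = []
    for c in cutoffs:
        bp = sum(l.length for l in loci if l.fdr is not None and l.fdr <= c)
        rows.append({"fdr_max": c, "annotated_bp": bp})
    return pd.DataFrame(rows)
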