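"""K-mer counting and over-representation statistics for CLIP tag sets.

The analysis counts every overlapping k-mer window (default k=6) in a CLIP
tag set and in a length-matched random genomic control, then scores each
k-mer's over-representation with a Pearson chi-squared test on the 2x2 table

    [[obs_count, obs_total - obs_count],
     [bg_count,  bg_total  - bg_count ]]

with 1 degree of freedom and no continuity correction.  The counting unit is
the window: ``obs_total`` is the number of valid (N-free) windows scanned in
the CLIP set, so that the summed counts over all 4^k k-mers equal the window
total.  Significant, enriched k-mers (p < alpha, ratio > 1) are ranked, and
the tags containing the top-ranked k-mers are stacked into a position count
matrix (the numeric content of a sequence logo).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from starbind.sequences import TagSet

logger = logging.getLogger(__name__)

RNA_BASES = ("A", "C", "G", "U")

__all__ = [
    "KmerTable",
    "KmerEnrichmentResult",
    "PositionCountMatrix",
    "count_kmers",
    "chi2_two_by_two",
    "enrich_kmers",
    "select_top_kmers",
    "build_logo_counts",
]


@dataclass
class KmerTable:
    """Occurrence counts of all k-mers observed in a tag set.

    ``total_windows`` counts every valid window, i.e. sum over sequences of
    max(0, len - k + 1) minus windows containing N.  Absent k-mers have
    implicit count 0.
    """

    k: int
    counts: dict[str, int]
    total_windows: int

    def __getitem__(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)


@dataclass
class KmerEnrichmentResult:
    """Per-k-mer enrichment of a CLIP set over its control."""

    kmer: str
    obs_count: int
    obs_total: int
    bg_count: int
    bg_total: int
    ratio: float
    chi2: float
    p_value: float
    degenerate: bool = False


@dataclass
class PositionCountMatrix:
    """Base counts per position relative to a k-mer anchor.

    ``positions`` are offsets relative to the anchored k-mer start (0-based;
    negative offsets are 5' flank).  Fully covered columns sum to
    ``n_sequences``; flank columns that fall outside shorter tags sum to less.
    """

    positions: list[int]
    counts: dict[str, np.ndarray]  # base -> per-column counts
    n_sequences: int

    def column(self, position: int) -> dict[str, int]:
        i = self.positions.index(position)
        return {b: int(self.counts[b][i]) for b in RNA_BASES}

    def to_array(self) -> np.ndarray:
        """(4, n_positions) array in A, C, G, U row order."""
        return np.vstack([self.counts[b] for b in RNA_BASES])


def count_kmers(tags: TagSet, k: int = 6) -> KmerTable:
    """Count all overlapping k-mer windows in ``tags``.

    Windows containing N are skipped and excluded from ``total_windows``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    total = 0
    for seq in tags:
        s = seq.residues
        for i in range(len(s) - k + 1):
            window = s[i : i + k]
            if "N" in window:
                continue
            counts[window] = counts.get(window, 0) + 1
            total += 1
    if total == 0:
        logger.warning(
            "no valid %d-mer windows in tag set %r (k larger than every sequence?)",
            k,
            tags.name,
        )
    return KmerTable(k=k, counts=counts, total_windows=total)


def chi2_two_by_two(
    obs_count: int, obs_total: int, bg_count: int, bg_total: int
) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on a 2x2 table.

    Closed form N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for the table
    [[a, b], [c, d]] = [[obs_count, obs_total-obs_count],
    [bg_count, bg_total-bg_count]].  A zero marginal (k-mer absent from, or
    saturating, both sets) yields (0.0, 1.0) by convention.
    """
    if obs_total <= 0 or bg_total <= 0:
        raise ValueError("totals must be > 0")
    if not (0 <= obs_count <= obs_total and 0 <= bg_count <= bg_total):
        raise ValueError("counts must lie within their totals")
    a, b = obs_count, obs_total - obs_count
    c, d = bg_count, bg_total - bg_count
    n = obs_total + bg_total
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    # survival function can underflow to exactly 0; p is defined on (0, 1]
    p = max(p, math.ulp(0.0))
    return float(chi2), p


def _smoothed_ratio(a: int, obs_total: int, c: int, bg_total: int) -> float:
    """Relative frequency ratio with +0.5 on all four cells when any cell is 0."""
    b, d = obs_total - a, bg_total - c
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / (a + b)) / (c / (c + d))


def enrich_kmers(
    clip: TagSet, control: TagSet, k: int = 6, alpha: float = 0.05
) -> list[KmerEnrichmentResult]:
    """Score every k-mer observed in either set for CLIP-over-control enrichment.

    Returns one :class:`KmerEnrichmentResult` per k-mer, sorted by the
    top-k-mer ranking key (descending ratio, then ascending p, then k-mer).
    Chi-squared and p are computed on raw counts; the enrichment ratio uses a
    +0.5 pseudocount on all four cells when any cell is zero, so it is always
    finite and positive.  Use ``[r for r in results if r.p_value < alpha and
    r.ratio > 1]`` (or :func:`select_top_kmers`) for the filtered view.
    """
    if len(clip) == 0 or len(control) == 0:
        raise ValueError("both tag sets must be non-empty")
    obs = count_kmers(clip, k)
    bg = count_kmers(control, k)
    if bg.total_windows == 0:
        raise ValueError("control set has zero valid windows")
    if obs.total_windows == 0:
        raise ValueError("CLIP set has zero valid windows")

    results = []
    for kmer in sorted(set(obs.counts) | set(bg.counts)):
        a, c = obs[kmer], bg[kmer]
        chi2, p = chi2_two_by_two(a, obs.total_windows, c, bg.total_windows)
        degenerate = (a + c == 0) or (
            a == obs.total_windows and c == bg.total_windows
        )
        results.append(
            KmerEnrichmentResult(
                kmer=kmer,
                obs_count=a,
                obs_total=obs.total_windows,
                bg_count=c,
                bg_total=bg.total_windows,
                ratio=_smoothed_ratio(a, obs.total_windows, c, bg.total_windows),
                chi2=chi2,
                p_value=p,
                degenerate=degenerate,
            )
        )
    results.sort(key=lambda r: (-r.ratio, r.p_value, r.kmer))
    return results


def select_top_kmers(
    results: Sequence[KmerEnrichmentResult], n: int = 15, alpha: float = 0.05
) -> list[KmerEnrichmentResult]:
    """The ``n`` highest-ranked significant, enriched k-mers.

    Significance filter: p < alpha and ratio > 1.  Ranking: descending ratio,
    ties broken by ascending p, then lexicographic k-mer.  If fewer than ``n``
    k-mers pass the filter, all of them are returned with a logged warning.
    """
    significant = [r for r in results if r.p_value < alpha and r.ratio > 1.0]
    significant.sort(key=lambda r: (-r.ratio, r.p_value, r.kmer))
    if len(significant) < n:
        logger.warning(
            "only %d significant enriched k-mers available (requested %d)",
            len(significant),
            n,
        )
    return significant[:n]


def build_logo_counts(
    tags: TagSet,
    top_kmers: Sequence[str] | Sequence[KmerEnrichmentResult],
    flank: int = 0,
) -> PositionCountMatrix:
    """Stack tags containing a top k-mer into a position count matrix.

    Each tag containing at least one of ``top_kmers`` contributes once,
    anchored at its leftmost occurrence (earliest-ranked k-mer wins position
    ties).  Base counts are accumulated over offsets [-flank, k + flank)
    relative to the anchor; offsets outside the tag contribute nothing, as do
    N residues.
    """
    kmers = [r.kmer if isinstance(r, KmerEnrichmentResult) else r for r in top_kmers]
    if not kmers:
        raise ValueError("top_kmers must be non-empty")
    k = len(kmers[0])
    if any(len(m) != k for m in kmers):
        raise ValueError("all top k-mers must have equal length")
    rank = {m: i for i, m in enumerate(kmers)}

    positions = list(range(-flank, k + flank))
    counts = {b: np.zeros(len(positions), dtype=np.int64) for b in RNA_BASES}
    n_sequences = 0
    for seq in tags:
        s = seq.residues
        anchor = None  # (position, rank)
        for i in range(len(s) - k + 1):
            m = s[i : i + k]
            if m in rank:
                cand = (i, rank[m])
                if anchor is None or cand < anchor:
                    anchor = cand
        if anchor is None:
            continue
        n_sequences += 1
        start = anchor[0]
        for col, offset in enumerate(positions):
            pos = start + offset
            if 0 <= pos < len(s) and s[pos] in counts:
                counts[s[pos]][col] += 1
    if n_sequences == 0:
        logger.warning("no tag contains any of the top k-mers; logo matrix is empty")
    return PositionCountMatrix(positions=positions, counts=counts, n_sequences=n_sequences)
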