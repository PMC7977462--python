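"""Epiallele loci, per-locus pattern counting and the coverage/sharing filters.

An epiallele locus is a window of four consecutive CpG sites; a fragment that
carries a definite call at all four contributes exactly one of the 16 binary
patterns.  Loci are rendered with 1-based inclusive coordinates spanning the
CG dinucleotides ("chr1:101-148" style) for all user-facing output.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .bisulfite_io import UNKNOWN, CpGIndex, PatternTable, ReadMethProfile
from .divergence import (
    DEFAULT_EPSILON,
    PatternDistribution,
    pattern_distribution as _pattern_distribution,
)
from .errors import ParameterError

__all__ = [
    "EpialleleLocus",
    "parse_locus_id",
    "enumerate_loci",
    "count_patterns",
    "filter_coverage",
    "shared_loci",
    "pattern_distribution",
    "pattern_to_index",
    "index_to_pattern",
]

N_CPG = 4
N_PATTERNS = 16


def pattern_to_index(pattern: str) -> int:
    """'0111' -> 7; leftmost character is the lowest-coordinate CpG."""
    if len(pattern) != N_CPG or any(c not in "01" for c in pattern):
        raise ValueError(f"bad pattern string {pattern!r}")
    return int(pattern, 2)


def index_to_pattern(i: int) -> str:
    if not 0 <= i < N_PATTERNS:
        raise ValueError(f"pattern index {i} out of range")
    return format(i, "04b")


@dataclass(frozen=True)
class EpialleleLocus:
    """Four consecutive CpG cytosines on one chromosome."""

    chrom: str
    cpg_positions: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.cpg_positions)
        if len(pos) != N_CPG or any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("cpg_positions must be four ascending coordinates")
        object.__setattr__(self, "cpg_positions", pos)

    @property
    def locus_id(self) -> str:
        """1-based inclusive span over the CG dinucleotides."""
        first, last = self.cpg_positions[0], self.cpg_positions[-1]
        return f"{self.chrom}:{first + 1}-{last + 2}"

    @property
    def start(self) -> int:
        """0-based start of the half-open genomic span."""
        return self.cpg_positions[0]

    @property
    def end(self) -> int:
        """0-based exclusive end (past the G of the last CpG)."""
        return self.cpg_positions[-1] + 2

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def parse_locus_id(locus_id: str) -> tuple[str, int, int]:
    """Invert a locus id into (chrom, 0-based start, 0-based exclusive end)."""
    try:
        chrom, span = locus_id.rsplit(":", 1)
        first, last = span.split("-")
        start, end = int(first) - 1, int(last)
    except ValueError as exc:
        raise ValueError(f"bad locus id {locus_id!r}") from exc
    if not (chrom and 0 <= start < end):
        raise ValueError(f"bad locus id {locus_id!r}")
    return chrom, start, end


def enumerate_loci(
    index: CpGIndex | Mapping[str, CpGIndex], *, disjoint: bool = False
) -> list[EpialleleLocus]:
    """All 4-CpG windows over one or several chromosome CpG indexes.

    By default windows slide by one CpG and overlap (n − 3 loci for n CpGs);
    with ``disjoint=True`` non-overlapping tiles are produced instead
    (floor(n / 4) loci).  Chromosomes with fewer than four CpGs yield none.
    """
    if isinstance(index, CpGIndex):
        indexes: Iterable[CpGIndex] = [index]
    else:
        indexes = index.values()
    step = N_CPG if disjoint else 1
    loci = []
    for idx in indexes:
        pos = idx.positions
        for i in range(0, len(pos) - N_CPG + 1, step):
            loci.append(EpialleleLocus(chrom=idx.chrom, cpg_positions=pos[i : i + N_CPG]))
    return loci


def count_patterns(
    profiles: Iterable[ReadMethProfile],
    loci: Iterable[EpialleleLocus],
    sample_id: str,
) -> PatternTable:
    """Count the 16 patterns at each locus over a sample's fragments.

    A fragment contributes to a locus iff it has a definite (non-UNKNOWN)
    call at all four CpG positions; it then increments exactly one of the 16
    counters.  Loci no fragment fully covers are absent from the table.
    """
    by_chrom: dict[str, list[EpialleleLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom_loci in by_chrom.values():
        chrom_loci.sort(key=lambda l: l.cpg_positions)
    starts = {c: [l.cpg_positions[0] for l in ls] for c, ls in by_chrom.items()}

    counts: dict[str, np.ndarray] = {}
    for prof in profiles:
        chrom_loci = by_chrom.get(prof.chrom)
        if not chrom_loci or not prof.calls:
            continue
        lo, hi = min(prof.calls), max(prof.calls)
        s = starts[prof.chrom]
        # candidate loci start within the fragment's covered span
        for k in range(bisect_left(s, lo), bisect_right(s, hi)):
            locus = chrom_loci[k]
            states = [prof.calls.get(p, UNKNOWN) for p in locus.cpg_positions]
            if UNKNOWN in states or None in states:
                continue
            idx = (states[0] << 3) | (states[1] << 2) | (states[2] << 1) | states[3]
            vec = counts.setdefault(locus.locus_id, np.zeros(N_PATTERNS, dtype=np.int64))
            vec[idx] += 1
    return PatternTable(sample_id=sample_id, counts=counts)


def filter_coverage(
    tables: Mapping[str, PatternTable], min_reads: int = 10
) -> dict[str, PatternTable]:
    """Keep only loci with depth >= ``min_reads`` in every supplied sample.

    The boundary is inclusive (depth 10 passes at the default).  A locus
    absent from any sample is removed from all.
    """
    if min_reads < 1:
        raise ParameterError(f"min_reads must be >= 1, got {min_reads}")
    keep = None
    for table in tables.values():
        ok = {loc for loc, vec in table.counts.items() if vec.sum() >= min_reads}
        keep = ok if keep is None else keep & ok
    keep = keep or set()
    return {
        sid: PatternTable(
            sample_id=table.sample_id,
            counts={loc: table.counts[loc] for loc in keep},
        )
        for sid, table in tables.items()
    }


def shared_loci(tables: Mapping[str, PatternTable]) -> set[str]:
    """Locus ids present in every one of >= 2 tables."""
    if len(tables) < 2:
        raise ParameterError("shared_loci needs at least two samples")
    sets = [t.loci() for t in tables.values()]
    return set.intersection(*sets)


def pattern_distribution(counts, epsilon: float = DEFAULT_EPSILON) -> PatternDistribution:
    """Pseudocount-adjusted pattern probability vector; see :mod:`divergence`."""
    return _pattern_distribution(counts, epsilon)
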