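"""Reference/alignment input and the portable pattern-count table format.

This module reduces bisulfite alignments (Bismark-style SAM/BAM with the
per-base XM methylation-call tag, or any aligner plus a reference for C/T
fallback calling) to per-fragment binary methylation calls at forward-strand
CpG cytosines.  It also reads and writes the plain-text table of per-locus
16-pattern counts that the rest of the pipeline consumes.

Coordinates are 0-based half-open internally.  CpG calls on reverse-strand
reads (which observe the G of the dinucleotide) are mapped back to the
forward-strand C coordinate, so both strands contribute to one site.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam

from .errors import DataFormatError

__all__ = [
    "METHYLATED",
    "UNMETHYLATED",
    "UNKNOWN",
    "CpGIndex",
    "ReadMethProfile",
    "PatternTable",
    "ExtractionStats",
    "index_cpg_sites",
    "extract_read_profiles",
    "read_pattern_table",
    "write_pattern_table",
]

# Methylation call states for a single CpG on a single fragment.
METHYLATED = 1
UNMETHYLATED = 0
UNKNOWN = -1

PATTERN_TABLE_COLUMNS = ("sample", "locus", "pattern", "count")


@dataclass(frozen=True)
class CpGIndex:
    """Sorted forward-strand CpG cytosine positions for one chromosome."""

    chrom: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.positions)
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("CpG positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "_posset", frozenset(pos))

    def __contains__(self, position: int) -> bool:
        return position in self._posset

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ReadMethProfile:
    """Binary methylation calls of one sequenced fragment at CpG sites.

    ``calls`` maps 0-based forward-strand CpG positions to METHYLATED,
    UNMETHYLATED or UNKNOWN (the latter from conflicting mate calls).
    """

    fragment_id: str
    chrom: str
    calls: dict[int, int] = field(default_factory=dict)


@dataclass
class PatternTable:
    """Per-locus 16-pattern fragment counts for one sample.

    ``counts`` maps locus_id to a length-16 integer vector; index ``i``
    encodes the pattern bits with the leftmost bit (most significant) being
    the lowest-coordinate CpG, '1' = methylated.
    """

    sample_id: str
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def depth(self, locus_id: str) -> int:
        return int(self.counts[locus_id].sum())

    def loci(self) -> set[str]:
        return set(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatternTable):
            return NotImplemented
        return self.sample_id == other.sample_id and self.loci() == other.loci() and all(
            np.array_equal(self.counts[k], other.counts[k]) for k in self.counts
        )


@dataclass
class ExtractionStats:
    """Bookkeeping for one extraction pass over an alignment file."""

    records_seen: int = 0
    records_skipped_flag: int = 0  # secondary/supplementary/unmapped
    records_skipped_no_tag: int = 0
    records_skipped_inconsistent: int = 0
    fragments: int = 0
    duplicates_removed: int = 0
    conflicting_positions: int = 0


def _scan_cpg(seq: str) -> list[int]:
    seq = seq.upper()
    out = []
    start = 0
    while True:
        i = seq.find("CG", start)
        if i == -1:
            return out
        out.append(i)
        start = i + 1


def index_cpg_sites(
    reference: str | os.PathLike | Mapping[str, str],
) -> dict[str, CpGIndex]:
    """Locate every forward-strand CpG cytosine in a reference.

    Parameters
    ----------
    reference
        Path to a FASTA file, or a mapping of chromosome name to sequence.
        Dinucleotides containing N are not CpGs and are excluded by the
        literal "CG" scan.

    Returns
    -------
    dict mapping chromosome name to its :class:`CpGIndex` (possibly empty).
    """
    if isinstance(reference, Mapping):
        items: Iterable[tuple[str, str]] = reference.items()
    else:
        import pyfaidx

        try:
            fasta = pyfaidx.Fasta(str(reference))
        except Exception as exc:  # pyfaidx raises several types on bad input
            raise DataFormatError(f"cannot read FASTA {reference!r}: {exc}") from exc
        items = ((name, str(fasta[name])) for name in fasta.keys())
    return {
        chrom: CpGIndex(chrom=chrom, positions=tuple(_scan_cpg(str(seq))))
        for chrom, seq in items
    }


def _call_from_tag(
    rec: pysam.AlignedSegment, index: CpGIndex
) -> Iterator[tuple[int, int]]:
    """Yield (forward C position, call) pairs from the Bismark XM tag."""
    xm = rec.get_tag("XM")
    for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
        char = xm[qpos]
        if char not in "Zz":
            continue
        # Forward-strand reads report the call at the C; reverse-strand reads
        # at the G one base downstream.  CpG symmetry maps both to the C.
        if rpos in index:
            pos = rpos
        elif rpos - 1 in index:
            pos = rpos - 1
        else:
            continue
        yield pos, (METHYLATED if char == "Z" else UNMETHYLATED)


def _bisulfite_strand(rec: pysam.AlignedSegment) -> str:
    """Return 'CT' (original top) or 'GA' (original bottom) for a record."""
    if rec.has_tag("XG"):
        return str(rec.get_tag("XG"))
    # Without the Bismark XG tag, infer from orientation: a directional
    # library maps OT reads forward (read1) and OB reads reverse.
    reverse = rec.is_reverse != (rec.is_paired and rec.is_read2)
    return "GA" if reverse else "CT"


def _call_from_reference(
    rec: pysam.AlignedSegment, index: CpGIndex
) -> Iterator[tuple[int, int]]:
    """Fallback calling by base comparison at CpG positions.

    On the original-top strand an unconverted (methylated) CpG cytosine reads
    C and a converted one reads T; on the original-bottom strand the read
    observes the G, which reads G when methylated and A when converted.
    """
    strand = _bisulfite_strand(rec)
    seq = rec.query_sequence
    for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
        base = seq[qpos].upper()
        if strand == "CT":
            if rpos in index:
                if base == "C":
                    yield rpos, METHYLATED
                elif base == "T":
                    yield rpos, UNMETHYLATED
        else:
            if rpos - 1 in index:
                if base == "G":
                    yield rpos - 1, METHYLATED
                elif base == "A":
                    yield rpos - 1, UNMETHYLATED


def extract_read_profiles(
    alignments: str | os.PathLike | pysam.AlignmentFile,
    index: Mapping[str, CpGIndex],
    *,
    mode: str = "tag",
    merge_mates: bool = True,
    remove_duplicates: bool = False,
) -> tuple[list[ReadMethProfile], ExtractionStats]:
    """Reduce alignments to per-fragment CpG methylation calls.

    Parameters
    ----------
    alignments
        SAM/BAM path or an open :class:`pysam.AlignmentFile`.
    index
        Per-chromosome CpG indexes from :func:`index_cpg_sites`.
    mode
        ``"tag"`` uses the Bismark XM call string (records without the tag are
        skipped and counted); ``"reference"`` compares read bases with the
        reference at CpG positions.
    merge_mates
        Merge paired mates into one fragment; a position with conflicting mate
        calls becomes UNKNOWN.  When False each record is its own fragment.
    remove_duplicates
        Drop fragments whose (chrom, covered span, calls) duplicate an earlier
        fragment.

    Returns
    -------
    (profiles, stats) — one profile per fragment, plus skip/merge counters.
    """
    if mode not in ("tag", "reference"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        close = True
    stats = ExtractionStats()
    profiles: dict[tuple[str, str], ReadMethProfile] = {}
    try:
        for rec in alignments:
            stats.records_seen += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                stats.records_skipped_flag += 1
                continue
            chrom = rec.reference_name
            if chrom not in index:
                stats.records_skipped_inconsistent += 1
                continue
            if mode == "tag":
                if not rec.has_tag("XM"):
                    stats.records_skipped_no_tag += 1
                    continue
                try:
                    calls = list(_call_from_tag(rec, index[chrom]))
                except (IndexError, ValueError):
                    stats.records_skipped_inconsistent += 1
                    continue
            else:
                calls = list(_call_from_reference(rec, index[chrom]))
            if merge_mates:
                key = (chrom, rec.query_name)
            else:
                suffix = "/2" if (rec.is_paired and rec.is_read2) else "/1"
                key = (chrom, rec.query_name + suffix)
            prof = profiles.get(key)
            if prof is None:
                prof = profiles[key] = ReadMethProfile(
                    fragment_id=key[1], chrom=chrom
                )
            for pos, state in calls:
                prev = prof.calls.get(pos)
                if prev is None:
                    prof.calls[pos] = state
                elif prev != state and prev != UNKNOWN:
                    prof.calls[pos] = UNKNOWN
                    stats.conflicting_positions += 1
    finally:
        if close:
            alignments.close()

    # Profiles with no CpG call are kept (they contribute to no locus and are
    # ignored downstream by the full-coverage rule).
    out: list[ReadMethProfile] = []
    seen_signatures: set[tuple] = set()
    for prof in profiles.values():
        if remove_duplicates:
            sig = (prof.chrom, tuple(sorted(prof.calls.items())))
            if sig in seen_signatures:
                stats.duplicates_removed += 1
                continue
            seen_signatures.add(sig)
        out.append(prof)
    stats.fragments = len(out)
    return out, stats


def write_pattern_table(table: PatternTable, path: str | os.PathLike) -> None:
    """Write a pattern-count table as TSV (sample, locus, pattern, count).

    Patterns are rendered as 4-character 0/1 strings; zero-count patterns are
    omitted.  The round trip through :func:`read_pattern_table` is lossless.
    """
    rows = []
    for locus_id in sorted(table.counts):
        vec = table.counts[locus_id]
        for i in np.flatnonzero(vec):
            rows.append((table.sample_id, locus_id, format(i, "04b"), int(vec[i])))
    df = pd.DataFrame(rows, columns=list(PATTERN_TABLE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_pattern_table(path: str | os.PathLike) -> PatternTable:
    """Read a TSV pattern-count table written by :func:`write_pattern_table`.

    Raises
    ------
    DataFormatError
        On a bad header, a pattern outside the 16 4-bit codes, a negative or
        non-integer count, or multiple sample ids in one file.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise DataFormatError(f"cannot parse pattern table {path!r}: {exc}") from exc
    if tuple(df.columns) != PATTERN_TABLE_COLUMNS:
        raise DataFormatError(
            f"bad header {tuple(df.columns)}, expected {PATTERN_TABLE_COLUMNS}"
        )
    if df.empty:
        return PatternTable(sample_id="", counts={})
    samples = df["sample"].unique()
    if len(samples) != 1:
        raise DataFormatError(f"expected one sample per table, got {list(samples)}")
    counts: dict[str, np.ndarray] = {}
    seen: set[tuple[str, str]] = set()
    for locus_id, pattern, count in zip(df["locus"], df["pattern"], df["count"]):
        if len(pattern) != 4 or any(c not in "01" for c in pattern):
            raise DataFormatError(f"bad pattern {pattern!r} at locus {locus_id}")
        try:
            n = int(count)
        except (TypeError, ValueError):
            raise DataFormatError(f"non-integer count {count!r} at locus {locus_id}")
        if n < 0:
            raise DataFormatError(f"negative count {n} at locus {locus_id}")
        if (locus_id, pattern) in seen:
            raise DataFormatError(f"duplicate record ({locus_id}, {pattern})")
        seen.add((locus_id, pattern))
        vec = counts.setdefault(locus_id, np.zeros(16, dtype=np.int64))
        vec[int(pattern, 2)] = n
    return PatternTable(sample_id=str(samples[0]), counts=counts)
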