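"""Synthetic multi-region RRBS cohorts with ground truth.

The generator emulates the study design the callers target: one tumor-core
sample plus several tumor-periphery samples sharing a common set of 4-CpG
loci.  At a *null* locus every sample draws reads from one shared pattern
mixture; at a *differential* locus one designated sample (the core by
default) draws from a divergent mixture while the remaining samples share a
concordant one.  Reads are i.i.d. multinomial draws per locus at a fixed
depth — there is no read-length, bisulfite-conversion-error or
sequencing-error model, which is sufficient to exercise all downstream
arithmetic but does not reproduce the coverage irregularity of real RRBS.

Loci are placed on a synthetic chromosome (4 CpGs spaced 10 bp within a
locus, 200 bp between loci) so that the same cohort can be emitted as
Bismark-style SAM plus a FASTA reference and round-tripped through the
alignment reader.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pysam

from .bisulfite_io import PatternTable
from .epiallele import N_PATTERNS, EpialleleLocus
from .errors import ParameterError

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate_cohort",
    "emit_reads",
    "reference_for_loci",
    "mixture_from_subclones",
]

_CHROM = "chrS"
_CPG_SPACING = 10
_LOCUS_SPACING = 200
_FIRST_CPG = 100


@dataclass
class SimConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the targeted design: one core and four periphery samples
    at ~25x read depth per locus.  Null mixtures are drawn from a sparse
    Dirichlet (concentration 0.3 over the 16 patterns), which concentrates
    mass on a few dominant patterns the way RRBS pattern tables do.
    """

    n_peripheries: int = 4
    n_null: int = 500
    n_differential: int = 20
    depth: int = 25
    seed: int = 0
    core_id: str = "C1"
    #: sample the differential mixture is planted in; defaults to the core
    differential_sample: str | None = None
    #: "uniform_vs_pointmass": divergent sample uniform over 16 patterns,
    #: concordant samples a '1111' point mass.  "dirichlet_pair": divergent
    #: sample draws an independent sparse Dirichlet mixture per locus.
    effect: str = "uniform_vs_pointmass"
    null_concentration: float = 0.3
    #: optional explicit per-locus null mixtures (overrides the Dirichlet draw)
    locus_mixtures: Sequence[np.ndarray] | None = None

    @property
    def n_loci(self) -> int:
        return self.n_null + self.n_differential

    @property
    def sample_ids(self) -> list[str]:
        return [self.core_id] + [f"P{i + 1}" for i in range(self.n_peripheries)]

    def validate(self) -> None:
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if self.n_differential < 0 or self.n_null < 0:
            raise ParameterError("locus counts must be non-negative")
        if self.n_peripheries < 1:
            raise ParameterError("need at least one periphery sample")
        if self.effect not in ("uniform_vs_pointmass", "dirichlet_pair"):
            raise ParameterError(f"unknown effect model {self.effect!r}")
        if self.locus_mixtures is not None:
            if len(self.locus_mixtures) != self.n_loci:
                raise ParameterError("locus_mixtures must cover every locus")
            for m in self.locus_mixtures:
                m = np.asarray(m, dtype=float)
                if m.shape != (N_PATTERNS,) or abs(m.sum() - 1.0) > 1e-9 or (m < 0).any():
                    raise ParameterError("each mixture must be a 16-simplex point")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated locus."""

    locus_id: str
    is_differential: bool
    assigned_sample: str  # sample carrying the divergent mixture ('' if null)
    divergent_mixture: tuple[float, ...]
    concordant_mixture: tuple[float, ...]


@dataclass
class SimResult:
    tables: dict[str, PatternTable]
    truth: list[SimTruth]
    loci: list[EpialleleLocus]

    def differential_loci(self) -> set[str]:
        return {t.locus_id for t in self.truth if t.is_differential}

    def null_loci(self) -> set[str]:
        return {t.locus_id for t in self.truth if not t.is_differential}


def mixture_from_subclones(
    components: Sequence[np.ndarray], weights: Sequence[float]
) -> np.ndarray:
    """Combine subclone pattern distributions into one locus mixture."""
    w = np.asarray(weights, dtype=float)
    if w.size != len(components) or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
        raise ParameterError("weights must be non-negative and sum to 1")
    comps = np.vstack([np.asarray(c, dtype=float) for c in components])
    return w @ comps


def _locus_layout(n_loci: int) -> list[EpialleleLocus]:
    loci = []
    for j in range(n_loci):
        base = _FIRST_CPG + j * _LOCUS_SPACING
        loci.append(
            EpialleleLocus(
                chrom=_CHROM,
                cpg_positions=tuple(base + k * _CPG_SPACING for k in range(4)),
            )
        )
    return loci


def simulate_cohort(config: SimConfig) -> SimResult:
    """Draw a reproducible multi-sample cohort of pattern-count tables.

    Null loci share one mixture across all samples; at differential loci the
    designated sample uses the effect model's divergent mixture and the other
    samples its concordant mixture.  All randomness flows from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = config.sample_ids
    divergent_sample = config.differential_sample or config.core_id
    if divergent_sample not in samples:
        raise ParameterError(f"unknown differential sample {divergent_sample!r}")

    loci = _locus_layout(config.n_loci)
    # differential loci interleaved deterministically among the nulls
    diff_idx = set(
        np.linspace(0, config.n_loci - 1, config.n_differential, dtype=int).tolist()
        if config.n_differential
        else []
    )

    uniform = np.full(N_PATTERNS, 1.0 / N_PATTERNS)
    pointmass = np.zeros(N_PATTERNS)
    pointmass[N_PATTERNS - 1] = 1.0  # '1111'

    tables = {s: PatternTable(sample_id=s, counts={}) for s in samples}
    truth: list[SimTruth] = []
    n_diff_seen = 0
    for j, locus in enumerate(loci):
        lid = locus.locus_id
        if j in diff_idx and n_diff_seen < config.n_differential:
            n_diff_seen += 1
            if config.effect == "uniform_vs_pointmass":
                div_mix, con_mix = uniform, pointmass
            else:
                div_mix = rng.dirichlet(np.full(N_PATTERNS, config.null_concentration))
                con_mix = rng.dirichlet(np.full(N_PATTERNS, config.null_concentration))
            per_sample = {
                s: (div_mix if s == divergent_sample else con_mix) for s in samples
            }
            truth.append(
                SimTruth(
                    locus_id=lid,
                    is_differential=True,
                    assigned_sample=divergent_sample,
                    divergent_mixture=tuple(div_mix),
                    concordant_mixture=tuple(con_mix),
                )
            )
        else:
            if config.locus_mixtures is not None:
                mix = np.asarray(config.locus_mixtures[j], dtype=float)
            else:
                mix = rng.dirichlet(np.full(N_PATTERNS, config.null_concentration))
            per_sample = {s: mix for s in samples}
            truth.append(
                SimTruth(
                    locus_id=lid,
                    is_differential=False,
                    assigned_sample="",
                    divergent_mixture=tuple(mix),
                    concordant_mixture=tuple(mix),
                )
            )
        for s in samples:
            tables[s].counts[lid] = rng.multinomial(config.depth, per_sample[s]).astype(
                np.int64
            )
    return SimResult(tables=tables, truth=truth, loci=loci)


def reference_for_loci(loci: Sequence[EpialleleLocus]) -> dict[str, str]:
    """Build a minimal reference whose only CpGs are the loci's CpGs."""
    length: dict[str, int] = {}
    for locus in loci:
        length[locus.chrom] = max(length.get(locus.chrom, 0), locus.end + 10)
    seqs = {chrom: bytearray(b"A" * n) for chrom, n in length.items()}
    for locus in loci:
        for p in locus.cpg_positions:
            seqs[locus.chrom][p] = ord("C")
            seqs[locus.chrom][p + 1] = ord("G")
    return {chrom: seq.decode() for chrom, seq in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def emit_reads(
    table: PatternTable,
    loci: Sequence[EpialleleLocus],
    sam_path: str | os.PathLike,
    reference: Mapping[str, str] | None = None,
) -> Mapping[str, str]:
    """Write one sample's pattern counts as Bismark-style single-end SAM.

    Each counted fragment becomes one alignment exactly covering its locus
    (first CpG −3 bp to last CpG +4 bp) with a bisulfite-converted sequence
    (unmethylated CpG cytosines read T) and a per-base XM call string (Z/z at
    CpG cytosines, '.' elsewhere).  Returns the reference used, generated via
    :func:`reference_for_loci` when none is supplied.

    Raises
    ------
    ParameterError
        If a supplied reference lacks a CG at a locus position.
    """
    by_id = {l.locus_id: l for l in loci}
    if reference is None:
        reference = reference_for_loci(loci)
    for locus in loci:
        seq = reference.get(locus.chrom, "")
        for p in locus.cpg_positions:
            if seq[p : p + 2].upper() != "CG":
                raise ParameterError(
                    f"locus {locus.locus_id} not representable: no CG at {p}"
                )
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in sorted(reference.items())],
    }
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        for lid in sorted(table.counts):
            locus = by_id.get(lid)
            if locus is None:
                raise ParameterError(f"counts for unknown locus {lid}")
            vec = table.counts[lid]
            start = locus.cpg_positions[0] - 3
            end = locus.cpg_positions[-1] + 4  # covers the final G
            ref_seq = reference[locus.chrom][start:end]
            cpg_offsets = [p - start for p in locus.cpg_positions]
            n_emitted = 0
            for pattern_idx in np.flatnonzero(vec):
                bits = format(pattern_idx, "04b")
                read = list(ref_seq)
                xm = ["."] * len(ref_seq)
                for off, bit in zip(cpg_offsets, bits):
                    if bit == "1":
                        xm[off] = "Z"
                    else:
                        read[off] = "T"
                        xm[off] = "z"
                for _ in range(int(vec[pattern_idx])):
                    rec = pysam.AlignedSegment()
                    rec.query_name = f"{table.sample_id}|{lid}|{n_emitted}"
                    rec.query_sequence = "".join(read)
                    rec.flag = 0
                    rec.reference_id = tid[locus.chrom]
                    rec.reference_start = start
                    rec.mapping_quality = 42
                    rec.cigartuples = [(0, len(ref_seq))]
                    rec.query_qualities = pysam.qualitystring_to_array(
                        "I" * len(ref_seq)
                    )
                    rec.set_tag("XM", "".join(xm))
                    rec.set_tag("XG", "CT")
                    out.write(rec)
                    n_emitted += 1
    return reference
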