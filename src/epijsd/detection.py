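"""Differential and sample-specific epiallele calling with normal-null thresholds.

Three callers operate on coverage-filtered, shared pattern tables:

* **PPDE** — differential epialleles between two tumor-periphery samples:
  a locus is called for a periphery pair when its JSD exceeds a threshold
  delta fitted as a one-tailed normal quantile of the pooled periphery-pair
  JSD distribution.
* **CPDE** — differential epialleles between the tumor core and a periphery
  sample P_i.  For each locus, S_i collects the JSDs between P_i and every
  other tumor sample (the core plus the remaining peripheries).  The
  composite specific index CSI = max(S_i) − mean(S_i \\ {max}) is high when
  the core comparison stands out from the periphery-periphery background.
  A call requires (i) JSD(core, P_i) > gamma, (ii) the unique maximum of
  S_i to be the core comparison, and (iii) CSI above a per-pair one-tailed
  normal-null threshold (Thres1).
* **Local-specific** — for each tumor sample, the per-locus mean JSD to the
  other samples; CSI on those means with the argmax naming the sample the
  epiallele is specific to, thresholded the same way (Thres2).

The CSI algebra (max against the mean of the rest) is deliberately isolated
in :func:`_csi` so an alternative contrast (e.g. max − second max) can be
swapped in one place.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .bisulfite_io import PatternTable
from .divergence import DEFAULT_EPSILON, jsd
from .epiallele import shared_loci
from .errors import DegenerateNullError, ParameterError

__all__ = [
    "NullModel",
    "ComparisonRecord",
    "fit_null_threshold",
    "csi_core_periphery",
    "csi_local",
    "detect_ppde",
    "detect_cpde",
    "detect_local_specific",
    "CpdeResult",
    "PpdeResult",
    "SpecificResult",
    "DEFAULT_GAMMA",
    "DEFAULT_ALPHA",
]

#: Minimum JSD between core and periphery for a CPDE / mean JSD for a
#: specific epiallele, chosen from the location of the core-periphery JSD
#: distribution peak.
DEFAULT_GAMMA = 0.3
#: One-tailed significance level of the fitted normal null.
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class NullModel:
    """A normal null fitted to an observed score distribution."""

    mu: float
    sigma: float
    alpha: float
    n_scores: int

    @property
    def threshold(self) -> float:
        """One-tailed exceedance threshold mu + z_{1-alpha} * sigma."""
        return self.mu + sps.norm.ppf(1.0 - self.alpha) * self.sigma


@dataclass
class ComparisonRecord:
    """Per-locus result of one sample-pair or one-sample-vs-rest comparison."""

    locus_id: str
    pair: tuple[str, str] | None = None
    jsd: float = float("nan")
    csi: float = float("nan")
    threshold: float = float("nan")
    call: str = "none"  # none | PPDE | CPDE | specific
    assigned_sample: str = ""
    jsd_values: dict[str, float] = field(default_factory=dict)


def fit_null_threshold(
    scores: Sequence[float], alpha: float = DEFAULT_ALPHA, *, robust: bool = False
) -> NullModel:
    """Fit a normal null to observed scores and derive the one-tailed threshold.

    Location and scale come from moment estimation on the scores themselves
    (``robust=True`` substitutes median and normalised MAD).  The threshold is
    ``mu + Phi^{-1}(1 - alpha) * sigma``; scores above it are significant at
    the one-tailed level ``alpha`` under the fitted null.

    Raises
    ------
    ParameterError
        Fewer than 30 scores, non-finite scores, or alpha outside (0, 1).
    DegenerateNullError
        Zero fitted spread (constant scores).
    """
    x = np.asarray(scores, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if x.size < 30:
        raise ParameterError(f"need >= 30 scores to fit a null, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("scores must be finite")
    if robust:
        mu = float(np.median(x))
        sigma = float(sps.median_abs_deviation(x, scale="normal"))
    else:
        mu = float(x.mean())
        sigma = float(x.std(ddof=1))
    # relative test: the std of a constant vector is ~1e-17, not exactly 0
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        raise DegenerateNullError("score distribution has zero spread")
    return NullModel(mu=mu, sigma=sigma, alpha=float(alpha), n_scores=int(x.size))


def _csi(values: Sequence[float]) -> tuple[float, int, bool]:
    """CSI contrast: (max − mean(rest), argmax index, max unique?).

    This is the single place the composite-specific-index algebra lives.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("CSI needs at least two comparisons")
    k = int(np.argmax(v))
    rest = np.delete(v, k)
    unique = bool(np.sum(v == v[k]) == 1)
    return float(v[k] - rest.mean()), k, unique


def csi_core_periphery(
    jsd_set: Mapping[str, float], core_id: str
) -> tuple[float, bool]:
    """CSI of one periphery sample at one locus.

    ``jsd_set`` maps each counterpart sample (the core and the other
    peripheries) to its JSD with the periphery under test.  Returns the CSI
    and whether the unique maximum is the core comparison (a tie at the
    maximum yields False).

    Raises
    ------
    ParameterError
        If all JSDs are zero (the locus is consistent across samples and is
        excluded from CSI scoring).
    """
    names = list(jsd_set)
    values = [jsd_set[n] for n in names]
    if all(v == 0.0 for v in values):
        raise ParameterError("all-zero JSD set: consistent locus is excluded")
    csi, k, unique = _csi(values)
    return csi, bool(unique and names[k] == core_id)


def csi_local(mean_jsds: Mapping[str, float]) -> tuple[float, str | None]:
    """CSI over per-sample mean JSDs; assigns the epiallele to the argmax.

    Returns ``(csi, assigned_sample)``; ``assigned_sample`` is None when the
    maximum is tied (locus ineligible) and the call is skipped upstream.

    Raises
    ------
    ParameterError
        Fewer than 3 samples or an all-zero set.
    """
    if len(mean_jsds) < 3:
        raise ParameterError("local-specific CSI needs >= 3 samples")
    names = list(mean_jsds)
    values = [mean_jsds[n] for n in names]
    if all(v == 0.0 for v in values):
        raise ParameterError("all-zero JSD set: consistent locus is excluded")
    csi, k, unique = _csi(values)
    return csi, (names[k] if unique else None)


def _pairwise_jsd(
    tables: Mapping[str, PatternTable], loci: Sequence[str], epsilon: float
) -> dict[str, dict[tuple[str, str], float]]:
    """JSD for every unordered sample pair at every locus."""
    samples = sorted(tables)
    out: dict[str, dict[tuple[str, str], float]] = {}
    for locus in loci:
        d: dict[tuple[str, str], float] = {}
        for a, b in itertools.combinations(samples, 2):
            d[(a, b)] = jsd(tables[a].counts[locus], tables[b].counts[locus], epsilon)
        out[locus] = d
    return out


def _get_pair(d: Mapping[tuple[str, str], float], a: str, b: str) -> float:
    return d[(a, b)] if (a, b) in d else d[(b, a)]


@dataclass
class PpdeResult:
    records: list[ComparisonRecord]
    null: NullModel

    @property
    def delta(self) -> float:
        return self.null.threshold

    def called(self) -> list[ComparisonRecord]:
        return [r for r in self.records if r.call == "PPDE"]


def detect_ppde(
    periphery_tables: Mapping[str, PatternTable],
    alpha: float = DEFAULT_ALPHA,
    epsilon: float = DEFAULT_EPSILON,
    *,
    robust: bool = False,
) -> PpdeResult:
    """Differential epialleles between pairs of periphery samples.

    All periphery-pair JSDs at shared loci are pooled; a normal null fitted
    to that pooled distribution gives the threshold delta, and every
    pair-locus JSD strictly above delta is called a PPDE.
    """
    if len(periphery_tables) < 2:
        raise ParameterError("PPDE detection needs >= 2 periphery samples")
    loci = sorted(shared_loci(periphery_tables))
    pairjsd = _pairwise_jsd(periphery_tables, loci, epsilon)
    all_scores = [v for locus in loci for v in pairjsd[locus].values()]
    null = fit_null_threshold(all_scores, alpha, robust=robust)
    delta = null.threshold
    records = [
        ComparisonRecord(
            locus_id=locus,
            pair=pair,
            jsd=value,
            threshold=delta,
            call="PPDE" if value > delta else "none",
        )
        for locus in loci
        for pair, value in sorted(pairjsd[locus].items())
    ]
    return PpdeResult(records=records, null=null)


@dataclass
class CpdeResult:
    records: list[ComparisonRecord]
    nulls: dict[str, NullModel]  # per periphery sample (per core-periphery pair)
    gamma: float

    def called(self, periphery: str | None = None) -> list[ComparisonRecord]:
        return [
            r
            for r in self.records
            if r.call == "CPDE" and (periphery is None or r.pair[1] == periphery)
        ]

    def called_loci(self, periphery: str) -> set[str]:
        return {r.locus_id for r in self.called(periphery)}

    @property
    def union(self) -> set[str]:
        return {r.locus_id for r in self.called()}

    @property
    def intersection(self) -> set[str]:
        per_pair = [self.called_loci(p) for p in self.nulls]
        return set.intersection(*per_pair) if per_pair else set()


def detect_cpde(
    core_table: PatternTable,
    periphery_tables: Mapping[str, PatternTable],
    gamma: float = DEFAULT_GAMMA,
    alpha: float = DEFAULT_ALPHA,
    epsilon: float = DEFAULT_EPSILON,
    *,
    robust: bool = False,
) -> CpdeResult:
    """Differential epialleles between the core and each periphery sample.

    For each periphery P_i and shared locus, S_i holds the JSDs between P_i
    and every other tumor sample.  Loci whose S_i is all zero are excluded;
    the CSI values of the remaining loci for that core-periphery pair define
    the null from which Thres1 is fitted.  A locus is a CPDE for the pair iff
    JSD(core, P_i) > gamma, the unique maximum of S_i is the core comparison,
    and CSI > Thres1.
    """
    core_id = core_table.sample_id
    if core_id in periphery_tables:
        raise ParameterError("core sample also listed among peripheries")
    if len(periphery_tables) < 2:
        raise ParameterError("CPDE detection needs >= 2 periphery samples")
    tables: dict[str, PatternTable] = {core_id: core_table, **periphery_tables}
    loci = sorted(shared_loci(tables))
    pairjsd = _pairwise_jsd(tables, loci, epsilon)

    records: list[ComparisonRecord] = []
    nulls: dict[str, NullModel] = {}
    for p_i in sorted(periphery_tables):
        others = [core_id] + [p for p in sorted(periphery_tables) if p != p_i]
        candidates: list[tuple[str, dict[str, float], float, bool]] = []
        for locus in loci:
            s_i = {o: _get_pair(pairjsd[locus], p_i, o) for o in others}
            if all(v == 0.0 for v in s_i.values()):
                continue  # consistent epiallele, removed before CSI scoring
            csi, argmax_is_core = csi_core_periphery(s_i, core_id)
            candidates.append((locus, s_i, csi, argmax_is_core))
        null = fit_null_threshold([c[2] for c in candidates], alpha, robust=robust)
        nulls[p_i] = null
        thres1 = null.threshold
        for locus, s_i, csi, argmax_is_core in candidates:
            core_jsd = s_i[core_id]
            called = core_jsd > gamma and argmax_is_core and csi > thres1
            records.append(
                ComparisonRecord(
                    locus_id=locus,
                    pair=(core_id, p_i),
                    jsd=core_jsd,
                    csi=csi,
                    threshold=thres1,
                    call="CPDE" if called else "none",
                    jsd_values=dict(s_i),
                )
            )
    return CpdeResult(records=records, nulls=nulls, gamma=gamma)


@dataclass
class SpecificResult:
    records: list[ComparisonRecord]
    null: NullModel
    gamma: float

    def called(self, sample: str | None = None) -> list[ComparisonRecord]:
        return [
            r
            for r in self.records
            if r.call == "specific"
            and (sample is None or r.assigned_sample == sample)
        ]


def detect_local_specific(
    tables: Mapping[str, PatternTable],
    gamma: float = DEFAULT_GAMMA,
    alpha: float = DEFAULT_ALPHA,
    epsilon: float = DEFAULT_EPSILON,
    *,
    robust: bool = False,
) -> SpecificResult:
    """Epialleles specific to one tumor sample (core- or periphery-specific).

    For each shared locus, m_s is the mean JSD between sample s and the other
    tumor samples; the CSI contrasts the largest m against the rest and the
    argmax names the sample.  Thres2 is fitted to all eligible CSI values; a
    call requires max(m) > gamma, a unique argmax, and CSI > Thres2.
    """
    if len(tables) < 3:
        raise ParameterError("local-specific detection needs >= 3 samples")
    samples = sorted(tables)
    loci = sorted(shared_loci(tables))
    pairjsd = _pairwise_jsd(tables, loci, epsilon)

    candidates: list[tuple[str, dict[str, float], float, str | None]] = []
    for locus in loci:
        means = {
            s: float(
                np.mean([_get_pair(pairjsd[locus], s, o) for o in samples if o != s])
            )
            for s in samples
        }
        if all(v == 0.0 for v in means.values()):
            continue
        csi, assigned = csi_local(means)
        candidates.append((locus, means, csi, assigned))
    null = fit_null_threshold([c[2] for c in candidates], alpha, robust=robust)
    thres2 = null.threshold

    records = []
    for locus, means, csi, assigned in candidates:
        eligible = assigned is not None and means[assigned] > gamma
        called = eligible and csi > thres2
        records.append(
            ComparisonRecord(
                locus_id=locus,
                jsd=max(means.values()),
                csi=csi,
                threshold=thres2,
                call="specific" if called else "none",
                assigned_sample=assigned if called else "",
                jsd_values=dict(means),
            )
        )
    return SpecificResult(records=records, null=null, gamma=gamma)
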