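"""Heterogeneity summaries: epipolymorphism, drift labels, methylation, AUC.

Epipolymorphism of a locus is ``1 - sum(p_i^2)`` over the raw (no
pseudocount) pattern frequencies — the probability that two fragments drawn
at random carry different patterns.  It is 0 for a pure population and
reaches its maximum 15/16 = 0.9375 at the uniform 16-pattern mixture.

The per-sample methylation-heterogeneity AUC bins differential epialleles by
average methylation level into 21 bins — (0%, 2.5%], nineteen width-5 bins,
and (97.5%, 100%] — and sums bin width times the bin's median
epipolymorphism, giving a score in [0, 100].
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .bisulfite_io import METHYLATED, UNMETHYLATED, ReadMethProfile
from .errors import UndefinedDistributionError

__all__ = [
    "epipolymorphism",
    "classify_drift",
    "epiallele_methylation",
    "adjacent_cpg_jaccard",
    "heterogeneity_auc",
    "EPIPOLYMORPHISM_MAX",
    "AUC_BIN_WIDTHS",
]

EPIPOLYMORPHISM_MAX = 15.0 / 16.0  # 1 - 16 * (1/16)^2

#: Inner edges of the 21 methylation bins (percent); bin b holds values in
#: (edge[b-1], edge[b]], with 0% assigned to the first bin and 100% to the last.
_AUC_EDGES = np.arange(2.5, 100.0, 5.0)  # 2.5, 7.5, ..., 97.5
AUC_BIN_WIDTHS = np.array([2.5] + [5.0] * 19 + [2.5])

_BITCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=float)


def _depth(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    depth = counts.sum()
    if depth <= 0:
        raise UndefinedDistributionError("locus has zero depth")
    return depth


def epipolymorphism(counts: np.ndarray) -> float:
    """1 - sum of squared raw pattern frequencies, in [0, 15/16]."""
    counts = np.asarray(counts, dtype=float)
    depth = _depth(counts)
    p = counts / depth
    return float(1.0 - np.dot(p, p))


def classify_drift(epipoly_core: float, epipoly_periphery: float) -> str:
    """Label a differential epiallele by its direction of disorder change.

    Higher epipolymorphism in the core than the periphery marks a *drift*
    epiallele; lower marks an *adaptation* epiallele; exact equality gets its
    own *unchanged* label rather than silently joining either class.
    """
    if epipoly_core > epipoly_periphery:
        return "drift"
    if epipoly_core < epipoly_periphery:
        return "adaptation"
    return "unchanged"


def epiallele_methylation(counts: np.ndarray) -> float:
    """Average methylation of the four CpGs, weighted by pattern counts.

    ``sum_i counts_i * bitcount(i) / (4 * depth)``, in [0, 1].
    """
    counts = np.asarray(counts, dtype=float)
    depth = _depth(counts)
    return float(np.dot(counts, _BITCOUNT) / (4.0 * depth))


def adjacent_cpg_jaccard(
    profiles: Iterable[ReadMethProfile], site_a: int, site_b: int
) -> float:
    """Jaccard similarity of methylation status at two CpG sites.

    Over fragments with definite calls at both sites, J = n11 / (n11 + n10 +
    n01).  When no fragment is methylated at either site (n11 = n10 = n01 =
    0) the sites agree perfectly and J is defined as 1.

    Raises
    ------
    UndefinedDistributionError
        If no fragment covers both sites with definite calls.
    """
    n11 = n_disagree = n_covered = 0
    for prof in profiles:
        a = prof.calls.get(site_a)
        b = prof.calls.get(site_b)
        if a not in (METHYLATED, UNMETHYLATED) or b not in (METHYLATED, UNMETHYLATED):
            continue
        n_covered += 1
        if a == METHYLATED and b == METHYLATED:
            n11 += 1
        elif a != b:
            n_disagree += 1
    if n_covered == 0:
        raise UndefinedDistributionError("no fragment covers both sites")
    if n11 + n_disagree == 0:
        return 1.0
    return n11 / (n11 + n_disagree)


def heterogeneity_auc(records: Iterable[tuple[float, float]]) -> float:
    """Methylation-heterogeneity AUC of one sample's differential epialleles.

    Parameters
    ----------
    records
        Iterable of ``(methylation_percent, epipolymorphism)`` per locus;
        methylation on the 0-100 percent scale.

    Returns
    -------
    Sum over the 21 bins of bin width times the median epipolymorphism of the
    bin's records (empty bins contribute 0), in [0, 100].
    """
    per_bin: list[list[float]] = [[] for _ in range(21)]
    for meth, epipoly in records:
        if not 0.0 <= meth <= 100.0:
            raise ValueError(f"methylation percent out of range: {meth}")
        b = int(np.searchsorted(_AUC_EDGES, meth, side="left"))
        per_bin[b].append(epipoly)
    medians = np.array([np.median(v) if v else 0.0 for v in per_bin])
    return float(np.dot(AUC_BIN_WIDTHS, medians))


def drift_fractions(
    core_counts: Mapping[str, np.ndarray],
    periphery_counts: Mapping[str, np.ndarray],
    loci: Sequence[str],
) -> dict[str, float]:
    """Fractions of drift / adaptation / unchanged loci for one sample pair."""
    if not loci:
        return {"drift": 0.0, "adaptation": 0.0, "unchanged": 0.0}
    labels = [
        classify_drift(
            epipolymorphism(core_counts[l]), epipolymorphism(periphery_counts[l])
        )
        for l in loci
    ]
    n = len(labels)
    return {
        lab: labels.count(lab) / n for lab in ("drift", "adaptation", "unchanged")
    }
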