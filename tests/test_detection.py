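"""Null-threshold fitting and the PPDE / CPDE / local-specific callers."""

import numpy as np
import pytest

from epijsd import (
    csi_core_periphery,
    csi_local,
    detect_cpde,
    detect_local_specific,
    detect_ppde,
    fit_null_threshold,
    filter_coverage,
)
from epijsd.errors import DegenerateNullError, ParameterError
from epijsd.simulate import SimConfig, simulate_cohort

from conftest import counts


def scores_with_moments(mu, sigma, n=1000, seed=0):
    """Draws standardised to carry the exact requested sample moments."""
    x = np.random.default_rng(seed).normal(size=n)
    return (x - x.mean()) / x.std(ddof=1) * sigma + mu


class TestFitNullThreshold:
    def test_threshold_is_one_tailed_normal_quantile(self):
        null = fit_null_threshold(scores_with_moments(0.10, 0.05), alpha=0.05)
        assert null.mu == pytest.approx(0.10, abs=1e-12)
        assert null.sigma == pytest.approx(0.05, abs=1e-12)
        assert null.threshold == pytest.approx(0.18224, abs=1e-5)

    def test_alpha_half_gives_the_mean(self):
        null = fit_null_threshold(scores_with_moments(0.3, 0.1), alpha=0.5)
        assert null.threshold == pytest.approx(null.mu, abs=1e-12)

    def test_constant_scores_rejected(self):
        with pytest.raises(DegenerateNullError):
            fit_null_threshold(np.full(100, 0.2))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ParameterError):
            fit_null_threshold(np.arange(10.0))

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_alpha_outside_open_interval_rejected(self, alpha):
        with pytest.raises(ParameterError):
            fit_null_threshold(scores_with_moments(0.1, 0.05), alpha=alpha)

    def test_robust_fit_uses_median_and_mad(self):
        x = np.concatenate([scores_with_moments(0.1, 0.05), [50.0, 60.0]])
        plain = fit_null_threshold(x)
        robust = fit_null_threshold(x, robust=True)
        assert robust.threshold < plain.threshold  # outliers inflate the moments

    def test_exceedance_calibration_on_normal_draws(self):
        """Fraction above the fitted threshold ~= alpha within 3 binomial SEs."""
        rng = np.random.default_rng(42)
        x = rng.normal(0.3, 0.05, size=100_000)
        for alpha in (0.05, 0.01):
            null = fit_null_threshold(x, alpha=alpha)
            frac = float(np.mean(x > null.threshold))
            tol = 3 * np.sqrt(alpha * (1 - alpha) / x.size)
            assert abs(frac - alpha) < tol + 1e-3  # small non-normality slack


class TestCsi:
    def test_core_periphery_contrast(self):
        s = {"C1": 0.6, "P2": 0.10, "P3": 0.20, "P4": 0.15}
        csi, argmax_is_core = csi_core_periphery(s, "C1")
        assert csi == pytest.approx(0.6 - 0.15)
        assert argmax_is_core

    def test_argmax_on_a_periphery_marks_ineligible(self):
        s = {"C1": 0.2, "P2": 0.6, "P3": 0.1, "P4": 0.1}
        _, argmax_is_core = csi_core_periphery(s, "C1")
        assert not argmax_is_core

    def test_tied_maximum_is_not_core(self):
        s = {"C1": 0.6, "P2": 0.6, "P3": 0.1, "P4": 0.1}
        _, argmax_is_core = csi_core_periphery(s, "C1")
        assert not argmax_is_core

    def test_all_zero_set_excluded(self):
        with pytest.raises(ParameterError, match="consistent"):
            csi_core_periphery({"C1": 0.0, "P2": 0.0}, "C1")

    def test_local_assignment(self):
        m = {"C1": 0.5, "P3": 0.1, "P6": 0.1, "P9": 0.1, "P12": 0.1}
        csi, assigned = csi_local(m)
        assert csi == pytest.approx(0.4)
        assert assigned == "C1"

    def test_local_tie_gives_no_assignment(self):
        csi, assigned = csi_local({"A": 0.4, "B": 0.4, "C": 0.1})
        assert assigned is None

    def test_local_all_equal_nonzero_gives_no_assignment(self):
        _, assigned = csi_local({"A": 0.2, "B": 0.2, "C": 0.2})
        assert assigned is None


class TestDetectPpde:
    def test_null_cohort_call_rate_near_alpha(self, null_cohort_filtered):
        result = detect_ppde(
            {s: t for s, t in null_cohort_filtered.items() if s != "C1"}, alpha=0.05
        )
        frac = len(result.called()) / len(result.records)
        assert 0.01 < frac < 0.10  # normal fit of a mildly skewed score set

    def test_spiked_divergent_loci_all_called(self, null_cohort_filtered):
        tables = {
            s: t for s, t in null_cohort_filtered.items() if s in ("P1", "P2")
        }
        spiked = []
        for j in range(5):
            lid = f"spike:{10 * j + 1}-{10 * j + 4}"
            spiked.append(lid)
            tables["P1"].counts[lid] = counts(p0000=30)
            tables["P2"].counts[lid] = counts(p1111=30)
        try:
            result = detect_ppde(tables, alpha=0.05)
            called = {r.locus_id for r in result.called()}
            assert set(spiked) <= called
        finally:
            for lid in spiked:
                del tables["P1"].counts[lid], tables["P2"].counts[lid]

    def test_locus_absent_from_one_sample_not_tested(self, null_cohort_filtered):
        tables = {
            s: t for s, t in null_cohort_filtered.items() if s in ("P1", "P2")
        }
        tested = {r.locus_id for r in detect_ppde(tables).records}
        assert tested == tables["P1"].loci() & tables["P2"].loci()

    def test_needs_two_samples(self, null_cohort_filtered):
        with pytest.raises(ParameterError):
            detect_ppde({"P1": null_cohort_filtered["P1"]})


class TestDetectCpde:
    def test_power_on_default_cohort(self, default_cohort, default_cohort_filtered):
        tables = default_cohort_filtered
        result = detect_cpde(
            tables["C1"], {s: t for s, t in tables.items() if s != "C1"}
        )
        injected = default_cohort.differential_loci()
        nulls = default_cohort.null_loci()
        for periphery in result.nulls:
            called = result.called_loci(periphery)
            assert len(called & injected) >= 18  # >= 90% recovery per pair
            assert len(called & nulls) / len(nulls) <= 0.05

    def test_null_cohort_calls_at_most_alpha_level(self, null_cohort_filtered):
        tables = null_cohort_filtered
        result = detect_cpde(
            tables["C1"], {s: t for s, t in tables.items() if s != "C1"}, alpha=0.05
        )
        n_loci = len({r.locus_id for r in result.records})
        for periphery in result.nulls:
            assert len(result.called_loci(periphery)) <= 0.05 * n_loci + 3
        assert result.intersection == set()

    def test_gamma_one_yields_no_calls(self, default_cohort_filtered):
        tables = default_cohort_filtered
        result = detect_cpde(
            tables["C1"], {s: t for s, t in tables.items() if s != "C1"}, gamma=1.0
        )
        assert result.called() == []

    def test_monotone_in_gamma_and_alpha(self, default_cohort_filtered):
        tables = default_cohort_filtered
        peripheries = {s: t for s, t in tables.items() if s != "C1"}
        base = len(detect_cpde(tables["C1"], peripheries, gamma=0.3, alpha=0.05).called())
        higher_gamma = len(
            detect_cpde(tables["C1"], peripheries, gamma=0.5, alpha=0.05).called()
        )
        lower_alpha = len(
            detect_cpde(tables["C1"], peripheries, gamma=0.3, alpha=0.01).called()
        )
        assert higher_gamma <= base and lower_alpha <= base

    def test_periphery_relabeling_permutes_calls(self, default_cohort_filtered):
        tables = default_cohort_filtered
        peripheries = {s: t for s, t in tables.items() if s != "C1"}
        relabeled = {
            "Q" + name[1:]: type(t)(sample_id="Q" + name[1:], counts=t.counts)
            for name, t in peripheries.items()
        }
        a = detect_cpde(tables["C1"], peripheries)
        b = detect_cpde(tables["C1"], relabeled)
        assert a.union == b.union

    def test_deterministic_on_identical_inputs(self, default_cohort_filtered):
        tables = default_cohort_filtered
        peripheries = {s: t for s, t in tables.items() if s != "C1"}
        a = detect_cpde(tables["C1"], peripheries)
        b = detect_cpde(tables["C1"], peripheries)
        assert [(r.locus_id, r.pair, r.jsd, r.csi, r.call) for r in a.records] == [
            (r.locus_id, r.pair, r.jsd, r.csi, r.call) for r in b.records
        ]

    def test_core_listed_as_periphery_rejected(self, default_cohort_filtered):
        tables = default_cohort_filtered
        with pytest.raises(ParameterError):
            detect_cpde(tables["C1"], tables)


class TestDetectLocalSpecific:
    def test_divergent_sample_gets_the_assignment(self):
        config = SimConfig(
            n_null=300,
            n_differential=10,
            depth=30,
            seed=3,
            differential_sample="P2",
        )
        cohort = simulate_cohort(config)
        tables = filter_coverage(cohort.tables, 10)
        result = detect_local_specific(tables)
        injected = cohort.differential_loci()
        hits = {r.locus_id for r in result.called("P2")}
        assert len(hits & injected) >= 8
        wrong = [r for r in result.called() if r.locus_id in injected and r.assigned_sample != "P2"]
        assert wrong == []

    def test_null_cohort_call_rate_near_alpha(self, null_cohort_filtered):
        # the CSI null is right-skewed, so the normal fit's exceedance sits
        # near alpha rather than exactly at it
        result = detect_local_specific(null_cohort_filtered, alpha=0.05)
        frac = len(result.called()) / len(result.records)
        assert frac <= 0.10

    def test_core_divergent_loci_are_both_cpde_and_core_specific(
        self, default_cohort, default_cohort_filtered
    ):
        tables = default_cohort_filtered
        cpde = detect_cpde(tables["C1"], {s: t for s, t in tables.items() if s != "C1"})
        specific = detect_local_specific(tables)
        core_specific = {r.locus_id for r in specific.called("C1")}
        injected = default_cohort.differential_loci()
        assert injected <= cpde.intersection
        assert injected <= core_specific

    def test_needs_three_samples(self, null_cohort_filtered):
        two = {s: null_cohort_filtered[s] for s in ("C1", "P1")}
        with pytest.raises(ParameterError):
            detect_local_specific(two)
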