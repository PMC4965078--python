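"""Manifold fitting, log-log noise scaling, perturbation scoring."""

import numpy as np
import pytest

from burstnoise import (
    BurstEstimate,
    ManifoldSet,
    PerturbationConfig,
    PopulationSummary,
    TelegraphParams,
    analytic_mrna_moments,
    apply_perturbation,
    clone_params_from_burst,
    estimate_bursts,
    fit_extreme_manifolds,
    loglog_slope,
    manifold_cv2,
    perturbation_analysis,
)


def _est(clone, mean, burst_size, condition="baseline"):
    cv2 = burst_size / mean
    return BurstEstimate(
        clone_id=clone, condition=condition, mean=mean, cv2=cv2, burst_size=burst_size,
        b_geom=max(burst_size - 1, 0), burst_frequency=mean / burst_size, manifold=0,
        source="fish",
    )


def _sum(mean, cv2, clone="c", cond="baseline"):
    return PopulationSummary(
        clone_id=clone, condition=cond, n=1000, mean=mean, variance=cv2 * mean**2,
        cv2=cv2, fano=cv2 * mean,
    )


def _analytic_estimates(params_by_clone, condition="baseline"):
    """Burst estimates from closed-form moments (no sampling noise)."""
    summaries = []
    for clone, p in sorted(params_by_clone.items()):
        mean, fano = analytic_mrna_moments(p)
        summaries.append(_sum(mean, fano / mean, clone=clone, cond=condition))
    return estimate_bursts(summaries)


class TestManifoldCurves:
    def test_fish_units(self):
        assert manifold_cv2(10.0, 4.0, "fish") == pytest.approx(0.4)

    def test_mesf_units_offset(self):
        # B = 5 in MESF units: cv2 = 5000 * 6 / mean
        assert manifold_cv2(60_000.0, 5.0, "mesf") == pytest.approx(0.5)

    def test_curves_decreasing_and_ordered(self):
        mset = ManifoldSet.integer_grid(12)
        grid = np.geomspace(1, 100, 50)
        prev = None
        for b in mset.burst_levels[1:]:
            c = mset.cv2(grid, b)
            assert np.all(np.diff(c) < 0)
            if prev is not None:
                assert np.all(c > prev)
            prev = c

    def test_curve_table_layout(self):
        tab = ManifoldSet((1.0, 2.0), units="fish").curve_table([1.0, 10.0])
        assert list(tab.columns) == ["B", "mean_grid", "cv2"]
        assert len(tab) == 4


class TestExtremeManifolds:
    def test_dimmest_and_brightest(self):
        b_min, b_max = fit_extreme_manifolds([_est("a", 100, 2.0), _est("b", 10_000, 8.0)])
        assert (b_min, b_max) == (2.0, 8.0)

    def test_degenerate_identical_clones(self):
        b_min, b_max = fit_extreme_manifolds([_est("a", 50, 3.0), _est("b", 50, 3.0)])
        assert b_min == b_max == 3.0

    def test_needs_two_clones(self):
        with pytest.raises(ValueError):
            fit_extreme_manifolds([_est("a", 50, 3.0)])


class TestLogLogSlope:
    def test_exact_manifold(self):
        pops = [_sum(m, 4.0 / m) for m in (1.0, 10.0, 100.0, 1000.0)]
        slope, intercept, r = loglog_slope(pops)
        assert slope == pytest.approx(-1.0, abs=1e-12)
        assert intercept == pytest.approx(np.log(4.0), abs=1e-12)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_constant_noise_gives_zero_slope(self):
        pops = [_sum(m, 0.5) for m in (1.0, 10.0, 100.0)]
        slope, _, _ = loglog_slope(pops)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            loglog_slope([_sum(5.0, 0.5)] * 4)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            loglog_slope([_sum(1.0, 1.0), _sum(2.0, 0.5)])


class TestPerturbationAnalysis:
    def _panel(self):
        return {f"c{i}": clone_params_from_burst(b, f)
                for i, (b, f) in enumerate([(2, 0.1), (4, 0.5), (8, 1.2), (11, 1.8)])}

    def test_identity_perturbation(self):
        base = self._panel()
        before = _analytic_estimates(base)
        after = _analytic_estimates(base, condition="perturbed")
        r = perturbation_analysis(before, after)
        assert r.contraction_fraction == 0.0
        assert set(r.modulation_class.values()) == {"frequency"}
        assert r.containment_fraction == 1.0

    def test_frequency_perturbation_contracts_noise(self):
        """k_on-only activation: every clone's mean rises and CV^2 falls,
        burst size stays put -> all classed frequency-modulated."""
        base = self._panel()
        pert = apply_perturbation(
            base, PerturbationConfig(freq_fold_change=5.0, size_threshold_mean=float("inf"))
        )
        before = _analytic_estimates(base)
        after = _analytic_estimates(pert, condition="perturbed")
        r = perturbation_analysis(before, after)
        assert r.contraction_fraction == 1.0
        assert r.containment_fraction == 1.0
        assert set(r.modulation_class.values()) == {"frequency"}
        assert r.n_above_exclusion == 0 and r.n_below_exclusion == 0

    def test_size_perturbation_classified(self):
        base = self._panel()
        bright_mean, _ = analytic_mrna_moments(base["c3"])
        pert = apply_perturbation(
            base,
            PerturbationConfig(
                freq_fold_change=5.0, size_threshold_mean=bright_mean - 0.1, size_fold_change=2.0
            ),
        )
        r = perturbation_analysis(
            _analytic_estimates(base), _analytic_estimates(pert, condition="perturbed")
        )
        assert r.modulation_class["c3"] == "size"
        assert all(r.modulation_class[c] == "frequency" for c in ("c0", "c1", "c2"))

    def test_containment_is_one_on_fitting_data(self):
        """The extreme manifolds pass through the dimmest/brightest clones,
        so the baseline panel they were fitted to is fully contained."""
        before = _analytic_estimates(self._panel())
        r = perturbation_analysis(before, before)
        assert r.containment_fraction == 1.0

    def test_unmatched_clones_listed(self):
        before = _analytic_estimates(self._panel())
        with pytest.raises(ValueError, match="c3"):
            perturbation_analysis(before, before[:-1])

    def test_result_serializes(self):
        import json

        before = _analytic_estimates(self._panel())
        r = perturbation_analysis(before, before)
        blob = json.dumps(r.to_dict())
        assert "containment_fraction" in blob
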