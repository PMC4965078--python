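"""Clone-panel generator: determinism, ground truth, perturbation model."""

import logging

import numpy as np
import pandas as pd
import pytest

from burstnoise import (
    ClonePanelConfig,
    PerturbationConfig,
    TelegraphParams,
    analytic_mrna_moments,
    apply_perturbation,
    clone_params_from_burst,
    generate_clone_panel,
    generate_perturbation_experiment,
    summarize_table,
)


class TestPanelGeneration:
    def test_same_seed_identical_tables(self, small_panel_cfg):
        c1, f1, t1 = generate_clone_panel(small_panel_cfg)
        c2, f2, t2 = generate_clone_panel(small_panel_cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(f1, f2)
        assert t1 == t2

    def test_schema_and_sizes(self, small_panel_cfg):
        counts, flow, truth = generate_clone_panel(small_panel_cfg)
        assert list(counts.columns) == ["clone_id", "condition", "cell_id", "mrna_count"]
        assert list(flow.columns) == ["clone_id", "condition", "event_id", "fsc", "ssc", "mesf"]
        assert len(truth) == small_panel_cfg.n_clones
        assert len(counts) == small_panel_cfg.n_clones * small_panel_cfg.n_cells_fish
        assert len(flow) == small_panel_cfg.n_clones * small_panel_cfg.n_events_flow

    def test_burst_params_within_configured_ranges(self, small_panel_cfg):
        _, _, truth = generate_clone_panel(small_panel_cfg)
        lo_b, hi_b = small_panel_cfg.burst_size_range
        lo_f, hi_f = small_panel_cfg.burst_freq_range
        for t in truth.values():
            assert lo_b <= t["burst_size"] <= hi_b
            assert lo_f <= t["burst_frequency"] <= hi_f

    def test_mesf_scale_only_rescales_fluorescence(self, small_panel_cfg):
        """With the same seed, doubling mesf_per_protein exactly doubles the
        fluorescence channel: flow noise is the scaled protein noise."""
        import dataclasses

        cfg0 = dataclasses.replace(
            small_panel_cfg, extrinsic_cv=0.0, autofluorescence_mean=0.0, autofluorescence_sd=0.0
        )
        cfg2 = dataclasses.replace(cfg0, mesf_per_protein=2.0)
        _, f1, _ = generate_clone_panel(cfg0)
        _, f2, _ = generate_clone_panel(cfg2)
        np.testing.assert_allclose(f2["mesf"], 2.0 * f1["mesf"], rtol=1e-12)

    def test_fish_counts_recover_analytic_fano(self):
        cfg = ClonePanelConfig(n_clones=3, n_cells_fish=20_000, n_events_flow=2, seed=3)
        counts, _, truth = generate_clone_panel(cfg)
        for s in summarize_table(counts, "mrna_count"):
            assert s.fano == pytest.approx(truth[s.clone_id]["fano_mrna"], rel=0.08)

    def test_ssa_sampler_agrees_with_exact(self):
        import dataclasses

        cfg = ClonePanelConfig(n_clones=2, n_cells_fish=4000, n_events_flow=2, seed=9)
        c_exact, _, truth = generate_clone_panel(cfg)
        c_ssa, _, _ = generate_clone_panel(dataclasses.replace(cfg, mrna_sampler="ssa"))
        for s_e, s_s in zip(
            summarize_table(c_exact, "mrna_count"), summarize_table(c_ssa, "mrna_count")
        ):
            assert s_s.mean == pytest.approx(s_e.mean, rel=0.1)
            assert s_s.fano == pytest.approx(s_e.fano, rel=0.15)

    def test_marginal_bursting_regime_logged(self, caplog):
        with caplog.at_level(logging.WARNING, logger="burstnoise.synthetic"):
            clone_params_from_burst(2.0, 2.0)
        assert any("bursting regime" in r.message for r in caplog.records)


class TestPerturbation:
    def _base(self):
        return {
            "dim": clone_params_from_burst(2.0, 0.1),
            "bright": clone_params_from_burst(8.0, 1.5),
        }

    def test_identity_folds_leave_params_unchanged(self):
        base = self._base()
        pcfg = PerturbationConfig(freq_fold_change=1.0, size_fold_change=1.0)
        assert apply_perturbation(base, pcfg) == base

    def test_below_threshold_preserves_burst_size(self):
        base = self._base()
        pcfg = PerturbationConfig(freq_fold_change=5.0, size_threshold_mean=float("inf"))
        pert = apply_perturbation(base, pcfg)
        for clone in base:
            assert pert[clone].burst_size == pytest.approx(base[clone].burst_size)
            m0, _ = analytic_mrna_moments(base[clone])
            m1, _ = analytic_mrna_moments(pert[clone])
            assert m1 > m0

    def test_above_threshold_doubles_burst_size(self):
        base = self._base()
        m_bright, _ = analytic_mrna_moments(base["bright"])
        pcfg = PerturbationConfig(
            freq_fold_change=5.0, size_threshold_mean=m_bright - 1, size_fold_change=2.0
        )
        pert = apply_perturbation(base, pcfg)
        assert pert["bright"].burst_size == pytest.approx(2 * base["bright"].burst_size)
        assert pert["dim"].burst_size == pytest.approx(base["dim"].burst_size)

    def test_mean_strictly_increases_for_every_clone(self):
        cfg = ClonePanelConfig(n_clones=10, n_cells_fish=2, n_events_flow=2, seed=1)
        _, _, truth = generate_clone_panel(cfg)
        base = {c: TelegraphParams.from_dict(t["params"]) for c, t in truth.items()}
        pert = apply_perturbation(base, PerturbationConfig(freq_fold_change=5.0))
        for c in base:
            assert analytic_mrna_moments(pert[c])[0] > analytic_mrna_moments(base[c])[0]

    def test_experiment_tables_are_matched(self, small_panel_cfg):
        counts, flow, truth = generate_perturbation_experiment(
            small_panel_cfg, PerturbationConfig()
        )
        assert set(counts.condition) == {"baseline", "perturbed"}
        per = counts.groupby(["clone_id", "condition"]).size()
        assert (per == small_panel_cfg.n_cells_fish).all()
        for c, t in truth.items():
            assert t["perturbed"]["mean_mrna"] > t["baseline"]["mean_mrna"]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PerturbationConfig(freq_fold_change=0.0)
        with pytest.raises(ValueError):
            ClonePanelConfig(n_clones=0)
        with pytest.raises(ValueError):
            ClonePanelConfig(burst_size_range=(0.0, 5.0))
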