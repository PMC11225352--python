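import dataclasses

import numpy as np
import pytest

from silkstudy.cohort import InfusionSpec, simulate_leucine_enrichment
from silkstudy.compartment import KineticParameters, simulate
from silkstudy.data_model import (ConcentrationSeries, SampleSchedule,
                                  SilkSeries)
from silkstudy.gridfit import (FitRecord, GridConfig, InsufficientDataError,
                               OptimizerSettings, fit_one_combo,
                               fit_subject_grid, prepare_fit_data,
                               select_and_average)

LEAN = OptimizerSettings(maxiter=300, n_restarts=1, xatol=1e-3)


def _noise_free_case(schedule, enrichment, **true_overrides):
    true = dict(age=70, r_app=1.2, f_vcsf=1.0, v_sp=80.0, q_leak=0.0,
                k_bpd40=0.09, sf40=1.0, q_csf=20.0, q_osc=30.0)
    true.update(true_overrides)
    p = KineticParameters.default(**true)
    out = simulate(p, enrichment, schedule)
    silk = SilkSeries("X", "Ab40", schedule.times,
                      out.labeled_fraction_lumbar,
                      np.zeros(len(schedule.times), bool))
    clock = (600 + 60 * schedule.times) % 1440
    conc = ConcentrationSeries("X", "Ab40", "CSF", schedule.times,
                               out.measured_lumbar_pg,
                               np.zeros(len(schedule.times), bool), clock)
    return true, silk, conc


class TestGridConfig:
    def test_default_grid_has_128_combinations(self):
        cfg = GridConfig()
        assert cfg.n_combinations == 128
        assert len(list(cfg.grid_points())) == 128

    def test_reduced_grid_has_8(self):
        assert GridConfig.test_preset().n_combinations == 8

    def test_grid_order_is_lexicographic(self):
        pts = list(GridConfig.test_preset().grid_points())
        assert pts == sorted(pts)


class TestPrepareFitData:
    def test_clock_filter_excludes_pre_eleven_samples(self, schedule,
                                                      enrichment):
        """Experiment starting 09:00: t = 0 and 1 h fall before 11:00 and
        are excluded; the 2 h draw (11:00) is retained."""
        _, silk, conc = _noise_free_case(schedule, enrichment)
        conc.clock_minutes = (540 + 60 * conc.times) % 1440
        data = prepare_fit_data(silk, conc, enrichment, schedule,
                                GridConfig(), 70)
        kept_times = schedule.times[data.conc_idx]
        assert kept_times.min() == 2.0      # 09:00 start: t=0, 1 h excluded
        assert kept_times.max() == 14.0     # 15-h window on the 2-h grid

    def test_start_at_eleven_applies_only_window(self, schedule, enrichment):
        _, silk, conc = _noise_free_case(schedule, enrichment)
        conc.clock_minutes = (660 + 60 * conc.times) % 1440
        data = prepare_fit_data(silk, conc, enrichment, schedule,
                                GridConfig(), 70)
        kept = schedule.times[data.conc_idx]
        assert kept.min() == 0.0 and kept.max() == 14.0
        assert len(kept) == 8

    def test_retained_count_matches_enumeration(self, schedule, enrichment):
        """Start 10:00: retained = samples with t >= 1 h (clock >= 11:00)
        and t <= 15 h, minus missing draws."""
        _, silk, conc = _noise_free_case(schedule, enrichment)
        conc.clock_minutes = (600 + 60 * conc.times) % 1440
        conc.missing_mask[2] = True
        data = prepare_fit_data(silk, conc, enrichment, schedule,
                                GridConfig(), 70)
        expect = sum(1 for i, t in enumerate(schedule.times)
                     if 1 <= t <= 15 and not conc.missing_mask[i])
        assert len(data.conc_idx) == expect

    def test_too_few_silk_points_is_error(self, schedule, enrichment):
        _, silk, conc = _noise_free_case(schedule, enrichment)
        silk.missing_mask[:] = True
        silk.missing_mask[:5] = False
        with pytest.raises(InsufficientDataError):
            prepare_fit_data(silk, conc, enrichment, schedule,
                             GridConfig(), 70)


class TestFitOneCombo:
    def test_noise_free_on_grid_self_consistency(self, schedule, enrichment):
        """Data generated on a grid point are recovered by that combo's fit:
        near-zero relative residuals and production within 2%."""
        true, silk, conc = _noise_free_case(schedule, enrichment)
        gc = GridConfig.test_preset()
        data = prepare_fit_data(silk, conc, enrichment, schedule, gc, 70)
        rec = fit_one_combo(data, (1.0, 80.0, 0.0, 0), gc,
                            OptimizerSettings(maxiter=800))
        assert rec.r_app == pytest.approx(true["r_app"], rel=0.02)
        rel_silk = rec.ssr_silk / len(data.silk_values)
        rel_conc = rec.ssr_conc / max(len(data.conc_values), 1)
        assert rel_silk < 1e-6 and rel_conc < 1e-6

    def test_objective_trace_is_monotone_nonincreasing(self, schedule,
                                                       enrichment):
        true, silk, conc = _noise_free_case(schedule, enrichment)
        gc = GridConfig.test_preset()
        data = prepare_fit_data(silk, conc, enrichment, schedule, gc, 70)
        trace = []
        fit_one_combo(data, (1.0, 80.0, 0.0, 0), gc,
                      OptimizerSettings(maxiter=120, n_restarts=0),
                      trace=trace)
        assert len(trace) > 5
        assert np.all(np.diff(trace) <= 1e-12)

    def test_deterministic_records(self, schedule, enrichment):
        true, silk, conc = _noise_free_case(schedule, enrichment)
        gc = GridConfig.test_preset()
        data = prepare_fit_data(silk, conc, enrichment, schedule, gc, 70)
        r1 = fit_one_combo(data, (0.75, 40.0, 0.0, 0), gc, LEAN)
        r2 = fit_one_combo(data, (0.75, 40.0, 0.0, 0), gc, LEAN)
        assert r1 == r2

    def test_penalized_mixing_collapse_not_kept(self, schedule, enrichment):
        """Optimizations started in a Q_osc -> 0 regime do not return kept
        fits implying ISF:lumbar ratios above the cap."""
        true, silk, conc = _noise_free_case(schedule, enrichment)
        gc = GridConfig.test_preset()
        data = prepare_fit_data(silk, conc, enrichment, schedule, gc, 70)
        settings = OptimizerSettings(maxiter=300, n_restarts=1, xatol=1e-3,
                                     q_osc_start=1e-3)
        records = [fit_one_combo(data, gp, gc, settings)
                   for gp in gc.grid_points()]
        summary = select_and_average(records, gc, "X")
        kept = {r.grid_point: r for r in records}
        for gp in summary.kept_grid_points:
            assert kept[gp].isf_lumbar_ratio <= gc.penalty_ratio_cap + 1e-6


class TestGridExecution:
    def test_reduced_grid_yields_eight_records_in_order(self, schedule,
                                                        enrichment):
        true, silk, conc = _noise_free_case(schedule, enrichment)
        gc = GridConfig.test_preset()
        data = prepare_fit_data(silk, conc, enrichment, schedule, gc, 70)
        records = fit_subject_grid(
            data, gc, OptimizerSettings(maxiter=30, n_restarts=0))
        assert len(records) == 8
        assert [r.grid_point for r in records] == list(gc.grid_points())
        for r in records:
            lo, hi = gc.k_bpd40_ranges[r.k_range_index]
            assert lo <= r.k_bpd40 <= hi


class TestSelectAndAverage:
    @staticmethod
    def _rec(ssr_s, ssr_c, r_app, converged=True):
        return FitRecord(1.0, 40.0, 0.0, 0, 0.1, 1.0, 20.0, 30.0, r_app,
                         ssr_s, ssr_c, 0.0, ssr_s + ssr_c, 2.0, converged, 10)

    def test_identical_records_all_kept(self):
        recs = [self._rec(1.0, 1.0, 2.0) for _ in range(4)]
        s = select_and_average(recs, GridConfig(), "s")
        assert s.n_kept == 4 and s.r_app == 2.0

    def test_twenty_percent_band_keeps_first_two(self):
        recs = [self._rec(1.0, 1.0, 1.0), self._rec(1.1, 1.1, 2.0),
                self._rec(1.3, 1.3, 3.0)]
        s = select_and_average(recs, GridConfig(), "s")
        assert s.n_kept == 2
        assert s.r_app == pytest.approx(1.5)

    def test_disjoint_bands_fall_back_to_best_objective(self):
        recs = [self._rec(1.0, 5.0, 1.0), self._rec(5.0, 1.0, 3.0)]
        s = select_and_average(recs, GridConfig(), "s")
        assert s.fallback_used and s.n_kept == 1

    def test_average_lies_within_kept_range(self):
        recs = [self._rec(1.0, 1.0, 1.0), self._rec(1.05, 1.05, 2.0),
                self._rec(1.15, 1.0, 4.0)]
        s = select_and_average(recs, GridConfig(), "s")
        kept_r = [1.0, 2.0, 4.0][:s.n_kept]
        assert min(kept_r) <= s.r_app <= max(kept_r)
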