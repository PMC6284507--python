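"""QC, rank clustering, heatmap ordering, regressions, FMR ratio, summaries."""

import numpy as np
import pytest

from recruitkit.population import (
    cluster_by_final_fmr,
    cross_correlation_scatter,
    fit_linear,
    fmr_ratio,
    heatmap_order,
    intensity_kinetics_scatter,
    mean_sem_curves,
    nuclear_size_scatter,
    qc_filter,
    t50_scatter,
)

from conftest import make_record


def step_series(meta, final_fmr, T=40, peak_frame=20):
    """Corrected series rising to a shared peak of 2.0 and decaying so the
    final FMR equals ``final_fmr`` exactly."""
    s = np.ones(T)
    rise = peak_frame - meta.damage_frame
    s[meta.damage_frame : peak_frame] = 1.0 + np.linspace(1.0 / rise, 1.0, rise)
    s[peak_frame:] = np.linspace(2.0, 1.0 + final_fmr, T - peak_frame)
    return s


class TestQCFilter:
    @pytest.mark.parametrize(
        "green,red,passes,reason",
        [
            (150.0, 300.0, True, ""),
            (250.0, 300.0, False, "green i0 out of range"),
            (190.0, 180.0, False, "red i0 out of range; red i0 <= green i0"),
            (150.0, 500.0, False, "red i0 out of range"),
            (140.0, 200.0, True, ""),  # boundaries are inclusive
        ],
    )
    def test_intensity_range_rules(self, meta, green, red, passes, reason):
        cell = make_record("c", meta, i0_raw_green=green, i0_raw_red=red)
        passing, failing = qc_filter([cell])
        assert (len(passing) == 1) is passes
        assert cell.qc_reason == reason

    def test_red_above_green_flag_can_be_disabled(self, meta):
        cell = make_record("c", meta, i0_raw_green=199.0, i0_raw_red=250.0)
        cell2 = make_record("d", meta, i0_raw_green=180.0, i0_raw_red=210.0)
        passing, _ = qc_filter(
            [cell, cell2], green_range=(0, 1e9), red_range=(0, 260),
            require_red_gt_green=False,
        )
        assert len(passing) == 2


class TestClustering:
    def test_rank_quartiles_of_eight_cells(self, meta):
        cells = [
            make_record(f"c{i}", meta, green_corrected=step_series(meta, f))
            for i, f in enumerate([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        ]
        clusters = cluster_by_final_fmr(cells, "green", k=4)
        assert [len(c.cell_ids) for c in clusters] == [2, 2, 2, 2]
        assert clusters[0].cell_ids == ["c7", "c6"]  # strongest final FMR first

    def test_remainder_goes_to_leading_clusters(self, meta):
        cells = [
            make_record(f"c{i}", meta, green_corrected=step_series(meta, 0.1 * (i + 1)))
            for i in range(10)
        ]
        clusters = cluster_by_final_fmr(cells, "green", k=4)
        assert [len(c.cell_ids) for c in clusters] == [3, 3, 2, 2]

    def test_ranges_partition_without_overlap(self, meta):
        rng = np.random.default_rng(0)
        cells = [
            make_record(f"c{i:02d}", meta, green_corrected=step_series(meta, f))
            for i, f in enumerate(rng.uniform(0.1, 2.0, 17))
        ]
        clusters = cluster_by_final_fmr(cells, "green", k=4)
        assert sum(len(c.cell_ids) for c in clusters) == 17
        assert max(len(c.cell_ids) for c in clusters) - min(
            len(c.cell_ids) for c in clusters
        ) <= 1
        for upper, lower in zip(clusters, clusters[1:]):
            assert upper.fmr_range[0] >= lower.fmr_range[1]

    def test_too_few_cells_rejected(self, meta):
        cells = [make_record("a", meta), make_record("b", meta)]
        with pytest.raises(ValueError, match="at least"):
            cluster_by_final_fmr(cells, "green", k=4)


class TestHeatmapOrder:
    def _cells_with_constant_fmr(self, meta, levels):
        # rfi whose post-damage plateau height orders the FMR window means
        cells = []
        for i, level in enumerate(levels):
            s = np.ones(40)
            s[meta.damage_frame :] = 1.0 + level
            s[-1] = 2.5  # shared maximum so FMR scale matches
            cells.append(make_record(f"c{i}", meta, green_corrected=s))
        return cells

    def test_descending_window_mean(self, meta):
        cells = self._cells_with_constant_fmr(meta, [0.5, 1.4, 0.1])
        order = heatmap_order(cells, "green", window=(12, 30))
        assert order == [1, 0, 2]

    def test_window_clamped_with_warning(self, meta):
        cells = self._cells_with_constant_fmr(meta, [0.5, 1.4, 0.1])
        with pytest.warns(UserWarning, match="clamped"):
            order = heatmap_order(cells, "green", window=(15, 150))
        assert order == [1, 0, 2]

    def test_equal_means_keep_cell_id_order(self, meta):
        cells = self._cells_with_constant_fmr(meta, [0.7, 0.7, 0.7])
        with pytest.warns(UserWarning, match="clamped"):
            assert heatmap_order(cells, "green") == [0, 1, 2]


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r2 = fit_linear(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_y_defined_as_zero_r2(self):
        slope, intercept, r2 = fit_linear([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert (slope, intercept, r2) == (0.0, 5.0, 0.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 3, 50)
        y = rng.normal(0, 5, 50)
        slope, intercept, r2 = fit_linear(x, y)
        # closed-form normal equations, assembled independently
        A = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        resid = y - A @ beta
        r2_oracle = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(beta[0], abs=1e-10)
        assert intercept == pytest.approx(beta[1], abs=1e-10)
        assert r2 == pytest.approx(r2_oracle, abs=1e-10)


class TestScatters:
    def _cohort(self, meta, n=50, seed=6, planted=None):
        rng = np.random.default_rng(seed)
        cells = []
        for i in range(n):
            i0 = rng.uniform(140, 200)
            t50 = 0.05 * i0 if planted == "linear" else rng.uniform(2, 60)
            cells.append(
                make_record(
                    f"c{i:02d}",
                    meta,
                    i0_raw_green=i0,
                    nucleus_area_px=int(rng.uniform(2000, 5000)),
                    green_scalars={"t50": t50},
                )
            )
        return cells

    def test_planted_linear_relation_gives_r2_one(self, meta):
        (slope, _, r2), table, excluded = intensity_kinetics_scatter(
            self._cohort(meta, planted="linear"), "green"
        )
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(0.05)
        assert excluded == 0
        assert len(table) == 50

    def test_independent_kinetics_give_low_r2(self, meta):
        (_, _, r2), _, _ = intensity_kinetics_scatter(self._cohort(meta), "green")
        assert r2 < 0.2

    def test_undefined_t50_cells_are_excluded_and_counted(self, meta):
        cells = self._cohort(meta, n=5)
        cells[0].green_curve.t50 = None
        _, table, excluded = intensity_kinetics_scatter(cells, "green")
        assert excluded == 1
        assert len(table) == 4

    def test_fewer_than_three_points_rejected(self, meta):
        with pytest.raises(ValueError, match="fewer than 3"):
            intensity_kinetics_scatter(self._cohort(meta, n=2), "green")

    def test_cross_correlation_null_and_mismatch(self, meta):
        cells = self._cohort(meta)
        for cell in cells:
            cell.red_curve.t50 = float(np.random.default_rng(7).uniform(2, 60))
        (_, _, r2), _, _ = cross_correlation_scatter(cells, "green", "red")
        assert r2 < 0.2
        with pytest.raises(ValueError, match="mismatch"):
            cross_correlation_scatter(cells, cells_y=cells[::-1])

    def test_nuclear_size_null(self, meta):
        (_, _, r2), table, _ = nuclear_size_scatter(self._cohort(meta), "green")
        assert r2 < 0.2
        assert {"cell_id", "x", "y"} <= set(table.columns)


class TestFmrRatio:
    def test_ratio_by_formula(self):
        from recruitkit.core import AcquisitionMeta

        meta = AcquisitionMeta(0.5, 0.11, damage_frame=1)
        green = np.array([1.0, 1.0, 1.5, 2.0])  # FMR 0, 0, 0.5, 1
        red = np.array([1.0, 1.0, 1.25, 2.0])  # FMR 0, 0, 0.25, 1
        cell = make_record("c", meta, green_corrected=green, red_corrected=red)
        ratios, mean, _, n = fmr_ratio([cell], start=1, delta=0.05)
        assert ratios[0, 2] == pytest.approx(0.5)
        assert mean[3] == pytest.approx(1.0)
        assert n[1] == 0  # frames up to the damage frame stay masked

    def test_channel_against_itself_is_exactly_one(self, meta):
        rng = np.random.default_rng(8)
        s = np.ones(40)
        s[meta.damage_frame :] = 1.0 + np.abs(np.cumsum(rng.normal(0.05, 0.02, 30)))
        cell = make_record("c", meta, green_corrected=s, red_corrected=s)
        _, mean, _, n = fmr_ratio([cell], numerator="green", denominator="green")
        np.testing.assert_array_equal(mean[n > 0], 1.0)

    def test_denominator_below_threshold_everywhere_rejected(self, meta):
        flat = np.ones(40)
        flat[meta.damage_frame :] = 1.001  # tiny recruitment, FMR max at argmax=1
        spike = np.ones(40)
        spike[-1] = 2.0
        cell = make_record("c", meta, green_corrected=spike, red_corrected=spike)
        # mask everything via a start beyond the series
        with pytest.raises(ValueError):
            fmr_ratio([cell], start=45)


class TestSummaries:
    def test_identical_curves_have_zero_sem(self, meta):
        cells = [make_record(f"c{i}", meta) for i in range(3)]
        _, sem, n = mean_sem_curves(cells, "green", "rfi")
        np.testing.assert_array_equal(sem, 0.0)
        assert (n == 3).all()

    def test_two_values_zero_and_two(self, meta):
        a = np.ones(40)
        b = np.ones(40)
        a[-1], b[-1] = 0.0, 2.0
        cells = [
            make_record("a", meta, green_corrected=1 + (a - 1)),
            make_record("b", meta, green_corrected=1 + (b - 1)),
        ]
        mean, sem, _ = mean_sem_curves(cells, "green", "rfi")
        assert mean[-1] == pytest.approx(1.0)
        assert sem[-1] == pytest.approx(1.0)  # sd sqrt(2), n=2

    def test_matches_direct_formula_oracle(self, meta):
        rng = np.random.default_rng(9)
        data = rng.uniform(0.8, 2.0, (50, 40))
        data[:, : meta.damage_frame] = 1.0
        cells = [
            make_record(f"c{i:02d}", meta, green_corrected=row) for i, row in enumerate(data)
        ]
        mean, sem, _ = mean_sem_curves(cells, "green", "rfi")
        stacked = np.vstack([c.green_curve.rfi for c in cells])
        np.testing.assert_allclose(mean, stacked.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            sem, stacked.std(axis=0, ddof=1) / np.sqrt(50), atol=1e-12
        )


class TestT50Scatter:
    def test_pairs_and_exclusions(self, meta):
        a = make_record("a", meta, green_scalars={"t50": 3.0}, red_scalars={"t50": 4.0})
        b = make_record("b", meta, green_scalars={"t50": None})
        b.green_curve.t50 = None
        table, excluded = t50_scatter([a, b])
        assert len(table) == 1
        assert excluded == 1
        assert table.loc[0, "t50_green"] == 3.0

    def test_empty_input_gives_empty_table(self):
        table, excluded = t50_scatter([])
        assert table.empty
        assert excluded == 0
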