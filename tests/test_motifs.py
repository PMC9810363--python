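"""Edge metric series, motif correlations, state contrasts, and surrogates."""
from __future__ import annotations

import numpy as np
import pytest

from edgeflow import (
    BAND_TABLE,
    ContrastResult,
    DirectedCoupling,
    EpochNetworkMetrics,
    Recording,
    SimulationConfig,
    ValidationError,
    build_edge_series,
    count_changed_edges,
    dpte_dpte_correlation,
    dpte_plv_correlation,
    generate_recording,
    node_disjoint_mask,
    pool_edge_series,
    shuffle_surrogate_null,
    state_contrast,
)


def synthetic_metrics(n_regions=6, n_epochs=60, states=("RS",), seed=0, shift=None):
    """Epoch metrics with random antisymmetric dPTE and symmetric PLV matrices.

    ``shift`` optionally maps state -> additive dPTE offset (applied to the
    upper triangle, mirrored antisymmetrically).
    """
    rng = np.random.default_rng(seed)
    regions = [f"R{i}" for i in range(n_regions)]
    out = []
    per_state = {s: 0 for s in states}
    for k in range(n_epochs):
        state = states[k % len(states)]
        upper = rng.normal(0.0, 0.05, size=(n_regions, n_regions))
        if shift:
            upper = upper + shift.get(state, 0.0)
        dpte = np.triu(upper, 1)
        dpte = dpte - dpte.T
        plv = np.abs(rng.uniform(0.2, 0.9, size=(n_regions, n_regions)))
        plv = (plv + plv.T) / 2
        np.fill_diagonal(plv, 1.0)
        out.append(
            EpochNetworkMetrics(
                regions=regions,
                plv_matrix=plv,
                dpte_matrix=dpte,
                epoch_index=per_state[state],
                state=state,
            )
        )
        per_state[state] += 1
    return out


class TestBuildEdgeSeries:
    def test_six_regions_sixty_epochs_shapes(self):
        series = build_edge_series(synthetic_metrics())
        assert series.dpte.shape == (60, 30)
        assert series.plv.shape == (60, 15)
        assert len(series.directed_edges) == 30
        assert len(series.undirected_edges) == 15

    def test_single_epoch(self):
        series = build_edge_series(synthetic_metrics(n_epochs=1))
        assert series.dpte.shape == (1, 30)

    def test_reverse_columns_negate_exactly(self):
        series = build_edge_series(synthetic_metrics())
        for (a, b) in series.directed_edges:
            i = series.directed_edges.index((a, b))
            j = series.directed_edges.index((b, a))
            np.testing.assert_array_equal(series.dpte[:, i], -series.dpte[:, j])

    def test_inconsistent_region_sets_rejected(self):
        bad = synthetic_metrics(n_epochs=2)
        bad[1].regions = ["X"] * 6
        with pytest.raises(ValidationError):
            build_edge_series(bad)


class TestMotifCorrelation:
    def test_self_correlation_is_unity(self):
        series = build_edge_series(synthetic_metrics())
        corr = dpte_dpte_correlation(series, "RS")
        np.testing.assert_array_equal(np.diag(corr.r), 1.0)
        np.testing.assert_array_equal(np.diag(corr.p), 0.0)

    def test_reverse_edge_correlates_minus_one_exactly(self):
        series = build_edge_series(synthetic_metrics())
        corr = dpte_dpte_correlation(series, "RS")
        for (a, b) in series.directed_edges[:6]:
            i = series.directed_edges.index((a, b))
            j = series.directed_edges.index((b, a))
            assert corr.r[i, j] == -1.0

    def test_cross_correlation_shape(self):
        series = build_edge_series(synthetic_metrics())
        corr = dpte_plv_correlation(series, "RS")
        assert corr.r.shape == (30, 15)
        assert corr.p.shape == (30, 15)

    def test_duplicated_column_correlates_perfectly(self):
        series = build_edge_series(synthetic_metrics())
        series.plv[:, 0] = series.dpte[:, 3]
        corr = dpte_plv_correlation(series, "RS")
        assert corr.r[3, 0] == pytest.approx(1.0, abs=1e-12)

    def test_too_few_epochs_rejected(self):
        series = build_edge_series(synthetic_metrics(n_epochs=2))
        with pytest.raises(ValidationError):
            dpte_dpte_correlation(series, "RS")

    def test_zero_variance_column_reported_missing_with_warning(self):
        series = build_edge_series(synthetic_metrics())
        # zero both orientations of one pair to keep antisymmetry consistent
        i = series.directed_edges.index(("R0", "R1"))
        j = series.directed_edges.index(("R1", "R0"))
        series.dpte[:, i] = series.dpte[:, j] = 0.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            corr = dpte_dpte_correlation(series, "RS")
        assert np.isnan(corr.r[i, 7])
        assert np.isnan(corr.p[i, 7])

    def test_thresholded_view_is_not_destructive(self):
        series = build_edge_series(synthetic_metrics())
        corr = dpte_dpte_correlation(series, "RS")
        view = corr.thresholded(1e-10)
        assert np.isfinite(corr.r).all()
        assert np.isnan(view).any()

    def test_node_disjoint_mask(self):
        edges = [("A", "B"), ("B", "C"), ("C", "D")]
        mask = node_disjoint_mask(edges, edges)
        expected = np.array(
            [[False, False, True], [False, False, False], [True, False, False]]
        )
        np.testing.assert_array_equal(mask, expected)


class TestPooling:
    def test_pooled_epochs_and_per_subject_means(self):
        a = build_edge_series(synthetic_metrics(n_epochs=20, states=("RS",), seed=1))
        b = build_edge_series(synthetic_metrics(n_epochs=30, states=("RS",), seed=2))
        pooled, per_subject = pool_edge_series([a, b], subjects=["rat1", "rat2"])
        assert pooled.dpte.shape == (50, 30)
        assert set(per_subject.subject) == {"rat1", "rat2"}
        rat1 = per_subject[(per_subject.subject == "rat1")]
        edge = rat1.iloc[0]
        c = a.directed_edges.index((edge.source, edge.target))
        assert edge.mean_dpte == pytest.approx(a.dpte[:, c].mean())

    def test_inconsistent_regions_rejected(self):
        a = build_edge_series(synthetic_metrics(n_regions=4, n_epochs=3))
        b = build_edge_series(synthetic_metrics(n_regions=5, n_epochs=3))
        with pytest.raises(ValidationError):
            pool_edge_series([a, b])


class TestStateContrast:
    def test_recovers_designed_shift(self):
        metrics = synthetic_metrics(
            n_epochs=480, states=("EPM", "RS"), shift={"EPM": 0.03}, seed=1
        )
        series = build_edge_series(metrics)
        contrast = state_contrast(series, "EPM", "RS", metric="dpte")
        # upper-triangle columns shifted by +0.03, mirrored columns by -0.03
        assert np.max(np.abs(np.abs(contrast.mean_diff) - 0.03)) < 0.01
        assert (contrast.pvalue < 1e-3).all()
        assert contrast.n_a == contrast.n_b == 240

    def test_identical_states_calibrate_near_alpha(self):
        metrics = synthetic_metrics(n_epochs=480, states=("A", "B"), seed=2)
        series = build_edge_series(metrics)
        contrast = state_contrast(series, "A", "B", metric="dpte")
        assert np.max(np.abs(contrast.mean_diff)) < 0.02
        assert np.mean(contrast.pvalue < 0.05) < 0.25

    def test_paired_test_requires_equal_counts(self):
        metrics = synthetic_metrics(n_epochs=50, states=("A", "B"))
        metrics.append(synthetic_metrics(n_epochs=1, states=("A",))[0])
        series = build_edge_series(metrics)
        with pytest.raises(ValidationError, match="paired"):
            state_contrast(series, "A", "B", test="paired")

    def test_single_epoch_per_state_rejected(self):
        series = build_edge_series(synthetic_metrics(n_epochs=2, states=("A", "B")))
        with pytest.raises(ValidationError):
            state_contrast(series, "A", "B")

    def test_bh_adjustment_only_raises_pvalues(self):
        metrics = synthetic_metrics(n_epochs=120, states=("A", "B"), seed=3)
        series = build_edge_series(metrics)
        raw = state_contrast(series, "A", "B")
        adj = state_contrast(series, "A", "B", adjust="bh")
        assert (adj.pvalue >= raw.pvalue - 1e-15).all()


class TestCountChangedEdges:
    def _contrast(self, diffs_by_pair):
        edges, diffs = [], []
        for (a, b), d in diffs_by_pair.items():
            edges += [(a, b), (b, a)]
            diffs += [d, -d]
        n = len(edges)
        return ContrastResult(
            edges=edges,
            mean_diff=np.array(diffs),
            statistic=np.zeros(n),
            pvalue=np.ones(n),
            test="two-sample",
            n_a=10,
            n_b=10,
            metric="dpte",
        )

    def test_counts_each_pair_once(self):
        contrast = self._contrast({("A", "B"): 0.025, ("A", "C"): -0.021, ("B", "C"): 0.01})
        assert count_changed_edges(contrast, 0.02) == 2

    def test_all_zero_changes(self):
        contrast = self._contrast({("A", "B"): 0.0})
        assert count_changed_edges(contrast, 0.02) == 0

    def test_zero_threshold_rejected(self):
        contrast = self._contrast({("A", "B"): 0.1})
        with pytest.raises(ValidationError):
            count_changed_edges(contrast, 0.0)


class TestSurrogateNull:
    @pytest.fixture
    def small_recording(self):
        cfg = SimulationConfig(
            n_regions=2,
            region_names=["A", "B"],
            state_schedule=[("RS", 60.0)],
            coupling_edges=[DirectedCoupling(0, 1, {"RS": 20.0})],
            seed=8,
        )
        rec, _ = generate_recording(cfg)
        return rec

    def test_same_seed_reproduces_null_vector(self, small_recording):
        a = shuffle_surrogate_null(
            small_recording, BAND_TABLE["theta"], "plv", n_shuffles=5, seed=3
        )
        b = shuffle_surrogate_null(
            small_recording, BAND_TABLE["theta"], "plv", n_shuffles=5, seed=3
        )
        np.testing.assert_array_equal(a.values, b.values)
        assert a.n_shuffles == 5

    def test_too_few_segments_rejected(self):
        rec = Recording(np.random.default_rng(0).standard_normal((2, 12000)), 1000.0,
                        ["A", "B"], [("RS", 0, 12000)])
        with pytest.raises(ValidationError, match="segments"):
            shuffle_surrogate_null(rec, BAND_TABLE["theta"], "dpte", n_shuffles=2, seed=0)
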