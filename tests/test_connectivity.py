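"""Unit and property tests for PLV, phase binning, entropies, PTE, and dPTE."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgeflow import (
    BinningScheme,
    DegenerateSignalError,
    LagSpec,
    NoOscillationError,
    ValidationError,
    analysis_lag,
    directed_pte,
    epoch_network_metrics,
    pair_metrics,
    phase_entropy,
    plv,
    pte,
    scott_bin_size,
)

from conftest import (
    TWO_PI,
    entropy_bits_oracle,
    make_phase_series,
    pte_oracle,
    sinusoid_phase,
)


class TestPlv:
    def test_identical_series_lock_perfectly(self):
        p = sinusoid_phase(6.0, 1.0, 1000.0)
        assert plv(p, p) == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("offset", [np.pi / 3, 1.0, 5.0])
    def test_constant_offset_locks_perfectly(self, offset):
        p = sinusoid_phase(6.0, 1.0, 1000.0)
        assert plv(p, np.mod(p + offset, TWO_PI)) == pytest.approx(1.0, abs=1e-12)

    def test_common_rotation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, TWO_PI, 500)
        y = rng.uniform(0, TWO_PI, 500)
        rotated = plv(np.mod(x + 1.23, TWO_PI), np.mod(y + 1.23, TWO_PI))
        assert rotated == pytest.approx(plv(x, y), abs=1e-12)

    def test_independent_phases_approach_rayleigh_mean(self):
        # E[PLV] for N iid uniform phases is sqrt(pi)/2 * N**-0.5
        rng = np.random.default_rng(7)
        n = 10_000
        values = [
            plv(rng.uniform(0, TWO_PI, n), rng.uniform(0, TWO_PI, n))
            for _ in range(50)
        ]
        expected = math.sqrt(math.pi) / 2 * n**-0.5  # ~0.0089
        assert np.mean(values) == pytest.approx(expected, rel=0.15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            plv(np.zeros(10), np.zeros(11))


class TestScottBinning:
    def test_uniform_grid_matches_closed_form(self):
        # sd of uniform phases is pi/sqrt(3); binsize = 3.49 * sd * N**(-1/3)
        n = 10_000
        grid = np.linspace(0, TWO_PI, n, endpoint=False)
        scheme = scott_bin_size(grid)
        expected = 3.49 * np.std(grid) * n ** (-1 / 3)
        assert scheme.bin_size == pytest.approx(expected, abs=1e-15)
        assert scheme.bin_size == pytest.approx(0.2938, abs=2e-3)
        assert scheme.n_bins == 22

    def test_bin_count_is_ceiling_rule(self):
        scheme = BinningScheme(bin_size=0.294, n_bins=math.ceil(TWO_PI / 0.294))
        assert scheme.n_bins == 22
        assert scheme.bin_edges[0] == 0.0
        assert scheme.bin_edges[-1] == pytest.approx(TWO_PI)

    def test_constant_phases_rejected(self):
        with pytest.raises(DegenerateSignalError):
            scott_bin_size(np.full(100, 1.0))


class TestPhaseEntropy:
    def test_single_occupied_bin_has_zero_entropy(self):
        scheme = BinningScheme(bin_size=0.294, n_bins=22)
        assert phase_entropy(np.full(500, 0.1), scheme) == 0.0

    def test_equidistributed_phases_reach_log2_bins(self):
        scheme = BinningScheme(bin_size=0.294, n_bins=22)
        centers = (np.arange(22) + 0.5) * TWO_PI / 22
        phases = np.tile(centers, 10)
        assert phase_entropy(phases, scheme) == pytest.approx(math.log2(22), abs=1e-12)

    def test_matches_histogram_oracle_on_random_series(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n_bins = int(rng.integers(3, 30))
            scheme = BinningScheme(bin_size=TWO_PI / n_bins, n_bins=n_bins)
            # phases at bin centres: no edge-assignment ambiguity
            codes = rng.integers(0, n_bins, size=100)
            phases = (codes + 0.5) * TWO_PI / n_bins
            expected = entropy_bits_oracle(phases, scheme.bin_edges)
            assert phase_entropy(phases, scheme) == pytest.approx(expected, abs=1e-12)


class TestAnalysisLag:
    def test_one_hertz_pair_gives_thousand_sample_lag(self):
        p = sinusoid_phase(1.0, 10.0, 1000.0)
        lag = analysis_lag(p, p.copy())
        assert lag.crossings == 20  # 10 full oscillations per series
        assert lag.delta == 1000

    def test_five_hertz_pair(self):
        p = sinusoid_phase(5.0, 10.0, 1000.0)
        lag = analysis_lag(p, p.copy())
        assert lag.crossings == 100
        assert lag.delta == 200

    def test_lag_never_below_one_sample(self):
        # very fast oscillation: more crossings than half the samples
        p = np.mod(np.arange(100) * 2.5, TWO_PI)
        lag = analysis_lag(p, p.copy())
        assert lag.delta >= 1

    def test_constant_phase_has_no_oscillation(self):
        with pytest.raises(NoOscillationError):
            analysis_lag(np.full(100, 1.0), np.full(100, 2.0))


class TestPte:
    def test_matches_brute_force_oracle_on_discrete_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n_bins = int(rng.integers(3, 6))
            scheme = BinningScheme(bin_size=TWO_PI / n_bins, n_bins=n_bins)
            codes_x = rng.integers(0, n_bins, size=200)
            codes_y = rng.integers(0, n_bins, size=200)
            px = (codes_x + 0.5) * TWO_PI / n_bins
            py = (codes_y + 0.5) * TWO_PI / n_bins
            delta = int(rng.integers(1, 11))
            lag = LagSpec(delta=delta, crossings=1, n_combined=400)
            expected = pte_oracle(px, py, delta, scheme.bin_edges)
            assert pte(px, py, lag, scheme) == pytest.approx(expected, abs=1e-12)

    def test_exact_copy_transfers_nothing(self):
        # when x == y the source past adds nothing beyond the target's own past
        p = sinusoid_phase(6.0, 2.0, 1000.0)
        scheme = scott_bin_size(p)
        lag = analysis_lag(p, p.copy())
        assert pte(p, p.copy(), lag, scheme) == pytest.approx(0.0, abs=1e-12)

    def test_lag_longer_than_series_rejected(self):
        scheme = BinningScheme(bin_size=1.0, n_bins=7)
        with pytest.raises(ValidationError):
            pte(np.zeros(10), np.zeros(10), LagSpec(10, 1, 20), scheme)


class TestDirectedPte:
    def test_arithmetic(self):
        assert directed_pte(0.3, 0.1) == pytest.approx(0.25, abs=1e-15)

    def test_balanced_flow_is_zero(self):
        assert directed_pte(0.2, 0.2) == 0.0

    def test_no_flow_convention(self):
        assert directed_pte(0.0, 0.0) == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            directed_pte(-0.1, 0.2)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.floats(min_value=0.0, max_value=10.0, allow_nan=False),
        b=st.floats(min_value=0.0, max_value=10.0, allow_nan=False),
    )
    def test_antisymmetry_and_range(self, a, b):
        d = directed_pte(a, b)
        assert directed_pte(b, a) == -d
        assert -0.5 <= d <= 0.5


class TestEpochNetworkMetrics:
    def _random_series(self, n_regions, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n_regions):
            drift = TWO_PI * 6.0 / 1000.0
            phase = np.mod(
                np.cumsum(drift + 0.05 * rng.standard_normal(n)), TWO_PI
            )
            out.append(make_phase_series(phase, region=f"R{i}"))
        return out

    def test_matrix_shapes_and_structure(self):
        series = self._random_series(6)
        m = epoch_network_metrics(series)
        assert m.plv_matrix.shape == (6, 6)
        np.testing.assert_array_equal(m.plv_matrix, m.plv_matrix.T)
        np.testing.assert_array_equal(m.dpte_matrix, -m.dpte_matrix.T)
        np.testing.assert_array_equal(np.diag(m.plv_matrix), np.ones(6))
        np.testing.assert_array_equal(np.diag(m.dpte_matrix), np.zeros(6))
        # 15 unordered pairs populated off-diagonal
        assert np.isfinite(m.plv_matrix).all()

    def test_duplicated_region_locks_and_carries_no_flow(self):
        series = self._random_series(3)
        series[1] = make_phase_series(series[0].phase.copy(), region="R1")
        m = epoch_network_metrics(series)
        assert m.plv_matrix[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert m.dpte_matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        series = self._random_series(2)
        series[1] = make_phase_series(series[1].phase[:-5], region="R1")
        with pytest.raises(ValidationError):
            epoch_network_metrics(series)

    def test_single_region_rejected(self):
        with pytest.raises(ValidationError):
            epoch_network_metrics(self._random_series(1))


def test_metrics_invariant_to_positive_signal_rescaling(theta):
    """All phase metrics are amplitude-blind: scaling the raw signal changes nothing."""
    from edgeflow import bandpass, hilbert_phase
    from conftest import make_epoch

    rng = np.random.default_rng(5)
    raw_a, raw_b = rng.standard_normal(4000), rng.standard_normal(4000)
    metrics = []
    for scale in (1.0, 37.5):
        pa = hilbert_phase(bandpass(make_epoch(scale * raw_a, "A"), theta))
        pb = hilbert_phase(bandpass(make_epoch(scale * raw_b, "B"), theta))
        metrics.append(pair_metrics(pa, pb))
    assert metrics[0].plv == pytest.approx(metrics[1].plv, abs=1e-9)
    assert metrics[0].dpte_xy == pytest.approx(metrics[1].dpte_xy, abs=1e-9)
    assert metrics[0].scheme.n_bins == metrics[1].scheme.n_bins
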