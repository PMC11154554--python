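"""Unscaled Bayes factors, the p-value lower bound, and the W sequence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhtcnn import (EvidenceSpec, bf_lower_bound, build_w_sequence,
                    log_bf_lower_bound, unscaled_bf_normal,
                    unscaled_log_bf_battery)
from mhtcnn.bf import read_evidence_tsv, write_evidence_tsv
from mhtcnn.bf import TestBattery as Battery

from _oracles import quadrature_log_bf


class TestUnscaledBF:
    def test_matches_quadrature_oracle_on_spec_example(self):
        x = np.array([-0.2, 0.1, 0.3])
        y = np.array([2.9, 3.2, 3.4])
        closed = unscaled_bf_normal(x, y)
        oracle = quadrature_log_bf(x, y)
        assert closed == pytest.approx(oracle, rel=1e-6)

    def test_matches_quadrature_oracle_on_random_samples(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            nx, ny = rng.integers(2, 8, 2)
            x = rng.normal(0, rng.uniform(0.5, 2), nx)
            y = rng.normal(rng.normal(0, 2), rng.uniform(0.5, 2), ny)
            assert unscaled_bf_normal(x, y) == pytest.approx(
                quadrature_log_bf(x, y), rel=1e-6)

    def test_identical_samples_attain_minimum_at_t_zero(self):
        # equal means with the same pooled spread give the t=0 minimum
        x = np.array([0.0, 1.0, 2.0])
        base = unscaled_bf_normal(x, x)
        shifted = unscaled_bf_normal(x, x + 1e-6)
        assert shifted >= base
        # same value for any configuration with equal means and pooled SS
        y = np.array([1.0, 0.0, 2.0])
        assert unscaled_bf_normal(x, y) == pytest.approx(base, rel=1e-12)

    def test_monotone_in_t(self):
        strong = unscaled_bf_normal([0.0, 1.0], [10.0, 11.0])
        weak = unscaled_bf_normal([0.0, 1.0], [0.5, 1.5])
        assert strong > weak
        # grid of |t| values at fixed n: log-BF strictly increasing
        x = np.array([-1.0, 0.0, 1.0])
        vals = [unscaled_bf_normal(x, x + d) for d in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(vals) > 0)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError, match="zero residual variability"):
            unscaled_bf_normal([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="non-finite"):
            unscaled_bf_normal([0.0, np.nan], [1.0, 2.0])
        with pytest.raises(ValueError, match="at least two"):
            unscaled_bf_normal([1.0], [1.0, 2.0])

    def test_battery_vectorisation_matches_per_test(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 5))
        y = rng.normal(size=(20, 6))
        battery = Battery(ids=[str(i) for i in range(20)], x=x, y=y)
        vec = unscaled_log_bf_battery(battery)
        per = [unscaled_bf_normal(xi, yi) for xi, yi in zip(x, y)]
        np.testing.assert_allclose(vec, per, rtol=1e-12)

    def test_heteroskedastic_variant_monotone_and_finite(self):
        spec = EvidenceSpec(options={"heteroskedastic": True})
        x = np.array([-0.5, 0.2, 0.4, 0.1])
        weak = unscaled_bf_normal(x, x + 0.2, spec)
        strong = unscaled_bf_normal(x, x + 3.0, spec)
        assert np.isfinite(weak) and np.isfinite(strong)
        assert strong > weak


class TestBFLowerBound:
    def test_boundary_and_otherwise_branch(self):
        assert bf_lower_bound(np.exp(-1.0)) == pytest.approx(1.0, abs=1e-12)
        assert bf_lower_bound(0.9) == 1.0
        assert bf_lower_bound(1.0) == 1.0

    def test_agrees_with_arbitrary_precision_at_p05(self):
        # mpmath, 40 digits: 1/(-e * 0.05 * ln 0.05)
        assert bf_lower_bound(0.05) == pytest.approx(
            2.456023486604883112886234438194134451666, rel=1e-12)

    def test_monotone_nonincreasing_below_e_inv(self):
        pv = np.geomspace(1e-12, np.exp(-1.0), 200)
        vals = bf_lower_bound(pv)
        assert np.all(np.diff(vals) <= 0)
        assert np.all(vals >= 1.0)
        # equality with 1 holds exactly on [e^-1, 1]
        assert np.all(bf_lower_bound(np.linspace(np.exp(-1.0), 1.0, 50)) == 1.0)

    def test_log_version_consistent(self):
        pv = np.array([1e-10, 1e-3, 0.05, 0.2, 0.5, 0.9])
        np.testing.assert_allclose(log_bf_lower_bound(pv),
                                   np.log(bf_lower_bound(pv)), rtol=1e-12)

    def test_invalid_and_clamped_pvalues(self):
        with pytest.raises(ValueError):
            bf_lower_bound(1.5)
        with pytest.warns(RuntimeWarning, match="clamped"):
            val = bf_lower_bound(0.0)
        assert np.isfinite(val) and val > 1e100


class TestWSequence:
    def test_spec_examples(self):
        seq = build_w_sequence([0.0, 0.0, 0.0])
        np.testing.assert_array_equal(seq.w, [1.0, 0.0, 0.0])
        np.testing.assert_array_equal(seq.order, [0, 1, 2])
        seq = build_w_sequence([0.0, 1.0, 3.0])
        np.testing.assert_allclose(seq.w, [1.0, 1.0, 2.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=30),
           st.floats(-100, 100))
    def test_shift_invariance(self, log_bfs, k):
        base = build_w_sequence(log_bfs)
        shifted = build_w_sequence(np.asarray(log_bfs) + k)
        # exact in exact arithmetic; floating point only approximately,
        # and a shift can merge near-ties, so compare w not the permutation
        np.testing.assert_allclose(shifted.w, base.w, atol=1e-6)

    def test_w_nonnegative_and_sentinel(self):
        rng = np.random.default_rng(0)
        seq = build_w_sequence(rng.normal(size=100))
        assert seq.w[0] == 1.0
        assert np.all(seq.w[1:] >= 0)
        assert np.all(np.diff(seq.log_bf_sorted) >= 0)

    def test_permutation_round_trip(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=50)
        ids = np.array([f"g{i}" for i in range(50)])
        seq = build_w_sequence(vals, ids=ids)
        np.testing.assert_array_equal(seq.to_original_order(seq.ids_sorted), ids)
        np.testing.assert_allclose(seq.to_original_order(seq.log_bf_sorted), vals)

    def test_stable_tie_break_and_errors(self):
        seq = build_w_sequence([1.0, 0.0, 1.0, 0.0])
        np.testing.assert_array_equal(seq.order, [1, 3, 0, 2])
        with pytest.raises(ValueError):
            build_w_sequence([1.0])
        with pytest.raises(ValueError, match="bad"):
            build_w_sequence([0.0, np.inf], ids=["ok", "bad"])

    def test_labels_travel_with_sort(self):
        seq = build_w_sequence([3.0, 1.0, 2.0], labels=[1, 0, 0])
        np.testing.assert_array_equal(seq.labels_sorted, [0, 0, 1])


def test_evidence_tsv_round_trip(tmp_path):
    ids = [f"g{i}" for i in range(5)]
    vals = np.linspace(-2, 7, 5)
    path = tmp_path / "ev.tsv"
    write_evidence_tsv(path, ids, log_bf=vals)
    df = read_evidence_tsv(path)
    assert list(df["id"]) == ids
    np.testing.assert_allclose(df["log_bf"], vals)
    with pytest.raises(ValueError, match="exactly one"):
        write_evidence_tsv(path, ids, log_bf=vals, pvalue=vals)


def test_evidence_tsv_rejects_bad_columns(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("id\tother\na\t1\n")
    with pytest.raises(ValueError, match="log_bf' or 'pvalue"):
        read_evidence_tsv(path)
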