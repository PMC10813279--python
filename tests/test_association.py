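"""r-charts, BH-FDR, CI windows, Fisher z and the adjusted-association wrapper."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circalight.association import (
    adjusted_association,
    bh_fdr,
    ci_window,
    compare_correlations,
    compute_rchart,
    stratified_rchart,
)
from circalight.exceptions import (
    DegenerateError,
    InsufficientDataError,
    ParameterError,
)
from circalight.io import N_BINS


def bh_oracle(p, q):
    """Step-up from the definition: largest k with p_(k) ≤ k·q/m rejects the k smallest."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_best = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_best = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_best]] = True
    return reject


class TestBH:
    def test_uniform_strong_signal_all_rejected(self):
        assert bh_fdr(np.full(48, 0.001), 0.1).all()

    def test_single_p_reduces_to_threshold(self):
        assert bh_fdr([0.04], 0.1)[0]
        assert not bh_fdr([0.2], 0.1)[0]

    def test_mixed_vector_matches_oracle(self, rng):
        p = np.round(rng.uniform(size=20), 2)
        np.testing.assert_array_equal(bh_fdr(p, 0.1), bh_oracle(p, 0.1))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ParameterError):
            bh_fdr([0.5, 1.2], 0.1)

    @settings(derandomize=True, max_examples=300)
    @given(
        st.lists(st.integers(min_value=0, max_value=100), min_size=1, max_size=10),
        st.sampled_from([0.05, 0.1, 0.25]),
    )
    def test_matches_oracle_on_grid_vectors(self, grid, q):
        p = np.asarray(grid, dtype=float) / 100.0
        np.testing.assert_array_equal(bh_fdr(p, q), bh_oracle(p, q))


class TestRChart:
    def test_exact_linear_bin_has_r_one(self, rng):
        n = 30
        mat = rng.normal(0, 1, (n, N_BINS))
        outcome = rng.normal(0, 1, n)
        mat[:, 47] = 2.0 * outcome + 1.0
        rc = compute_rchart(mat, outcome)
        row = rc.bins.iloc[47]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-12
        assert row["significant_fdr"]

    def test_constant_outcome_degenerate(self, rng):
        with pytest.raises(DegenerateError):
            compute_rchart(rng.normal(0, 1, (10, N_BINS)), np.full(10, 3.0))

    def test_small_bins_flagged_not_evaluable(self, rng):
        mat = rng.normal(0, 1, (10, N_BINS))
        mat[:7, 5] = np.nan  # only 3 pairs left in bin 5
        rc = compute_rchart(mat, rng.normal(0, 1, 10))
        assert not rc.bins.loc[5, "evaluable"]
        assert rc.bins.loc[5, "n"] == 3

    def test_invariant_to_participant_order_and_profile_offset(self, rng):
        n = 25
        mat = rng.normal(0, 1, (n, N_BINS))
        outcome = rng.normal(0, 1, n)
        rc1 = compute_rchart(mat, outcome)
        perm = rng.permutation(n)
        rc2 = compute_rchart(mat[perm] + 5.0, outcome[perm])
        np.testing.assert_allclose(rc1.bins["r"], rc2.bins["r"], atol=1e-12)

    def test_planted_sinusoidal_weights_recovered(self, rng):
        # outcome loads on evening bins with weights peaking at 23:30
        n = 200
        mids = np.arange(N_BINS) * 0.5 + 0.25
        w = np.cos(2 * np.pi * (mids - 23.5) / 24)
        mat = rng.normal(0, 1, (n, N_BINS))
        outcome = mat @ w * 0.3 + rng.normal(0, 1, n)
        rc = compute_rchart(mat, outcome)
        cos = rc.cosinor_of_r
        assert cos is not None
        assert abs((cos.acrophase - 23.5 + 12) % 24 - 12) < 1.0
        assert cos.p_zero_amplitude < 0.01


class TestCIWindow:
    def test_identical_groups_empty(self, rng):
        mat = rng.normal(0, 1, (20, N_BINS))
        win = ci_window(mat, mat.copy())
        assert win.empty

    def test_planted_evening_shift_recovered(self, rng):
        # groups differ by 5 pooled SDs only in bins 43–47 (21:30–00:00)
        n = 400
        a = rng.normal(0, 1, (n, N_BINS))
        b = rng.normal(0, 1, (n, N_BINS))
        b[:, 43:48] += 5.0
        win = ci_window(a, b)
        assert win.bins == [43, 44, 45, 46, 47]
        assert win.start_hour == pytest.approx(21.5)
        assert win.end_hour == pytest.approx(0.0)
        # threshold curve belongs to the lower-mean group (a)
        for bin_ in win.bins:
            assert win.threshold_curve[bin_] < 2.5

    def test_window_wraps_midnight(self, rng):
        n = 400
        a = rng.normal(0, 1, (n, N_BINS))
        b = rng.normal(0, 1, (n, N_BINS))
        b[:, 45:48] += 5.0
        b[:, 0:2] += 5.0
        win = ci_window(a, b)
        assert win.bins == [45, 46, 47, 0, 1]
        assert win.end_hour == pytest.approx(1.0)

    def test_longest_run_wins_ties_broken_from_noon(self, rng):
        n = 400
        a = rng.normal(0, 1, (n, N_BINS))
        b = rng.normal(0, 1, (n, N_BINS))
        b[:, 10:12] += 5.0  # 2-bin run in the morning
        b[:, 40:44] += 5.0  # 4-bin run in the evening → longest
        win = ci_window(a, b)
        assert win.bins == [40, 41, 42, 43]

    def test_symmetric_in_group_labels(self, rng):
        n = 300
        a = rng.normal(0, 1, (n, N_BINS))
        b = rng.normal(0, 1, (n, N_BINS))
        b[:, 44:47] += 5.0
        w1 = ci_window(a, b)
        w2 = ci_window(b, a)
        assert w1.bins == w2.bins

    def test_insufficient_group_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            ci_window(rng.normal(0, 1, (1, N_BINS)), rng.normal(0, 1, (10, N_BINS)))


class TestCompareCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = compare_correlations(0.3, 20, 0.3, 50)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_printed_genotype_contrast(self):
        # independent evaluation of the formula for the published contrast
        z, p = compare_correlations(-0.659, 22, 0.049, 28)
        expected = (np.arctanh(-0.659) - np.arctanh(0.049)) / np.sqrt(1 / 19 + 1 / 25)
        assert z == pytest.approx(expected)
        assert z == pytest.approx(-2.76, abs=0.01)
        assert p < 0.01

    def test_antisymmetry(self):
        z1, _ = compare_correlations(0.5, 30, -0.2, 40)
        z2, _ = compare_correlations(-0.2, 40, 0.5, 30)
        assert z1 == pytest.approx(-z2)

    def test_degenerate_r_rejected(self):
        with pytest.raises(DegenerateError):
            compare_correlations(1.0, 30, 0.0, 30)


class TestStratified:
    def test_identical_strata_give_identical_charts(self, rng):
        n = 40
        mat = rng.normal(0, 1, (n, N_BINS))
        outcome = rng.normal(0, 1, n)
        mat2 = np.vstack([mat, mat])
        out2 = np.concatenate([outcome, outcome])
        strata = np.array(["A"] * n + ["B"] * n)
        res = stratified_rchart(mat2, out2, strata)
        np.testing.assert_allclose(res["A"].bins["r"], res["B"].bins["r"])

    def test_small_stratum_not_evaluable(self, rng):
        n = 20
        mat = rng.normal(0, 1, (n, N_BINS))
        outcome = rng.normal(0, 1, n)
        strata = np.array(["big"] * 19 + ["solo"])
        res = stratified_rchart(mat, outcome, strata)
        assert res["solo"] is None
        assert res["big"] is not None

    def test_effect_planted_in_one_stratum_only(self, rng):
        mids = np.arange(N_BINS) * 0.5 + 0.25
        w = np.cos(2 * np.pi * (mids - 23.5) / 24)
        n = 150
        mat_a = rng.normal(0, 1, (n, N_BINS))
        out_a = mat_a @ w * 0.3 + rng.normal(0, 1, n)
        mat_b = rng.normal(0, 1, (n, N_BINS))
        out_b = rng.normal(0, 1, n)
        mat = np.vstack([mat_a, mat_b])
        out = np.concatenate([out_a, out_b])
        strata = np.array(["carrier"] * n + ["noncarrier"] * n)
        res = stratified_rchart(mat, out, strata)
        assert res["carrier"].cosinor_of_r.p_zero_amplitude < 0.01
        assert res["noncarrier"].cosinor_of_r.p_zero_amplitude > 0.01


class TestAdjustedAssociation:
    def test_orthogonal_covariates_reduce_to_simple_slope(self, rng):
        n = 4000
        x = rng.normal(0, 1, n)
        age = rng.normal(40, 10, n)
        y = 0.5 * x + rng.normal(0, 1, n)
        cov = pd.DataFrame({"age": age})
        beta, p = adjusted_association(y, x, cov)
        r_simple = np.corrcoef(
            (x - x.mean()) / x.std(), (y - y.mean()) / y.std()
        )[0, 1]
        assert beta == pytest.approx(r_simple, abs=0.01)

    def test_exact_linear_relation(self, rng):
        n = 50
        x = rng.normal(0, 1, n)
        y = -2.0 * x + 1.0
        cov = pd.DataFrame({"age": rng.normal(40, 10, n)})
        beta, p = adjusted_association(y, x, cov)
        assert beta < 0
        assert p < 1e-12

    def test_confounding_removed_by_adjustment(self, rng):
        n = 1000
        age = rng.normal(0, 1, n)
        x = age + rng.normal(0, 0.3, n)
        y = age + rng.normal(0, 0.3, n)  # association only through age
        r_unadj = np.corrcoef(x, y)[0, 1]
        beta, p = adjusted_association(y, x, pd.DataFrame({"age": age}))
        assert r_unadj > 0.5
        assert abs(beta) < 0.12

    def test_categorical_covariates_dummy_coded(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        sex = rng.choice(["female", "male"], n)
        y = 0.4 * x + (sex == "male") * 2.0 + rng.normal(0, 1, n)
        beta, p = adjusted_association(y, x, pd.DataFrame({"sex": sex}))
        assert p < 1e-4

    def test_collinear_design_rejected(self, rng):
        n = 50
        x = rng.normal(0, 1, n)
        cov = pd.DataFrame({"x2": x})  # duplicates the predictor
        with pytest.raises(DegenerateError):
            adjusted_association(rng.normal(0, 1, n), x, cov)
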