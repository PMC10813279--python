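"""mEDI conversion, reference curve and NEI/DDI quadrature against a 1-s oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circalight.exceptions import ParameterError, UnitError
from circalight.io import DailyProfile, N_BINS
from circalight.light_hygiene import (
    DAY_WINDOW,
    NIGHT_WINDOW,
    ReferenceCurve,
    build_reference_curve,
    compute_ddi,
    compute_nei,
    irradiance_to_medi,
    light_indices,
    medi_to_irradiance,
)


def make_profile(values, n_contrib=None, transform="raw"):
    values = np.asarray(values, dtype=float)
    if n_contrib is None:
        n_contrib = np.where(np.isfinite(values), 210, 0)
    return DailyProfile(values=values, n_contrib=n_contrib, channel="blue",
                        transform=transform)


def oracle_area(profile_values, ref, window, sign, dt=1.0 / 3600.0):
    """1-second-grid numerical integration of the positive part.

    The step profile is piecewise constant on the 30-min bins, the reference
    is evaluated on the fine grid.
    """
    start, end = window
    hours = np.arange(0, 24, dt)
    if start <= end:
        in_win = (hours >= start) & (hours < end)
    else:
        in_win = (hours >= start) | (hours < end)
    t = hours[in_win]
    bins = (t / 0.5).astype(int) % N_BINS
    expo = np.asarray(profile_values, dtype=float)[bins]
    r = ref.value(t)
    diff = sign * (np.nan_to_num(expo) - r)
    contrib = np.where(np.isfinite(expo), np.maximum(diff, 0.0), 0.0)
    return float(np.sum(contrib) * dt)


class TestConversion:
    @pytest.mark.parametrize(
        "medi,expected,round_to",
        [(250.0, 33.0, 0), (10.0, 1.33, 2), (1.0, 0.13, 2), (0.0, 0.0, 6)],
    )
    def test_recommendation_anchors(self, medi, expected, round_to):
        assert round(medi_to_irradiance(medi), round_to) == expected

    def test_exact_values(self):
        assert medi_to_irradiance(250.0) == pytest.approx(33.155)
        assert medi_to_irradiance(10.0) == pytest.approx(1.3262)

    def test_inverse_composition_is_identity(self):
        x = np.array([0.0, 0.1, 1.33, 33.0, 500.0])
        np.testing.assert_allclose(
            medi_to_irradiance(irradiance_to_medi(x)), x, rtol=1e-12
        )

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            medi_to_irradiance(-1.0)


class TestReferenceCurve:
    def test_printed_anchor_values(self):
        ref = ReferenceCurve()
        assert ref.value(20.0) == pytest.approx(1.33)
        assert ref.value(2.0) == pytest.approx(0.1)
        assert ref.value(9.0) == pytest.approx(33.0)
        assert ref.value(17.0) == pytest.approx(33.0)
        # peak of the arc: P = 33/sin(3π/14)
        assert ref.value(13.0) == pytest.approx(33.0 / np.sin(3 * np.pi / 14))
        assert ref.value(13.0) == pytest.approx(52.93, abs=0.01)

    def test_continuous_and_above_sleep_ceiling(self):
        ref = ReferenceCurve()
        t = np.arange(0, 24, 1 / 240.0)
        v = ref.value(t)
        assert (v >= ref.sleep_ceiling - 1e-12).all()
        assert np.max(np.abs(np.diff(v))) < 0.5  # no jumps at 1/240 h resolution

    def test_inconsistent_anchors_rejected(self):
        with pytest.raises(ParameterError):
            ReferenceCurve(day_target=1.0, prebed_ceiling=5.0)

    def test_plateau_preset(self):
        ref = build_reference_curve("plateau")
        assert ref.value(7.0) == pytest.approx(33.0)
        assert ref.value(19.9) == pytest.approx(33.0)
        assert ref.value(2.0) == pytest.approx(0.1)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ParameterError):
            build_reference_curve("triangle")


class TestIndices:
    def setup_method(self):
        self.ref = ReferenceCurve()
        self.mids = DailyProfile.bin_midpoints_hours()
        self.ref_at_mid = np.asarray(self.ref.value(self.mids))

    def test_exposure_equal_to_reference_gives_zero(self):
        prof = make_profile(self.ref_at_mid)
        assert compute_nei(prof, self.ref) == 0.0
        assert compute_ddi(prof, self.ref) == 0.0

    def test_uniform_offset_over_night_window(self):
        vals = self.ref_at_mid.copy()
        in_night = (self.mids >= 20.0) | (self.mids < 5.0)
        vals[in_night] += 1.0
        prof = make_profile(vals)
        assert compute_nei(prof, self.ref) == pytest.approx(9.0)
        assert compute_ddi(prof, self.ref) == 0.0

    def test_exposure_above_reference_all_day_gives_zero_ddi(self):
        prof = make_profile(self.ref_at_mid + 10.0)
        assert compute_ddi(prof, self.ref) == 0.0

    def test_zero_exposure_ddi_equals_reference_integral(self):
        prof = make_profile(np.zeros(N_BINS))
        ddi = compute_ddi(prof, self.ref)
        oracle = oracle_area(np.zeros(N_BINS), self.ref, DAY_WINDOW, sign=-1)
        # bin-midpoint quadrature vs 1-s grid: bounded by curve slope × bin width
        assert ddi == pytest.approx(oracle, rel=5e-3)
        # closed form for the pure arc: ∫P·sin = 2·14·P/π ≈ 471.7 plus the clip lift
        assert 465 < ddi < 480

    def test_step_profile_matches_fine_grid_oracle(self, rng):
        # reference constant within each bin → quadrature must be near-exact
        ref = ReferenceCurve()
        for _ in range(10):
            vals = rng.exponential(5.0, N_BINS)
            prof = make_profile(vals)
            nei = compute_nei(prof, ref)
            ddi = compute_ddi(prof, ref)
            nei_o = oracle_area(vals, ref, NIGHT_WINDOW, sign=+1)
            ddi_o = oracle_area(vals, ref, DAY_WINDOW, sign=-1)
            # smooth reference: agreement within the discretization bound
            assert nei == pytest.approx(nei_o, abs=0.1)
            assert ddi == pytest.approx(ddi_o, abs=1.0)

    def test_piecewise_constant_reference_matches_oracle_to_1e9(self, rng):
        # with a bin-resolved (stepped) reference the bin sum is exactly the integral
        class SteppedRef:
            def __init__(self, inner):
                mids = DailyProfile.bin_midpoints_hours()
                self.table = np.asarray(inner.value(mids))
                self.sleep_ceiling = inner.sleep_ceiling

            def value(self, t):
                t = np.mod(np.asarray(t, dtype=float), 24.0)
                return self.table[(np.atleast_1d(t) / 0.5).astype(int) % N_BINS]

        stepped = SteppedRef(ReferenceCurve())
        for _ in range(5):
            vals = rng.exponential(5.0, N_BINS)
            prof = make_profile(vals)
            nei = compute_nei(prof, stepped)
            ddi = compute_ddi(prof, stepped)
            nei_o = oracle_area(vals, stepped, NIGHT_WINDOW, sign=+1)
            ddi_o = oracle_area(vals, stepped, DAY_WINDOW, sign=-1)
            assert nei == pytest.approx(nei_o, rel=1e-9, abs=1e-9)
            assert ddi == pytest.approx(ddi_o, rel=1e-9, abs=1e-9)

    def test_missing_bins_contribute_zero_and_are_reported(self):
        vals = self.ref_at_mid + 1.0
        n_contrib = np.full(N_BINS, 210)
        n_contrib[40] = 0  # 20:00–20:30 missing
        vals[40] = np.nan
        prof = make_profile(vals, n_contrib=n_contrib)
        li = light_indices(prof, self.ref)
        assert li.nei_bl == pytest.approx(8.5)  # 17 of 18 night bins
        assert li.nei_missing_bins == [40]

    def test_log_profile_rejected(self):
        prof = make_profile(np.zeros(N_BINS), transform="log10")
        with pytest.raises(UnitError):
            compute_nei(prof, self.ref)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=N_BINS - 1),
           st.floats(min_value=0.01, max_value=20.0))
    def test_pointwise_increase_monotonicity(self, b, bump):
        ref = ReferenceCurve()
        mids = DailyProfile.bin_midpoints_hours()
        base = np.asarray(ref.value(mids)) * 0.7
        p1 = make_profile(base)
        base2 = base.copy()
        base2[b] += bump
        p2 = make_profile(base2)
        assert compute_nei(p2, ref) >= compute_nei(p1, ref)
        assert compute_ddi(p2, ref) <= compute_ddi(p1, ref)
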