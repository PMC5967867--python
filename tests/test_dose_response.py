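"""Hill-equation forms, per-replicate fitting, log-space aggregation and
paired fold-shift analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allomod import dose_response as dr
from allomod.exceptions import (
    AggregationError,
    FitRefusedError,
    PairingError,
    ValidationError,
)


def crc_frame(conc, resp, rid="r1"):
    return pd.DataFrame({"replicate_id": rid, "condition": "c",
                         "concentration_um": conc, "response": resp})


class TestHillForms:
    @pytest.mark.parametrize("m,expected", [
        (0.0, 1.0),                      # zero-concentration identity
        (0.2, 0.57),                     # midpoint: 1 + Extent/2
        (2000.0, 0.1400860),             # 1e4 x EC50: saturation at 1+Extent
    ])
    def test_modulator_form_inhibitor_curve(self, m, expected):
        """An inhibitor with Extent -0.86 plateaus at 14% of control."""
        assert dr.hill_modulator(m, 0.2, 1.0, -0.86) == pytest.approx(
            expected, abs=1e-7)

    @pytest.mark.parametrize("a,ec50,h,expected", [
        (0.0, 1.0, 1.3, 0.0),
        (5.0, 5.0, 2.2, 0.5),     # midpoint identity for any slope
        (3.0, 1.0, 1.0, 0.75),
    ])
    def test_agonist_form(self, a, ec50, h, expected):
        assert dr.hill_agonist(a, ec50, h) == pytest.approx(expected)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            dr.hill_modulator(1.0, -1.0, 1.0, 0.5)
        with pytest.raises(ValidationError):
            dr.hill_agonist(1.0, 1.0, 0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(ec50=st.floats(1e-3, 1e3), h=st.floats(0.3, 5),
           extent=st.floats(-1, 20))
    def test_modulator_form_monotone(self, ec50, h, extent):
        m = np.logspace(-4, 4, 60)
        y = dr.hill_modulator(m, ec50, h, extent)
        d = np.diff(y)
        assert (d >= -1e-12).all() if extent >= 0 else (d <= 1e-12).all()


class TestFitHill:
    def test_noiseless_recovery_exact(self):
        conc = np.logspace(-1.5, 1.5, 7)
        truth = (2.0, 1.2, 1.5)
        df = crc_frame(conc, dr.hill_modulator(conc, *truth))
        f = dr.fit_hill(df, apply_refusal=False)[0]
        assert f.converged
        assert f.ec50 == pytest.approx(truth[0], rel=1e-6)
        assert f.h == pytest.approx(truth[1], rel=1e-6)
        assert f.extent == pytest.approx(truth[2], rel=1e-6)

    def test_refit_of_fitted_curve_is_idempotent(self):
        conc = np.logspace(-2, 2, 9)
        df = crc_frame(conc, dr.hill_modulator(conc, 0.7, 0.9, -0.8))
        f1 = dr.fit_hill(df, apply_refusal=False)[0]
        df2 = crc_frame(conc, dr.hill_modulator(conc, f1.ec50, f1.h, f1.extent))
        f2 = dr.fit_hill(df2, apply_refusal=False)[0]
        assert f2.ec50 == pytest.approx(f1.ec50, rel=1e-9)
        assert f2.h == pytest.approx(f1.h, rel=1e-9)

    def test_noisy_fit_matches_grid_search_oracle(self):
        """Brute-force profile over a fine log-EC50 grid must agree with the
        optimizer within one grid step (Hill slope fixed to 1)."""
        rng = np.random.default_rng(42)
        conc = np.array([0.3, 1.0, 3.0, 10.0, 30.0])
        clean = dr.hill_modulator(conc, 2.5, 1.0, 1.8)
        noisy = clean * np.exp(0.05 * rng.standard_normal(5) - 0.05 ** 2 / 2)
        fit = dr.fit_hill(crc_frame(conc, noisy), fix_hill=1.0,
                          apply_refusal=False)[0]

        grid = np.logspace(-3, 3, 2000)
        best_sse, best_ec50 = np.inf, None
        for ec50 in grid:
            frac = conc / (conc + ec50)
            # Extent enters linearly: closed-form least squares
            e = float(frac @ (noisy - 1.0) / (frac @ frac))
            sse = float(((1 + e * frac) - noisy) ** 2 @ np.ones(5))
            if sse < best_sse:
                best_sse, best_ec50 = sse, ec50
        step = math.log10(grid[1] / grid[0])
        assert abs(math.log10(fit.ec50) - math.log10(best_ec50)) <= step

    def test_weak_response_at_30um_not_fit(self):
        """A replicate whose 30 µM response is within 15% of control is
        flagged 'not fit' rather than fitted."""
        conc = np.array([0.3, 1.0, 3.0, 10.0, 30.0])
        resp = dr.hill_modulator(conc, 100.0, 1.0, -0.5)  # ~11% change at 30
        fits = dr.fit_hill(crc_frame(conc, resp))
        assert not fits[0].converged
        assert "not fit" in fits[0].message
        # the same curve is fitted once the screening rule is disabled
        assert dr.fit_hill(crc_frame(conc, resp), apply_refusal=False)[0].converged

    def test_too_few_points_refused(self):
        df = crc_frame([1.0, 10.0], [1.1, 1.6])
        with pytest.raises(FitRefusedError):
            dr.fit_hill(df)

    def test_agonist_form_recovery_with_fixed_slope(self):
        conc = np.logspace(-2, 2, 7)
        df = crc_frame(conc, dr.hill_agonist(conc, 0.4, 1.0))
        f = dr.fit_hill(df, form="agonist", fix_hill=1.0)[0]
        assert f.ec50 == pytest.approx(0.4, rel=1e-8)
        assert f.extent is None


class TestAggregation:
    def make_fits(self, ec50s, extents=None):
        extents = extents or [1.0] * len(ec50s)
        return [dr.HillFit(i, "modulator", e, 1.0, x, 0.0, True)
                for i, (e, x) in enumerate(zip(ec50s, extents))]

    def test_degenerate_sample_zero_width(self):
        s = dr.aggregate_log_ec50(self.make_fits([2.0, 2.0, 2.0]))
        assert s.ec50 == pytest.approx(2.0)
        assert s.ci_low == pytest.approx(2.0)
        assert s.ci_high == pytest.approx(2.0)

    def test_geometric_mean_over_decades(self):
        s = dr.aggregate_log_ec50(self.make_fits([0.1, 1.0, 10.0]))
        assert s.ec50 == pytest.approx(1.0, rel=1e-12)

    def test_t_interval_matches_hand_computation(self):
        """{1, 2, 4} µM: log10 values {0, 0.30103, 0.60206}, SEM 0.17380,
        t(0.975, df=2) = 4.3027, half-width 0.74780."""
        s = dr.aggregate_log_ec50(self.make_fits([1.0, 2.0, 4.0]))
        assert s.ec50 == pytest.approx(2.0, rel=1e-9)
        assert math.log10(s.ci_high) - math.log10(s.ec50) == pytest.approx(
            0.747800, abs=1e-5)
        assert s.ci_low == pytest.approx(10 ** (0.30103 - 0.747800), rel=1e-4)

    def test_fewer_than_two_fits_rejected(self):
        with pytest.raises(AggregationError):
            dr.aggregate_log_ec50(self.make_fits([1.0]))

    def test_order_and_unit_rescale_invariance(self):
        ec50s = [0.5, 1.3, 2.9, 8.0]
        s1 = dr.aggregate_log_ec50(self.make_fits(ec50s))
        s2 = dr.aggregate_log_ec50(self.make_fits(ec50s[::-1]))
        s3 = dr.aggregate_log_ec50(self.make_fits([e * 1000 for e in ec50s]))
        assert s1.ec50 == pytest.approx(s2.ec50, rel=1e-12)
        assert s3.ec50 == pytest.approx(1000 * s1.ec50, rel=1e-9)
        assert s3.ci_high / s3.ci_low == pytest.approx(
            s1.ci_high / s1.ci_low, rel=1e-9)


class TestFoldShift:
    def make(self, ec50s):
        return [dr.HillFit(i, "agonist", e, 1.0, None, 0.0, True)
                for i, e in enumerate(ec50s)]

    def test_identical_groups_fold_one(self):
        fs = dr.fold_shift(self.make([1.0, 2.0]), self.make([1.0, 2.0]))
        assert fs.fold == pytest.approx(1.0)
        assert not fs.non_overlapping

    @pytest.mark.parametrize("control,treated,expected", [
        ([2.0, 4.0], [1.0, 2.0], 2.0),
        ([1.0, 4.0], [0.5, 1.0], math.sqrt(8)),  # geomean of {2, 4}
    ])
    def test_geometric_mean_of_per_pair_ratios(self, control, treated, expected):
        fs = dr.fold_shift(self.make(control), self.make(treated))
        assert fs.fold == pytest.approx(expected, rel=1e-12)

    def test_unpaired_replicate_rejected(self):
        treated = [dr.HillFit(99, "agonist", 1.0, 1.0, None, 0.0, True),
                   dr.HillFit(0, "agonist", 1.0, 1.0, None, 0.0, True)]
        with pytest.raises(PairingError):
            dr.fold_shift(self.make([1.0, 2.0]), treated)
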