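"""Impactor reduction: cumulative distributions, percentiles, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aerodep.impactor_reduction import (
    P84,
    ImpactorRun,
    StageDeposit,
    build_cumulative,
    default_stage_bounds,
    emitted_fraction,
    fit_lognormal,
    fraction_below,
    percentile_diameter,
    summarize,
)
from aerodep.synthetic_data import AerosolSpec, gen_impactor_run

from conftest import lognormal_run


class TestBuildCumulative:
    def test_two_stage_knots(self, two_stage_run):
        dist = build_cumulative(two_stage_run)
        np.testing.assert_allclose(dist.diameters, [0.1, 1.0, 10.0])
        np.testing.assert_allclose(dist.fractions, [0.0, 0.3, 1.0])

    def test_single_bin_distribution(self):
        run = ImpactorRun(
            [StageDeposit(1, 1.0, 2.0, 50.0), StageDeposit(2, 2.0, 4.0, 0.0)]
        )
        dist = build_cumulative(run)
        np.testing.assert_allclose(dist.fractions, [0.0, 1.0, 1.0])

    def test_throat_excluded_from_distribution(self, two_stage_run):
        with_throat = ImpactorRun(list(two_stage_run.stages), throat_activity=500.0)
        np.testing.assert_allclose(
            build_cumulative(with_throat).fractions,
            build_cumulative(two_stage_run).fractions,
        )

    def test_median_of_dense_lognormal(self):
        # closed-form oracle: cumulative fraction at the median is 0.5
        run = lognormal_run(2.8, 3.2, n_stages=24)
        dist = build_cumulative(run)
        assert fraction_below(dist, 2.8) == pytest.approx(0.5, abs=0.02)

    def test_zero_activity_rejected(self):
        run = ImpactorRun(
            [StageDeposit(1, 0.1, 1.0, 0.0), StageDeposit(2, 1.0, 10.0, 0.0)]
        )
        with pytest.raises(ValueError, match="zero total"):
            build_cumulative(run)

    def test_nonmonotone_ladder_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            ImpactorRun(
                [StageDeposit(1, 0.1, 1.0, 10.0), StageDeposit(2, 2.0, 10.0, 10.0)]
            )


class TestPercentileDiameter:
    def test_geometric_midpoint_of_single_bin(self):
        run = ImpactorRun(
            [StageDeposit(1, 1.0, 2.0, 100.0), StageDeposit(2, 2.0, 4.0, 0.0)]
        )
        dist = build_cumulative(run)
        assert percentile_diameter(dist, 0.5) == pytest.approx(np.sqrt(2.0))

    def test_one_sigma_point_matches_closed_form(self):
        # d84 of lognormal(2.8, 3.2) = 2.8 x 3.2 = 8.96 um
        dist = build_cumulative(lognormal_run(2.8, 3.2))
        assert percentile_diameter(dist, P84) == pytest.approx(8.96, rel=5e-3)

    def test_out_of_span_rejected(self, two_stage_run):
        dist = build_cumulative(two_stage_run)
        with pytest.raises(ValueError, match="outside"):
            percentile_diameter(dist, 1.5)

    def test_nondecreasing_in_p(self, two_stage_run):
        dist = build_cumulative(two_stage_run)
        ps = np.linspace(0.01, 0.99, 25)
        ds = [percentile_diameter(dist, p) for p in ps]
        assert np.all(np.diff(ds) >= 0)


class TestFractionBelow:
    def test_clamps_outside_bounds(self, two_stage_run):
        dist = build_cumulative(two_stage_run)
        assert fraction_below(dist, 100.0) == 1.0
        assert fraction_below(dist, 0.001) == 0.0

    def test_fine_particle_fraction_of_micron_aerosol(self):
        # Phi(ln(2.5/2.8)/ln 3.2) = 0.461
        dist = build_cumulative(lognormal_run(2.8, 3.2))
        expected = stats.norm.cdf(np.log(2.5 / 2.8) / np.log(3.2))
        assert fraction_below(dist, 2.5) == pytest.approx(expected, abs=0.005)

    def test_nondecreasing_in_cutoff(self, two_stage_run):
        dist = build_cumulative(two_stage_run)
        cuts = np.logspace(-2, 2, 40)
        fracs = [fraction_below(dist, c) for c in cuts]
        assert np.all(np.diff(fracs) >= 0)

    def test_nonpositive_cutoff_rejected(self, two_stage_run):
        dist = build_cumulative(two_stage_run)
        with pytest.raises(ValueError):
            fraction_below(dist, 0.0)


class TestSummarize:
    def test_gsd_of_dense_lognormal(self):
        s = summarize(lognormal_run(0.55, 2.1))
        assert s.gsd == pytest.approx(2.1, abs=0.05)
        assert s.d16 <= s.amad <= s.d84
        assert s.gsd == pytest.approx(np.sqrt(s.d84 / s.d16))

    def test_single_stage_gsd_is_bound_ratio(self):
        # all activity in one stage: d16/d84 interpolate inside it, so the
        # percentile GSD is forced to a sub-ratio of the stage bounds
        run = ImpactorRun(
            [StageDeposit(1, 1.0, 4.0, 100.0), StageDeposit(2, 4.0, 8.0, 0.0)]
        )
        s = summarize(run)
        # d84 - d16 span 0.6827 of the [1, 4] bin in log space
        expected = (4.0 / 1.0) ** ((P84 - (1 - P84)) / 2)
        assert s.gsd == pytest.approx(expected)

    def test_frac_below_nondecreasing_in_cutoff(self):
        s = summarize(lognormal_run(0.55, 2.1))
        ordered = [s.frac_below[c] for c in (0.1, 0.5, 1.0, 2.5)]
        assert np.all(np.diff(ordered) >= 0)

    def test_lognormal_fit_exact_on_noiseless_knots(self):
        spec = AerosolSpec(0.23, 1.6)
        run = gen_impactor_run(spec)  # default 12-stage ladder
        amad_fit, gsd_fit = fit_lognormal(build_cumulative(run))
        assert amad_fit == pytest.approx(0.23, rel=1e-6)
        assert gsd_fit == pytest.approx(1.6, rel=1e-6)

    @pytest.mark.parametrize("amad,gsd", [(2.8, 3.2), (0.55, 2.1), (0.23, 1.6)])
    def test_oracle_convergence_with_stage_count(self, amad, gsd):
        """Percentile AMAD/GSD approach the lognormal truth as the ladder
        is refined (12 vs 48 stages over the same span)."""
        err = {}
        for n in (12, 48):
            s = summarize(lognormal_run(amad, gsd, n_stages=n))
            err[n] = (abs(s.amad - amad) / amad, abs(s.gsd - gsd))
        assert err[48][0] < err[12][0] or err[12][0] < 1e-9
        assert err[48][1] < err[12][1]
        assert err[48][0] < 0.01
        assert err[48][1] < 0.01 * gsd


class TestScaleInvariance:
    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=25, deadline=None)
    def test_summary_invariant_under_activity_rescaling(self, scale):
        base = lognormal_run(0.55, 2.1, n_stages=12)
        scaled = ImpactorRun(
            [
                StageDeposit(s.stage_index, s.d_lower, s.d_upper, s.activity * scale)
                for s in base.stages
            ]
        )
        s0, s1 = summarize(base), summarize(scaled)
        assert s1.amad == pytest.approx(s0.amad)
        assert s1.gsd == pytest.approx(s0.gsd)
        assert s1.frac_below == pytest.approx(s0.frac_below)


class TestRoundTrip:
    @given(
        activities=st.lists(
            st.floats(min_value=0.1, max_value=1e4), min_size=3, max_size=12
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_percentile_at_knot_fraction_returns_knot(self, activities):
        bounds = default_stage_bounds(len(activities))
        run = ImpactorRun(
            [
                StageDeposit(i + 1, bounds[i], bounds[i + 1], a)
                for i, a in enumerate(activities)
            ]
        )
        dist = build_cumulative(run)
        for d, f in zip(dist.diameters, dist.fractions):
            assert percentile_diameter(dist, f) == pytest.approx(d, rel=1e-12)


class TestEmittedFraction:
    def test_collected_over_charge(self):
        run = ImpactorRun(
            [
                StageDeposit(1, 0.1, 1.0, 20.0),
                StageDeposit(2, 1.0, 10.0, 10.0),
            ],
            throat_activity=2.93,
            charge_before=74.0,
            charge_after=0.0,
        )
        assert emitted_fraction(run) == pytest.approx(32.93 / 74.0)

    def test_zero_collected_is_zero(self):
        run = ImpactorRun(
            [StageDeposit(1, 0.1, 1.0, 0.0), StageDeposit(2, 1.0, 10.0, 0.0)],
            charge_before=74.0,
            charge_after=10.0,
        )
        assert emitted_fraction(run) == 0.0

    def test_negative_net_charge_rejected(self):
        run = ImpactorRun(
            [StageDeposit(1, 0.1, 1.0, 5.0)], charge_before=10.0, charge_after=20.0
        )
        with pytest.raises(ValueError, match="charge"):
            emitted_fraction(run)

    def test_recovery_from_noisy_synthetic_run(self):
        spec = AerosolSpec(0.55, 2.1, noise_model="poisson", seed=7)
        run = gen_impactor_run(spec, emitted_fraction=0.093, counts_per_mbq=1000.0)
        ef = emitted_fraction(run, counts_per_mbq=1000.0)
        assert ef == pytest.approx(0.093, abs=0.005)

    def test_summarize_attaches_emitted_fraction(self):
        spec = AerosolSpec(0.55, 2.1)
        run = gen_impactor_run(spec, emitted_fraction=0.445, counts_per_mbq=1000.0)
        s = summarize(run, counts_per_mbq=1000.0)
        assert s.emitted_fraction == pytest.approx(0.445, rel=1e-9)
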