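"""Gompertz growth law, kill arithmetic, regimen builders, and the
per-cycle percentage-chain replay utility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemocycle.growth import (
    GrowthParams,
    Schedule,
    apply_kill,
    build_regimen,
    gompertz_growth,
    replay_reported_cycle_chain,
)

# frozen from an independent 40-digit evaluation of the Gompertz closed form
# at N = 5e9 cells, t = 1 month, b = 0.0283 /month, N_inf = 3.1e12
GOMPERTZ_ONE_MONTH = 5982558637.394447


class TestGompertz:
    def test_identity_at_zero_time(self):
        gp = GrowthParams()
        assert gompertz_growth(gp.n0, 0.0, gp) == pytest.approx(gp.n0, rel=1e-14)

    def test_saturates_at_carrying_capacity(self):
        gp = GrowthParams()
        assert gompertz_growth(gp.n0, 1e4, gp) == pytest.approx(gp.n_inf, rel=1e-6)

    def test_scalar_oracle(self):
        gp = GrowthParams()
        assert gompertz_growth(5e9, 1.0, gp) == pytest.approx(GOMPERTZ_ONE_MONTH, rel=1e-12)

    def test_healthy_tissue_uses_half_rate_and_own_capacity(self):
        gp = GrowthParams()
        full = gompertz_growth(1e12, 2.0, gp, carrying=gp.n1)
        half = gompertz_growth(1e12, 2.0, gp, rate_factor=0.5, carrying=gp.n1)
        same_as_half_time = gompertz_growth(1e12, 1.0, gp, carrying=gp.n1)
        assert half < full
        assert half == pytest.approx(same_as_half_time, rel=1e-12)

    def test_above_capacity_rejected(self):
        gp = GrowthParams()
        with pytest.raises(ValueError):
            gompertz_growth(gp.n_inf * 2, 1.0, gp)

    @settings(max_examples=50, deadline=None)
    @given(
        t1=st.floats(min_value=0.0, max_value=50.0),
        dt=st.floats(min_value=0.01, max_value=50.0),
        n=st.floats(min_value=1e6, max_value=3e12),
    )
    def test_monotone_in_time_and_slower_when_large(self, t1, dt, n):
        gp = GrowthParams()
        assert gompertz_growth(n, t1 + dt, gp) > gompertz_growth(n, t1, gp)
        # relative growth factor decreases with tumor size
        small = gompertz_growth(n / 2, 1.0, gp) / (n / 2)
        large = gompertz_growth(n, 1.0, gp) / n
        assert large <= small + 1e-12


class TestApplyKill:
    def test_limits_and_arithmetic(self):
        assert apply_kill(5e9, 0.0) == 5e9
        assert apply_kill(5e9, 1.0) == 0.0
        assert apply_kill(5e9, 0.3678) == pytest.approx(3.161e9, rel=1e-4)
        with pytest.raises(ValueError):
            apply_kill(5e9, 1.5)


class TestRegimens:
    def test_mtd_six_events_over_two_and_a_half_months(self):
        sched = build_regimen("MTD", 2.5)
        assert sched.times.tolist() == [0.0, 0.5, 1.0, 1.5, 2.0, 2.5]
        assert np.all(sched.doses == 1.0)

    def test_ldc_five_events_over_half_month(self):
        sched = build_regimen("LDC", 0.4999)
        assert len(sched.events) == 5
        assert np.all(sched.doses == 0.2)
        assert np.allclose(np.diff(sched.times), 0.1)

    def test_cs_block_pattern(self):
        sched = build_regimen("CS", 1.9999)
        doses = sched.doses
        times = sched.times
        # one full dose, a 0.5-month break, then five 0.2 doses 0.1 apart
        assert doses[0] == 1.0 and np.all(doses[1:6] == 0.2)
        assert times[1] - times[0] == pytest.approx(0.5)
        assert np.allclose(np.diff(times[1:6]), 0.1)
        # block repeats after 1.0 month
        assert doses[6] == 1.0 and times[6] == pytest.approx(1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_regimen("bolus", 1.0)

    def test_schedule_invariants(self):
        with pytest.raises(ValueError):
            Schedule(events=[(0.0, 1.0), (0.0, 1.0)], horizon_months=1.0)
        with pytest.raises(ValueError):
            Schedule(events=[(0.0, -1.0)], horizon_months=1.0)


class TestReplayChain:
    def test_single_kill(self):
        assert replay_reported_cycle_chain([50.0], []) == pytest.approx(50.0)

    def test_two_kills_one_regrowth(self):
        assert replay_reported_cycle_chain([10.0, 10.0], [5.0]) == pytest.approx(85.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            replay_reported_cycle_chain([10.0, 10.0], [5.0, 5.0])

    def test_negative_intermediate_rejected(self):
        with pytest.raises(ValueError):
            replay_reported_cycle_chain([60.0, 60.0], [1.0])
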