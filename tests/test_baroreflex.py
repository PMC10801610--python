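"""Sequence-method ramp detection, classification and BRS/BEI indices."""

import itertools

import numpy as np
import pytest

import autonomics as au
from autonomics.baroreflex import ClassifiedRamp, Ramp
from conftest import make_series


# --- independent brute-force oracle ---------------------------------------

def oracle_ramps(sbp, min_len=3, delta=1.0):
    """Enumerate every monotone window, keep maximal ones, then assign
    beats left to right (later ramps trimmed past used beats)."""
    n = len(sbp)
    candidates = []
    for start in range(n):
        for end in range(start + min_len - 1, n):
            steps = [sbp[i + 1] - sbp[i] for i in range(start, end)]
            for sign in (1, -1):
                if all(sign * s >= delta for s in steps):
                    candidates.append((start, end, "up" if sign == 1 else "down"))
    # maximal = not contained in a longer qualifying window of the same direction
    maximal = [c for c in candidates
               if not any(o != c and o[2] == c[2] and o[0] <= c[0] and o[1] >= c[1]
                          for o in candidates)]
    maximal.sort()
    out, last_used = [], -1
    for start, end, direction in maximal:
        start = max(start, last_used + 1)
        if end - start + 1 >= min_len:
            out.append((start, end, direction))
            last_used = end
    return out


def oracle_classify(start, end, direction, rr, max_lag=2, rr_delta=4.0):
    sign = 1.0 if direction == "up" else -1.0
    for k in range(max_lag + 1):
        if end + k >= len(rr):
            continue
        window = rr[start + k:end + k + 1]
        if all(sign * (window[i + 1] - window[i]) >= rr_delta
               for i in range(len(window) - 1)):
            return True, k
    return False, None


# --- detection -------------------------------------------------------------

class TestDetectRamps:
    def test_single_up_ramp(self):
        ramps = au.detect_ramps(np.array([120.0, 121.5, 123.0, 124.5]))
        assert len(ramps) == 1
        r = ramps[0]
        assert r.direction == "up" and list(r.beat_indices) == [0, 1, 2, 3]

    def test_constant_pressure_no_ramps(self):
        assert au.detect_ramps(np.full(20, 120.0)) == []

    def test_alternation_below_run_length_no_ramps(self):
        assert au.detect_ramps(np.array([120.0, 121.5, 120.0, 121.5])) == []

    def test_matches_bruteforce_on_random_series(self):
        grid = np.array([120.0, 121.5, 123.0])
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(3, 12)
            sbp = grid[rng.integers(0, 3, size=n)]
            got = [(r.beat_indices[0], r.beat_indices[-1], r.direction)
                   for r in au.detect_ramps(sbp)]
            assert got == oracle_ramps(list(sbp))


# --- classification --------------------------------------------------------

class TestClassifyRamp:
    def up_ramp(self):
        return Ramp("up", [1, 2, 3], [120.0, 122.0, 124.0])

    def test_lagged_concordant_response_effective(self):
        # lag 0 fails on the first RR step, lag 1 qualifies
        rr = np.array([805.0, 799.0, 800.0, 810.0, 820.0])
        cr = au.classify_ramp(self.up_ramp(), rr)
        assert cr.effective and cr.lag == 1
        assert np.array_equal(cr.rr_values, [800.0, 810.0, 820.0])

    def test_flat_rr_ineffective(self):
        cr = au.classify_ramp(self.up_ramp(), np.full(8, 800.0))
        assert not cr.effective and cr.reason == "discordant"

    def test_discordant_rr_ineffective(self):
        rr = np.array([850.0, 840.0, 830.0, 820.0, 810.0, 800.0])
        assert not au.classify_ramp(self.up_ramp(), rr).effective

    def test_truncated_ramp_reported(self):
        ramp = Ramp("up", [2, 3, 4], [120.0, 122.0, 124.0])
        cr = au.classify_ramp(ramp, np.array([800.0, 810.0, 820.0, 830.0]))
        assert not cr.effective and cr.reason == "truncated"

    def test_matches_bruteforce_over_lag_grid(self):
        rr_grid = np.array([800.0, 806.0, 812.0])
        ramp = self.up_ramp()
        for rr in itertools.product(rr_grid, repeat=6):
            cr = au.classify_ramp(ramp, np.array(rr))
            exp_eff, exp_lag = oracle_classify(1, 3, "up", list(rr))
            assert cr.effective == exp_eff and cr.lag == exp_lag


# --- slopes and aggregation ------------------------------------------------

class TestSequenceBrs:
    def test_collinear_sequence_slope(self):
        ramp = Ramp("up", [0, 1, 2], [120.0, 122.0, 124.0])
        cr = ClassifiedRamp(ramp, effective=True, lag=0,
                            rr_values=np.array([800.0, 810.0, 820.0]))
        res = au.sequence_brs([cr])
        assert res.brs_up == pytest.approx(5.0)
        assert res.brs_mean == pytest.approx(5.0)

    def test_constant_rr_zero_slope(self):
        ramp = Ramp("up", [0, 1, 2], [120.0, 122.0, 124.0])
        cr = ClassifiedRamp(ramp, effective=True, lag=0,
                            rr_values=np.array([800.0, 800.0, 800.0]))
        assert au.sequence_brs([cr]).brs_up == pytest.approx(0.0)

    def test_directional_mean_of_sequence_slopes(self):
        def eff(slope):
            sbp = np.array([120.0, 122.0, 124.0])
            rr = 800.0 + slope * (sbp - 120.0)
            return ClassifiedRamp(Ramp("up", [0, 1, 2], sbp), True, 0, rr)
        res = au.sequence_brs([eff(4.0), eff(6.0)])
        assert res.brs_up == pytest.approx(5.0)

    def test_endpoint_mode_equals_least_squares_on_collinear(self):
        sbp = np.array([118.0, 121.0, 124.0, 127.0])
        rr = 780.0 + 6.5 * (sbp - 118.0)
        cr = ClassifiedRamp(Ramp("up", [0, 1, 2, 3], sbp), True, 0, rr)
        a = au.sequence_brs([cr], slope_method="least_squares").brs_up
        b = au.sequence_brs([cr], slope_method="endpoint").brs_up
        assert a == pytest.approx(b) == pytest.approx(6.5)


class TestBaroreflexIndices:
    def test_bei_is_effective_fraction(self):
        # 10 up ramps, 7 with a concordant RR response
        sbp, rr = [], []
        for j in range(10):
            step = 8.0 if j < 7 else 0.0
            sbp += [120.0, 122.0, 124.0, 126.0, 123.0, 120.0]
            rr += [800.0, 800.0 + step, 800.0 + 2 * step,
                   800.0 + 3 * step, 800.0 + 3 * step, 800.0]
        series = make_series(rr, sbp=np.array(sbp))
        res = au.baroreflex_indices(series)
        assert res.br_up + res.brx_up == 10
        assert res.bei_up == pytest.approx(0.7)

    def test_flat_pressure_gives_undefined_result(self):
        series = make_series([800.0] * 50)
        res = au.baroreflex_indices(series)
        assert not res.defined
        assert np.isnan(res.brs_mean) and np.isnan(res.bei_up)

    def test_direction_symmetry_under_negation(self):
        rng = np.random.default_rng(5)
        n = 200
        sbp = 120.0 + np.round(rng.normal(0, 3, size=n), 1)
        rr = 800.0 + np.round(rng.normal(0, 10, size=n), 1)
        s1 = make_series(rr, sbp=sbp)
        s2 = make_series(2 * 800.0 - rr, sbp=2 * 120.0 - sbp)
        r1 = au.baroreflex_indices(s1)
        r2 = au.baroreflex_indices(s2)
        assert r1.br_up == r2.br_down and r1.brx_up == r2.brx_down
        assert r1.br_down == r2.br_up and r1.brx_down == r2.brx_up
        if np.isfinite(r1.brs_up):
            assert r1.brs_up == pytest.approx(r2.brs_down)
        if np.isfinite(r1.brs_down):
            assert r1.brs_down == pytest.approx(r2.brs_up)

    def test_raising_rr_threshold_never_raises_bei(self):
        series = au.simulate_beats(au.recovery_config(3))
        last = None
        for thresh in (0.0, 2.0, 4.0, 8.0, 16.0):
            res = au.baroreflex_indices(series, delta_rr=thresh)
            bei = np.nansum([res.bei_up, res.bei_down])
            if last is not None:
                assert bei <= last + 1e-12
            last = bei

    def test_recovers_generating_gain(self):
        vals = [au.baroreflex_indices(au.simulate_beats(au.recovery_config(s))).brs_mean
                for s in range(10)]
        assert abs(np.median(vals) / 6.0 - 1.0) < 0.15
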