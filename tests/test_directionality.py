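import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dispersalkit.data import CaptureRecord, build_trap_layout
from dispersalkit.directionality import (
    NetDisplacementTest,
    bootstrap_se,
    dispersal_scale,
    drift_fraction,
    project_displacements,
    weighted_pooled_mean,
    weighted_t_test,
)

LAYOUT = build_trap_layout("D170")


def _trap_at(x_sign=None, ring=40):
    """Pick a trap id on a given ring, optionally constrained in x."""
    for t in LAYOUT.traps:
        if t.ring_m == ring and (x_sign is None or np.sign(round(t.x, 6)) == x_sign):
            return t
    raise AssertionError("no such trap")


class TestProjection:
    def test_symmetric_pair_cancels(self):
        east = _trap_at(1)
        west = _trap_at(-1)
        caps = [CaptureRecord(1, east.trap_id, 1, n_male=1),
                CaptureRecord(1, west.trap_id, 1, n_male=1)]
        per = project_displacements(caps, LAYOUT)
        assert per.mean_x.iloc[0] == pytest.approx((east.x + west.x) / 2, abs=1e-9)

    def test_count_weighting(self):
        # 2 beetles in one record count twice in the mean
        east = _trap_at(1)
        west = _trap_at(-1)
        caps = [CaptureRecord(1, east.trap_id, 2, n_male=2),
                CaptureRecord(1, west.trap_id, 1, n_male=1)]
        per = project_displacements(caps, LAYOUT)
        assert per.mean_x.iloc[0] == pytest.approx((2 * east.x + west.x) / 3)
        assert per.n_captured.iloc[0] == 3

    def test_single_far_capture(self):
        far = max(LAYOUT.traps, key=lambda t: -t.y)  # southernmost trap
        per = project_displacements([CaptureRecord(1, far.trap_id, 1, n_male=1)], LAYOUT)
        assert per.mean_y.iloc[0] == pytest.approx(far.y)
        assert per.mean_y.iloc[0] < -900

    def test_no_captures_rejected(self):
        with pytest.raises(ValueError):
            project_displacements([], LAYOUT)


class TestPooling:
    def test_equal_weights(self):
        assert weighted_pooled_mean([10.0, 20.0], [5, 5]) == pytest.approx(15.0)

    def test_capture_count_weights(self):
        # normalized weights {0.5, 1.5}
        assert weighted_pooled_mean([10.0, 20.0], [2, 6]) == pytest.approx(17.5)

    def test_single_release(self):
        assert weighted_pooled_mean([42.0], [3]) == pytest.approx(42.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        means=st.lists(st.floats(-500, 500), min_size=1, max_size=6),
        scale=st.integers(min_value=2, max_value=50),
    )
    def test_invariant_to_count_rescaling(self, means, scale):
        n = np.arange(1, len(means) + 1)
        a = weighted_pooled_mean(means, n)
        b = weighted_pooled_mean(means, n * scale)
        assert a == pytest.approx(b, abs=1e-9)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_pooled_mean([1.0], [0])


class TestBootstrap:
    def test_identical_coordinates_zero_se(self):
        t = _trap_at(1)
        caps = [CaptureRecord(1, t.trap_id, 3, n_male=3), CaptureRecord(2, t.trap_id, 2, n_male=2)]
        assert bootstrap_se(caps, LAYOUT, "east_west", n_boot=300, seed=0) == pytest.approx(0.0, abs=1e-9)

    def test_seeded_reproducibility(self):
        caps = [
            CaptureRecord(1, _trap_at(1).trap_id, 2, n_male=2),
            CaptureRecord(1, _trap_at(-1).trap_id, 1, n_male=1),
            CaptureRecord(2, _trap_at(1, ring=80).trap_id, 2, n_male=2),
            CaptureRecord(2, _trap_at(-1, ring=80).trap_id, 3, n_male=3),
        ]
        a = bootstrap_se(caps, LAYOUT, "east_west", n_boot=500, seed=42)
        b = bootstrap_se(caps, LAYOUT, "east_west", n_boot=500, seed=42)
        assert a == b > 0

    def test_matches_analytic_se_two_equal_releases(self):
        # two releases, n=500 each, iid x in {+a, -a}: the pooled mean has
        # variance s^2 / (2n) with s the within-release SD
        rng = np.random.default_rng(3)
        east, west = _trap_at(1), _trap_at(-1)
        caps = []
        counts = {}
        for rel in (1, 2):
            ne = int(rng.binomial(500, 0.5))
            caps += [CaptureRecord(rel, east.trap_id, ne, n_male=ne),
                     CaptureRecord(rel, west.trap_id, 500 - ne, n_male=500 - ne)]
            counts[rel] = 500
        xs = np.array([east.x, west.x])
        s = xs.std(ddof=0)  # Bernoulli(1/2) mixture of the two x values
        analytic = s / np.sqrt(2 * 500)
        boot = bootstrap_se(caps, LAYOUT, "east_west", n_boot=2000, seed=9)
        assert boot == pytest.approx(analytic, rel=0.10)

    def test_minimum_replicates_enforced(self):
        caps = [CaptureRecord(1, _trap_at(1).trap_id, 1, n_male=1)]
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_se(caps, LAYOUT, "east_west", n_boot=50)


class TestTTest:
    def test_study_scale_example(self):
        # 5 m mean displacement, 23 m SE over six releases is clearly null
        t, df, p = weighted_t_test(5.0, 23.0, 6)
        assert t == pytest.approx(0.22, abs=0.005)
        assert df == 5
        assert p == pytest.approx(0.84, abs=0.005)

    def test_marginal_southward_drift_example(self):
        t, df, p = weighted_t_test(-114.0, 34.0, 4)
        assert t == pytest.approx(-3.35, abs=0.02)
        assert df == 3
        assert abs(p - 0.045) < 0.005

    def test_degenerate_se(self):
        assert weighted_t_test(0.0, 0.0, 3)[2] == 1.0
        assert weighted_t_test(5.0, 0.0, 3)[2] == 0.0

    def test_zero_mean(self):
        t, _, p = weighted_t_test(0.0, 10.0, 5)
        assert (t, p) == (0.0, 1.0)


class TestScale:
    def test_rms(self):
        assert dispersal_scale([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))
        assert dispersal_scale([7.0, 7.0, 7.0]) == pytest.approx(7.0)

    def test_drift_fraction_study_example(self):
        # 76 m westward drift over a 376 m dispersal scale ~ 20 %
        assert drift_fraction(-76.0, 376.0) == pytest.approx(0.20, abs=0.003)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dispersal_scale([])


class TestEndToEnd:
    def test_summary_consistency(self):
        caps = [
            CaptureRecord(1, _trap_at(1).trap_id, 3, n_male=3),
            CaptureRecord(1, _trap_at(-1).trap_id, 1, n_male=1),
            CaptureRecord(2, _trap_at(1, ring=80).trap_id, 2, n_male=2),
            CaptureRecord(2, _trap_at(-1, ring=80).trap_id, 2, n_male=2),
        ]
        res = NetDisplacementTest(caps, LAYOUT).fit_both(n_boot=400, seed=1)
        for axis, summ in res.items():
            assert summ.df == 1
            assert 0 <= summ.p_value <= 1
            assert summ.dispersal_scale > 0
            assert summ.drift_fraction == abs(summ.pooled_mean) / summ.dispersal_scale
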