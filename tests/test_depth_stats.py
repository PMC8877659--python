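"""Exact Mann-Whitney oracle equivalence, symmetry, and depth-wise comparison."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from saaidkit import (
    SAAIDProfile,
    depthwise_compare,
    mann_whitney_u,
    pvalue_frame,
    sensitive_depth,
)


def _pair_u_less(xs, ys):
    """Direct pairwise count of x<y plus half ties (no ranks)."""
    u = 0.0
    for xv in xs:
        for yv in ys:
            if xv < yv:
                u += 1.0
            elif xv == yv:
                u += 0.5
    return u


def brute_force_mw(x, y):
    """Independent oracle: enumerate every group assignment by pair counting.

    Two-sided p is twice the smaller tail of the observed x<y pair count
    (with half-credit for ties), capped at 1.
    """
    pooled = list(x) + list(y)
    n1, n = len(x), len(x) + len(y)
    n2 = n - n1
    obs = _pair_u_less(x, y)
    lower = upper = total = 0
    for idx in combinations(range(n), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        u1 = _pair_u_less(xs, ys)
        total += 1
        if u1 <= obs + 1e-9:
            lower += 1
        if u1 >= obs - 1e-9:
            upper += 1
    return min(obs, n1 * n2 - obs), min(1.0, 2.0 * min(lower, upper) / total)


class TestExactTest:
    def test_complete_separation_at_n5(self):
        res = mann_whitney_u([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], mode="exact")
        assert res.u == 0
        assert res.p_value == pytest.approx(2 / 252)

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3], mode="exact")
        assert res.p_value == 1.0

    def test_tied_pairs_enumeration(self):
        res = mann_whitney_u([1, 2], [1, 2], mode="exact")
        assert res.u == 2.0
        assert res.p_value == 1.0

    @given(
        n1=st.integers(1, 8),
        n2=st.integers(1, 8),
        data=st.data(),
    )
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_matches_brute_force_with_ties(self, n1, n2, data):
        """Exact mode equals assignment-by-assignment enumeration, ties included."""
        draw = st.integers(0, 6)  # small support forces plenty of ties
        x = [data.draw(draw) for _ in range(n1)]
        y = [data.draw(draw) for _ in range(n2)]
        res = mann_whitney_u(x, y, mode="exact")
        u_ref, p_ref = brute_force_mw(x, y)
        assert res.u == pytest.approx(u_ref)
        assert res.p_value == pytest.approx(p_ref)

    @given(
        x=st.lists(st.floats(-50, 50), min_size=2, max_size=8, unique=True),
        y=st.lists(st.floats(-50, 50), min_size=2, max_size=8, unique=True),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_in_arguments(self, x, y):
        a = mann_whitney_u(x, y, mode="exact")
        b = mann_whitney_u(y, x, mode="exact")
        assert a.u == pytest.approx(b.u)
        assert a.p_value == pytest.approx(b.p_value)

    def test_scipy_cross_check_tie_free(self, rng):
        """Independent route: scipy's exact test on tie-free samples."""
        for _ in range(25):
            x = rng.permutation(40)[:6].astype(float)
            y = (rng.permutation(40)[:7] + 0.5).astype(float)
            ours = mann_whitney_u(x, y, mode="exact")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approx_close_to_exact_at_moderate_n(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 12)
        exact = mann_whitney_u(x, y, mode="exact")
        approx = mann_whitney_u(x, y, mode="normal")
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_auto_switches_on_enumeration_size(self, rng):
        small = mann_whitney_u(rng.normal(size=5), rng.normal(size=5))
        big = mann_whitney_u(rng.normal(size=15), rng.normal(size=15))
        assert small.mode == "exact" and big.mode == "normal"

    def test_location_shift_does_not_raise_one_sided_evidence(self, rng):
        """Shifting y upward can only strengthen (not weaken) x<y separation."""
        x = np.sort(rng.normal(0, 1, 6))
        y = np.sort(rng.normal(0, 1, 6)) + 0.1
        u0 = mann_whitney_u(x, y, mode="exact")
        u1 = mann_whitney_u(x, y + 5.0, mode="exact")
        assert u1.u <= u0.u

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


def _profiles(matrix, group, day=14):
    """One SAAIDProfile per row of ``matrix`` (animal-level values)."""
    depths = np.arange(matrix.shape[1]) * 4.0
    return [
        SAAIDProfile(depths, row, {"animal": f"{group}_m{i}", "group": group, "day": day})
        for i, row in enumerate(matrix)
    ]


class TestDepthwiseCompare:
    def test_identical_groups_all_p_one(self):
        mat = np.tile(np.linspace(-0.3, 0.3, 4), (5, 1))
        prof = depthwise_compare(_profiles(mat, "a"), _profiles(mat, "b"))
        assert np.all(prof.p[prof.tested] == 1.0)
        assert not prof.significant.any()

    def test_separated_depths_flagged(self, rng):
        a = rng.normal(0.0, 0.02, (5, 4))
        b = rng.normal(0.0, 0.02, (5, 4))
        b[:, 2:] += 0.5  # strong separation at the two deep depths
        prof = depthwise_compare(_profiles(a, "healthy"), _profiles(b, "wound"))
        assert list(prof.significant) == [False, False, True, True]
        assert np.all(prof.u[prof.tested] <= prof.n1[prof.tested] * prof.n2[prof.tested])

    def test_insufficient_data_marked_untested(self):
        a = np.full((5, 3), 0.1)
        a[1:, 0] = np.nan  # only one defined value at depth 0
        prof = depthwise_compare(_profiles(a, "a"), _profiles(np.full((5, 3), 0.2), "b"))
        assert not prof.tested[0] and prof.tested[1]

    def test_holm_adjustment_is_monotone_and_conservative(self, rng):
        a = rng.normal(0, 0.02, (5, 5))
        b = rng.normal(0.4, 0.02, (5, 5))
        raw = depthwise_compare(_profiles(a, "a"), _profiles(b, "b"))
        adj = depthwise_compare(_profiles(a, "a"), _profiles(b, "b"), adjust="holm")
        assert np.all(adj.p[adj.tested] >= raw.p[raw.tested] - 1e-12)

    def test_grid_mismatch_rejected(self):
        a = _profiles(np.zeros((3, 4)), "a")
        b = [
            SAAIDProfile(np.arange(4) * 8.0, np.zeros(4), {"animal": f"b{i}", "group": "b"})
            for i in range(3)
        ]
        with pytest.raises(ValueError, match="depth grids"):
            depthwise_compare(a, b)

    def test_tidy_frame(self, rng):
        prof = depthwise_compare(
            _profiles(rng.normal(size=(5, 3)) * 0.1, "a"),
            _profiles(rng.normal(size=(5, 3)) * 0.1, "b"),
        )
        df = pvalue_frame([prof])
        assert len(df) == 3
        assert {"U", "p", "n1", "n2", "significant"} <= set(df.columns)


class TestSensitiveDepth:
    def test_unique_minimum_centres_interval(self):
        depths = np.array([40.0, 44, 48, 52, 56])
        prof = _fake_profile(depths, [0.5, 0.3, 0.004, 0.3, 0.5])
        interval = sensitive_depth(prof)
        assert interval.localized
        assert interval.low_um <= 48.0 <= interval.high_um
        assert interval.high_um - interval.low_um <= 8.0

    def test_flat_profile_returns_whole_range_unlocalized(self):
        prof = _fake_profile(np.arange(5) * 4.0, [0.2] * 5)
        interval = sensitive_depth(prof)
        assert not interval.localized
        assert (interval.low_um, interval.high_um) == (0.0, 16.0)

    def test_tie_breaks_to_shallower_depth(self):
        prof = _fake_profile(np.arange(5) * 4.0, [0.5, 0.01, 0.4, 0.01, 0.5])
        interval = sensitive_depth(prof, factor=1.0)
        assert interval.low_um == 4.0 and interval.high_um == 4.0

    def test_too_few_tested_depths_rejected(self):
        prof = _fake_profile(np.array([0.0, 4.0]), [0.5, 0.1])
        with pytest.raises(ValueError, match="3 tested"):
            sensitive_depth(prof)

    def test_aggregates_over_multiple_profiles(self):
        depths = np.arange(6) * 4.0
        a = _fake_profile(depths, [0.9, 0.9, 0.02, 0.9, 0.9, 0.9])
        b = _fake_profile(depths, [0.9, 0.9, 0.03, 0.9, 0.9, 0.9])
        interval = sensitive_depth([a, b])
        assert interval.low_um <= 8.0 <= interval.high_um


def _fake_profile(depths, pvals):
    from saaidkit import DepthPValueProfile

    pvals = np.asarray(pvals, float)
    k = pvals.size
    return DepthPValueProfile(
        depths_um=np.asarray(depths, float),
        u=np.zeros(k),
        p=pvals,
        n1=np.full(k, 5),
        n2=np.full(k, 5),
        significant=pvals < 0.05,
        tested=np.ones(k, dtype=bool),
    )
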