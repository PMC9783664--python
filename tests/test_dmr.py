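"""DMR calling: coverage filter, t statistics, cutoffs, region finding, filters."""

import numpy as np
import pandas as pd
import pytest

from methylrad import (
    DMR,
    SmoothedProfile,
    TStatTrack,
    compute_tstats,
    count_directions,
    filter_coverage,
    find_regions,
    quantile_cutoffs,
    select_significant,
    select_top,
)
from tests.conftest import make_matrix


def make_profile(pos, smoothed, groups, chrom="chr1"):
    smoothed = np.atleast_2d(np.asarray(smoothed, dtype=float))
    samples = [f"s{i}" for i in range(smoothed.shape[1])]
    return SmoothedProfile(
        sites=pd.DataFrame({"chrom": chrom, "pos": np.asarray(pos, dtype=int)}),
        samples=samples,
        smoothed=smoothed,
        groups=dict(zip(samples, groups)),
    )


def make_track(pos, t, diff=None, chrom="chr1"):
    t = np.asarray(t, dtype=float)
    diff = t * 0.01 if diff is None else np.asarray(diff, dtype=float)
    return TStatTrack(
        sites=pd.DataFrame({"chrom": chrom, "pos": np.asarray(pos, dtype=int)}),
        tstat=t,
        mean_diff=diff,
    )


class TestCoverageFilter:
    def test_threshold_arithmetic(self):
        cov = np.array([[12, 11, 10, 9, 15, 15, 15, 0]])
        m = make_matrix([100], cov, np.zeros_like(cov), ["a"] * 4 + ["b"] * 4)
        assert filter_coverage(m).n_sites == 1

    def test_two_qualifying_samples_is_dropped(self):
        cov = np.array([[12, 11, 9, 9, 15, 15, 15, 15]])
        m = make_matrix([100], cov, np.zeros_like(cov), ["a"] * 4 + ["b"] * 4)
        assert filter_coverage(m).n_sites == 0

    def test_small_group_unsatisfiable(self):
        cov = np.array([[12, 11, 15, 15]])
        m = make_matrix([100], cov, np.zeros_like(cov), ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="unsatisfiable"):
            filter_coverage(m, min_samples=3)

    def test_matches_bruteforce_double_loop(self, rng):
        for _ in range(10):
            n = 50
            cov = rng.poisson(9, size=(n, 8))
            groups = ["a"] * 4 + ["b"] * 4
            m = make_matrix(
                np.arange(1, n + 1) * 10, cov, np.zeros_like(cov), groups
            )
            got = filter_coverage(m).n_sites
            want = 0
            for i in range(n):
                ok = True
                for g in ("a", "b"):
                    count = sum(
                        cov[i, j] >= 10 for j in range(8) if groups[j] == g
                    )
                    ok &= count >= 3
                want += ok
            assert got == want


class TestTStats:
    def test_identical_groups_give_zero(self):
        sm = np.tile([[0.4, 0.4, 0.4, 0.4]], (30, 1))
        prof = make_profile(np.arange(30) * 100 + 1, sm, ["a", "a", "b", "b"])
        track = compute_tstats(prof, "a", "b")
        np.testing.assert_array_equal(track.tstat, 0.0)

    def test_label_swap_negates(self, rng):
        sm = rng.uniform(0.2, 0.8, size=(60, 6))
        prof = make_profile(np.arange(60) * 50 + 1, sm, ["a"] * 3 + ["b"] * 3)
        t1 = compute_tstats(prof, "a", "b").tstat
        t2 = compute_tstats(prof, "b", "a").tstat
        np.testing.assert_allclose(t2, -t1, atol=1e-12)

    def test_single_sample_group_rejected(self, rng):
        sm = rng.uniform(size=(10, 3))
        prof = make_profile(np.arange(10) * 50 + 1, sm, ["a", "b", "b"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            compute_tstats(prof, "a", "b")

    def test_matches_direct_formula_with_flooring(self, rng):
        n1, n2, n = 4, 4, 50
        sm = rng.uniform(0.1, 0.9, size=(n, n1 + n2))
        prof = make_profile(np.arange(n) * 80 + 1, sm, ["a"] * n1 + ["b"] * n2)
        track = compute_tstats(prof, "a", "b", sd_floor_quantile=0.75)
        a, b = sm[:, :n1], sm[:, n1:]
        sd_pool = np.array(
            [
                np.sqrt(((n1 - 1) * np.var(a[i], ddof=1) + (n2 - 1) * np.var(b[i], ddof=1))
                        / (n1 + n2 - 2))
                for i in range(n)
            ]
        )
        floor = np.quantile(sd_pool, 0.75)
        want = (a.mean(1) - b.mean(1)) / (np.maximum(sd_pool, floor) * np.sqrt(1 / n1 + 1 / n2))
        np.testing.assert_allclose(track.tstat, want, atol=1e-12)


class TestQuantileCutoffs:
    def test_extreme_quantiles(self):
        track = make_track(np.arange(5) * 10 + 1, [-2, -1, 0, 1, 2])
        with pytest.warns(UserWarning, match="unstable"):
            lo, hi = quantile_cutoffs(track, 0.0, 1.0)
        assert (lo, hi) == (-2.0, 2.0)

    def test_negation_symmetry(self, rng):
        t = rng.normal(size=500)
        lo1, hi1 = quantile_cutoffs(t, 0.01, 0.99)
        lo2, hi2 = quantile_cutoffs(-t, 0.01, 0.99)
        assert lo2 == pytest.approx(-hi1) and hi2 == pytest.approx(-lo1)

    def test_matches_sort_and_interpolate_oracle(self, rng):
        for _ in range(20):
            t = rng.normal(size=int(rng.integers(100, 400)))
            lo, hi = quantile_cutoffs(t, 0.01, 0.99)
            s = np.sort(t)
            for q, got in ((0.01, lo), (0.99, hi)):
                h = (len(s) - 1) * q  # type-7 plotting position
                f = int(np.floor(h))
                want = s[f] + (h - f) * (s[min(f + 1, len(s) - 1)] - s[f])
                assert got == pytest.approx(want, abs=1e-12)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            quantile_cutoffs(np.array([]))


def brute_force_regions(pos, t, cutoffs, max_gap, min_size):
    """Enumerate maximal qualifying runs by direct scanning."""
    lo, hi = cutoffs
    out = []
    for direction, ok in (("hyper", t >= hi), ("hypo", t <= lo)):
        run = []
        for i in range(len(pos)):
            if ok[i] and (not run or (run[-1] == i - 1 and pos[i] - pos[i - 1] <= max_gap)):
                run.append(i)
            else:
                if len(run) >= min_size:
                    out.append((direction, run[0], run[-1]))
                run = [i] if ok[i] else []
        if len(run) >= min_size:
            out.append((direction, run[0], run[-1]))
    return sorted(out, key=lambda r: (r[1], r[0]))


class TestFindRegions:
    def test_no_site_beyond_cutoffs(self):
        track = make_track(np.arange(10) * 50 + 1, np.zeros(10))
        assert find_regions(track, (-2, 2)) == []

    def test_constructed_run(self):
        track = make_track(np.arange(5) * 50 + 1, [3.0] * 5)
        (dmr,) = find_regions(track, (-2, 2))
        assert dmr.direction == "hyper" and dmr.n_cpgs == 5
        assert dmr.area == pytest.approx(15.0)
        assert (dmr.start, dmr.end) == (1, 201)

    def test_gap_splits_run(self):
        pos = [1, 51, 101, 1001, 1051, 1101]
        track = make_track(pos, [3.0] * 6)
        dmrs = find_regions(track, (-2, 2), max_gap=300)
        assert [(d.start, d.end) for d in dmrs] == [(1, 101), (1001, 1101)]

    def test_membership_is_inclusive_at_cutoff(self):
        track = make_track([1, 51, 101], [2.0, 2.0, 2.0])
        assert len(find_regions(track, (-2, 2.0))) == 1

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 120))
            pos = np.cumsum(rng.integers(10, 400, size=n)) + 1
            t = rng.normal(scale=2.0, size=n)
            cutoffs = (-float(rng.uniform(1, 3)), float(rng.uniform(1, 3)))
            dmrs = find_regions(make_track(pos, t), cutoffs, max_gap=300, min_cpgs_region=2)
            got = sorted(
                (d.direction, int(np.searchsorted(pos, d.start)),
                 int(np.searchsorted(pos, d.end)))
                for d in dmrs
            )
            want = sorted(brute_force_regions(pos, t, cutoffs, 300, 2))
            assert got == want
            for d in dmrs:  # area = sum |t| over members (additivity)
                members = (pos >= d.start) & (pos <= d.end)
                sel = members & ((t >= cutoffs[1]) if d.direction == "hyper" else (t <= cutoffs[0]))
                assert d.area == pytest.approx(np.abs(t[sel]).sum())

    def test_label_swap_antisymmetry(self, rng):
        sm = rng.uniform(0.1, 0.9, size=(200, 8))
        sm[40:60, :4] += 0.5  # strong group difference
        sm = np.clip(sm, 0, 1)
        prof = make_profile(np.arange(200) * 50 + 1, sm, ["a"] * 4 + ["b"] * 4)
        t_ab = compute_tstats(prof, "a", "b")
        t_ba = compute_tstats(prof, "b", "a")
        cuts = quantile_cutoffs(t_ab, 0.05, 0.95)
        d_ab = find_regions(t_ab, cuts)
        d_ba = find_regions(t_ba, (-cuts[1], -cuts[0]))
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert [(d.chrom, d.start, d.end, flip[d.direction], round(d.area, 9)) for d in d_ab] == [
            (d.chrom, d.start, d.end, d.direction, round(d.area, 9)) for d in d_ba
        ]

    def test_raising_cutoff_only_shrinks_hyper_regions(self, rng):
        pos = np.cumsum(rng.integers(10, 200, size=300)) + 1
        t = rng.normal(scale=2, size=300)
        track = make_track(pos, t)
        low = find_regions(track, (-10, 1.5), min_cpgs_region=1)
        high = find_regions(track, (-10, 2.5), min_cpgs_region=1)
        for d in high:
            assert any(o.start <= d.start and d.end <= o.end for o in low)


class TestSelection:
    def d(self, p=None, diff=0.3, direction="hyper"):
        return DMR("chr1", 1, 100, 3, direction, diff, 9.0, p=p)

    def test_strict_p_boundary(self):
        dmrs = [self.d(0.04), self.d(0.05), self.d(0.06)]
        assert select_significant(dmrs) == [dmrs[0]]
        assert select_significant(dmrs, alpha=1.0) == dmrs

    def test_unset_p_rejected(self):
        with pytest.raises(ValueError, match="unset"):
            select_significant([self.d()])

    def test_top_filter_conjunction(self):
        keep = self.d(0.04, 0.30)
        assert select_top([keep, self.d(0.04, 0.20), self.d(0.06, 0.40)]) == [keep]
        assert select_top([self.d(0.04, -0.40)]) != []  # absolute difference

    def test_selection_counts_match_bruteforce(self, rng):
        dmrs = [self.d(float(p), float(m)) for p, m in
                zip(rng.uniform(size=50), rng.uniform(-0.6, 0.6, size=50))]
        assert len(select_significant(dmrs)) == sum(1 for d in dmrs if d.p < 0.05)
        assert len(select_top(dmrs)) == sum(
            1 for d in dmrs if d.p < 0.05 and abs(d.mean_diff) > 0.25
        )

    def test_direction_tallies(self):
        assert count_directions([]) == (0, 0)
        dmrs = [self.d(0.01)] * 3 + [self.d(0.01, direction="hypo")] * 2
        assert count_directions(dmrs) == (3, 2)
        n_hyper, n_hypo = count_directions(dmrs)
        assert n_hyper + n_hypo == len(dmrs)
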