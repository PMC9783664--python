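"""Synthetic-data generators: validity, determinism, exchangeability, scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylrad import DMR, SimulationConfig
from methylrad.simulate import (
    PlantedDMR,
    evaluate_recovery,
    interval_jaccard,
    simulate_cpg_landscape,
    simulate_elisa,
    simulate_methylation,
    simulate_outcomes,
    simulate_qpcr,
)


class TestLandscape:
    def test_expected_site_count(self):
        cfg = SimulationConfig(chrom_length=10_000, mean_spacing=100.0, seed=3)
        sites = simulate_cpg_landscape(cfg)
        # renewal process: count ~ L/mu with sd ~ sqrt(L sigma^2 / mu^3) ~ 10
        assert abs(len(sites) - 100) <= 30

    def test_deterministic_and_increasing(self):
        cfg = SimulationConfig(seed=9)
        a = simulate_cpg_landscape(cfg)
        b = simulate_cpg_landscape(cfg)
        pd.testing.assert_frame_equal(a, b)
        for _, sub in a.groupby("chrom"):
            assert (np.diff(sub["pos"]) > 0).all()
            assert (np.diff(sub["pos"]) >= 2).all()

    def test_spacing_below_min_gap_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            SimulationConfig(mean_spacing=1.0)


class TestMethylationSim:
    def test_counts_valid_and_deterministic(self):
        cfg = SimulationConfig(seed=5, chrom_length=50_000, n_dmrs=5)
        m1, t1 = simulate_methylation(cfg)
        m2, _ = simulate_methylation(cfg)
        assert (m1.methylated <= m1.coverage).all()
        np.testing.assert_array_equal(m1.coverage, m2.coverage)
        np.testing.assert_array_equal(m1.methylated, m2.methylated)

    def test_planted_truth_contract(self):
        cfg = SimulationConfig(seed=8)
        matrix, truth = simulate_methylation(cfg)
        assert len(truth.dmrs) == cfg.n_dmrs
        spans = sorted((d.start, d.end) for d in truth.dmrs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2  # disjoint
        pos = matrix.sites["pos"].to_numpy()
        pi0 = truth.profiles["sham"]
        pi1 = truth.profiles["irradiated"]
        inside = np.zeros(len(pos), dtype=bool)
        for d in truth.dmrs:
            sel = (pos >= d.start) & (pos <= d.end)
            inside |= sel
            shift = cfg.delta_pi if d.direction == "hyper" else -cfg.delta_pi
            np.testing.assert_allclose(pi1[sel] - pi0[sel], shift, atol=1e-12)
            assert sel.sum() == d.n_cpgs
        np.testing.assert_array_equal(pi1[~inside], pi0[~inside])
        assert (pi0 >= 0.02).all() and (pi0 <= 0.98).all()

    def test_null_groups_exchangeable(self):
        cfg = SimulationConfig(seed=21, delta_pi=0.0, chrom_length=200_000)
        matrix, _ = simulate_methylation(cfg)
        frac = matrix.fractions()
        g1 = frac[:, matrix.sample_indices("sham")].ravel()
        g2 = frac[:, matrix.sample_indices("irradiated")].ravel()
        assert stats.ks_2samp(g1, g2).pvalue > 0.01

    def test_law_of_large_numbers_limit(self):
        cfg = SimulationConfig(
            seed=2, chrom_length=20_000, coverage_lambda=10_000,
            overdispersion=0.0, n_dmrs=0,
        )
        matrix, truth = simulate_methylation(cfg)
        frac = matrix.methylated / matrix.coverage
        err = np.abs(frac - truth.profiles["sham"][:, None])
        assert err.max() < 0.02


class TestQpcrSim:
    def test_noiseless_recovery_exact(self):
        from methylrad import delta_delta_ct

        table, _ = simulate_qpcr({"TG": 1.7}, ct_noise=0.0, seed=0)
        res = delta_delta_ct(table, "TG", "PHLPP1", "irradiated", "sham")
        assert res.group_mean_log2fc == pytest.approx(1.7, abs=1e-12)

    def test_null_gene_within_three_sem(self):
        from methylrad import delta_delta_ct

        ok = 0
        for seed in range(10):
            table, _ = simulate_qpcr({"TG": 0.0}, ct_noise=0.2, seed=seed)
            res = delta_delta_ct(table, "TG", "PHLPP1", "irradiated", "sham")
            tol = 3 * res.group_sem_log2fc * np.sqrt(2)
            ok += abs(res.group_mean_log2fc) <= tol
        assert ok >= 9

    def test_same_seed_identical(self):
        a, _ = simulate_qpcr({"TG": 1.0}, seed=7)
        b, _ = simulate_qpcr({"TG": 1.0}, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestElisaSim:
    def test_noiseless_round_trip_exact(self):
        from methylrad import compute_5mc_percent, fit_standard_slope

        truth = {"s1": 2.5, "s2": 4.0}
        plate, gt = simulate_elisa(truth, od_noise=0.0, seed=0)
        slope = fit_standard_slope(plate.standards, plate.nc_od)
        assert slope == pytest.approx(gt.true_slope, abs=1e-12)
        for sid, od, dna in plate.samples:
            pct = compute_5mc_percent(od, plate.nc_od, slope, dna)
            assert pct == pytest.approx(truth[sid], abs=1e-12)

    def test_halving_dna_keeps_recovered_percent(self):
        from methylrad import compute_5mc_percent, fit_standard_slope

        for dna in (50.0, 100.0):
            plate, _ = simulate_elisa({"s1": 3.0}, dna_ng=dna, od_noise=0.0)
            slope = fit_standard_slope(plate.standards, plate.nc_od)
            sid, od, d = plate.samples[0]
            assert compute_5mc_percent(od, plate.nc_od, slope, d) == pytest.approx(3.0)


class TestOutcomesSim:
    def test_perfect_correlation_is_affine(self, rng):
        x = pd.Series(rng.normal(size=20), index=[f"p{i}" for i in range(20)])
        out, _ = simulate_outcomes(x, true_r=1.0, seed=0)
        r = np.corrcoef(x.to_numpy(), out["value"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_null_correlation_small(self, rng):
        x = pd.Series(rng.normal(size=1000), index=[f"p{i}" for i in range(1000)])
        out, _ = simulate_outcomes(x, true_r=0.0, seed=1)
        assert abs(np.corrcoef(x.to_numpy(), out["value"])[0, 1]) < 0.1

    def test_constant_measures_rejected(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            simulate_outcomes(x, true_r=0.5)
        out, _ = simulate_outcomes(x, true_r=0.0, seed=0)
        assert len(out) == 3


def called(start, end, direction="hyper"):
    return DMR("chr1", start, end, 3, direction, 0.3, 9.0)


def planted(start, end, direction="hyper"):
    return PlantedDMR("chr1", start, end, 3, direction, 0.3)


class TestRecovery:
    def test_exact_match(self):
        truth = [planted(100, 200), planted(500, 700)]
        rec = evaluate_recovery([called(100, 200), called(500, 700)], truth)
        assert rec.sensitivity == 1.0 and rec.fdr == 0.0

    def test_no_calls_flagged(self):
        rec = evaluate_recovery([], [planted(1, 10)])
        assert rec.sensitivity == 0.0 and rec.fdr == 0.0 and rec.no_calls

    def test_jaccard_threshold(self):
        truth = [planted(100, 199)]
        assert evaluate_recovery([called(100, 149)], truth).sensitivity == 1.0  # J=0.5
        assert evaluate_recovery([called(100, 139)], truth).sensitivity == 0.0  # J=0.4

    def test_one_to_one_matching(self):
        truth = [planted(100, 200)]
        rec = evaluate_recovery([called(100, 200), called(101, 200)], truth)
        assert rec.sensitivity == 1.0 and rec.fdr == pytest.approx(0.5)

    def test_matches_bruteforce_optimal_assignment(self, rng):
        """Greedy matching attains the exhaustive maximum on small instances.

        With planted intervals disjoint (the generator's invariant) a call
        cannot reach Jaccard >= 0.5 with two planted intervals at once, so
        the overlap graph is a union of stars and greedy is optimal.
        """
        from itertools import combinations, permutations

        for _ in range(50):
            starts = np.cumsum(rng.integers(200, 500, size=5))
            truth = [planted(int(s), int(s + rng.integers(20, 150))) for s in starts[:-1]]
            calls = []
            for _ in range(int(rng.integers(0, 6))):
                s = int(rng.integers(1, starts[-1]))
                calls.append(called(s, s + int(rng.integers(10, 180))))
            rec = evaluate_recovery(calls, truth)

            def qualifies(ti, ci):
                return interval_jaccard(
                    (truth[ti].start, truth[ti].end),
                    (calls[ci].start, calls[ci].end),
                ) >= 0.5

            best = 0
            for k in range(min(len(truth), len(calls)), 0, -1):
                for tsub in combinations(range(len(truth)), k):
                    for csub in permutations(range(len(calls)), k):
                        if all(qualifies(t, c) for t, c in zip(tsub, csub)):
                            best = k
                            break
                    if best:
                        break
                if best:
                    break
            assert len(rec.matches) == best
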