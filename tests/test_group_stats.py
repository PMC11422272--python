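"""Rank-test battery vs independent enumeration oracles; census and flags."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from fishmetals.group_stats import (
    ConstantInputError,
    correlation_census,
    kruskal_wallis,
    mann_whitney,
    normality_screen,
    seasonal_flags,
    spearman,
)
from fishmetals.synthetic_data import GeneratorConfig, generate


# ---------------------------------------------------------------------------
# Independent oracles (brute-force enumeration, no reuse of package code)
# ---------------------------------------------------------------------------

def oracle_kw_p(groups):
    """Exact KW p by enumerating every assignment of observations to groups."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    sizes = [len(g) for g in groups]
    n = pooled.size
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)

    def h_of(assign):
        h, start = 0.0, 0
        for m in sizes:
            r = sum(ranks[i] for i in assign[start:start + m])
            h += r * r / m
            start += m
        return (12 / (n * (n + 1)) * h - 3 * (n + 1)) / tie

    h_obs = h_of(list(range(n)))
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if h_of(perm) >= h_obs - 1e-12:
            hits += 1
    return h_obs, hits / total


def oracle_mwu_p(a, b):
    """Exact two-sided MWU p by enumerating every split of the pooled sample."""
    pooled = list(a) + list(b)
    na = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = sum(ranks[:na]) - na * (na + 1) / 2
    mean_u = na * (len(pooled) - na) / 2
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        u = sum(ranks[i] for i in comb) - na * (na + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            hits += 1
    return hits / total


def oracle_spearman_p(x, y):
    """Exact two-sided Spearman p over all permutations of y."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rho_obs) - 1e-12:
            hits += 1
    return rho_obs, hits / total


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_identical_groups_no_effect(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]], method="asymptotic")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "groups",
        [
            ([1, 2, 3], [4, 5, 6], [7, 8, 9]),
            ([1.5, 2.2, 9.1], [0.3, 4.4, 5.5], [2.9, 3.3]),
            ([1, 1, 2], [3, 1, 2], [5, 6]),  # ties across groups
        ],
    )
    def test_exact_p_matches_enumeration_oracle(self, groups):
        h_oracle, p_oracle = oracle_kw_p(groups)
        res = kruskal_wallis(groups, method="exact")
        assert res.statistic == pytest.approx(h_oracle, rel=1e-9)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)

    def test_tie_corrected_h_hand_formula(self):
        # {1,1,1} vs {1,1,2}: ranks are 3,3,3,3,3,6 (five ties at 1)
        # H_raw = 12/(6*7) * (9^2/3 + 12^2/3) - 3*7 = 3/7
        # C = 1 - (5^3-5)/(6^3-6) = 3/7, so H = 1 exactly
        res = kruskal_wallis([[1, 1, 1], [1, 1, 2]], method="asymptotic")
        expected = (12 / 42 * (81 / 3 + 144 / 3) - 21) / (1 - 120 / 210)
        assert expected == pytest.approx(1.0)
        assert res.statistic == pytest.approx(expected, rel=1e-9)

    def test_asymptotic_matches_scipy_chi2(self):
        groups = [[3.1, 4.5, 2.2, 8], [5.5, 6.1, 7.7], [1.1, 9.9, 0.5]]
        res = kruskal_wallis(groups, method="asymptotic")
        h, p = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(h)
        assert res.p_value == pytest.approx(p)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="n=1"):
            kruskal_wallis([[1], [2, 3]])


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_identical_multisets(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_full_separation_exact(self):
        res = mann_whitney([1, 2, 3], [10, 11, 12], method="exact")
        assert res.statistic in (0.0, 9.0)
        assert res.p_value == pytest.approx(0.1)  # 2/C(6,3)

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1.2, 5.5, 3.3], [2.2, 7.7, 0.1, 9.9]),
            ([10, 20, 30, 40, 50], [15, 25, 35]),
        ],
    )
    def test_exact_p_matches_enumeration_oracle(self, a, b):
        res = mann_whitney(a, b, method="exact")
        assert res.p_value == pytest.approx(oracle_mwu_p(a, b), rel=1e-9)

    def test_swap_symmetry(self):
        a, b = [1.0, 4.0, 2.5], [3.0, 6.0, 5.0, 7.0]
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r2.statistic == pytest.approx(len(a) * len(b) - r1.statistic)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_extremes(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 9, 11, 30]).statistic == pytest.approx(1.0)
        assert spearman(x, [30, 11, 9, 4, 2]).statistic == pytest.approx(-1.0)

    def test_exact_p_matches_full_permutation_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.3, 1.1, 4.4, 3.2, 6.8, 5.0]
        rho_oracle, p_oracle = oracle_spearman_p(x, y)  # 720 permutations
        res = spearman(x, y, method="exact")
        assert res.statistic == pytest.approx(rho_oracle, rel=1e-9)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)

    def test_constant_vector_is_explicit_outcome(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 2, 3, 4], [5, 5, 5, 5])

    def test_minimum_n(self):
        with pytest.raises(ValueError, match="n >= 4"):
            spearman([1, 2, 3], [1, 2, 3])


# ---------------------------------------------------------------------------
# Type-I calibration (null simulations)
# ---------------------------------------------------------------------------

class TestTypeICalibration:
    N_REPS = 500
    ALPHA = 0.05

    def _band(self, n_reps):
        se = math.sqrt(self.ALPHA * (1 - self.ALPHA) / n_reps)
        return self.ALPHA - 2 * se, self.ALPHA + 2 * se

    def test_mwu_null_rate(self):
        rng = np.random.default_rng(11)
        rate = np.mean([
            mann_whitney(rng.normal(size=8), rng.normal(size=8)).p_value < self.ALPHA
            for _ in range(self.N_REPS)
        ])
        lo, hi = self._band(self.N_REPS)
        assert lo <= rate <= hi

    def test_kw_null_rate(self):
        rng = np.random.default_rng(12)
        rate = np.mean([
            kruskal_wallis(
                [rng.normal(size=7) for _ in range(3)], method="asymptotic"
            ).p_value < self.ALPHA
            for _ in range(self.N_REPS)
        ])
        lo, hi = self._band(self.N_REPS)
        assert lo <= rate <= hi

    def test_spearman_null_rate(self):
        rng = np.random.default_rng(13)
        rate = np.mean([
            spearman(rng.normal(size=13), rng.normal(size=13)).p_value < self.ALPHA
            for _ in range(self.N_REPS)
        ])
        lo, hi = self._band(self.N_REPS)
        assert lo <= rate <= hi


# ---------------------------------------------------------------------------
# Census and seasonal verdicts on synthetic ground truth
# ---------------------------------------------------------------------------

class TestCorrelationCensus:
    def test_planted_tl_slope_detected(self):
        cfg = GeneratorConfig(seed=21, n_per_dam=15,
                              tl_slope={(3, "guts", "Pb"): 0.25})
        census = correlation_census(generate(cfg))
        hit = [e for e in census.entries
               if (e.dam_id, e.tissue, e.metal, e.variable) == (3, "guts", "Pb", "TL")]
        assert hit and hit[0].significant
        assert census.total_significant >= 1

    def test_total_equals_significant_rows(self, small_specimens):
        census = correlation_census(small_specimens)
        assert census.total_significant == sum(e.significant for e in census.entries)

    def test_null_rate_near_alpha_over_seeds(self):
        # pure-noise data: TL enters no concentration, so each of the
        # 11*4*4 = 176 TL cells is a null test at alpha = 0.05
        rates = []
        for seed in range(30):
            census = correlation_census(
                generate(GeneratorConfig(seed=100 + seed)), variables=("TL",)
            )
            rates.append(census.total_significant / len(census.entries))
        mean_rate = float(np.mean(rates))
        n_tests = 30 * 176
        se = math.sqrt(0.05 * 0.95 / n_tests)
        assert abs(mean_rate - 0.05) < 3 * se + 0.005

    def test_undersized_cells_skipped_and_logged(self, small_specimens):
        subset = [r for r in small_specimens if r.dam_id == 1][:3]
        census = correlation_census(subset)
        assert not census.entries
        assert census.skipped
        assert all("n=3" in reason for *_, reason in census.skipped)

    def test_bh_adjustment_is_opt_in_extension(self, small_specimens):
        plain = correlation_census(small_specimens)
        adj = correlation_census(small_specimens, adjust=True)
        assert all(e.q is None for e in plain.entries)
        assert all(e.q is not None and e.q >= e.p - 1e-12 for e in adj.entries)
        # significance still uses raw p (the study applied no correction)
        assert adj.total_significant == plain.total_significant


class TestSeasonalFlags:
    def test_identical_samples_not_different(self):
        cfg = GeneratorConfig(seed=31)
        recs = generate(cfg)
        for r in recs:
            for tissue in r.concentrations:
                for metal in r.concentrations[tissue]:
                    c = r.concentrations[tissue][metal]
                    r.concentrations[tissue][metal] = type(c)(1.0, c.basis)
        verdicts = seasonal_flags(recs, "muscle", "Cd")
        assert all(v.verdict == "not different" for v in verdicts)
        assert all(v.letters == ("a", "a") for v in verdicts)

    def test_planted_shift_detected(self):
        # large dry-season effect in muscle Zn, a low-CV cell in every dam
        # (factor 3 is ~4 log-SDs there), 7 fish per season
        cfg = GeneratorConfig(seed=32, n_per_dam=14,
                              season_effect={("muscle", "Zn"): 3.0})
        verdicts = seasonal_flags(generate(cfg), "muscle", "Zn")
        frac = np.mean([v.verdict == "different" for v in verdicts])
        assert frac >= 0.8
        assert all(v.letters == ("a", "b") for v in verdicts if v.verdict == "different")

    def test_missing_season_not_assessable(self, small_specimens):
        dry_only = [r for r in small_specimens if r.season == "dry"]
        verdicts = seasonal_flags(dry_only, "muscle", "Cd")
        assert verdicts and all(v.verdict == "not assessable" for v in verdicts)

    def test_null_flag_rate_calibrated(self):
        flags = []
        for seed in range(40):
            verdicts = seasonal_flags(
                generate(GeneratorConfig(seed=200 + seed, dams=(1, 2, 3, 4),
                                         tissues=("muscle",))),
                "muscle", "Zn",
            )
            flags += [v.verdict == "different" for v in verdicts]
        rate = float(np.mean(flags))
        se = math.sqrt(0.05 * 0.95 / len(flags))
        assert rate <= 0.05 + 3 * se + 0.01


def test_normality_screen_reports_only():
    rng = np.random.default_rng(5)
    res = normality_screen(rng.lognormal(0, 1, 200))
    assert res.method == "lilliefors"
    assert res.p_value < 0.05  # lognormal data flagged non-normal
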