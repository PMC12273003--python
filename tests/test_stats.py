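"""Correlation records, sign odds ratios, rank-sum tests and group analyses."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from psiquant import stats
from psiquant.synthdata import simulate_tissue_coupling


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        assert stats.pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert stats.pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 8.0])
        dx, dy = x - x.mean(), y - y.mean()
        expect = float((dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum()))
        r, p = stats.pearson_r(x, y)
        assert r == pytest.approx(expect)
        # two-sided p from the t transform
        t = expect * math.sqrt(3 / (1 - expect**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 3))

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            stats.pearson_r([1, 1, 1], [1, 2, 3])


def test_percent_share_rounding():
    assert stats.percent_share(54, 1423) == 3.8
    assert stats.percent_share(104, 1191) == 8.7


class TestSignOddsRatio:
    def test_nine_positive_three_negative(self):
        r = [0.1] * 9 + [-0.1] * 3
        out = stats.sign_odds_ratio(r)
        assert out.odds_ratio == pytest.approx(3.0)
        # term-by-term binomial summation oracle
        oracle = sum(math.comb(12, k) for k in range(9, 13)) / 2**12
        assert out.p_value == pytest.approx(oracle)

    def test_even_split(self):
        out = stats.sign_odds_ratio([0.5] * 6 + [-0.5] * 6)
        assert out.odds_ratio == pytest.approx(1.0)
        oracle = sum(math.comb(12, k) for k in range(6, 13)) / 2**12
        assert out.p_value == pytest.approx(oracle)

    def test_zero_correlations_excluded_and_tally_conserved(self):
        r = [0.2, -0.3, 0.0, 0.0, 0.1]
        out = stats.sign_odds_ratio(r)
        assert out.n_positive + out.n_negative == 3

    def test_no_negatives_infinite_or(self):
        out = stats.sign_odds_ratio([0.1, 0.2])
        assert math.isinf(out.odds_ratio)
        assert out.p_value == pytest.approx(0.25)


class TestWilcoxon:
    def test_smallest_case_exact(self):
        assert stats.wilcoxon_one_tailed([1, 2], [3, 4], "less") == pytest.approx(1 / 6)
        assert stats.wilcoxon_one_tailed([3, 4], [1, 2], "greater") == pytest.approx(1 / 6)

    def test_identical_samples_large_p(self):
        assert stats.wilcoxon_one_tailed([1, 2, 3], [1, 2, 3], "less") > 0.4

    def test_exact_matches_independent_implementation(self, rng):
        """Exact enumeration vs scipy's exact rank-sum across all sample-size
        splits with n <= 10 (tie-free inputs)."""
        for na in range(1, 10):
            for nb in range(1, 11 - na):
                values = rng.permutation(np.arange(1.0, na + nb + 1))
                a, b = values[:na], values[na:]
                for alt in ("less", "greater"):
                    ours = stats.wilcoxon_one_tailed(a, b, alt)
                    theirs = sps.mannwhitneyu(
                        a, b, alternative=alt, method="exact"
                    ).pvalue
                    assert ours == pytest.approx(theirs, abs=1e-12)

    def test_exact_handles_ties(self):
        # enumeration over midranks: oracle by explicit combinations
        a, b = [1.0, 2.0, 2.0], [2.0, 3.0]
        ranks = sps.rankdata(a + b)
        w_obs = ranks[:3].sum()
        total = math.comb(5, 3)
        count = sum(
            1
            for idx in itertools.combinations(range(5), 3)
            if ranks[list(idx)].sum() <= w_obs + 1e-9
        )
        assert stats.wilcoxon_one_tailed(a, b, "less") == pytest.approx(count / total)

    def test_normal_approximation_close_to_exact_at_boundary(self, rng):
        """Just above the enumeration cut-off the normal approximation stays
        within 0.02 of the exact null distribution (tie-free samples)."""
        for _ in range(10):
            a = rng.normal(size=7)
            b = rng.normal(loc=0.5, size=7)  # n=14 -> normal-approximation path
            approx = stats.wilcoxon_one_tailed(a, b, "less")
            exact = sps.mannwhitneyu(a, b, alternative="less", method="exact").pvalue
            assert abs(approx - exact) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.wilcoxon_one_tailed([], [1.0], "less")


class TestGrouping:
    def test_ten_transcripts_five_groups_of_two(self):
        f = pd.Series(np.arange(10.0), index=[f"t{i}" for i in range(10)])
        groups = stats.group_by_feature(f, k=5)
        assert groups.value_counts().tolist() == [2, 2, 2, 2, 2]
        assert groups["t0"] == 0 and groups["t9"] == 4

    def test_group_sizes_differ_by_at_most_one(self, rng):
        for n in (11, 23, 57):
            f = pd.Series(rng.uniform(size=n))
            sizes = stats.group_by_feature(f, k=5).value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_tie_breaking_is_stable_by_label(self):
        f = pd.Series([1.0, 1.0, 1.0, 1.0], index=["d", "a", "c", "b"])
        groups = stats.group_by_feature(f, k=2)
        # ties ordered by index label: a,b -> group 0; c,d -> group 1
        assert groups["a"] == 0 and groups["b"] == 0
        assert groups["c"] == 1 and groups["d"] == 1

    def test_relative_utr5_length(self):
        rel = stats.relative_utr5_length(
            pd.Series({"t": 100.0, "z": 50.0}), pd.Series({"t": 400.0, "z": 0.0})
        )
        assert rel["t"] == pytest.approx(0.25)
        assert "z" not in rel.index  # zero CDS excluded


class TestSiteTECorrelation:
    def test_planted_coupling_gives_positive_medians(self):
        site_m, te_m = simulate_tissue_coupling(30, 40, 9, coupling=1.0, seed=3)
        out = stats.site_te_correlation(site_m, te_m)
        assert (out.site_median > 0).mean() > 0.9

    def test_constant_te_rows_are_skipped(self):
        site_m, _ = simulate_tissue_coupling(5, 5, 6, coupling=0.0, seed=1)
        te_m = pd.DataFrame(1.0, index=["x"], columns=site_m.columns)
        out = stats.site_te_correlation(site_m, te_m)
        assert len(out.records) == 0

    def test_sites_with_few_tissues_skipped(self):
        site_m, te_m = simulate_tissue_coupling(4, 5, 6, coupling=0.0, seed=1)
        site_m.iloc[0, 2:] = np.nan  # only 2 tissues left
        out = stats.site_te_correlation(site_m, te_m)
        assert site_m.index[0] in out.skipped_sites

    def test_null_sign_tally_within_binomial_band(self):
        site_m, te_m = simulate_tissue_coupling(80, 100, 9, coupling=0.0, seed=7)
        out = stats.site_te_correlation(site_m, te_m)
        lo, hi = stats.binomial_band(out.n_positive + out.n_negative, level=0.99)
        assert lo <= out.n_positive <= hi

    def test_records_match_per_pair_pearson(self):
        site_m, te_m = simulate_tissue_coupling(3, 4, 7, coupling=0.5, seed=9)
        out = stats.site_te_correlation(site_m, te_m)
        for row in out.records.sample(6, random_state=0).itertuples():
            r, p = stats.pearson_r(
                site_m.loc[row.site], te_m.loc[row.transcript]
            )
            assert row.r == pytest.approx(r)
            assert row.p == pytest.approx(p, rel=1e-6)


class TestTRNACorrelation:
    def _sites(self, n_tissues=6):
        tissues = [f"t{i}" for i in range(n_tissues)]
        rng = np.random.default_rng(0)
        rows = [
            ("trnaA", 55, "T-arm-loop", t, float(rng.uniform(0.3, 0.8)))
            for t in tissues
        ]
        return pd.DataFrame(
            rows, columns=["trna_id", "position", "region", "tissue", "fraction"]
        ), tissues

    def test_two_decoded_codons_give_two_records(self):
        sites, tissues = self._sites()
        decode = pd.DataFrame(
            {"trna_id": ["trnaA", "trnaA"], "codon": ["GCC", "GCT"]}
        )
        rng = np.random.default_rng(1)
        e_codon = pd.DataFrame(
            rng.uniform(0.5, 2.0, size=(2, len(tissues))),
            index=["GCC", "GCT"], columns=tissues,
        )
        out = stats.trna_region_te_correlation(sites, decode, e_codon)
        assert len(out) == 2
        assert set(out["codon"]) == {"GCC", "GCT"}

    def test_unlabeled_region_rejected(self):
        sites, tissues = self._sites()
        sites.loc[0, "region"] = None
        with pytest.raises(ValueError):
            stats.trna_region_te_correlation(
                sites, pd.DataFrame({"trna_id": [], "codon": []}),
                pd.DataFrame(columns=tissues),
            )


class TestGroupAnalyses:
    def test_lifetime_planted_negative_effect_recovered(self):
        rng = np.random.default_rng(5)
        s = pd.Series(rng.uniform(0, 1.5, size=400))
        lt = pd.Series(np.exp(np.log(4.0) - 0.5 * s + rng.normal(0, 0.3, 400)))
        out = stats.lifetime_group_analysis(s, lt, k=4)
        assert out.medians_monotone_decreasing
        assert out.bottom_vs_top_p < 1e-6
        assert out.groups["n"].max() - out.groups["n"].min() <= 1

    def test_te_identical_everywhere_has_large_p(self):
        s = pd.Series(np.linspace(0, 1, 60))
        te = pd.Series(1.0, index=s.index)
        out = stats.te_group_analysis(s, te, k=3)
        assert out.bottom_vs_top_p > 0.4
        assert not out.medians_monotone_increasing

    def test_te_planted_positive_effect_recovered(self):
        rng = np.random.default_rng(6)
        s = pd.Series(rng.uniform(0, 1.5, size=400))
        te = pd.Series(np.exp(0.5 * s + rng.normal(0, 0.3, 400)))
        out = stats.te_group_analysis(s, te, k=3)
        assert out.medians_monotone_increasing
        assert out.bottom_vs_top_p < 1e-6

    def test_te_strata_handled_separately(self):
        rng = np.random.default_rng(7)
        idx = [f"t{i}" for i in range(120)]
        s = pd.Series(rng.uniform(0, 1.5, size=120), index=idx)
        te = pd.Series(np.exp(0.5 * s + rng.normal(0, 0.3, 120)), index=idx)
        strata = pd.Series(["5UTR"] * 60 + ["non-5UTR"] * 60, index=idx)
        out = stats.te_group_analysis(s, te, k=3, strata=strata)
        assert set(out) == {"5UTR", "non-5UTR"}

    def test_too_few_transcripts_rejected(self):
        with pytest.raises(ValueError):
            stats.lifetime_group_analysis(
                pd.Series([0.1, 0.2]), pd.Series([1.0, 2.0]), k=4
            )
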