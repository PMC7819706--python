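"""Phylostratigraphy slopes, profile correlations and companion statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from phylostrat.sequence_metrics import STANDARD_AA
from phylostrat.trends import (
    aa_slope_profile,
    binomial_sign_test,
    consensus_recruitment_order,
    correlate_profiles,
    load_aa_properties,
    min_age_sweep,
    phylostrat_slope,
    transform_values,
    welch_t_test,
    wilcoxon_paired,
)


class TestPhylostratSlope:
    def test_exact_line_recovered(self):
        ages = np.linspace(0, 4000, 25)
        values = 1.0 - 0.05 * ages / 1000.0
        res = phylostrat_slope(ages, values)
        assert res.slope == pytest.approx(-0.05)
        assert res.r_squared == pytest.approx(1.0)
        assert res.ci95[0] <= res.slope <= res.ci95[1]

    def test_constant_values_zero_slope(self):
        res = phylostrat_slope([100, 900, 2500], [0.3, 0.3, 0.3])
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_returns_none(self):
        assert phylostrat_slope([100, 200], [1, 2]) is None

    def test_missing_values_dropped(self):
        res = phylostrat_slope([0, 1000, 2000, 3000], [1.0, np.nan, 3.0, 4.0])
        assert res.n == 3

    def test_scaling_ages_scales_slope_inversely(self, rng):
        ages = rng.uniform(0, 4000, 40)
        values = rng.normal(0, 1, 40) + 0.01 * ages
        a = phylostrat_slope(ages, values)
        b = phylostrat_slope(ages * 2, values)
        assert b.slope == pytest.approx(a.slope / 2)

    def test_shifting_values_preserves_slope(self, rng):
        ages = rng.uniform(0, 4000, 40)
        values = rng.normal(0, 1, 40)
        a = phylostrat_slope(ages, values)
        b = phylostrat_slope(ages, values + 7.5)
        assert b.slope == pytest.approx(a.slope)
        assert b.se == pytest.approx(a.se)


def _comp_frame(rng, n=120, proline_slope_pp_by=0.0):
    """Random compositions with an exactly planted proline trend: the proline
    fraction is p0 + slope*age and the remaining mass is split among the
    other 19 amino acids at random."""
    ages = rng.uniform(0, 4000, n)
    p = 0.05 + proline_slope_pp_by / 100.0 * ages / 1000.0
    p += rng.normal(0, 0.005, n)
    rest = rng.dirichlet(np.full(19, 40.0), size=n) * (1 - p)[:, None]
    comp = np.empty((n, 20))
    p_idx = STANDARD_AA.index("P")
    comp[:, p_idx] = p
    comp[:, [i for i in range(20) if i != p_idx]] = rest
    df = pd.DataFrame(comp, columns=[f"comp_{aa}" for aa in STANDARD_AA])
    df["age_my"] = ages
    return df


class TestAaSlopeProfile:
    def test_constant_composition_zero_slopes(self):
        df = pd.DataFrame(
            {f"comp_{aa}": [0.05] * 5 for aa in STANDARD_AA}
            | {"age_my": [0, 1000, 2000, 3000, 4000]}
        )
        profile = aa_slope_profile(df)
        assert len(profile) == 20
        assert np.allclose(profile["slope"], 0.0, atol=1e-12)

    def test_planted_proline_trend_recovered(self, rng):
        df = _comp_frame(rng, n=400, proline_slope_pp_by=2.0)
        profile = aa_slope_profile(df)
        row = profile.loc["P"]
        assert row["slope"] == pytest.approx(2.0, abs=3 * row["se"])

    def test_composition_slopes_sum_to_zero(self, rng):
        profile = aa_slope_profile(_comp_frame(rng))
        assert profile["slope"].sum() == pytest.approx(0.0, abs=1e-9)


class TestCorrelateProfiles:
    def test_identity_and_reversal(self, rng):
        x = rng.normal(size=20)
        assert correlate_profiles(x, x).rho == pytest.approx(1.0)
        order = np.argsort(x)
        y = np.empty(20)
        y[order] = -np.arange(20, dtype=float)
        assert correlate_profiles(x, y).rho == pytest.approx(-1.0)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        for method in ("spearman", "pearson"):
            assert correlate_profiles(x, y, method).rho == pytest.approx(
                correlate_profiles(y, x, method).rho
            )

    def test_spearman_against_exhaustive_rank_oracle(self):
        """rho for small vectors must equal the textbook definition:
        Pearson correlation of the average-rank vectors."""
        x = [3.1, -0.2, 5.5, 5.5, 1.0, 2.2]
        y = [0.4, 0.1, 9.9, 2.0, 2.0, 7.3]

        def ranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            r = [0.0] * len(v)
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    r[order[k]] = avg
                i = j + 1
            return r

        expected = np.corrcoef(ranks(x), ranks(y))[0, 1]
        assert correlate_profiles(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_spearman_invariant_under_monotone_transform(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        a = correlate_profiles(x, y).rho
        b = correlate_profiles(np.exp(x), y).rho
        assert a == pytest.approx(b)

    def test_fisher_se_and_ci(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        res = correlate_profiles(x, y)
        assert res.fisher_se == pytest.approx(np.sqrt(1.06 / 17))
        assert res.rho_ci[0] < res.rho < res.rho_ci[1]

    def test_missing_entries_dropped_pairwise(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, 4.0, np.nan]
        assert correlate_profiles(x, y).n == 3


class TestConsensusRecruitmentOrder:
    def test_single_criterion_identity(self):
        m = pd.DataFrame({"c1": np.arange(1.0, 21.0)}, index=list(STANDARD_AA))
        assert consensus_recruitment_order(m).tolist() == list(range(1, 21))

    def test_mutually_reversed_criteria_flatten(self):
        m = pd.DataFrame(
            {"c1": np.arange(1.0, 21.0), "c2": np.arange(20.0, 0.0, -1.0)},
            index=list(STANDARD_AA),
        )
        assert np.allclose(consensus_recruitment_order(m), 10.5)

    def test_exclusion_equals_reduced_matrix(self, rng):
        m = pd.DataFrame(
            rng.integers(1, 21, size=(20, 5)).astype(float),
            index=list(STANDARD_AA),
            columns=[f"c{i}" for i in range(5)],
        )
        a = consensus_recruitment_order(m, excluded_criteria=["c3", "c4"])
        b = consensus_recruitment_order(m[["c0", "c1", "c2"]])
        assert a.equals(b)

    def test_excluding_everything_rejected(self):
        m = pd.DataFrame({"c1": np.arange(1.0, 21.0)}, index=list(STANDARD_AA))
        with pytest.raises(ValueError):
            consensus_recruitment_order(m, excluded_criteria=["c1"])


class TestMinAgeSweep:
    def test_zero_threshold_reduces_to_full_profile(self, rng):
        df = _comp_frame(rng, n=150)
        props = load_aa_properties()["recruitment_rank"]
        sweep = min_age_sweep(df, [0.0], props)
        full = correlate_profiles(
            aa_slope_profile(df)["slope"].reindex(props.index), props
        )
        assert sweep.iloc[0]["rho"] == pytest.approx(full.rho)
        assert sweep.iloc[0]["fisher_se"] == pytest.approx(full.fisher_se)

    def test_threshold_above_all_ages_missing(self, rng):
        df = _comp_frame(rng, n=50)
        props = load_aa_properties()["recruitment_rank"]
        sweep = min_age_sweep(df, [9999.0], props)
        assert np.isnan(sweep.iloc[0]["rho"]) and sweep.iloc[0]["n_pfams"] == 0


class TestGroupComparisons:
    def test_identical_paired_vectors_p_one(self):
        vals = {"a": 1.0, "b": 2.0, "c": 3.0}
        out = wilcoxon_paired(vals, dict(vals))
        assert out["p_value"] == 1.0

    def test_paired_key_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired({"a": 1.0}, {"b": 1.0})

    def test_binomial_six_of_nine_exact_tail(self):
        # sum_{k>=6} C(9,k) / 2^9 = 130/512
        out = binomial_sign_test(6, 9)
        assert out["p_value"] == pytest.approx(130 / 512, abs=1e-12)

    def test_welch_reports_two_sided_p(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        out = welch_t_test(a, b)
        assert out["p_value"] < 1e-6 and out["n_a"] == out["n_b"] == 30

    def test_welch_null_p_uniformish(self):
        """Under the null the Welch p-value distribution is ~uniform."""
        rng = np.random.default_rng(11)
        ps = [
            welch_t_test(rng.normal(size=25), rng.normal(size=25))["p_value"]
            for _ in range(300)
        ]
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestTransforms:
    def test_boxcox_lambda_one_is_affine_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        out, params = transform_values(x, "boxcox")
        lam = params["lambda"]
        expected = (x ** lam - 1) / lam
        assert np.allclose(out, expected)

    def test_arcsine_endpoints(self):
        out, _ = transform_values([0.0, 1.0], "arcsine")
        assert out[0] == pytest.approx(0.0)
        assert out[1] == pytest.approx(np.pi / 2)

    def test_arcsine_domain_enforced(self):
        with pytest.raises(ValueError):
            transform_values([-0.1, 0.5], "arcsine")

    @pytest.mark.parametrize("lam", [0.5, 2.0])
    def test_boxcox_lambda_recovery(self, lam):
        rng = np.random.default_rng(5)
        z = np.clip(rng.normal(2.0, 1.0, 500), (0.05 - 1) / lam, None)
        x = (1 + lam * z) ** (1 / lam)  # box-cox of x with true lam is z + const
        _, params = transform_values(x, "boxcox")
        assert params["lambda"] == pytest.approx(lam, abs=0.2)
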