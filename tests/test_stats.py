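"""Association statistics: Spearman-on-ranks, median-Z fits, Welch's t."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from cnconcord import (FIXED_THRESHOLDS, SimulationConfig, analyze_cohort,
                       cohort_fit, median_z_fit, simulate_cohort,
                       spearman_rho, welch_t)
from cnconcord.stats import cross_dataset_agreement


# --- independent brute-force oracles ---------------------------------------

def oracle_ranks(v):
    """Midranks built by explicit sorting and tie-group averaging."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j < len(v) and v[order[j]] == v[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0          # mean of positions i+1 .. j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    return ranks


def oracle_spearman(x, y):
    rx, ry = oracle_ranks(x), oracle_ranks(y)
    cov = np.mean((rx - rx.mean()) * (ry - ry.mean()))
    sx = np.sqrt(np.mean((rx - rx.mean()) ** 2))
    sy = np.sqrt(np.mean((ry - ry.mean()) ** 2))
    if sx == 0 or sy == 0:
        return np.nan
    return cov / (sx * sy)


class TestSpearman:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [6, 4, 2], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),   # 1 - 6*2/(4*15)
    ])
    def test_closed_form(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_oracle_on_random_tied_vectors(self):
        """Agreement with the explicit rank-construction oracle to 1e-12
        on 1000 random small vectors with ties."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = rng.integers(3, 12)
            x = rng.integers(-2, 3, n).astype(float)   # heavy ties
            y = np.round(rng.normal(size=n), 1)
            got = spearman_rho(x, y)
            want = oracle_spearman(x, y)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.integers(-2, 3, 30).astype(float)
            y = x * 0.5 + rng.normal(size=30)
            assert spearman_rho(x, y) == pytest.approx(
                sps.spearmanr(x, y).statistic, abs=1e-12)

    @given(st.lists(st.floats(min_value=-50, max_value=50,
                              allow_nan=False).map(lambda v: round(v, 2)),
                    min_size=4, max_size=30))
    def test_invariant_under_monotone_transform(self, xs):
        # values rounded to 0.01 so exp(x/25) stays injective in floats
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(xs))
        base = spearman_rho(xs, y)
        transformed = spearman_rho(np.exp(np.asarray(xs) / 25.0), y)
        if np.isnan(base):
            assert np.isnan(transformed)
        else:
            assert transformed == pytest.approx(base, abs=1e-10)

    def test_degenerate_inputs(self):
        assert np.isnan(spearman_rho([1, 2], [3, 4]))            # too short
        assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))      # constant
        # NaN pairs dropped before the length check
        assert np.isnan(spearman_rho([1, 2, np.nan, np.nan],
                                     [1, 2, 3, 4]))
        with pytest.raises(ValueError, match="equal length"):
            spearman_rho([1, 2, 3], [1, 2])


class TestMedianZFit:
    def test_hand_ols(self):
        """Levels {-2,0,2} with medians {-1, 0, 0.8}: closed-form OLS."""
        calls = [-2, -2, 0, 0, 2, 2]
        z = [-1.5, -0.5, -1.0, 1.0, 0.7, 0.9]   # medians -1.0, 0.0, 0.8
        fit = median_z_fit(calls, z)
        assert fit.n_levels == 3
        assert fit.slope == pytest.approx(0.45, abs=1e-12)
        assert fit.intercept == pytest.approx(-0.2 / 3, abs=1e-12)
        assert fit.r == pytest.approx(3.6 / np.sqrt(8 * 1.62666666666667),
                                      abs=1e-10)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_collinear_medians(self, sign):
        calls = [-2, -1, 0, 1, 2]
        z = [sign * c * 0.7 + 0.1 for c in calls]
        fit = median_z_fit(calls, z)
        assert fit.r == pytest.approx(sign, abs=1e-12)
        assert fit.slope == pytest.approx(sign * 0.7, abs=1e-12)

    def test_duplicating_samples_within_level_is_invariant(self):
        """Medians are unweighted: replicating samples at one level must
        not change the fit."""
        calls = [-2, 0, 0, 2]
        z = [-1.2, 0.1, -0.1, 1.4]
        base = median_z_fit(calls, z)
        dup = median_z_fit(calls + [2, 2], z + [1.4, 1.4])
        assert dup.slope == pytest.approx(base.slope, abs=1e-12)
        assert dup.r == pytest.approx(base.r, abs=1e-12)

    def test_too_few_levels_undefined(self):
        fit = median_z_fit([0, 0, 2, 2], [0.0, 0.1, 1.0, 1.1])
        assert fit.n_levels == 2
        assert np.isnan(fit.r) and np.isnan(fit.slope)


class TestWelch:
    def test_identical_groups(self):
        cmp = welch_t([1, 2, 3], [1, 2, 3])
        assert cmp.t == 0.0
        assert cmp.p == pytest.approx(1.0)

    def test_hand_computation(self):
        """a=[1,2,3], b=[2,4,6]: t = -2/sqrt(1/3 + 4/3), df = 50/17."""
        cmp = welch_t([1, 2, 3], [2, 4, 6])
        assert cmp.t == pytest.approx(-2 / np.sqrt(5 / 3), abs=1e-12)
        assert cmp.df == pytest.approx(50 / 17, abs=1e-12)
        ref = sps.ttest_ind([1, 2, 3], [2, 4, 6], equal_var=False)
        assert cmp.t == pytest.approx(ref.statistic, abs=1e-12)
        assert cmp.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_scipy_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = rng.normal(size=rng.integers(2, 20))
            b = rng.normal(1.0, 2.0, size=rng.integers(2, 20))
            cmp = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert cmp.t == pytest.approx(ref.statistic, abs=1e-12)
            assert cmp.p == pytest.approx(ref.pvalue, abs=1e-12)
            assert 0 < cmp.p <= 1

    def test_degenerate_variances(self):
        cmp = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (cmp.t, cmp.p) == (0.0, 1.0)
        cmp = welch_t([3.0, 3.0], [2.0, 2.0])
        assert np.isinf(cmp.t) and cmp.t > 0
        assert cmp.p == 0.0
        with pytest.raises(ValueError, match=">= 2"):
            welch_t([1.0], [1.0, 2.0])

    def test_amplified_vs_deleted_in_dosage_cohort(self, default_analysis):
        """In a dosage-sensitive cohort the amplified-event Z-scores are
        significantly higher than the deleted-event ones."""
        z = default_analysis.zmat.z.to_numpy()
        c = default_analysis.calls.to_numpy()
        finite = np.isfinite(z)
        cmp = welch_t(z[(c == 2) & finite], z[(c == -2) & finite])
        assert cmp.mean_a > cmp.mean_b
        assert cmp.p < 0.05


class TestCohortFit:
    def test_noiseless_cohort_r_is_one(self):
        genes = pd.Index(["g0", "g1"], name="gene")
        samples = pd.Index([f"s{i}" for i in range(6)], name="sample")
        calls = pd.DataFrame([[-2, -1, 0, 1, 2, 0]] * 2, index=genes,
                             columns=samples, dtype=float)
        z = calls * 0.8
        fit = cohort_fit(z, calls)
        assert fit.r == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.8, abs=1e-12)
        assert fit.p < 1e-4

    def test_default_scenario_strongly_linear(self, default_analysis):
        fit = default_analysis.fit
        assert fit.r > 0.9
        assert fit.slope > 0
        assert fit.p < 0.05

    def test_dosage_free_cohort_near_zero_slope(self):
        cfg = SimulationConfig(n_genes=400, n_samples=200,
                               dosage_fraction=0.0, n_planted_aug=0,
                               n_planted_ddg=0, n_ref_oncogenes=0,
                               n_ref_tsgs=0, seed=23)
        analysis = analyze_cohort(simulate_cohort(cfg),
                                  thresholds=FIXED_THRESHOLDS)
        assert abs(analysis.fit.slope) < 0.05


def test_gene_associations_table(small_analysis):
    assoc = small_analysis.assoc
    defined = assoc["rho"].dropna()
    assert len(defined) > 100
    assert ((defined >= -1) & (defined <= 1)).all()
    fr = assoc["fit_r"].dropna()
    assert ((fr >= -1 - 1e-12) & (fr <= 1 + 1e-12)).all()
    # fit defined only with >= 3 observed levels
    assert (assoc.loc[assoc["fit_r"].notna(), "n_levels"] >= 3).all()


def test_cross_dataset_agreement():
    a = pd.DataFrame({"rho": [0.5, 0.2, -0.3, 0.1]},
                     index=["g1", "g2", "g3", "g4"])
    b = pd.DataFrame({"rho": [0.4, -0.1, -0.2, np.nan]},
                     index=["g1", "g2", "g3", "g4"])
    out = cross_dataset_agreement(a, b)
    assert out["n_shared"] == 3
    assert out["both_positive"] == pytest.approx(1 / 3)
    assert out["both_negative"] == pytest.approx(1 / 3)
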