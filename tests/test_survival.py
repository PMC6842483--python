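"""Kaplan-Meier estimator, log-rank test and tendency stratification."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from cnconcord import (km_estimate, logrank_test, survival_scan,
                       tendency_groups)


# --- brute-force oracle -----------------------------------------------------

def oracle_logrank(ta, ea, tb, eb):
    """Exhaustive O-E and hypergeometric variance at each event time."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, int), np.asarray(eb, int)
    all_t = sorted(set(ta[ea == 1]) | set(tb[eb == 1]))
    o_e, v = 0.0, 0.0
    for t in all_t:
        n1 = (ta >= t).sum()
        n2 = (tb >= t).sum()
        d1 = ((ta == t) & (ea == 1)).sum()
        d2 = ((tb == t) & (eb == 1)).sum()
        n, d = n1 + n2, d1 + d2
        if n1 == 0 or n2 == 0 or n < 2:
            continue
        o_e += d1 - d * n1 / n
        v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (o_e ** 2 / v) if v > 0 else 0.0


class TestKaplanMeier:
    def test_all_events_no_censoring(self):
        """Times [1,2,3], all events: S steps 2/3, 1/3, 0."""
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0],
                                   atol=1e-12)
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_all_censored(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert (curve.survival == 1.0).all()

    def test_single_event(self):
        curve = km_estimate([5.0], [1])
        assert curve.survival_at(4.9) == 1.0
        assert curve.survival_at(5.0) == 0.0

    def test_censoring_shrinks_risk_set_only(self):
        """Hand product-limit with interleaved censoring:
        t=1 event (n=4): S=3/4; t=2 censored; t=3 event (n=2): S=3/8."""
        curve = km_estimate([1, 2, 3, 4], [1, 0, 1, 0])
        assert curve.survival_at(1) == pytest.approx(3 / 4)
        assert curve.survival_at(3) == pytest.approx(3 / 8)
        assert curve.survival_at(10) == pytest.approx(3 / 8)

    def test_event_precedes_censoring_at_tied_time(self):
        """A subject censored at an event time is still at risk there."""
        curve = km_estimate([2, 2, 3], [1, 0, 1])
        assert curve.survival_at(2) == pytest.approx(2 / 3)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 60).round(1) + 0.1
        events = rng.integers(0, 2, 60)
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in np.unique(times):
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        curve = km_estimate(rng.exponential(5, 100) + 1e-3,
                            rng.integers(0, 2, 100))
        s = curve.survival
        assert ((s >= 0) & (s <= 1)).all()
        assert (np.diff(s) <= 1e-15).all()

    def test_invalid_times_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            km_estimate([0.0, 1.0], [1, 1])
        with pytest.raises(ValueError, match="at least one"):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups(self):
        chisq, p = logrank_test([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        # symmetric identical groups: O-E cancels exactly
        assert chisq == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_oracle_on_small_tables(self):
        """Exhaustive hand computation on 6-sample cohorts with ties and
        censoring, across many random tables."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            ta = rng.integers(1, 5, 3).astype(float)
            tb = rng.integers(1, 5, 3).astype(float)
            ea = rng.integers(0, 2, 3)
            eb = rng.integers(0, 2, 3)
            if ea.sum() + eb.sum() == 0:
                continue
            chisq, _ = logrank_test(ta, ea, tb, eb)
            assert chisq == pytest.approx(oracle_logrank(ta, ea, tb, eb),
                                          abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(29)
        ta = rng.exponential(10, 40) + 0.01
        tb = rng.exponential(20, 50) + 0.01
        ea = rng.integers(0, 2, 40)
        eb = rng.integers(0, 2, 50)
        chisq, p = logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chisq == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_symmetric_in_group_labels(self):
        ta, ea = [1, 3, 5, 7], [1, 1, 0, 1]
        tb, eb = [2, 4, 6], [1, 0, 1]
        c1, p1 = logrank_test(ta, ea, tb, eb)
        c2, p2 = logrank_test(tb, eb, ta, ea)
        assert c1 == pytest.approx(c2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_zero_events_undefined(self):
        chisq, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert np.isnan(chisq) and np.isnan(p)

    def test_detects_planted_hazard(self, default_cohort, default_analysis):
        """Carriers of the planted survival gene's concordant
        amplification have significantly worse survival."""
        grp = tendency_groups(default_analysis.table.labels,
                              default_cohort.clinical,
                              default_cohort.survival_gene, "AU")
        a = grp[grp["group"] == "carrier"]
        b = grp[grp["group"] == "non-carrier"]
        chisq, p = logrank_test(a["time"], a["event"], b["time"], b["event"])
        assert p < 0.05
        # worse prognosis: carrier survival curve sits below
        ka = km_estimate(a["time"], a["event"])
        kb = km_estimate(b["time"], b["event"])
        horizon = np.median(np.concatenate([ka.times, kb.times]))
        assert ka.survival_at(horizon) < kb.survival_at(horizon)


class TestTendencyGroups:
    def _labels(self):
        genes = pd.Index(["g1", "g2"], name="gene")
        samples = pd.Index([f"s{i}" for i in range(5)], name="sample")
        return pd.DataFrame(
            [["AU", "none", "AU", "none", "none"],
             ["none"] * 5], index=genes, columns=samples)

    def _clinical(self):
        return pd.DataFrame({
            "sample": [f"s{i}" for i in range(5)],
            "os_time": [1.0, 2.0, 3.0, 4.0, 5.0],
            "os_event": [1, 0, 1, 0, 1]})

    def test_partition(self):
        grp = tendency_groups(self._labels(), self._clinical(), "g1", "AU")
        assert len(grp) == 5
        assert sorted(grp.loc[grp["group"] == "carrier", "sample"]) == \
            ["s0", "s2"]

    def test_missing_clinical_dropped(self):
        clin = self._clinical().iloc[:4]
        grp = tendency_groups(self._labels(), clin, "g1", "AU")
        assert len(grp) == 4

    def test_empty_carrier_group_errors(self):
        with pytest.raises(ValueError, match="empty carrier"):
            tendency_groups(self._labels(), self._clinical(), "g2", "AU")

    def test_absent_gene_errors(self):
        with pytest.raises(ValueError, match="absent"):
            tendency_groups(self._labels(), self._clinical(), "nope", "AU")
        with pytest.raises(ValueError, match="tendency"):
            tendency_groups(self._labels(), self._clinical(), "g1", "XX")

    def test_truth_cross_check_strong_cohort(self):
        """With strong slopes and low noise the AU carrier set equals the
        simulator's concordant-amplification truth set."""
        from cnconcord import SimulationConfig, analyze_cohort, simulate_cohort
        cfg = SimulationConfig(n_genes=200, n_samples=150, slope_mean=4.0,
                               noise_sd=0.3, n_planted_aug=5, n_planted_ddg=5,
                               n_ref_oncogenes=4, n_ref_tsgs=3, seed=31)
        cohort = simulate_cohort(cfg)
        analysis = analyze_cohort(cohort)
        grp = tendency_groups(analysis.table.labels, cohort.clinical,
                              cohort.survival_gene, "AU")
        carriers = set(grp.loc[grp["group"] == "carrier", "sample"])
        truth = set(cohort.survival_carriers.index[cohort.survival_carriers])
        assert carriers == truth


def test_survival_scan_bh_adjustment(default_cohort, default_analysis):
    gc = default_analysis.gene_concordance
    aug = list(gc.index[gc["status"] == "AUG"][:5])
    ddg = list(gc.index[gc["status"] == "DDG"][:3])
    scan = survival_scan(default_analysis.table.labels,
                         default_cohort.clinical,
                         [(g, "AU") for g in aug] + [(g, "DD") for g in ddg])
    tested = scan[scan["p"].notna()]
    assert len(tested) == len(aug) + len(ddg)
    # BH never decreases p and preserves order of the max
    assert (tested["p_adj"] >= tested["p"] - 1e-15).all()
    assert tested["p_adj"].max() <= 1.0
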