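import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cffvar.carrier import (
    bca_ci,
    carrier_freq,
    carrier_or,
    carrier_probability,
    cohort_carrier_probability,
    table3_report,
)
from cffvar.model import SiteCounts, ValidationError
from cffvar.simulate import gen_reference_sites
from conftest import make_matrix


def site(ac, hom, an):
    return SiteCounts(("1", 100, "A", "G"), ac=ac, hom=hom, an=an)


class TestCarrierFreq:
    def test_arithmetic(self):
        assert carrier_freq(site(3, 1, 100)) == pytest.approx(0.04)
        assert carrier_freq(site(0, 0, 100)) == 0.0

    def test_hwe_simulation_matches_closed_form(self):
        (s,) = gen_reference_sites(10_000, [0.01], seed=5)
        expected = 1 - 0.99**2
        assert carrier_freq(s) == pytest.approx(expected, abs=3 * np.sqrt(expected / 10_000))


class TestCarrierProbability:
    def test_two_coin_example(self):
        assert carrier_probability([0.5, 0.5]) == pytest.approx(0.75)

    def test_single_site_identity(self):
        assert carrier_probability([0.123]) == pytest.approx(0.123)

    def test_empty_set_is_zero(self):
        assert carrier_probability([]) == 0.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=80, deadline=None)
    def test_monotone_and_union_bound(self, qs):
        p = carrier_probability(qs)
        assert 0.0 <= p <= min(1.0, sum(qs) + 1e-9)
        bumped = list(qs)
        bumped[0] = min(1.0, bumped[0] + 0.1)
        assert carrier_probability(bumped) >= p - 1e-12

    def test_matches_large_independence_simulation(self):
        rng = np.random.default_rng(55)
        qs = rng.uniform(0.0, 0.1, 20)
        expected = carrier_probability(qs)
        draws = 100_000
        carried = (rng.random((draws, 20)) < qs).any(axis=1).mean()
        se = np.sqrt(expected * (1 - expected) / draws)
        assert abs(carried - expected) <= 3 * se


class TestCohortCarrierProbability:
    def test_three_of_fifty_one(self):
        dosages = np.zeros((51, 2))
        dosages[0, 0] = 1
        dosages[1, 1] = 2
        dosages[2, 0] = 1
        m = make_matrix(dosages, keys=["v1", "v2"])
        p, indicators = cohort_carrier_probability(m, ["v1", "v2"])
        assert p == pytest.approx(3 / 51)
        assert indicators.sum() == 3

    def test_no_qualifying_variants(self):
        m = make_matrix(np.ones((5, 1)), keys=["v1"])
        p, indicators = cohort_carrier_probability(m, [])
        assert p == 0.0 and indicators.sum() == 0

    def test_everyone_carries(self):
        m = make_matrix(np.ones((5, 1)), keys=["v1"])
        assert cohort_carrier_probability(m, ["v1"])[0] == 1.0


class TestCarrierOr:
    def test_identity_and_examples(self):
        assert carrier_or(0.3, 0.3) == pytest.approx(1.0)
        assert carrier_or(0.75, 0.5) == pytest.approx(3.0)
        assert carrier_or(0.06, 0.15) == pytest.approx(0.3617, abs=1e-4)

    def test_reciprocal_symmetry(self):
        assert carrier_or(0.2, 0.4) * carrier_or(0.4, 0.2) == pytest.approx(1.0)

    def test_boundaries(self):
        assert carrier_or(0.0, 0.5) == 0.0
        assert carrier_or(1.0, 0.5) == np.inf
        with pytest.raises(ValidationError):
            carrier_or(0.5, 0.0)


def naive_bca(indicators, p_reference, n_boot, seed, alpha=0.05):
    """Straightforward loop implementation of the BCa interval on ln OR,
    written independently of the vectorised version it checks."""
    ind = np.asarray(indicators, dtype=float)
    n = len(ind)

    def log_or(p):
        if p == 0.0:
            return -np.inf
        if p == 1.0:
            return np.inf
        return np.log(p / (1 - p)) - np.log(p_reference / (1 - p_reference))

    theta_hat = log_or(ind.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    theta_star = np.array([log_or(ind[row].mean()) for row in idx])
    z0 = stats.norm.ppf((theta_star < theta_hat).sum() / n_boot)
    jack = np.array([log_or(np.delete(ind, i).mean()) for i in range(n)])
    diffs = jack.mean() - jack
    accel = (diffs**3).sum() / (6 * ((diffs**2).sum()) ** 1.5)
    out = []
    for z in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = stats.norm.cdf(z0 + (z0 + z) / (1 - accel * (z0 + z)))
        k = min(max(int(np.ceil(adj * n_boot)) - 1, 0), n_boot - 1)
        out.append(np.exp(np.sort(theta_star)[k]))
    return tuple(out)


class TestBcaCi:
    def indicators(self, n_carriers, n=51):
        ind = np.zeros(n)
        ind[:n_carriers] = 1.0
        return ind

    def test_degenerate_input_collapses_to_point(self):
        res = bca_ci(self.indicators(0), 0.15, n_boot=1000, seed=1)
        assert res.ci_low == res.ci_high == 0.0
        assert "degenerate" in res.flags

    def test_forced_z0_a_zero_reduces_to_percentile(self):
        ind = self.indicators(10)
        res = bca_ci(ind, 0.15, n_boot=2000, seed=3, z0=0.0, accel=0.0)
        # recompute the plain percentile interval from the same replicate stream
        rng = np.random.default_rng(3)
        idx = rng.integers(0, 51, size=(2000, 51))
        p_star = ind[idx].mean(axis=1)
        theta = np.log(p_star / (1 - p_star)) - np.log(0.15 / 0.85)
        lo = np.sort(theta)[int(np.ceil(0.025 * 2000)) - 1]
        hi = np.sort(theta)[int(np.ceil(0.975 * 2000)) - 1]
        assert res.ci_low == pytest.approx(np.exp(lo))
        assert res.ci_high == pytest.approx(np.exp(hi))

    def test_matches_independent_implementation(self):
        ind = self.indicators(3)
        res = bca_ci(ind, 0.15, n_boot=10_000, seed=7)
        lo, hi = naive_bca(ind, 0.15, n_boot=10_000, seed=7)
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)
        assert res.ci_low <= carrier_or(3 / 51, 0.15) <= res.ci_high

    def test_zero_lower_bound_reachable_with_few_carriers(self):
        # With 1 carrier of 51, many resamples contain no carrier: the
        # replicate OR is 0 and the lower bound hits 0 exactly.
        res = bca_ci(self.indicators(1), 0.15, n_boot=2000, seed=11)
        assert res.ci_low == 0.0

    def test_fixed_seed_bit_identical(self):
        ind = self.indicators(12)
        a = bca_ci(ind, 0.2, n_boot=2000, seed=42)
        b = bca_ci(ind, 0.2, n_boot=2000, seed=42)
        assert (a.ci_low, a.ci_high, a.z0, a.accel) == (b.ci_low, b.ci_high, b.z0, b.accel)

    def test_seed_mandatory(self):
        with pytest.raises(ValidationError):
            bca_ci(self.indicators(5), 0.15, n_boot=1000)


class TestTable3Report:
    def test_no_cohort_variants_row(self):
        sites = gen_reference_sites(1000, [0.02] * 5, seed=9)
        m = make_matrix(np.zeros((51, 1)), keys=["v"])
        report = table3_report(
            [{"source": "rahman", "consequence_class": "lof", "matrix": m,
              "cohort_variants": [], "reference_sites": sites}],
            n_boot=1000, seed=1,
        )
        row = report.iloc[0]
        assert row["p_cohort_pct"] == "0 %"
        assert np.isnan(row["or"])
        assert row["reference_n_variants"] == 5

    def test_planted_probabilities_round_trip(self):
        qs = [0.03, 0.05, 0.01]
        sites = [SiteCounts(("1", i + 1, "A", "G"), ac=int(q * 1000), hom=0, an=2000) for i, q in enumerate(qs)]
        keys = [s.variant_key for s in sites]
        dosages = np.zeros((51, 3))
        dosages[:10, 0] = 1
        m = make_matrix(dosages, keys=keys)
        report = table3_report(
            [{"source": "wei", "consequence_class": "non_synonymous", "matrix": m,
              "cohort_variants": keys, "reference_sites": sites}],
            n_boot=1000, seed=2,
        )
        row = report.iloc[0]
        assert row["p_reference"] == pytest.approx(carrier_probability(qs))
        assert row["p_cohort"] == pytest.approx(10 / 51)
        assert row["ci_low"] <= row["or"] <= row["ci_high"]
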