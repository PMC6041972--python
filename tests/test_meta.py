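import itertools
import math

import numpy as np
import pytest

from mqtl.errors import MQTLError
from mqtl.meta import (classification_loglik, combine_votes, declare_mqtl,
                       fit_mixture, flanking_markers, information_criteria,
                       qtl_sd, run_meta, select_model)

from conftest import make_map
from test_standardize import std


class TestQtlSd:
    @pytest.mark.parametrize("width, expected", [
        (3.92, 1.0), (19.6, 5.0), (17.47, 17.47 / 3.92)])
    def test_definition(self, width, expected):
        assert qtl_sd(width) == pytest.approx(expected)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(MQTLError):
            qtl_sd(0.0)


def ivw_mean(x, s):
    w = 1 / np.asarray(s, float) ** 2
    return float(np.sum(w * np.asarray(x, float)) / w.sum())


class TestFitMixture:
    def test_k1_identical_points(self):
        fit = fit_mixture([10, 10, 10], [1, 2, 3], K=1)
        assert fit.means[0] == pytest.approx(10.0)
        closed = sum(-0.5 * (math.log(2 * math.pi * s**2) + 0) for s in (1, 2, 3))
        assert fit.loglik == pytest.approx(closed)

    def test_k1_equal_weights_symmetric(self):
        fit = fit_mixture([0, 10], [1, 1], K=1)
        assert fit.means[0] == pytest.approx(5.0)

    def test_k1_matches_analytic_ivw_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0, 100, 8)
            s = rng.uniform(0.5, 5, 8)
            fit = fit_mixture(x, s, K=1)
            assert fit.means[0] == pytest.approx(ivw_mean(x, s), abs=1e-9)

    def test_two_separated_clusters_recovered(self):
        fit = fit_mixture([0, 0.1, 49.9, 50], [1, 1, 1, 1], K=2, seed=3)
        means = np.sort(fit.means)
        assert means[0] == pytest.approx(0.05, abs=0.1)
        assert means[1] == pytest.approx(49.95, abs=0.1)

    def test_loglik_trace_non_decreasing(self):
        rng = np.random.default_rng(5)
        for K in (2, 3):
            x = np.concatenate([rng.normal(0, 1, 5), rng.normal(30, 1, 5)])
            fit = fit_mixture(x, np.full(10, 1.0), K=K, seed=1)
            trace = np.array(fit.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-9)

    def test_responsibilities_and_weights_normalized(self):
        fit = fit_mixture([0, 1, 20, 21], [1, 1, 1, 1], K=2, seed=2)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-9)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(MQTLError):
            fit_mixture([0, 1], [1, 1], K=3)

    def test_deterministic_under_seed(self):
        a = fit_mixture([0, 1, 20, 21, 40], [1] * 5, K=3, seed=9)
        b = fit_mixture([0, 1, 20, 21, 40], [1] * 5, K=3, seed=9)
        assert np.array_equal(a.means, b.means)
        assert a.loglik == b.loglik


class TestInformationCriteria:
    def test_aic_bic_closed_forms(self):
        fit = fit_mixture([0.0], [1.0], K=1)
        fit.loglik = -10.0
        values = information_criteria(fit, n=math.e)
        assert values["AIC"] == pytest.approx(22.0)
        assert values["BIC"] == pytest.approx(21.0)  # 20 + nu * ln(e)
        # AIC and BIC coincide where nu*ln(n) = 2*nu, i.e. n = e^2
        at_e2 = information_criteria(fit, n=math.e ** 2)
        assert at_e2["BIC"] == pytest.approx(at_e2["AIC"])

    def test_aic3_minus_aic_is_nu(self):
        rng = np.random.default_rng(1)
        for K in (1, 2, 3):
            x = rng.uniform(0, 50, 6)
            fit = fit_mixture(x, np.full(6, 1.0), K=K, seed=0)
            v = information_criteria(fit, n=6)
            assert v["AIC3"] - v["AIC"] == pytest.approx(fit.n_params)

    def test_aicc_undefined_reported_as_inf(self):
        fit = fit_mixture([0, 1, 2], [1, 1, 1], K=2, seed=0)  # nu=3, n=3
        assert information_criteria(fit, n=3)["AICc"] == math.inf

    def test_identical_points_prefer_k1_over_kn(self):
        x = [10.0] * 5
        s = [1.0] * 5
        f1 = fit_mixture(x, s, K=1)
        fn = fit_mixture(x, s, K=5, seed=0)
        v1, vn = information_criteria(f1, 5), information_criteria(fn, 5)
        for c in ("AIC", "AICc", "AIC3", "BIC", "AWE"):
            assert v1[c] < vn[c]

    def test_awe_uses_hardened_classification(self):
        fit = fit_mixture([0, 0.1, 49.9, 50], [1, 1, 1, 1], K=2, seed=3)
        assert classification_loglik(fit) <= fit.loglik + 1e-9


class TestSelectModel:
    def test_unanimous(self):
        x = np.concatenate([np.zeros(4), np.full(4, 60.0), np.full(4, 120.0)])
        s = np.full(12, 1.0)
        fits = {K: fit_mixture(x + np.arange(12) * 0.01, s, K, seed=1)
                for K in range(1, 5)}
        sel = select_model(fits, n=12)
        assert sel.chosen_K == 3
        assert set(sel.votes.values()) == {3}

    def test_majority_tie_goes_to_smaller_k(self):
        assert combine_votes({"AIC": 2, "AICc": 2, "AIC3": 3, "BIC": 3,
                              "AWE": 1}) == 2
        assert combine_votes({"AIC": 3, "AICc": 3, "AIC3": 2, "BIC": 2,
                              "AWE": 1}) == 2

    def test_alternative_strategies(self):
        votes = {"AIC": 4, "AICc": 2, "AIC3": 3, "BIC": 3, "AWE": 1}
        assert combine_votes(votes, "aicc_only") == 2
        assert combine_votes(votes, "consensus_min") == 1
        with pytest.raises(ValueError):
            combine_votes(votes, "bogus")

    def test_single_cluster_chooses_k1_across_seeds(self):
        """One well-separated cluster: the vote lands on K=1 in >=95% of seeds."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(50.0, 1.0, 8)
            s = np.full(8, 1.0)
            fits = {K: fit_mixture(x, s, K, seed=seed) for K in (1, 2, 3)}
            if select_model(fits, n=8).chosen_K == 1:
                wins += 1
        assert wins >= 95


def enumeration_oracle(x, s, K):
    """Best mixture loglik over all hard assignments, each assignment scored
    with its clusters' inverse-variance means and empirical weights."""
    n = len(x)
    best = -math.inf
    for labels in itertools.product(range(K), repeat=n):
        means, weights = np.zeros(K), np.zeros(K)
        ok = True
        for k in range(K):
            idx = [i for i in range(n) if labels[i] == k]
            if not idx:
                ok = False
                break
            means[k] = ivw_mean([x[i] for i in idx], [s[i] for i in idx])
            weights[k] = len(idx) / n
        if not ok:
            continue
        ll = 0.0
        for i in range(n):
            dens = sum(weights[k] / (math.sqrt(2 * math.pi) * s[i])
                       * math.exp(-((x[i] - means[k]) ** 2) / (2 * s[i] ** 2))
                       for k in range(K))
            ll += math.log(dens)
        best = max(best, ll)
    return best


class TestOracleEquivalence:
    def test_em_attains_enumeration_likelihood(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n = int(rng.integers(2, 7))
            K = int(rng.integers(1, min(2, n) + 1))
            x = rng.uniform(0, 50, n)
            s = rng.uniform(0.5, 4.0, n)
            fit = fit_mixture(x, s, K, seed=trial)
            assert fit.loglik >= enumeration_oracle(x, s, K) - 1e-6


class TestDeclareMqtl:
    def ref(self):
        return make_map("ref", {"1": [("m1", 0.0), ("m2", 50.0), ("m3", 100.0)]})

    def test_single_qtl_k1(self):
        q = std("q1", 40, 60, 0.2)
        fit = fit_mixture([50.0], [qtl_sd(20.0)], K=1)
        (m,) = declare_mqtl(fit, [q], "stem", self.ref())
        assert m.mqtl_id == "SIR1"
        assert m.position == pytest.approx(50.0)
        assert m.sd == pytest.approx(qtl_sd(20.0))

    def test_two_member_closed_form(self):
        qtls = [std("a", -2, 2, 0.2), std("b", 8, 12, 0.2)]
        fit = fit_mixture([0.0, 10.0], [1.0, 1.0], K=1)
        (m,) = declare_mqtl(fit, qtls, "leaf", self.ref())
        assert m.position == pytest.approx(5.0)
        assert m.sd == pytest.approx(1 / math.sqrt(2))
        assert m.ci95_end - m.ci95_start == pytest.approx(2 * 1.96 / math.sqrt(2))
        assert m.mqtl_id == "LIR1"

    def test_flanking_nearest_outside(self):
        assert flanking_markers(self.ref(), "1", 40.0, 60.0) == ("m1", "m3")
        assert flanking_markers(self.ref(), "1", 50.0, 50.0) == ("m2", "m2")
        # CI past the mapped ends falls back to the terminal markers
        assert flanking_markers(self.ref(), "1", -5.0, 120.0) == ("m1", "m3")

    def test_members_carry_responsibilities(self):
        qtls = [std(f"q{i}", p - 2, p + 2, 0.2) for i, p in
                enumerate([0, 1, 49, 50])]
        fit = fit_mixture([0, 1, 49, 50], [1, 1, 1, 1], K=2, seed=0)
        mqtls = declare_mqtl(fit, qtls, "kernel", self.ref())
        assert [m.mqtl_id for m in mqtls] == ["KIR1", "KIR2"]
        for m in mqtls:
            for _, frac in m.members:
                assert 0.0 <= frac <= 1.0
        assert sum(len(m.members) for m in mqtls) == 4


class TestRunMeta:
    def project(self, qtl, ref_pos=None):
        from mqtl.projection import project_qtl, AnchorSet
        anchors = AnchorSet("1", [("a", 0, 0), ("b", 200, 200)], 1.0)
        return project_qtl(qtl, anchors)

    def test_single_qtl_chromosome_gives_one_mqtl(self, reference_map):
        p = self.project(std("q1", 40, 60, 0.2))
        result = run_meta([p], "stem", reference_map, seed=0)
        assert len(result.mqtls) == 1
        assert result.mqtls[0].members[0][0] == "q1"

    def test_tissues_are_independent(self, reference_map):
        stem = self.project(std("s", 40, 60, 0.2))
        leaf = self.project(std("l", 40, 60, 0.2))
        leaf.tissue_class = "leaf"
        r_stem = run_meta([stem, leaf], "stem", reference_map, seed=0)
        r_leaf = run_meta([stem, leaf], "leaf", reference_map, seed=0)
        assert [m.mqtl_id for m in r_stem.mqtls] == ["SIR1"]
        assert [m.mqtl_id for m in r_leaf.mqtls] == ["LIR1"]

    def test_mqtl_count_never_exceeds_qtl_count(self, reference_map):
        rng = np.random.default_rng(2)
        projected = []
        for i in range(12):
            pos = float(rng.uniform(5, 90))
            w = float(rng.uniform(2, 20))
            p = self.project(std(f"q{i}", pos - w / 2, pos + w / 2, 0.2))
            projected.append(p)
        result = run_meta(projected, "stem", reference_map, seed=1)
        assert 1 <= len(result.mqtls) <= 12
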