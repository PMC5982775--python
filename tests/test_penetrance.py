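"""EM estimator: likelihood arithmetic, actuarial collapse, oracle
equivalence with direct numerical maximization, and bootstrap behaviour."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import optimize
from scipy.special import expit

from kincohort import (
    EstimatorConfig,
    Family,
    GenotypeModel,
    HazardTable,
    MixingWeight,
    bootstrap_ci,
    cumulative_risk,
    fit_mml_em,
    marginal_loglik,
)
from kincohort.records import FollowUpRecord

from conftest import make_person


def fu(t, d, pid="x"):
    return FollowUpRecord("F", pid, "breast", float(t), d,
                          "none" if d else "last_followup")


def mw(p, pid="x"):
    return MixingWeight(pid, p)


class TestMarginalLoglik:
    def test_all_hazards_zero_censored(self):
        hz = HazardTable([40.0], [0.0], [0.0])
        assert marginal_loglik([fu(50, 0)], [mw(0.5)], hz) == 0.0

    def test_degenerate_mixture_single_event(self):
        hz = HazardTable([40.0], [0.2], [0.05])
        got = marginal_loglik([fu(40, 1)], [mw(1.0)], hz)
        assert got == pytest.approx(math.log(0.2))

    def test_two_relative_hand_computation(self):
        # event at 50 and censoring at 45 on grid (40, 50):
        #   L1(event) = 0.9*0.2, L0(event) = 0.95*0.1
        #   L1(cens)  = 0.9,     L0(cens)  = 0.95
        hz = HazardTable([40.0, 50.0], [0.1, 0.2], [0.05, 0.1])
        got = marginal_loglik([fu(50, 1), fu(45, 0)],
                              [mw(0.5), mw(0.5)], hz)
        want = math.log(0.5 * 0.18 + 0.5 * 0.095) + \
            math.log(0.5 * 0.9 + 0.5 * 0.95)
        assert got == pytest.approx(want, rel=1e-12)

    def test_event_off_grid_errors(self):
        hz = HazardTable([40.0], [0.1], [0.1])
        with pytest.raises(ValueError):
            marginal_loglik([fu(45, 1)], [mw(0.5)], hz)

    def test_weight_count_mismatch(self):
        hz = HazardTable([40.0], [0.1], [0.1])
        with pytest.raises(ValueError):
            marginal_loglik([fu(40, 1)], [], hz)


def _toy_families(rows):
    """Families from (genotype, onset_or_None, last) relative rows, all
    under one carrier proband."""
    pro = make_person("F1", "p", "proband", genotype="carrier",
                      breast=40.0, last=50.0)
    rels = [make_person("F1", f"r{i}", "sister", genotype=gt, breast=onset,
                        last=last)
            for i, (gt, onset, last) in enumerate(rows)]
    return [Family("F1", pro, rels, proband_gene_status="BRCA1")]


class TestFitEM:
    def test_fully_genotyped_collapses_to_actuarial(self):
        fams = _toy_families([
            ("carrier", 40.0, 40.0), ("carrier", None, 60.0),
            ("carrier", 50.0, 50.0), ("carrier", None, 45.0),
            ("noncarrier", 40.0, 40.0), ("noncarrier", None, 70.0),
            ("noncarrier", None, 70.0), ("noncarrier", None, 35.0),
        ])
        state = fit_mml_em(fams, "breast", GenotypeModel(q=0.02))
        # stratified occurrence/exposure computed by hand per class:
        # carriers: risk sets at 40: {40,60,50,45} -> 1/4; at 50: {60,50} -> 1/2
        # noncarriers: at 40: {40,70,70} -> 1/3 (r at 35 left the risk set); at 50: {70,70} -> 0
        np.testing.assert_allclose(state.hazards.grid, [40.0, 50.0])
        np.testing.assert_allclose(state.hazards.lambda_carrier,
                                   [0.25, 0.5], atol=1e-10)
        np.testing.assert_allclose(state.hazards.lambda_noncarrier,
                                   [1.0 / 3.0, 0.0], atol=1e-10)

    def test_no_carrier_events_gives_zero_carrier_hazard(self):
        fams = _toy_families([
            ("carrier", None, 60.0), ("carrier", None, 55.0),
            ("noncarrier", 45.0, 45.0), ("noncarrier", None, 70.0),
        ])
        state = fit_mml_em(fams, "breast", GenotypeModel(q=0.02))
        np.testing.assert_allclose(state.hazards.lambda_carrier, 0.0,
                                   atol=1e-12)
        assert state.hazards.lambda_noncarrier[0] > 0

    def test_no_events_raises(self):
        fams = _toy_families([("untested", None, 60.0)])
        with pytest.raises(ValueError):
            fit_mml_em(fams, "breast", GenotypeModel(q=0.02))

    def test_loglik_trace_nondecreasing(self, small_registry):
        state = fit_mml_em(small_registry, "breast", GenotypeModel(q=0.05))
        diffs = np.diff(state.loglik_trace)
        assert np.all(diffs >= -1e-9)

    def test_em_matches_direct_maximization(self):
        """On a small mixed-weight toy the EM solution must agree with a
        general-purpose optimizer run directly on the marginal
        log-likelihood over logit-hazards."""
        # observed genotypes in both classes anchor the hazards, so the
        # marginal likelihood has a unique, well-separated maximum
        fams = _toy_families([
            ("carrier", 40.0, 40.0), ("carrier", 50.0, 50.0),
            ("carrier", None, 60.0),
            ("noncarrier", 40.0, 40.0), ("noncarrier", None, 70.0),
            ("noncarrier", None, 70.0),
            ("untested", 40.0, 40.0), ("untested", None, 45.0),
            ("untested", 50.0, 50.0), ("untested", None, 55.0),
        ])
        model = GenotypeModel(q=0.05)
        state = fit_mml_em(fams, "breast", model,
                           EstimatorConfig(tol=1e-12, max_iter=20000))
        grid = state.hazards.grid
        K = len(grid)
        assert K <= 4

        followups, weights = [], []
        from kincohort.mendelian import mixing_weight
        from kincohort.records import derive_followup
        for fam in fams:
            for rel in fam.relatives:
                followups.append(derive_followup(rel, "breast"))
                weights.append(mixing_weight(rel, "carrier", model))

        def neg(z):
            lam = expit(z)
            hz = HazardTable(grid, lam[:K], lam[K:])
            return -marginal_loglik(followups, weights, hz)

        best = None
        for s in range(6):
            rng = np.random.default_rng(s)
            res = optimize.minimize(neg, rng.normal(-1.5, 1.0, 2 * K),
                                    method="Nelder-Mead",
                                    options={"maxiter": 20000,
                                             "xatol": 1e-10,
                                             "fatol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
        lam_opt = expit(best.x)
        assert -best.fun == pytest.approx(state.loglik, abs=1e-6)
        np.testing.assert_allclose(state.hazards.lambda_carrier,
                                   lam_opt[:K], atol=1e-4)
        np.testing.assert_allclose(state.hazards.lambda_noncarrier,
                                   lam_opt[K:], atol=1e-4)


class TestCumulativeRisk:
    def test_zero_hazards_zero_risk(self):
        hz = HazardTable([30.0, 40.0], [0.0, 0.0], [0.0, 0.0])
        curve = cumulative_risk(hz, 20, 70)
        np.testing.assert_allclose(curve.F, 0.0)

    def test_unit_hazard_is_absorbing(self):
        hz = HazardTable([30.0, 40.0], [1.0, 0.0], [0.0, 0.0])
        curve = cumulative_risk(hz, 20, 70, ages=[30, 40, 70])
        np.testing.assert_allclose(curve.F, 1.0)

    def test_constant_hazard_closed_form(self):
        grid = np.arange(21, 71, dtype=float)
        hz = HazardTable(grid, np.full(50, 0.01), np.zeros(50))
        curve = cumulative_risk(hz, 20, 70, ages=[70])
        assert curve.F[0] == pytest.approx(1 - 0.99**50, rel=1e-12)

    def test_hazards_before_origin_excluded(self):
        hz = HazardTable([15.0, 30.0], [0.5, 0.1], [0.0, 0.0])
        curve = cumulative_risk(hz, 20, 70, ages=[70])
        assert curve.F[0] == pytest.approx(0.1)

    def test_invalid_window(self):
        hz = HazardTable([30.0], [0.1], [0.0])
        with pytest.raises(ValueError):
            cumulative_risk(hz, 70, 20)


class TestBootstrap:
    def test_identical_families_give_zero_width_interval(self):
        fam = _toy_families([("carrier", 45.0, 45.0),
                             ("carrier", None, 60.0),
                             ("noncarrier", None, 60.0)])[0]
        fams = []
        for i in range(12):
            pro = make_person(f"F{i}", "p", "proband", genotype="carrier",
                              breast=40.0, last=50.0)
            rels = [make_person(f"F{i}", f"r{k}.{i}", r.role,
                                genotype=r.genotype,
                                breast=r.age_breast_dx, last=r.age_last)
                    for k, r in enumerate(fam.relatives)]
            fams.append(Family(f"F{i}", pro, rels,
                               proband_gene_status="BRCA1"))
        config = EstimatorConfig(B=50, seed=3, report_ages=[50.0],
                                 min_events_for_ci=1)
        res = bootstrap_ci(fams, "breast", GenotypeModel(q=0.02), config)
        assert res.carrier.ci_low[0] == pytest.approx(res.carrier.F[0],
                                                      abs=1e-9)
        assert res.carrier.ci_high[0] == pytest.approx(res.carrier.F[0],
                                                       abs=1e-9)

    def test_seed_reproducibility(self, small_registry):
        config = EstimatorConfig(B=40, seed=9, min_events_for_ci=1)
        a = bootstrap_ci(small_registry, "breast", GenotypeModel(q=0.05),
                         config)
        b = bootstrap_ci(small_registry, "breast", GenotypeModel(q=0.05),
                         config)
        np.testing.assert_array_equal(a.carrier.ci_low, b.carrier.ci_low)
        np.testing.assert_array_equal(a.noncarrier.ci_high,
                                      b.noncarrier.ci_high)

    def test_sparse_class_reported_without_band(self, small_registry):
        config = EstimatorConfig(B=20, seed=1, min_events_for_ci=1000)
        res = bootstrap_ci(small_registry, "breast", GenotypeModel(q=0.05),
                           config)
        assert res.carrier.ci_low is None
        assert res.carrier.F is not None

    def test_band_brackets_point_estimate(self, small_registry):
        config = EstimatorConfig(B=60, seed=5, min_events_for_ci=1)
        res = bootstrap_ci(small_registry, "breast", GenotypeModel(q=0.05),
                           config)
        for curve in (res.carrier, res.noncarrier):
            assert np.all(curve.ci_low <= curve.F + 1e-12)
            assert np.all(curve.ci_high >= curve.F - 1e-12)
            assert np.all(curve.F >= 0) and np.all(curve.F <= 1)
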