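import json
import math

import numpy as np
import pytest

from netmr.exceptions import ConfigurationError, EstimationError, NetmrError
from netmr.network import (
    MediatorPair,
    NetworkConfig,
    StepConfig,
    bootstrap_proportion,
    mediation_proportion,
    replication_filter,
    run_network,
    run_step,
    write_report,
)
from netmr.simulate import SimulationConfig, simulate_study, theoretical_effects

# skip the PRESSO bootstrap where outlier handling is not under test
FAST = StepConfig(presso_nsim=0)


def study(seed, **kw):
    return simulate_study(SimulationConfig(seed=seed, **kw))


class TestMediationProportion:
    def test_waist_circumference_any_stroke_example(self):
        """Printed consortium effects: SHBG->WC -0.091, WC->stroke OR 1.135,
        SHBG->stroke OR 0.941 -> 18.9% of the total effect mediated."""
        res = mediation_proportion(math.log(0.941), -0.091, math.log(1.135),
                                   se_total=0.012, se_xm=0.023, se_my=0.054)
        assert 100 * res.proportion == pytest.approx(18.9, abs=0.5)
        assert res.indirect == pytest.approx(-0.091 * math.log(1.135))
        assert res.proportion == pytest.approx(res.indirect / math.log(0.941))

    def test_triglycerides_small_vessel_example(self):
        res = mediation_proportion(math.log(0.871), -0.188, math.log(1.182))
        assert 100 * res.proportion == pytest.approx(22.8, abs=0.5)

    def test_null_mediator_outcome_path(self):
        res = mediation_proportion(-0.1, -0.2, 0.0)
        assert res.proportion == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(EstimationError):
            mediation_proportion(0.0, -0.2, 0.1)

    def test_inconsistent_mediation_warns(self):
        with pytest.warns(UserWarning, match="inconsistent mediation"):
            res = mediation_proportion(0.01, 0.5, 0.5)
        assert res.out_of_range

    def test_delta_se_formula(self):
        bt, bxm, bmy = -0.2, -0.3, 0.4
        st_, sxm, smy = 0.02, 0.03, 0.04
        res = mediation_proportion(bt, bxm, bmy, st_, sxm, smy)
        var = ((bmy / bt) ** 2 * sxm**2 + (bxm / bt) ** 2 * smy**2
               + (bxm * bmy / bt**2) ** 2 * st_**2)
        assert res.proportion_se == pytest.approx(math.sqrt(var), rel=1e-12)
        assert res.ci_low == pytest.approx(res.proportion - 1.96 * res.proportion_se)

    def test_delta_se_agrees_with_bootstrap(self):
        bt, bxm, bmy = -0.2, -0.3, 0.4
        st_, sxm, smy = 0.01, 0.015, 0.02
        res = mediation_proportion(bt, bxm, bmy, st_, sxm, smy)
        bs_se, (lo, hi) = bootstrap_proportion(bt, bxm, bmy, st_, sxm, smy,
                                               n_draws=20000, seed=1)
        assert bs_se == pytest.approx(res.proportion_se, rel=0.15)
        assert lo < res.proportion < hi

    def test_unit_rescaling_invariance(self):
        """Rescaling the mediator's units (xm * c, my / c) leaves the
        proportion unchanged."""
        c = 4.2
        a = mediation_proportion(-0.2, -0.3, 0.4)
        b = mediation_proportion(-0.2, -0.3 * c, 0.4 / c)
        assert b.proportion == pytest.approx(a.proportion, rel=1e-12)


class TestReplicationFilter:
    def _step(self, beta, p, name="mediator"):
        class E:
            pass

        est = E()
        est.beta, est.pvalue = beta, p
        s = E()
        s.exposure_name, s.outcome_name, s.estimate = "exp", name, est
        return s

    def test_both_significant_same_sign_passes(self):
        v = replication_filter(self._step(-0.1, 0.04), self._step(-0.2, 0.03))
        assert v.passed

    def test_failed_replication(self):
        v = replication_filter(self._step(-0.1, 0.04), self._step(-0.2, 0.20))
        assert not v.passed

    def test_sign_discordance_fails(self):
        v = replication_filter(self._step(-0.1, 0.01), self._step(0.1, 0.01))
        assert not v.passed
        assert v.reason == "sign_discordant"

    def test_trait_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            replication_filter(self._step(-0.1, 0.01, "m1"), self._step(-0.1, 0.01, "m2"))


class TestRunStep:
    def test_chain_recovery_coverage(self):
        """Chosen estimate's own 95% CI covers the true total effect in
        >= 93% of 200 replicates of the full selection pipeline."""
        covered = 0
        n = 200
        for s in range(n):
            st_ = study(1000 + s)
            res = run_step(st_.exposure, st_.outcome, StepConfig(presso_nsim=0, seed=s))
            total = theoretical_effects(st_.truth)[0]
            covered += res.estimate.ci_low <= total <= res.estimate.ci_high
        assert covered / n >= 0.93

    def test_null_effect_calibration(self):
        """True effect 0: the CI covers zero at roughly the nominal rate."""
        covered = 0
        n = 150
        for s in range(n):
            st_ = study(3000 + s, gamma_xm=0.0, theta_direct=0.0, k_snps_mediator=0)
            res = run_step(st_.exposure, st_.outcome, StepConfig(presso_nsim=0, seed=s))
            covered += res.estimate.ci_low <= 0 <= res.estimate.ci_high
        assert 0.90 <= covered / n <= 1.0

    def test_too_few_instruments_error_carries_step_label(self):
        st_ = study(4)
        # absurd threshold leaves nothing significant
        with pytest.raises(NetmrError, match="exposure_outcome"):
            run_step(st_.exposure, st_.outcome, StepConfig(p_threshold=1e-300))

    def test_sensitivity_record_complete(self):
        st_ = study(5)
        res = run_step(st_.exposure, st_.outcome, StepConfig(presso_nsim=2000))
        assert res.heterogeneity.df == res.harmonized.k - 1
        assert res.egger is not None
        assert res.loo is not None and len(res.loo.estimates) == res.harmonized.k
        assert res.presso  # ran at least one round
        assert res.estimate.method in ("ivw_fe", "ivw_mre")


def one_mediator_config(st_, seed=0, nsim=0):
    return NetworkConfig(
        exposure=st_.exposure,
        outcomes=[st_.outcome],
        mediators=[MediatorPair("mediator", st_.mediator, st_.mediator_replication)],
        step=StepConfig(presso_nsim=nsim, seed=seed),
    )


class TestRunNetwork:
    def test_single_chain_qualifies_and_decomposes(self):
        st_ = study(12)
        rep = run_network(one_mediator_config(st_))
        assert rep.qualified_mediators == ["mediator"]
        assert len(rep.mediation_forward) == 1
        med = rep.mediation_forward[0]
        truth_prop = theoretical_effects(st_.truth)[2]
        assert med.proportion == pytest.approx(truth_prop, abs=0.2)
        # decomposition: indirect + direct ~ total
        direct = med.beta_total - med.indirect
        assert med.beta_total == pytest.approx(direct + med.indirect, rel=1e-12)

    def test_mostly_disjoint_instruments(self):
        st_ = study(13)
        rep = run_network(one_mediator_config(st_))
        overlap = rep.instrument_overlap["mediator"]
        k_med = len(rep.mediator_exposure["mediator"].instrument_ids)
        assert len(overlap) < 0.2 * k_med

    def test_null_mediator_filtered_out(self):
        """A mediator with zero exposure->mediator effect passes the
        discovery+replication screen only at the alpha level."""
        passed = 0
        n = 40
        for s in range(n):
            st_ = study(8000 + s, gamma_xm=0.0, theta_direct=0.3)
            rep = run_network(one_mediator_config(st_, seed=s))
            passed += bool(rep.qualified_mediators)
        assert passed / n <= 0.10

    def test_empty_mediator_list_reports_step1_only(self):
        st_ = study(14)
        cfg = NetworkConfig(exposure=st_.exposure, outcomes=[st_.outcome],
                            mediators=[], step=FAST)
        rep = run_network(cfg)
        assert list(rep.step1) == ["outcome"]
        assert rep.mediation_forward == [] and rep.mediation_reverse == []

    def test_report_files_written(self, tmp_path):
        st_ = study(15)
        rep = run_network(one_mediator_config(st_))
        write_report(rep, tmp_path)
        for name in ("estimates.tsv", "sensitivity.tsv", "mediation.tsv", "summary.json"):
            assert (tmp_path / name).exists()
        summary = json.loads((tmp_path / "summary.json").read_text())
        assert summary["qualified_mediators"] == ["mediator"]
        assert summary["mediation_forward"][0]["proportion"] == pytest.approx(
            rep.mediation_forward[0].proportion)
        assert (tmp_path / "audit").is_dir()


def test_total_decomposes_across_legs():
    """On synthetic data the exposure->outcome total is approximately the
    direct path plus the product of the two mediated legs."""
    totals, indirects = [], []
    for s in range(30):
        st_ = study(9000 + s)
        cfg = one_mediator_config(st_, seed=s)
        rep = run_network(cfg)
        if not rep.mediation_forward:
            continue
        med = rep.mediation_forward[0]
        totals.append(med.beta_total)
        indirects.append(med.indirect)
    truth = theoretical_effects(SimulationConfig())
    assert np.mean(totals) == pytest.approx(truth[0], abs=0.01)
    assert np.mean(indirects) == pytest.approx(truth[1], abs=0.01)
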