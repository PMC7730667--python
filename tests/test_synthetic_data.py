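import io

import numpy as np
import pytest
from scipy.stats import chisquare

from symptomnet.data_model import SymptomCodebook
from symptomnet.synthetic_data import (
    STUDY_PREVALENCE,
    ConvergenceError,
    IsingModelSpec,
    calibrate_thresholds,
    emulate_study,
    enumerate_distribution,
    sample,
    study_specs,
)

from conftest import make_codebook


def random_spec(p: int, seed: int, scale: float = 1.0) -> IsingModelSpec:
    rng = np.random.default_rng(seed)
    beta = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    beta[iu] = rng.uniform(-scale, scale, size=len(iu[0]))
    beta = beta + beta.T
    tau = rng.uniform(-1.5, 0.5, size=p)
    return IsingModelSpec(tau, beta, make_codebook(p))


class TestEnumeration:
    def test_independent_zero_field_model_is_uniform(self):
        spec = IsingModelSpec(np.zeros(3), np.zeros((3, 3)), make_codebook(3))
        dist = enumerate_distribution(spec)
        assert dist.probabilities == pytest.approx(np.full(8, 1 / 8))

    def test_two_node_unit_coupling_hand_values(self):
        spec = IsingModelSpec(
            np.zeros(2), np.array([[0.0, 1.0], [1.0, 0.0]]), make_codebook(2)
        )
        dist = enumerate_distribution(spec)
        e = np.e
        # states in LSB order: 00, 10, 01, 11
        assert dist.probabilities[3] == pytest.approx(e / (3 + e), abs=1e-12)
        assert dist.marginals()[0] == pytest.approx((1 + e) / (3 + e), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_probabilities_normalize(self, seed):
        dist = enumerate_distribution(random_spec(4, seed))
        assert abs(dist.probabilities.sum() - 1.0) < 1e-12
        assert (dist.probabilities >= 0).all()

    def test_conditional_matches_logistic_at_every_state(self):
        spec = random_spec(4, seed=9)
        dist = enumerate_distribution(spec)
        pr, states = dist.probabilities, dist.states()
        for j in range(4):
            for s in range(2**4):
                partner = s ^ (1 << j)  # flip node j
                hi, lo = (s, partner) if states[s, j] == 1 else (partner, s)
                cond = pr[hi] / (pr[hi] + pr[lo])
                eta = spec.tau[j] + spec.beta[j] @ states[hi]
                assert cond == pytest.approx(1 / (1 + np.exp(-eta)), abs=1e-12)

    def test_large_p_refused_with_gibbs_hint(self):
        spec = IsingModelSpec(
            np.zeros(21), np.zeros((21, 21)), make_codebook(21)
        )
        with pytest.raises(ValueError, match="Gibbs"):
            enumerate_distribution(spec)


class TestSampling:
    def test_fair_coin_marginals_within_three_se(self):
        p, n = 9, 100_000
        spec = IsingModelSpec(np.zeros(p), np.zeros((p, p)), make_codebook(p))
        ds = sample(spec, n, seed=1)
        se = np.sqrt(0.25 / n)
        assert np.abs(ds.values.mean(axis=0) - 0.5).max() < 3 * se

    def test_exact_sampler_is_iid_lag_one(self):
        spec = random_spec(3, seed=2)
        ds = sample(spec, 50_000, seed=4)
        x = ds.values[:, 0].astype(float)
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(x))

    def test_gibbs_agrees_with_exact_enumeration(self):
        spec = random_spec(4, seed=5)
        dist = enumerate_distribution(spec)
        n = 20_000
        ds = sample(spec, n, seed=5, method="gibbs")
        codes = ds.values @ (1 << np.arange(4))
        obs = np.bincount(codes, minlength=16)
        assert chisquare(obs, n * dist.probabilities).pvalue > 0.001

    def test_sampling_is_deterministic(self):
        spec = random_spec(3, seed=6)
        a = sample(spec, 500, seed=8)
        b = sample(spec, 500, seed=8)
        assert np.array_equal(a.values, b.values)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            sample(random_spec(2, 0), 10, seed=0, method="metropolis")


class TestCalibration:
    def test_independent_model_closed_form(self):
        tau = calibrate_thresholds(np.zeros((3, 3)), np.array([0.45, 0.2, 0.5]))
        assert tau[0] == pytest.approx(np.log(0.45 / 0.55), abs=1e-12)
        assert tau[2] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_calibrate_then_enumerate_self_consistency(self, seed):
        rng = np.random.default_rng(seed)
        spec = random_spec(5, seed, scale=0.8)
        targets = rng.uniform(0.1, 0.6, size=5)
        tau = calibrate_thresholds(spec.beta, targets, labels=spec.labels)
        m = enumerate_distribution(
            IsingModelSpec(tau, spec.beta, spec.labels)
        ).marginals()
        assert np.abs(m - targets).max() < 1e-6

    def test_survey_prevalence_targets_are_reachable(self):
        specs = study_specs()
        for level in ("female", "male"):
            m = enumerate_distribution(specs[level]).marginals()
            assert np.abs(m - STUDY_PREVALENCE[level]).max() < 1e-6

    def test_boundary_targets_rejected(self):
        with pytest.raises(ValueError, match="strictly"):
            calibrate_thresholds(np.zeros((2, 2)), np.array([0.0, 0.5]))


class TestStudyEmulation:
    def test_dataset_shape_and_stratum_sizes(self):
        ds = emulate_study(seed=42)
        assert (ds.n, ds.p) == (555, 9)
        assert ds.covariates["gender"].value_counts().to_dict() == {
            "female": 288, "male": 267
        }
        assert ds.covariates["age_group"].value_counts().to_dict() == {
            "65-74": 296, "75-84": 259
        }

    def test_female_depressed_mood_prevalence_near_target(self):
        ds = emulate_study(seed=42)
        fem = ds.values[(ds.covariates["gender"] == "female").to_numpy()]
        target = STUDY_PREVALENCE["female"][0]  # DM
        se = np.sqrt(target * (1 - target) / len(fem))
        assert abs(fem[:, 0].mean() - target) < 3 * se

    def test_rerun_with_same_seed_is_bit_identical(self):
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            emulate_study(seed=7).to_frame().to_csv(buf, index=False)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_truth_report_carries_the_generating_model(self):
        ds, truth = emulate_study(seed=3, return_truth=True)
        assert set(truth["strata"]) == {"female", "male"}
        beta = np.array(truth["strata"]["female"]["beta"])
        assert np.array_equal(beta, beta.T)
        assert truth["strata"]["male"]["n"] == 267
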