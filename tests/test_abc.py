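"""ABC inference: Wasserstein metric, region distances, rejection sampler."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecdnasim import (
    ABCRejection,
    ABCSettings,
    ObservedPatientData,
    PriorGrid,
    posterior_summary,
    region_distance,
    wasserstein1d,
)
from ecdnasim.abc import _accept_mask
from ecdnasim.io import generate_synthetic_patient


def transport_w1(a, b):
    """Independent oracle: exhaustive minimum-cost assignment for equal-size
    multisets (W1 * n = min over permutations of sum |a_i - b_perm(i)|)."""
    n = len(a)
    best = min(sum(abs(x - y) for x, y in zip(a, perm))
               for perm in itertools.permutations(b))
    return best / n


class TestWasserstein:
    def test_identity_and_point_masses(self):
        assert wasserstein1d([1, 2, 3], [1, 2, 3]) == 0.0
        assert wasserstein1d([0], [4]) == 4.0

    def test_matches_transport_oracle_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 6))
            a = rng.integers(0, 10, n).tolist()
            b = rng.integers(0, 10, n).tolist()
            assert wasserstein1d(a, b) == pytest.approx(transport_w1(a, b))

    def test_unequal_sizes_via_lcm_expansion(self):
        rng = np.random.default_rng(1)
        for _ in range(12):
            a = rng.integers(0, 8, 2).tolist()
            b = rng.integers(0, 8, 3).tolist()
            # equalize weights by replication to the LCM size, then match
            expect = transport_w1(a * 3, b * 2)
            assert wasserstein1d(a, b) == pytest.approx(expect)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wasserstein1d([], [1])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.integers(min_value=0, max_value=100), min_size=1, max_size=30),
           st.integers(min_value=-20, max_value=20))
    def test_translation_identity(self, a, c):
        shifted = [x + c for x in a]
        assert wasserstein1d(a, shifted) == pytest.approx(abs(c))


class TestRegionDistance:
    def test_self_distance_zero(self):
        obs = np.array([3, 5, 8, 12])
        assert region_distance(obs, obs) == (0.0, 0.0)

    def test_fraction_gap_arithmetic(self):
        obs = np.array([3, 4, 5, 6, 7])
        sim = np.array([0, 4, 5, 6, 7])
        w, gap = region_distance(sim, obs)
        assert gap == pytest.approx(1 / 5)

    def test_composes_with_wasserstein_on_filtered(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = 30
            sim = rng.integers(0, 20, n)
            obs = rng.integers(0, 20, n)
            w, _ = region_distance(sim, obs, min_copy_filter=3)
            sim_f, obs_f = sim[sim >= 3], obs[obs >= 3]
            if len(sim_f) and len(obs_f):
                assert w == pytest.approx(wasserstein1d(sim_f, obs_f))
            else:
                assert w == np.inf

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            region_distance([1, 2], [1, 2, 3])


class TestObservedPatientData:
    def test_from_copy_table(self):
        df = pd.DataFrame({
            "tumor_id": ["t"] * 6,
            "region": ["core", "core", "margin", "margin", "margin", "leading_edge"],
            "replicate": [0, 0, 0, 0, 1, 0],
            "cell_id": [0, 1, 0, 1, 0, 0],
            "copies": [5, 8, 4, 9, 7, 3],
        })
        obs = ObservedPatientData.from_copy_table(df)
        assert obs.core.tolist() == [5, 8]
        assert [m.tolist() for m in obs.margins] == [[4, 9], [7]]
        assert obs.leading_edge.tolist() == [3]

    def test_requires_margin(self):
        with pytest.raises(ValueError):
            ObservedPatientData(core=[5, 6], margins=[])


@pytest.fixture(scope="module")
def patient():
    return generate_synthetic_patient(
        dict(k=20, s=1.0, q=5), dict(core=200, margins=[200]),
        seed=77, n_final=2000)


class TestRejectionSampler:

    def test_degenerate_thresholds_accept_everything(self, patient):
        settings_ = ABCSettings(budget=20, eps_region=1e9, delta_fraction=1.0,
                                n_final=500)
        res = ABCRejection(patient.observed(), PriorGrid(), settings_).fit(seed=3)
        assert res.acceptance_rate == 1.0
        assert res.n_accepted == 20 * settings_.margins_per_sim

    def test_perfect_match_accepted_with_zero_sigma(self):
        pairs = pd.DataFrame([dict(k=5, s=1.0, q=5, w_core=0.0, w_margin=0.0,
                                   gap_core=0.0, gap_margin=0.0, sigma=0.0)])
        assert _accept_mask(pairs, ABCSettings()).all()

    def test_acceptance_monotone_in_eps(self, patient):
        def accepted_keys(eps):
            settings_ = ABCSettings(budget=40, eps_region=eps, n_final=1000)
            res = ABCRejection(patient.observed(), PriorGrid(), settings_).fit(seed=9)
            return set(map(tuple, res.posterior[["sim_seed", "pair_index"]].to_numpy()))

        tight = accepted_keys(2.0)
        loose = accepted_keys(6.0)
        assert tight <= loose

    def test_empty_posterior_reports_diagnostics(self, patient):
        settings_ = ABCSettings(budget=5, eps_region=1e-9, delta_fraction=0.0,
                                n_final=500)
        res = ABCRejection(patient.observed(), PriorGrid(), settings_).fit(seed=1)
        assert res.n_accepted == 0
        diag = res.diagnostics()
        assert diag["n_pairs"] == 5 * settings_.margins_per_sim
        assert "w_core_quantiles" in diag
        with pytest.raises(ValueError):
            res.summary()

    def test_recovery_estimates_track_truth(self):
        # point estimates of k increase with the generating k
        estimates = []
        for i, k in enumerate([5, 20, 80]):
            pat = generate_synthetic_patient(
                dict(k=k, s=1.0, q=5), dict(core=300, margins=[300]),
                seed=40 + i, n_final=3000)
            res = ABCRejection(pat.observed(), PriorGrid(),
                               ABCSettings(budget=300, n_final=3000)).fit(seed=50 + i)
            estimates.append(res.param_estimate("k", point="median"))
        assert estimates[0] < estimates[1] < estimates[2]


class TestPosteriorSummary:
    def test_single_row_zero_width(self):
        post = pd.DataFrame([dict(k=20, s=1.0, q=5)])
        summ = posterior_summary(post)
        assert summ.loc["k", "mode"] == 20
        assert summ.loc["k", "minus"] == 0 and summ.loc["k", "plus"] == 0

    def test_asymmetric_interval(self):
        post = pd.DataFrame({"k": [10] * 50 + list(range(10, 60)),
                             "s": [1.0] * 100, "q": [5] * 100})
        summ = posterior_summary(post)
        assert summ.loc["k", "mode"] == 10
        assert summ.loc["k", "plus"] > summ.loc["k", "minus"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            posterior_summary(pd.DataFrame(columns=["k", "s", "q"]))
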