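"""Gibbs admixture sampler, label alignment, L estimator and delta-K."""

import itertools

import numpy as np
import pandas as pd
import pytest

from strmix import (
    AdmixtureModelSpec,
    AncestryEstimate,
    GenotypeMatrix,
    SimConfig,
    align_cluster_labels,
    best_k,
    estimate_log_prob_data,
    evanno_delta_k,
    gibbs_admixture,
    make_sample_table,
    mean_cluster_by_locale,
    simulate_dataset,
)


def make_estimate(Q, ids=None):
    Q = np.asarray(Q, dtype=float)
    ids = ids or [f"i{k}" for k in range(len(Q))]
    return AncestryEstimate(
        individual_ids=ids,
        locus_ids=["L1"],
        Q=Q,
        P=[[np.array([1.0])] for _ in range(Q.shape[1])],
        allele_codes=[np.array([1])],
        loglik_trace=np.array([-1.0, -2.0]),
    )


class TestGibbs:
    def test_k1_gives_unit_membership(self, two_pool_dataset):
        matrix, _, _ = two_pool_dataset
        est = gibbs_admixture(
            matrix, AdmixtureModelSpec(K=1, sweeps=20, burnin=5, seed=0)
        )
        assert np.allclose(est.Q, 1.0)

    def test_normalisation_invariants(self, two_pool_dataset):
        matrix, _, _ = two_pool_dataset
        est = gibbs_admixture(
            matrix, AdmixtureModelSpec(K=3, sweeps=40, burnin=10, seed=1)
        )
        assert np.allclose(est.Q.sum(axis=1), 1.0, atol=1e-6)
        for k in range(3):
            for v in est.P[k]:
                assert np.isclose(v.sum(), 1.0, atol=1e-6)
        assert len(est.loglik_trace) == 30

    def test_two_pool_recovery(self, two_pool_dataset):
        matrix, _, truth = two_pool_dataset
        est = gibbs_admixture(
            matrix,
            AdmixtureModelSpec(
                K=2, sweeps=300, burnin=100, seed=7, infer_alpha=True
            ),
        )
        err = min(
            np.abs(est.Q[:, 0] - truth.true_Q[:, 0]).max(),
            np.abs(est.Q[:, 1] - truth.true_Q[:, 0]).max(),
        )
        assert err < 0.15  # max per-individual error after alignment

    def test_no_admixture_model_hard_assigns(self, two_pool_dataset):
        matrix, _, truth = two_pool_dataset
        est = gibbs_admixture(
            matrix,
            AdmixtureModelSpec(
                K=2, admixture_model=False, sweeps=100, burnin=40, seed=3
            ),
        )
        hard = est.Q.max(axis=1)
        assert (hard > 0.9).mean() > 0.9  # most posteriors concentrated

    def test_missing_calls_tolerated(self):
        cfg = SimConfig(
            n_forest_locales=1, n_savanna_locales=1, n_mixed_locales=0,
            individuals_per_locale=10, missing_rate=0.2, seed=5,
        )
        matrix, _, _ = simulate_dataset(cfg)
        est = gibbs_admixture(
            matrix, AdmixtureModelSpec(K=2, sweeps=50, burnin=10, seed=0)
        )
        assert np.isfinite(est.loglik_trace).all()

    def test_recovery_improves_with_loci(self):
        # parameter recovery sharpens as the panel grows, matched seeds
        maes = {}
        for n_loci in (6, 24):
            errs = []
            for rep in range(10):
                cfg = SimConfig(
                    n_forest_locales=1, n_savanna_locales=1, n_mixed_locales=0,
                    individuals_per_locale=15, n_loci=n_loci,
                    divergence_F=0.2, missing_rate=0.0, seed=500 + rep,
                )
                matrix, _, truth = simulate_dataset(cfg)
                est = gibbs_admixture(
                    matrix,
                    AdmixtureModelSpec(
                        K=2, sweeps=150, burnin=50, seed=rep, infer_alpha=True
                    ),
                )
                err = min(
                    np.abs(est.Q[:, 0] - truth.true_Q[:, 0]).mean(),
                    np.abs(est.Q[:, 1] - truth.true_Q[:, 0]).mean(),
                )
                errs.append(err)
            maes[n_loci] = np.mean(errs)
        assert maes[24] <= maes[6]

    @pytest.mark.parametrize(
        "kwargs", [{"K": 0}, {"sweeps": 10, "burnin": 10}, {"alpha": 0.0}]
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AdmixtureModelSpec(**kwargs)


class TestAlignment:
    def test_identity_on_self(self):
        ref = make_estimate([[0.9, 0.1], [0.2, 0.8]])
        out = align_cluster_labels(ref, ref)
        assert np.allclose(out.Q, ref.Q)

    def test_recovers_column_swap(self):
        ref = make_estimate([[0.9, 0.1], [0.2, 0.8], [0.7, 0.3]])
        swapped = make_estimate(ref.Q[:, ::-1])
        out = align_cluster_labels(ref, swapped)
        assert np.allclose(out.Q, ref.Q)

    def test_matches_brute_force_at_k3(self):
        rng = np.random.default_rng(12)
        q1 = rng.dirichlet(np.ones(3), size=20)
        perm_true = (2, 0, 1)
        q2 = q1[:, perm_true] + rng.normal(0, 0.01, size=q1.shape)
        q2 = np.abs(q2)
        q2 /= q2.sum(axis=1, keepdims=True)
        ref, other = make_estimate(q1), make_estimate(q2)
        out = align_cluster_labels(ref, other)
        # brute-force oracle: best of all 6 permutations by the same score
        best_perm = max(
            itertools.permutations(range(3)),
            key=lambda p: np.sum(q1 * q2[:, p]),
        )
        assert np.allclose(out.Q, q2[:, best_perm])

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            align_cluster_labels(
                make_estimate([[1.0], [1.0]]), make_estimate([[0.5, 0.5]] * 2)
            )


class TestLogProbEstimate:
    def test_constant_trace(self):
        assert estimate_log_prob_data([-5.0, -5.0, -5.0]) == -5.0

    def test_hand_arithmetic(self):
        assert estimate_log_prob_data([-10.0, -12.0]) == pytest.approx(-12.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_log_prob_data([-1.0])


class TestDeltaK:
    def test_linear_l_gives_zero(self):
        runs = {1: [-10.0, -11.0], 2: [-8.0, -9.0], 3: [-6.0, -7.0]}
        dk = evanno_delta_k(runs)
        assert dk.loc[dk.K == 2, "delta_K"].iloc[0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        runs = {
            1: [-1000.0, -1000.0, -1000.0],
            2: [-900.0, -902.0, -904.0],
            3: [-880.0, -880.0, -880.0],
        }
        dk = evanno_delta_k(runs)
        assert dk.loc[dk.K == 2, "delta_K"].iloc[0] == pytest.approx(38.0)

    def test_boundaries_undefined(self):
        runs = {k: [-10.0 * k, -10.0 * k - 1] for k in (1, 2, 3)}
        dk = evanno_delta_k(runs)
        assert np.isnan(dk.loc[dk.K == 1, "delta_K"].iloc[0])
        assert np.isnan(dk.loc[dk.K == 3, "delta_K"].iloc[0])

    def test_two_k_values_rejected(self):
        with pytest.raises(ValueError):
            evanno_delta_k({1: [-1.0, -2.0], 2: [-1.0, -2.0]})

    def test_zero_sd_warns_infinite(self):
        runs = {1: [-9.0, -9.0], 2: [-5.0, -5.0], 3: [-4.0, -4.0]}
        with pytest.warns(UserWarning):
            dk = evanno_delta_k(runs)
        assert np.isinf(dk.loc[dk.K == 2, "delta_K"].iloc[0])

    def test_three_cluster_data_peaks_at_k3(self):
        # delta-K should vote K=3 on three-pool data for most seeds
        wins = 0
        for exp in range(5):
            rng = np.random.default_rng(200 + exp)
            n, L = 20, 10
            calls = np.zeros((3 * n, L, 2), dtype=np.int64)
            for pool in range(3):
                # three pools on disjoint allele ladders
                codes = 100 + 4 * (3 * pool + rng.integers(0, 3, size=(n, L, 2)))
                calls[pool * n : (pool + 1) * n] = codes
            m = GenotypeMatrix(
                [f"i{k}" for k in range(3 * n)],
                [f"L{j}" for j in range(L)],
                calls,
            )
            runs = {}
            for K in (1, 2, 3, 4):
                runs[K] = [
                    gibbs_admixture(
                        m,
                        AdmixtureModelSpec(
                            K=K, sweeps=300, burnin=120,
                            seed=1000 * exp + 10 * K + r, infer_alpha=True,
                        ),
                    ).L_hat
                    for r in range(5)
                ]
            wins += best_k(evanno_delta_k(runs)) == 3
        assert wins >= 3


class TestLocaleMeans:
    def test_single_locale_pure(self):
        est = make_estimate([[1.0, 0.0], [1.0, 0.0]], ids=["a", "b"])
        table = make_sample_table(["a", "b"], ["X", "X"])
        out = mean_cluster_by_locale(est, table)
        assert out.loc[0, "q_1"] == 1.0 and out.loc[0, "q_2"] == 0.0

    def test_arithmetic_mean(self):
        est = make_estimate([[1.0, 0.0], [0.8, 0.2]], ids=["a", "b"])
        table = make_sample_table(["a", "b"], ["X", "X"])
        out = mean_cluster_by_locale(est, table)
        assert out.loc[0, "q_1"] == pytest.approx(0.9)

    def test_unknown_individual_rejected(self):
        est = make_estimate([[1.0, 0.0]], ids=["ghost"])
        table = make_sample_table(["a"], ["X"])
        with pytest.raises(ValueError, match="ghost"):
            mean_cluster_by_locale(est, table)
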