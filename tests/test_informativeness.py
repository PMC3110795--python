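"""Shannon information content profiles, locus ranking, panel evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strmix import (
    SimConfig,
    evaluate_panel,
    max_sic,
    population_freqs,
    rank_loci,
    sic_profile,
    simulate_dataset,
)


class TestSicProfile:
    def test_identical_frequencies_uninformative(self):
        p = np.array([0.3, 0.7])
        prof = sic_profile(p, p)
        assert np.allclose(prof.sic_values, 0.0, atol=1e-12)

    def test_vanishes_at_grid_edges(self):
        prof = sic_profile(
            [0.9, 0.1], [0.2, 0.8], m_grid=np.array([1e-9, 0.5, 1 - 1e-9])
        )
        assert prof.sic_values[0] < 1e-6
        assert prof.sic_values[-1] < 1e-6

    def test_fully_diagnostic_biallelic_is_one_bit(self):
        prof = sic_profile([1.0, 0.0], [0.0, 1.0], m_grid=np.array([0.5]))
        assert prof.sic_values[0] == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_asymmetric_case(self):
        prof = sic_profile([1.0, 0.0], [0.5, 0.5], m_grid=np.array([0.5]))
        assert prof.sic_values[0] == pytest.approx(0.31128, abs=1e-5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_concavity_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        p1, p2 = rng.dirichlet(np.ones(k)), rng.dirichlet(np.ones(k))
        grid = np.linspace(0.01, 0.99, 99)
        prof = sic_profile(p1, p2, grid)
        mirrored = sic_profile(p2, p1, grid)
        # SIC(m; p1, p2) = SIC(1-m; p2, p1)
        assert np.allclose(prof.sic_values, mirrored.sic_values[::-1], atol=1e-12)
        # concave in m (entropy of the mixture is concave; the linear term
        # does not affect the second difference)
        second = np.diff(prof.sic_values, 2)
        assert (second <= 1e-9).all()
        assert (prof.sic_values >= 0).all()
        assert prof.sic_star <= np.log2(k) + 1e-12

    def test_mismatched_allele_sets_rejected(self):
        with pytest.raises(ValueError):
            sic_profile([0.5, 0.5], [0.3, 0.3, 0.4])

    def test_unnormalised_rejected(self):
        with pytest.raises(ValueError):
            sic_profile([0.5, 0.6], [0.5, 0.5])


class TestMaxSic:
    def test_symmetric_pair_peaks_at_half(self):
        prof = sic_profile([0.9, 0.1], [0.1, 0.9])
        m_star, _ = max_sic(prof)
        assert m_star == pytest.approx(0.5)

    def test_asymmetric_pair_peak_shifts(self):
        # dense-grid oracle: the peak moves off 0.5 when one population is
        # fixed and the other is 50/50
        prof = sic_profile([1.0, 0.0], [0.5, 0.5], np.linspace(0.001, 0.999, 999))
        m_star, sic_star = max_sic(prof)
        assert abs(m_star - 0.5) > 0.05
        assert sic_star > sic_profile(
            [1.0, 0.0], [0.5, 0.5], np.array([0.5])
        ).sic_values[0]

    def test_both_monomorphic_same_allele(self):
        prof = sic_profile([1.0, 0.0], [1.0, 0.0])
        _, sic_star = max_sic(prof)
        assert sic_star == 0.0

    def test_tie_broken_toward_half(self):
        prof = sic_profile([0.3, 0.7], [0.3, 0.7])  # all-zero profile
        m_star, _ = max_sic(prof)
        assert m_star == pytest.approx(0.5)


class TestRankLoci:
    def test_diagnostic_beats_monomorphic(self):
        f1 = {"diag": [1.0, 0.0], "mono": [1.0, 0.0]}
        f2 = {"diag": [0.0, 1.0], "mono": [1.0, 0.0]}
        out = rank_loci(f1, f2)
        assert list(out["locus"]) == ["diag", "mono"]

    def test_three_locus_ordering(self):
        f1 = {"a": [1.0, 0.0], "b": [0.8, 0.2], "c": [0.5, 0.5]}
        f2 = {"a": [0.0, 1.0], "b": [0.2, 0.8], "c": [0.5, 0.5]}
        out = rank_loci(f1, f2)
        assert list(out["locus"]) == ["a", "b", "c"]

    def test_ties_lexicographic(self):
        f1 = {"z": [1.0, 0.0], "a": [1.0, 0.0]}
        f2 = {"z": [0.0, 1.0], "a": [0.0, 1.0]}
        out = rank_loci(f1, f2)
        assert list(out["locus"]) == ["a", "z"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_loci({}, {})


def _split_dataset(cfg):
    """Simulate, then split individuals into train/test halves per habitat."""
    matrix, table, truth = simulate_dataset(cfg)
    t = table.set_index("individual_id")
    origin = {
        i: ("forest" if t.at[i, "habitat"] == "forest" else "savanna")
        for i in matrix.individual_ids
    }
    train_ids = matrix.individual_ids[0::2]
    test_ids = matrix.individual_ids[1::2]
    train = matrix.subset_individuals(train_ids)
    test = matrix.subset_individuals(test_ids)
    freqs, sizes = population_freqs(train, origin)
    return train, test, origin, freqs, sizes


class TestEvaluatePanel:
    def test_diagnostic_panel_is_perfect(self):
        import numpy as np

        from strmix import GenotypeMatrix

        # two fixed-difference loci
        calls_a = np.tile(np.array([[1, 1], [5, 5]]), (4, 1))[:, None, :]
        calls = np.concatenate([calls_a, calls_a + 2], axis=1)
        m = GenotypeMatrix([f"i{k}" for k in range(8)], ["L1", "L2"], calls)
        origin = {f"i{k}": ("p1" if k % 2 == 0 else "p2") for k in range(8)}
        freqs, sizes = population_freqs(m, origin)
        acc = evaluate_panel(["L1", "L2"], freqs, sizes, m, origin, seed=0)
        assert acc == 1.0

    def test_monomorphic_panel_is_chance(self):
        import numpy as np

        from strmix import GenotypeMatrix

        calls = np.full((200, 1, 2), 7)
        m = GenotypeMatrix([f"i{k}" for k in range(200)], ["L1"], calls)
        origin = {f"i{k}": ("p1" if k < 100 else "p2") for k in range(200)}
        freqs, sizes = population_freqs(m, origin)
        acc = evaluate_panel(["L1"], freqs, sizes, m, origin, seed=1)
        assert abs(acc - 0.5) < 0.12  # binomial noise around chance

    def test_top_panel_beats_bottom_panel(self):
        cfg = SimConfig(
            n_forest_locales=1,
            n_savanna_locales=1,
            n_mixed_locales=0,
            individuals_per_locale=100,
            divergence_F=0.1,
            missing_rate=0.0,
            seed=77,
        )
        train, test, origin, freqs, sizes = _split_dataset(cfg)
        ranking = rank_loci(freqs["forest"], freqs["savanna"])
        top = list(ranking["locus"][:4])
        bottom = list(ranking["locus"][-4:])
        acc_top = evaluate_panel(top, freqs, sizes, test, origin, seed=5)
        acc_bottom = evaluate_panel(bottom, freqs, sizes, test, origin, seed=5)
        assert acc_top >= acc_bottom

    def test_empty_panel_rejected(self, two_pool_dataset):
        matrix, table, _ = two_pool_dataset
        with pytest.raises(ValueError):
            evaluate_panel([], {}, {}, matrix, {})


class TestPairContrast:
    def test_between_species_more_informative_than_within(self):
        # most loci carry more information across the deep split than
        # between two locales of the same pool
        cfg = SimConfig(individuals_per_locale=30, seed=13, missing_rate=0.0)
        matrix, table, _ = simulate_dataset(cfg)
        t = table.set_index("individual_id")
        species_labels = {
            i: ("forest" if t.at[i, "habitat"] == "forest" else "savanna")
            for i in matrix.individual_ids
            if t.at[i, "habitat"] != "mixed"
        }
        sub = matrix.subset_individuals(list(species_labels))
        freqs, _ = population_freqs(sub, species_labels)
        between = rank_loci(freqs["forest"], freqs["savanna"])

        locale_ids = [
            i for i in matrix.individual_ids if t.at[i, "locale"] in ("S01", "S02")
        ]
        locale_labels = {i: t.at[i, "locale"] for i in locale_ids}
        sub2 = matrix.subset_individuals(locale_ids)
        freqs2, _ = population_freqs(sub2, locale_labels)
        within = rank_loci(freqs2["S01"], freqs2["S02"])

        merged = between.merge(within, on="locus", suffixes=("_between", "_within"))
        frac = (merged["sic_star_between"] > merged["sic_star_within"]).mean()
        assert frac > 0.5
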