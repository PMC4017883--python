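"""Rarefaction and Chao estimation against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trapeffort import chao_richness, rarefaction_curve, rarefy_exact

from conftest import incidence_from_counts


def brute_force_rarefaction(matrix: np.ndarray, d: int) -> float:
    """Mean richness over every d-subset of units, by full enumeration."""
    n_units = matrix.shape[0]
    richness = [
        (matrix[list(subset)].any(axis=0)).sum()
        for subset in itertools.combinations(range(n_units), d)
    ]
    return float(np.mean(richness))


class TestRarefyExact:
    def test_full_effort_returns_observed_richness(self, toy_incidence):
        assert rarefy_exact(toy_incidence, 4) == pytest.approx(3.0, abs=1e-12)

    def test_matches_enumeration_on_toy_matrix(self, toy_incidence):
        expected = brute_force_rarefaction(toy_incidence.binarized(), 2)
        assert rarefy_exact(toy_incidence, 2) == pytest.approx(expected, abs=1e-12)

    @given(
        occ=st.lists(st.integers(min_value=0, max_value=8), min_size=1, max_size=6),
        n_units=st.integers(min_value=1, max_value=8),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_enumeration_for_small_matrices(self, occ, n_units, data):
        occ = [min(o, n_units) for o in occ]
        incidence = incidence_from_counts(occ, n_units)
        d = data.draw(st.integers(min_value=1, max_value=n_units))
        expected = brute_force_rarefaction(incidence.binarized(), d)
        assert rarefy_exact(incidence, d) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_effort_rejected(self, toy_incidence):
        with pytest.raises(ValueError):
            rarefy_exact(toy_incidence, 0)
        with pytest.raises(ValueError):
            rarefy_exact(toy_incidence, 5)

    def test_unit_and_species_order_invariance(self, full_processed):
        incidence = full_processed["incidence"]
        rng = np.random.default_rng(0)
        shuffled = incidence.counts.sample(frac=1.0, random_state=1)
        shuffled = shuffled[rng.permutation(shuffled.columns)]
        from trapeffort.events import IncidenceMatrix

        permuted = IncidenceMatrix(counts=shuffled, unit_kind="day")
        d = np.array([1, 10, 100, 730])
        np.testing.assert_allclose(rarefy_exact(incidence, d), rarefy_exact(permuted, d))

    def test_numerically_stable_at_large_unit_counts(self):
        incidence = incidence_from_counts([20_000, 5_000, 3, 1], n_units=20_000)
        values = rarefy_exact(incidence, np.array([1, 100, 10_000, 20_000]))
        assert np.all(np.isfinite(values))
        assert values[-1] == pytest.approx(4.0, abs=1e-9)

    def test_curve_is_nondecreasing_and_concave(self, full_processed):
        incidence = full_processed["incidence"]
        curve = rarefy_exact(incidence, np.arange(1, incidence.n_units + 1))
        first = np.diff(curve)
        assert (first >= -1e-12).all()
        assert (np.diff(first) <= 1e-12).all()


class TestRarefactionCurve:
    def test_single_species_curve_is_flat_at_one(self):
        incidence = incidence_from_counts([6], n_units=6)
        curve = rarefaction_curve(incidence, method="permutation", n_permutations=20, seed=0)
        np.testing.assert_allclose(curve.expected_s, 1.0)

    def test_permutation_mean_tracks_exact(self, toy_incidence):
        n_perm = 2000
        curve = rarefaction_curve(
            toy_incidence, method="permutation", n_permutations=n_perm, seed=1
        )
        for d in range(1, 5):
            exact = rarefy_exact(toy_incidence, d)
            # richness per subset is bounded by S_obs; 3 SE of the MC mean
            se = 3.0 * toy_incidence.s_obs / (2 * np.sqrt(n_perm))
            assert abs(curve.expected_s[d - 1] - exact) <= se

    def test_same_seed_is_identical(self, toy_incidence):
        a = rarefaction_curve(toy_incidence, method="permutation", n_permutations=50, seed=9)
        b = rarefaction_curve(toy_incidence, method="permutation", n_permutations=50, seed=9)
        np.testing.assert_array_equal(a.expected_s, b.expected_s)
        np.testing.assert_array_equal(a.lower, b.lower)

    def test_band_brackets_the_mean(self, full_processed):
        curve = rarefaction_curve(full_processed["incidence"], n_permutations=100, seed=2)
        assert (curve.lower <= curve.expected_s + 1e-12).all()
        assert (curve.upper >= curve.expected_s - 1e-12).all()

    def test_ends_at_observed_richness(self, full_processed):
        incidence = full_processed["incidence"]
        curve = rarefaction_curve(incidence, n_permutations=10, seed=0)
        assert curve.expected_s[-1] == pytest.approx(incidence.s_obs, abs=1e-9)


class TestChao:
    def test_direct_substitution(self):
        est = chao_richness(incidence_from_counts([5, 5, 4, 1, 2], n_units=5))
        assert (est.s_obs, est.a1, est.a2) == (5, 1, 1)
        assert est.s_max == pytest.approx(5 + 1 / 2)
        est2 = chao_richness(incidence_from_counts([9, 9, 9, 1, 1, 2], n_units=9))
        assert est2.s_max == pytest.approx(6 + 4 / 2)
        assert not est2.corrected

    def test_no_uniques_means_no_extrapolation(self):
        est = chao_richness(incidence_from_counts([5, 4, 3], n_units=5))
        assert est.s_max == est.s_obs == 3 and est.a1 == 0

    def test_bias_corrected_fallback_when_no_duplicates(self):
        est = chao_richness(incidence_from_counts([5, 1, 1], n_units=5))
        assert est.corrected
        assert est.s_max == pytest.approx(3 + 2 * 1 / 2)

    def test_recovers_true_richness_on_simulation(self, full_processed):
        """All resident species seen in >= 3 days -> the pool equals truth."""
        incidence = full_processed["incidence"]
        assert (incidence.occurrence_counts() >= 3).all()
        truth = full_processed["truth"]
        assert chao_richness(incidence).s_max == truth["richness_by_guild"]["resident_terrestrial"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            chao_richness(incidence_from_counts([], n_units=0))


class TestVeganCrossCheck:
    """Independent oracle: the reference R implementation of the same
    estimators (sample-based 'exact' accumulation and the Chao pool)."""

    def test_matches_vegan_on_toy_matrix(self, tmp_path):
        import subprocess

        incidence = incidence_from_counts([7, 5, 3, 2, 1, 1], n_units=9)
        csv = tmp_path / "m.csv"
        incidence.counts.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            """
            suppressMessages(library(vegan))
            m <- read.csv(commandArgs(TRUE)[1])
            acc <- specaccum(m, method = "exact")
            pool <- specpool(m)
            cat(paste(sprintf("%.12f", acc$richness), collapse = ","), "\n")
            cat(sprintf("%.12f", pool$chao), "\n")
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, check=True
        ).stdout.splitlines()
        vegan_curve = np.array([float(x) for x in out[0].split(",")])
        vegan_chao = float(out[1])
        ours = rarefy_exact(incidence, np.arange(1, 10))
        np.testing.assert_allclose(ours, vegan_curve, atol=1e-8)
        # vegan multiplies the Chao add-on term by (N-1)/N; the classic
        # formula used here does not — undo the factor before comparing
        est = chao_richness(incidence)
        n = incidence.n_units
        assert est.s_max - est.s_obs == pytest.approx(
            (vegan_chao - est.s_obs) * n / (n - 1), abs=1e-8
        )
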