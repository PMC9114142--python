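"""LD estimators, decay fitting and the correlation-matrix test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from corrbreak import genio, kinship, ldtools

from .test_genio import _toy


class TestCompositeR2:
    def test_hand_value(self):
        x = np.array([0, 1, 2, 0, 1], float)
        y = np.array([0, 1, 2, 2, 1], float)
        expected = np.corrcoef(x, y)[0, 1] ** 2
        assert ldtools.composite_r2(x, y) == pytest.approx(expected)

    def test_perfect_ld(self):
        x = np.array([0, 1, 2, 1], float)
        assert ldtools.composite_r2(x, x) == pytest.approx(1.0)
        assert ldtools.composite_r2(x, 2 - x) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ldtools.composite_r2(np.ones(5), np.array([0, 1, 2, 0, 1.0]))

    @given(st.integers(0, 2**32 - 1))
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, 20).astype(float)
        y = rng.integers(0, 3, 20).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r2 = ldtools.composite_r2(x, y)
        assert 0 <= r2 <= 1
        assert r2 == pytest.approx(ldtools.composite_r2(y, x))


class TestCorrectedR2:
    def test_identity_kinship_reduces_to_composite(self, rng):
        for _ in range(20):
            x = rng.integers(0, 3, 30).astype(float)
            y = rng.integers(0, 3, 30).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert ldtools.corrected_r2(x, y, np.eye(30)) == pytest.approx(
                ldtools.composite_r2(x, y), abs=1e-12
            )

    def test_mismatched_kinship_rejected(self):
        with pytest.raises(ValueError):
            ldtools.corrected_r2(np.arange(5.0), np.arange(5.0), np.eye(4))

    def test_family_duplication_bias_removed(self, rng):
        # unlinked markers, but individuals duplicated into 'families' of 8:
        # the naive r2 is inflated, the corrected r2 stays near the null
        base = rng.integers(0, 3, size=(12, 2)).astype(float)
        reps = np.repeat(base, 8, axis=0)
        noise = rng.integers(0, 2, size=reps.shape) * 0.0  # keep dosages integral
        X = reps + noise
        if np.ptp(X[:, 0]) == 0 or np.ptp(X[:, 1]) == 0:
            X[0, :] = [0, 0]
            X[1, :] = [2, 2]
        K = np.kron(np.eye(12), np.ones((8, 8)))  # block family relatedness
        kinv = np.linalg.inv(0.99 * K + 0.01 * np.eye(96))
        naive = ldtools.composite_r2(X[:, 0], X[:, 1])
        corrected = ldtools.corrected_r2(X[:, 0], X[:, 1], kinv)
        # corrected should not exceed the naive family-confounded estimate
        assert corrected <= naive + 1e-8


class TestScaffoldLD:
    def test_pair_counts_and_distances(self):
        d = np.array(
            [[0, 1, 2, 0], [1, 1, 0, 2], [2, 0, 1, 1], [0, 2, 1, 0], [1, 0, 2, 1]],
            dtype=float,
        )
        g = _toy(d, positions=[0, 100, 250, 700])
        pairs, mats = ldtools.scaffold_ld(g)
        assert len(pairs) == 6  # 4 choose 2
        assert set(pairs["distance_bp"]) == {100, 150, 250, 450, 600, 700}
        ids, R = mats["s1"]
        assert len(ids) == 4
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_min_snps_threshold(self):
        g = _toy(np.array([[0, 1], [1, 0], [2, 2], [1, 1]], float))
        pairs, mats = ldtools.scaffold_ld(g, min_snps=3)
        assert len(pairs) == 0 and not mats
        pairs, mats = ldtools.scaffold_ld(g, min_snps=2)
        assert len(pairs) == 1

    def test_monomorphic_markers_dropped_before_threshold(self):
        d = np.array([[0, 1, 1], [0, 0, 2], [0, 2, 1], [0, 1, 0]], float)
        g = _toy(d)
        pairs, mats = ldtools.scaffold_ld(g, min_snps=2)
        ids, _ = mats["s1"]
        assert "m0" not in ids and len(ids) == 2


class TestHillWeir:
    def test_expected_r2_hand_values(self):
        # closed form at C=0: (10/22) * (1 + 36/(22 n))
        assert ldtools.hill_weir_expectation(0.0, 100) == pytest.approx(0.4620, abs=5e-5)
        # large C decays to the finite-sample noise floor 1/n
        assert ldtools.hill_weir_expectation(1e6, 100) == pytest.approx(0.01, abs=1e-4)

    def test_monotone_decreasing_in_c(self):
        C = np.linspace(0, 50, 200)
        vals = ldtools.hill_weir_expectation(C, 50)
        assert np.all(np.diff(vals) < 0)

    def test_fit_recovers_beta_noise_free(self, rng):
        beta = 5e-4
        d = rng.uniform(10, 10_000, 500)
        pairs = pd.DataFrame(
            {"distance_bp": d, "r2": ldtools.hill_weir_expectation(beta * d, 100)}
        )
        fit = ldtools.fit_hill_weir(pairs, n=100)
        assert fit.beta_per_bp == pytest.approx(beta, rel=1e-4)

    def test_fit_needs_enough_pairs(self):
        pairs = pd.DataFrame({"distance_bp": [10.0] * 5, "r2": [0.5] * 5})
        with pytest.raises(ValueError, match="at least 10"):
            ldtools.fit_hill_weir(pairs, n=50)

    def test_decay_distance_properties(self):
        fit = ldtools.HillWeirFit(beta_per_bp=5e-4, n=100, rss=0.0, n_pairs=100)
        d = ldtools.decay_distance(fit, 0.2)
        assert d is not None and d > 0
        # the fitted curve crosses the threshold exactly there
        assert ldtools.hill_weir_expectation(fit.beta_per_bp * d, 100) == pytest.approx(
            0.2, abs=1e-5
        )
        # steeper decay -> earlier crossing
        fit2 = ldtools.HillWeirFit(beta_per_bp=1e-3, n=100, rss=0.0, n_pairs=100)
        assert ldtools.decay_distance(fit2, 0.2) < d
        # flat curve never reaches the threshold
        flat = ldtools.HillWeirFit(beta_per_bp=0.0, n=100, rss=0.0, n_pairs=100)
        assert ldtools.decay_distance(flat, 0.2) is None
        # threshold above E(r2) at C=0 is reached immediately
        assert ldtools.decay_distance(fit, 0.5) == 0.0


class TestJennrich:
    def test_identical_matrices_give_zero(self, rng):
        X = rng.standard_normal((50, 4))
        R = np.corrcoef(X, rowvar=False)
        res = ldtools.jennrich(R, 50, R, 60)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 6

    def test_small_matrices_rejected(self):
        R = np.eye(2)
        with pytest.raises(ValueError):
            ldtools.jennrich(R, 10, R, 10)

    def test_detects_gross_difference(self):
        R1 = np.eye(4)
        R2 = np.full((4, 4), 0.8)
        np.fill_diagonal(R2, 1.0)
        res = ldtools.jennrich(R1, 200, R2, 200)
        assert res.p_value < 1e-10


@pytest.fixture(scope="module")
def cohorts():
    rng = np.random.default_rng(5)

    def draw(n):
        p = rng.uniform(0.2, 0.8, size=12)
        d = rng.binomial(2, p, size=(n, 12)).astype(float)
        markers = [f"m{j}" for j in range(12)]
        mm = pd.DataFrame(
            {
                "scaffold": ["s1"] * 6 + ["s2"] * 6,
                "pos_bp": list(range(0, 600, 100)) * 2,
            },
            index=pd.Index(markers, name="marker"),
        )
        return genio.GenotypeMatrix(
            individual_ids=np.array([f"i{k}" for k in range(n)], dtype=object),
            marker_ids=np.array(markers, dtype=object),
            dosages=d,
            marker_map=mm,
        )

    return draw(80), draw(90)


class TestComparePopulations:
    def test_structure_and_pairing(self, cohorts):
        ga, gb = cohorts
        ka = kinship.blended_inverse(kinship.vanraden_g(ga))
        kb = kinship.blended_inverse(kinship.vanraden_g(gb))
        out = ldtools.compare_populations(ga, gb, kinv_a=ka, kinv_b=kb)
        s = out["summary"]
        assert s["n_scaffolds_tested"] == 2
        assert set(out["results"]) == {"uncorrected", "corrected"}
        # same scaffolds tested under both variants (paired traces)
        assert [r.scaffold for r in out["results"]["uncorrected"]] == [
            r.scaffold for r in out["results"]["corrected"]
        ]
        assert 0.0 <= s["fraction_significant_uncorrected"] <= 1.0

    def test_identical_populations_not_significant(self, cohorts):
        ga, _ = cohorts
        out = ldtools.compare_populations(ga, ga)
        for r in out["results"]["uncorrected"]:
            assert r.p_value == pytest.approx(1.0)
        assert ldtools.significant_scaffolds(out, "uncorrected") == []
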