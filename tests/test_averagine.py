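"""Averagine compositions, isotopologue distributions, and reference search."""

import numpy as np
import pytest

from mzlsh import (DELTA_ISO, PROTON_MASS, averagine_composition,
                   build_reference_db, isotope_distribution, isotope_shift,
                   reference_search, theoretical_pattern)
from mzlsh.averagine import (AVERAGINE_RESIDUE, AVERAGINE_RESIDUE_MASS,
                             ISOTOPE_ABUNDANCES, REF_N_BINS, ElementalComposition,
                             ReferenceDB, _element_power, render_pattern_vector)


class TestComposition:
    def test_unit_residue(self):
        comp = averagine_composition(AVERAGINE_RESIDUE_MASS)
        for el, count in AVERAGINE_RESIDUE.items():
            assert comp.counts[el] == pytest.approx(count, rel=1e-12)

    def test_linearity(self):
        c1 = averagine_composition(AVERAGINE_RESIDUE_MASS)
        c2 = averagine_composition(2 * AVERAGINE_RESIDUE_MASS)
        for el in AVERAGINE_RESIDUE:
            assert c2.counts[el] == pytest.approx(2 * c1.counts[el], rel=1e-12)

    def test_scaling_rule_at_1000(self):
        comp = averagine_composition(1000.0)
        scale = 1000.0 / AVERAGINE_RESIDUE_MASS
        assert scale == pytest.approx(8.9989, abs=1e-4)
        assert comp.counts["C"] == pytest.approx(scale * 4.9384, rel=1e-12)

    def test_non_positive_mass_rejected(self):
        with pytest.raises(ValueError):
            averagine_composition(0.0)


class TestIsotopeDistribution:
    def test_single_carbon_ratio(self):
        dist = isotope_distribution(ElementalComposition({"C": 1.0}), 3)
        assert dist[1] / dist[0] == pytest.approx(0.0107 / 0.9893, rel=1e-9)

    def test_ten_carbons_binomial(self):
        dist = isotope_distribution(ElementalComposition({"C": 10.0}), 3)
        r = 0.0107 / 0.9893
        assert dist[1] / dist[0] == pytest.approx(10 * r, rel=1e-9)

    @pytest.mark.parametrize("element,count", [("C", 7), ("O", 4), ("S", 3), ("N", 12)])
    def test_integer_counts_match_convolution_oracle(self, element, count):
        """Fractional-power series equals repeated polynomial convolution."""
        k = 6
        single = np.zeros(k)
        for shift, ab in ISOTOPE_ABUNDANCES[element]:
            if shift < k:
                single[shift] = ab
        single /= single.sum()
        oracle = np.array([1.0] + [0.0] * (k - 1))
        for _ in range(count):
            oracle = np.convolve(oracle, single)[:k]
        series = _element_power(element, float(count), k)
        assert np.allclose(series, oracle, atol=1e-12)

    def test_averagine_1000_first_ratio(self):
        """Independent oracle: sum of per-element first-order contributions."""
        comp = averagine_composition(1000.0)
        dist = isotope_distribution(comp, 6)
        first_order = sum(
            comp.counts[el] * dict(ISOTOPE_ABUNDANCES[el]).get(1, 0.0)
            / dict(ISOTOPE_ABUNDANCES[el])[0]
            for el in comp.counts)
        assert dist[1] / dist[0] == pytest.approx(first_order, rel=1e-3)
        assert 0.48 <= dist[1] / dist[0] <= 0.58

    def test_distribution_is_nonnegative_and_max_normalised(self):
        for mass in (150.0, 700.0, 3000.0):
            dist = isotope_distribution(averagine_composition(mass), 6)
            assert np.all(dist >= 0)
            assert dist.max() == pytest.approx(1.0)


class TestTheoreticalPattern:
    def test_charge_sets_spacing(self):
        for z, spacing in [(1, DELTA_ISO), (2, DELTA_ISO / 2), (5, DELTA_ISO / 5)]:
            pattern = theoretical_pattern(1000.0, z)
            mzs = np.array([mz for mz, _ in pattern])
            assert np.allclose(np.diff(mzs), spacing, atol=1e-12)

    def test_charge2_spacing_is_half_mz(self):
        pattern = theoretical_pattern(1000.0, 2)
        gap = pattern[1][0] - pattern[0][0]
        assert gap == pytest.approx(0.5017, abs=1e-4)

    def test_mono_mz_arithmetic(self):
        pattern = theoretical_pattern(1000.0, 2)
        assert pattern[0][0] == pytest.approx((1000.0 + 2 * PROTON_MASS) / 2, rel=1e-12)
        assert pattern[0][0] == pytest.approx(501.007, abs=5e-4)

    def test_invalid_charge_rejected(self):
        with pytest.raises(ValueError):
            theoretical_pattern(1000.0, 6)


def _brute_force_best(query, db):
    """Explicit argmax of the anchored cosine over the FULL db (same shift
    set and tie-breaking as the candidate-based search)."""
    from mzlsh.averagine import COARSE_STEP, _canonicalise
    canon_q, _ = _canonicalise(np.asarray(query, dtype=float))
    qnorm = np.linalg.norm(canon_q)
    best = None
    for pat in db.patterns:
        ref = db._canon[pat.pattern_id]
        rnorm = db._norms[pat.pattern_id]
        dz = int(round(DELTA_ISO / pat.charge / COARSE_STEP))
        for s in (0, -dz, dz):
            qv = canon_q if s == 0 else np.roll(canon_q, s)
            score = float(qv @ ref / (qnorm * rnorm))
            rank = (-score, pat.charge, pat.mono_mass, abs(s))
            if best is None or rank < best[0]:
                best = (rank, pat.pattern_id)
    return best[1]


@pytest.fixture(scope="module")
def small_db():
    return build_reference_db(mass_min=600.0, mass_max=1200.0, mass_step=50.0,
                              charges=(1, 2, 3), seed=11)


class TestReferenceDb:
    def test_pattern_count_and_keys(self, small_db):
        assert len(small_db) == 13 * 3
        for pat in small_db.patterns[:3]:
            assert pat.keys.shape == (small_db.family.m,)

    def test_coarse_vector_length(self):
        vec = render_pattern_vector(800.0, 2)
        assert vec.shape == (1000,)
        assert REF_N_BINS == 1000

    def test_spacing_times_charge_is_isotope_gap(self, small_db):
        """Peak spacing on the coarse grid x charge ~ DELTA_ISO for all entries."""
        for pat in small_db.patterns:
            nz = np.nonzero(pat.vector > 0.01)[0]
            gaps = np.diff(nz) * 0.01 * pat.charge
            assert np.all(np.abs(gaps - DELTA_ISO) <= 0.01 * pat.charge)

    def test_self_query_scores_one(self, small_db):
        pat = small_db.patterns[7]
        match = reference_search(pat.vector, small_db)
        assert match is not None
        assert match.pattern_id == pat.pattern_id
        assert match.score == pytest.approx(1.0, abs=1e-9)
        assert match.charge == pat.charge

    def test_uniform_noise_finds_nothing(self, small_db):
        gen = np.random.default_rng(0)
        misses = sum(reference_search(gen.uniform(0, 1, REF_N_BINS), small_db) is None
                     for _ in range(20))
        assert misses >= 18

    def test_scaled_noisy_query_recovers_pattern(self, small_db):
        """Brute-force explicit cosine over the whole db confirms the match."""
        gen = np.random.default_rng(21)
        for _ in range(20):
            pat = small_db.patterns[int(gen.integers(len(small_db)))]
            query = pat.vector * 0.3
            idx = gen.integers(0, REF_N_BINS, size=int(gen.poisson(4)) + 1)
            query[idx] += gen.exponential(0.005, size=len(idx))
            match = reference_search(query, small_db)
            assert match is not None
            brute = _brute_force_best(query, small_db)
            assert match.pattern_id == brute
            assert match.pattern_id == pat.pattern_id

    def test_resolution_mismatch_rejected(self, small_db):
        with pytest.raises(ValueError, match="bins"):
            reference_search(np.ones(100), small_db)

    def test_amplification_recall_bound(self, small_db):
        """Candidate set contains near-identical patterns at least as often
        as the analytic collision probability at s=0.95 predicts."""
        from mzlsh import collision_probability
        gen = np.random.default_rng(3)
        fam = small_db.family
        hits = 0
        trials = 60
        for _ in range(trials):
            pat = small_db.patterns[int(gen.integers(len(small_db)))]
            noisy = pat.vector.copy()
            noisy += gen.uniform(0, 0.02, size=noisy.shape)  # s stays > 0.95
            from mzlsh.averagine import _canonicalise
            canon, _ = _canonicalise(noisy)
            keys = fam.signature_matrix(canon[None, :])[0]
            hits += pat.pattern_id in small_db.candidates(keys)
        bound = collision_probability(0.95, fam.m, fam.n)
        assert hits / trials >= bound - 3 * np.sqrt(bound * (1 - bound) / trials)

    def test_save_load_round_trip(self, small_db, tmp_path):
        path = tmp_path / "db.tsv"
        small_db.save(path)
        loaded = ReferenceDB.load(path)
        assert len(loaded) == len(small_db)
        for a, b in zip(small_db.patterns, loaded.patterns):
            assert np.array_equal(a.keys, b.keys)
            assert a.mono_mass == b.mono_mass and a.charge == b.charge


class TestShiftDiagnostic:
    def test_detects_single_isotopologue_shift(self):
        assert isotope_shift(500.0 + DELTA_ISO / 2, 500.0, 2) == 1
        assert isotope_shift(500.0 - 2 * DELTA_ISO / 3, 500.0, 3) == -2
        assert isotope_shift(500.0, 500.0, 1) == 0

    def test_unrelated_offset_is_not_a_shift(self):
        assert isotope_shift(500.43, 500.0, 2) is None
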