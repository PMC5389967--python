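"""Frequency spectra, diversity, Tajima's D, F_ST, sharing and rank tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mei_popgen import ValidationError, popgen_stats as ps
from mei_popgen.popgen_stats import (Polarization, sfs_from_counts,
                                     joint_sfs_from_counts, tajima_constants,
                                     tajimas_d_from_counts,
                                     wc_fst_from_dosages)
from conftest import make_snp_table, make_mei_table


class TestSfs:
    def test_singleton_locus(self, pop_map):
        t = make_mei_table([[1, 0, 0, 0, 0, 0, 0] + [0] * 6], [100],
                           pop_map=pop_map)
        spec = ps.sfs(t, "FLORIDA")
        assert spec.n == 14
        assert spec.counts[1] == 1
        assert spec.n_polymorphic == 1

    def test_fold_symmetry(self):
        spec = sfs_from_counts(np.array([13]), 14, Polarization.MINOR_FOLDED)
        assert spec.counts[1] == 1
        assert spec.counts[13] == 0

    def test_matches_hand_tally(self):
        dosages = np.array([[1, 0, 0], [2, 2, 2], [1, 1, 0], [0, 0, 0],
                            [2, 1, 1]])
        t = make_mei_table(dosages, [100] * 5)
        spec = ps.sfs(t)
        # hand tally of row sums: 1, 6, 2, 0, 4 over n = 6 chromosomes
        expected = np.zeros(7, dtype=int)
        for k in (1, 6, 2, 0, 4):
            expected[k] += 1
        assert (np.asarray(spec.counts) == expected).all()

    @given(st.lists(st.integers(0, 10), min_size=1, max_size=200))
    @settings(max_examples=30, deadline=None)
    def test_polymorphic_total_conserved(self, counts):
        spec = sfs_from_counts(np.array(counts), 10)
        n_poly = sum(1 for k in counts if 0 < k < 10)
        assert spec.n_polymorphic == n_poly

    def test_joint_sfs_total(self):
        j = joint_sfs_from_counts([0, 1, 3], [2, 2, 0], 4, 4)
        assert j.total == 3
        assert j.matrix[1, 2] == 1


class TestMeanPairwiseDiff:
    @pytest.mark.parametrize("n,k,expected", [(4, 1, 0.5), (2, 1, 1.0),
                                              (4, 0, 0.0), (4, 4, 0.0)])
    def test_closed_form_cases(self, n, k, expected):
        assert ps.per_site_pi(np.array([k]), n)[0] == pytest.approx(expected)

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=100))
    @settings(max_examples=40, deadline=None)
    def test_equals_brute_force_pair_enumeration(self, counts):
        """pi per locus equals the fraction of differing chromosome pairs."""
        n = 20
        got = ps.per_site_pi(np.array(counts), n).mean()
        brute = []
        for k in counts:
            alleles = [1] * k + [0] * (n - k)
            pairs = list(itertools.combinations(range(n), 2))
            brute.append(sum(alleles[i] != alleles[j] for i, j in pairs)
                         / len(pairs))
        assert got == pytest.approx(np.mean(brute), abs=1e-12)

    def test_empty_table_errors(self, pop_map):
        t = make_mei_table(np.zeros((0, 13), dtype=int), [], pop_map=pop_map)
        with pytest.raises(ValidationError):
            ps.mean_pairwise_diff(t)


def _oracle_tajima_d(counts, n):
    """Direct transcription of the 1989 definitions, kept independent of the
    implementation under test."""
    S = sum(1 for k in counts if 0 < k < n)
    pi = sum(2 * k * (n - k) / (n * (n - 1)) for k in counts if 0 < k < n)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_single_singleton_matches_oracle_and_is_negative(self):
        counts = np.array([1])
        comp = tajimas_d_from_counts(counts, 14)
        assert comp.D < 0
        assert comp.D == pytest.approx(_oracle_tajima_d(counts, 14), abs=1e-12)
        assert comp.S == 1
        assert comp.a1 == pytest.approx(sum(1 / i for i in range(1, 14)))

    def test_equilibrium_spectrum_gives_zero(self):
        """A spectrum with exactly theta/k sites in class k has pi = theta_W,
        so the numerator of D vanishes identically."""
        n, C = 14, 360360  # divisible by every class 1..13
        counts = np.concatenate([np.full(C // k, k) for k in range(1, n)])
        comp = tajimas_d_from_counts(counts, n)
        assert abs(comp.D) < 1e-10

    def test_no_segregating_sites_is_an_error(self):
        with pytest.raises(ValidationError):
            tajimas_d_from_counts(np.array([0, 14]), 14)

    @given(st.lists(st.integers(0, 12), min_size=1, max_size=300))
    @settings(max_examples=30, deadline=None)
    def test_matches_oracle_on_random_spectra(self, counts):
        counts = np.array(counts)
        if not ((counts > 0) & (counts < 12)).any():
            return
        comp = tajimas_d_from_counts(counts, 12)
        assert comp.D == pytest.approx(_oracle_tajima_d(counts, 12), abs=1e-10)


class TestWeirCockerhamFst:
    def test_no_differentiation_all_hets(self):
        """Both populations all heterozygous at p = 0.5: a = 0, estimate 0."""
        d1 = np.ones((5, 4), dtype=np.int16)
        d2 = np.ones((5, 6), dtype=np.int16)
        res = wc_fst_from_dosages(d1, d2)
        assert res.mean_fst == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_is_one(self):
        d1 = np.full((3, 4), 2, dtype=np.int16)
        d2 = np.zeros((3, 4), dtype=np.int16)
        res = wc_fst_from_dosages(d1, d2)
        assert res.per_site == pytest.approx(np.ones(3))
        assert res.weighted_fst == pytest.approx(1.0)

    def test_monomorphic_sites_excluded_from_mean(self):
        d1 = np.array([[0, 0], [2, 2]], dtype=np.int16)
        d2 = np.array([[0, 0], [0, 0]], dtype=np.int16)
        res = wc_fst_from_dosages(d1, d2)
        assert np.isnan(res.per_site[0])
        assert res.mean_fst == pytest.approx(1.0)

    def test_one_population_errors(self, pop_map):
        t = make_snp_table(np.ones((3, 13), dtype=int), pop_map=pop_map)
        with pytest.raises(ValidationError):
            ps.weir_cockerham_fst(t, "FLORIDA", "NOWHERE")

    def test_panmictic_sample_near_zero_in_expectation(self):
        """Random split of one panmictic pool: mean per-site estimate ~ 0."""
        rng = np.random.default_rng(7)
        n_sites = 4000
        p = rng.uniform(0.1, 0.9, size=n_sites)
        geno = rng.binomial(1, p[:, None], size=(n_sites, 26)) \
            + rng.binomial(1, p[:, None], size=(n_sites, 26))
        res = wc_fst_from_dosages(geno[:, :14], geno[:, 14:])
        assert abs(res.mean_fst) < 0.01


class TestSharingPartition:
    def test_private_and_fixed_classes(self, pop_map):
        rows = [
            [1, 0, 0, 0, 0, 0, 0] + [0] * 6,   # private Florida
            [2] * 7 + [0] * 6,                 # fixed difference
            [0] * 7 + [1, 0, 0, 0, 0, 0],      # private Gulf
            [1, 0, 0, 0, 0, 0, 0] + [1, 0, 0, 0, 0, 0],  # shared
        ]
        t = make_mei_table(rows, [100] * 4, pop_map=pop_map)
        part = ps.sharing_partition(t)
        assert part.n_loci == 4
        assert part.pct_private_pop1 == pytest.approx(25.0)
        assert part.pct_private_pop2 == pytest.approx(25.0)
        assert part.pct_fixed_diff == pytest.approx(25.0)
        assert part.pct_shared == pytest.approx(25.0)

    def test_hand_built_ten_locus_tally(self, pop_map):
        rng = np.random.default_rng(11)
        d = rng.integers(0, 3, size=(10, 13))
        t = make_mei_table(d, [100] * 10, pop_map=pop_map)
        part = ps.sharing_partition(t)
        total = (part.pct_private_pop1 + part.pct_private_pop2
                 + part.pct_fixed_diff + part.pct_shared)
        assert total == pytest.approx(100.0)


def _exact_signed_rank_p(diffs):
    """Enumerate all sign assignments of |differences| (oracle, n <= 12)."""
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(diffs))
    v_obs = ranks[np.asarray(diffs) > 0].sum()
    n = len(diffs)
    vs = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([0, 1], repeat=n)]
    mean_v = n * (n + 1) / 4
    dev = abs(v_obs - mean_v)
    more_extreme = sum(1 for v in vs if abs(v - mean_v) >= dev - 1e-12)
    return min(more_extreme / 2**n, 1.0)


class TestWilcoxonSignedRank:
    def test_thirteen_uniform_pairs(self):
        V, p = ps.wilcoxon_signed_rank_exact([(i + 1.0, 0.0) for i in range(13)])
        assert V == 91
        assert p == pytest.approx(2 / 2**13, rel=1e-9)

    def test_three_pairs_all_positive(self):
        V, p = ps.wilcoxon_signed_rank_exact([(2, 1), (4, 1), (9, 1)])
        assert V == 6
        assert p == pytest.approx(0.25)

    def test_single_pair(self):
        V, p = ps.wilcoxon_signed_rank_exact([(3, 1)])
        assert V == 1
        assert p == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        V, p = ps.wilcoxon_signed_rank_exact([(1, 1), (5, 2), (7, 2), (9, 2)])
        assert V == 6
        assert p == pytest.approx(0.25)

    def test_all_zero_errors(self):
        with pytest.raises(ValidationError):
            ps.wilcoxon_signed_rank_exact([(1, 1), (2, 2)])

    @given(mags=st.lists(st.integers(1, 50), min_size=1, max_size=9,
                         unique=True),
           signs=st.lists(st.sampled_from([-1, 1]), min_size=9, max_size=9))
    @settings(max_examples=25, deadline=None)
    def test_p_matches_enumeration_oracle(self, mags, signs):
        """Exact two-sided p equals full sign-assignment enumeration
        (tie-free magnitudes, where the classical exact test is defined)."""
        diffs = [m * s for m, s in zip(mags, signs)]
        _, p = ps.wilcoxon_signed_rank_exact([(d, 0) for d in diffs])
        assert p == pytest.approx(_exact_signed_rank_p(diffs), abs=1e-9)


class TestWilcoxonRankSum:
    def test_extreme_small_sample(self):
        W, p = ps.wilcoxon_rank_sum([1, 2], [3, 4])
        assert W == 3  # ranks 1 + 2
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = ps.wilcoxon_rank_sum([1, 2, 3], [3, 1, 2])
        assert p == pytest.approx(1.0)

    def test_empty_sample_errors(self):
        with pytest.raises(ValidationError):
            ps.wilcoxon_rank_sum([], [1.0])

    def test_large_sample_against_normal_oracle(self):
        """Tie-free large samples: p agrees with the classic normal
        approximation computed from first principles."""
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1, 300)
        y = rng.normal(0.3, 1, 250)
        W, p = ps.wilcoxon_rank_sum(x, y)
        nx, ny = len(x), len(y)
        mu = nx * (nx + ny + 1) / 2
        sd = np.sqrt(nx * ny * (nx + ny + 1) / 12)
        from scipy.stats import norm
        z = (W - mu) / sd
        p_norm = 2 * norm.sf(abs(z))
        assert p == pytest.approx(p_norm, abs=1e-3)
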