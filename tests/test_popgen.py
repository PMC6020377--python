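"""Estimator unit tests against hand computations and brute-force oracles."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from balscan.io_formats import HaplotypeMatrix
from balscan.popgen import (
    filter_loci_by_presence,
    haversine_km,
    ibd_regression,
    individual_heterozygosity,
    locus_amova_fst,
    locus_gene_diversity,
    locus_observed_het,
    locus_pi,
    pairwise_population_fst,
    tajima_constants,
    tajima_d,
)
from conftest import random_locus_calls

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def pi_bruteforce(calls, length):
    """Mean pairwise hamming distance per bp over all sequence pairs."""
    seqs = [h for c in calls if c is not None for h in c]
    pairs = list(combinations(seqs, 2))
    if not pairs:
        return float("nan")
    total = sum(sum(a != b for a, b in zip(x, y)) for x, y in pairs)
    return total / len(pairs) / length


def he_bruteforce(calls):
    seqs = [h for c in calls if c is not None for h in c]
    n = len(seqs)
    freqs = [seqs.count(a) / n for a in set(seqs)]
    return (n / (n - 1)) * (1 - sum(p * p for p in freqs)) if n > 1 else float("nan")


def amova_fst_distance_oracle(calls_by_pop):
    """AMOVA F_ST from the pairwise 0/1 distance-matrix decomposition.

    Independent of the frequency-based variance-component route: computes
    SSD(total) and SSD(within) directly from allele identity distances.
    """
    pops = [p for p, calls in calls_by_pop.items()
            if any(c is not None for c in calls)]
    seqs_by_pop = {
        p: [h for c in calls_by_pop[p] if c is not None for h in c] for p in pops
    }
    n_i = [len(seqs_by_pop[p]) for p in pops]
    N = sum(n_i)
    r = len(pops)
    if r < 2 or N - r <= 0:
        return float("nan")
    all_seqs = [s for p in pops for s in seqs_by_pop[p]]
    ssd_total = sum(a != b for a, b in combinations(all_seqs, 2)) / N
    ssd_within = sum(
        sum(a != b for a, b in combinations(seqs_by_pop[p], 2)) / len(seqs_by_pop[p])
        for p in pops
    )
    ms_among = (ssd_total - ssd_within) / (r - 1)
    ms_within = ssd_within / (N - r)
    n_c = (N - sum(n * n for n in n_i) / N) / (r - 1)
    sigma_a = (ms_among - ms_within) / n_c
    if sigma_a + ms_within == 0:
        return float("nan")
    return sigma_a / (sigma_a + ms_within)


def tajima_d_exact(S, pi_hat, n):
    """Tajima's D with all constants evaluated in exact rational arithmetic."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (float(pi_hat) - float(S / a1)) / math.sqrt(float(var))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _matrix_from_presence(present):
    """HaplotypeMatrix with a fixed dummy haplotype wherever present is True."""
    n_loci, n_ind = present.shape
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{i}" for i in range(n_loci)],
            "chrom": "chr1",
            "pos": np.arange(n_loci) * 100,
            "length": 2,
        }
    )
    samples = pd.DataFrame(
        {
            "individual": [f"i{j}" for j in range(n_ind)],
            "population": "p1",
            "group": "g",
            "lat": 0.0,
            "lon": 0.0,
        }
    )
    calls = np.empty(present.shape, dtype=object)
    for i in range(n_loci):
        for j in range(n_ind):
            calls[i, j] = ("AA", "AA") if present[i, j] else None
    return HaplotypeMatrix(loci=loci, samples=samples, calls=calls)


class TestPresenceFilter:
    def test_strict_filter_drops_locus_with_any_missing(self):
        present = np.ones((3, 4), dtype=bool)
        present[1, 2] = False
        matrix = _matrix_from_presence(present)
        keep, report = filter_loci_by_presence(matrix, max_missing_frac=0.0)
        assert list(keep) == [0, 2]
        assert report["dropped"] == 1

    def test_half_missing_threshold_rounds_up(self):
        # 17 individuals, <=50% missing -> present in at least 9
        rng = np.random.default_rng(5)
        present = rng.random((50, 17)) < 0.6
        matrix = _matrix_from_presence(present)
        keep, report = filter_loci_by_presence(matrix, max_missing_frac=0.5)
        assert report["min_present"] == 9
        expected = np.flatnonzero(present.sum(axis=1) >= 9)
        np.testing.assert_array_equal(keep, expected)

    def test_retained_counts_match_bruteforce(self, rng):
        present = rng.random((200, 12)) < 0.7
        matrix = _matrix_from_presence(present)
        for frac in (0.0, 0.25, 0.5, 1.0):
            keep, _ = filter_loci_by_presence(matrix, max_missing_frac=frac)
            min_present = math.ceil((1 - frac) * 12 - 1e-9)
            assert len(keep) == sum(
                1 for row in present if row.sum() >= min_present
            )

    def test_empty_group_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            filter_loci_by_presence(small_dataset.matrix, [], 0.5)


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------


class TestDiversityStatistics:
    def test_monomorphic_locus_has_zero_pi_he_ho(self):
        h = "A" * 92
        calls = [(h, h)] * 5
        assert locus_pi(calls) == 0.0
        assert locus_gene_diversity(calls) == 0.0
        assert locus_observed_het(calls) == 0.0

    def test_pi_two_diploids_single_site(self):
        # sequences {A..., A..., T..., T...} differing at 1 of 92 sites:
        # 4 of the 6 pairs differ -> pi = (4/6)/92
        a = "A" + "C" * 91
        t = "T" + "C" * 91
        calls = [(a, a), (t, t)]
        assert locus_pi(calls) == pytest.approx((4 / 6) / 92, abs=1e-12)

    def test_he_two_equifrequent_alleles(self):
        calls = [("AA", "AA"), ("TT", "TT")]  # 2n=4, p = 0.5 each
        assert locus_gene_diversity(calls) == pytest.approx(4 / 3 * 0.5, abs=1e-12)

    def test_he_biased_option(self):
        calls = [("AA", "AA"), ("TT", "TT")]
        assert locus_gene_diversity(calls, unbiased=False) == pytest.approx(0.5)

    def test_he_maximal_for_even_frequencies(self):
        # two equifrequent alleles beat any skewed two-allele spectrum at 2n=8
        even = [("AA", "TT")] * 4
        for k in (1, 2, 3):
            skewed = [("AA", "AA")] * k + [("TT", "TT")] * (3 - k) + [("AA", "TT")]
            assert locus_gene_diversity(even) > locus_gene_diversity(skewed)

    def test_ho_counts_heterozygotes(self):
        calls = [("AA", "TT"), ("AA", "AA"), ("TT", "TT"), ("AA", "AA"), None]
        assert locus_observed_het(calls) == pytest.approx(0.25)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            locus_pi([("AA", "AA")], length=92)

    @pytest.mark.parametrize("case", range(20))
    def test_estimators_match_bruteforce_on_random_loci(self, case):
        rng = np.random.default_rng(1000 + case)
        calls = random_locus_calls(rng, n_individuals=rng.integers(2, 7))
        if not any(c is not None for c in calls):
            return
        assert locus_pi(calls, 6) == pytest.approx(pi_bruteforce(calls, 6), abs=1e-12)
        seqs = [h for c in calls if c is not None for h in c]
        if len(seqs) > 1:
            assert locus_gene_diversity(calls) == pytest.approx(
                he_bruteforce(calls), abs=1e-12
            )
        geno = [c for c in calls if c is not None]
        assert locus_observed_het(calls) == pytest.approx(
            sum(a != b for a, b in geno) / len(geno)
        )


class TestIndividualHeterozygosity:
    def test_fully_homozygous_individual(self, small_dataset):
        # complete-selfing simulation: every call homozygous
        from balscan.simulate import GroupSpec, SimConfig, simulate_dataset

        ds = simulate_dataset(
            SimConfig(
                n_chromosomes=1,
                chrom_length=500_000,
                groups=[GroupSpec("s", 1, 4, inbreeding_f=1.0)],
                missing_rate=0.0,
                seed=9,
            )
        )
        for ind in ds.matrix.samples["individual"]:
            assert individual_heterozygosity(ds.matrix, ind) == 0.0

    def test_matches_bruteforce_recount(self, small_dataset):
        matrix = small_dataset.matrix
        ind = matrix.samples["individual"].iloc[0]
        col = matrix.sample_indices([ind])[0]
        geno = [c for c in matrix.calls[:, col] if c is not None]
        expected = sum(a != b for a, b in geno) / len(geno)
        assert individual_heterozygosity(matrix, ind) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# AMOVA / pairwise F_ST
# ---------------------------------------------------------------------------


class TestAmovaFst:
    def test_no_differentiation_near_zero(self):
        # identical allele frequency spectra as equal samples in both pops
        calls = [("AA", "AA")] * 5 + [("TT", "TT")] * 5
        fst = locus_amova_fst({"p1": calls, "p2": list(calls)})
        assert fst <= 0.05

    def test_complete_fixation_is_one(self):
        fst = locus_amova_fst(
            {"p1": [("AA", "AA")] * 4, "p2": [("TT", "TT")] * 4}
        )
        assert fst == pytest.approx(1.0, abs=1e-12)

    def test_single_population_undefined(self):
        assert math.isnan(locus_amova_fst({"p1": [("AA", "TT")] * 4}))

    def test_monomorphic_undefined(self):
        assert math.isnan(
            locus_amova_fst({"p1": [("AA", "AA")] * 3, "p2": [("AA", "AA")] * 3})
        )

    @pytest.mark.parametrize("case", range(25))
    def test_matches_distance_matrix_oracle(self, case):
        rng = np.random.default_rng(2000 + case)
        n_pops = int(rng.integers(2, 4))
        calls_by_pop = {
            f"p{i}": random_locus_calls(rng, int(rng.integers(2, 6)), n_haplotypes=3)
            for i in range(n_pops)
        }
        expected = amova_fst_distance_oracle(calls_by_pop)
        got = locus_amova_fst(calls_by_pop)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-9)


class TestPairwiseFst:
    def test_split_sample_near_zero(self, small_dataset):
        matrix = small_dataset.matrix
        pop = matrix.samples["population"].iloc[-1]
        members = list(
            matrix.samples.loc[matrix.samples["population"] == pop, "individual"]
        )
        half = len(members) // 2
        sub = matrix.subset_samples(members)
        sub.samples.loc[: half - 1, "population"] = "splitA"
        sub.samples.loc[half:, "population"] = "splitB"
        res = pairwise_population_fst(sub)
        assert abs(res.fst.loc["splitA", "splitB"]) < 0.1

    def test_standardized_transform(self, small_dataset):
        matrix = small_dataset.matrix
        pops = list(pd.unique(matrix.samples["population"]))[:3]
        res = pairwise_population_fst(matrix, populations=pops)
        for i in pops:
            for j in pops:
                if i == j:
                    assert res.standardized.loc[i, j] == 0.0
                else:
                    f = res.fst.loc[i, j]
                    assert res.standardized.loc[i, j] == pytest.approx(
                        f / (1 - f), abs=1e-12
                    )
        # symmetry and zero diagonal
        assert np.allclose(res.fst.to_numpy(), res.fst.to_numpy().T)
        assert np.allclose(np.diag(res.fst.to_numpy()), 0.0)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


class TestTajimaD:
    def test_no_segregating_sites_undefined(self):
        assert math.isnan(tajima_d(0, 0.0, 20))

    def test_too_few_sequences_undefined(self):
        assert math.isnan(tajima_d(3, 1.0, 3))

    def test_intermediate_variant_positive(self):
        # n=4, S=1, derived count 2 -> pi_hat = 2/3 -> D = +1.6329...
        d = tajima_d(1, 2 / 3, 4)
        assert d == pytest.approx(tajima_d_exact(1, Fraction(2, 3), 4), abs=1e-9)
        assert d == pytest.approx(1.6329, abs=1e-4)

    def test_singleton_negative(self):
        # n=4, S=1, singleton -> pi_hat = 1/2 -> D < 0
        d = tajima_d(1, 0.5, 4)
        assert d < 0
        assert d == pytest.approx(tajima_d_exact(1, Fraction(1, 2), 4), abs=1e-9)

    @given(
        S=st.integers(1, 50),
        n=st.integers(4, 60),
        data=st.floats(0.0, 30.0, allow_nan=False),
    )
    @settings(max_examples=60, derandomize=True)
    def test_matches_exact_arithmetic_oracle(self, S, n, data):
        assert tajima_d(S, data, n) == pytest.approx(
            tajima_d_exact(S, data, n), abs=1e-9
        )

    def test_constants_positive_for_valid_n(self):
        for n in range(4, 80):
            c = tajima_constants(n)
            assert c.e1 > 0 and c.e2 > 0


# ---------------------------------------------------------------------------
# isolation by distance
# ---------------------------------------------------------------------------


class TestIbd:
    def test_quarter_great_circle(self):
        assert haversine_km(0, 0, 0, 90) == pytest.approx(
            math.pi / 2 * 6371.0, rel=1e-9
        )

    def test_identical_coordinates_flagged(self):
        k = 5
        G = pd.DataFrame(np.zeros((k, k)), index=list("abcde"), columns=list("abcde"))
        coords = {p: (10.0, 20.0) for p in "abcde"}
        res = ibd_regression(G, coords, n_permutations=99, seed=0)
        assert math.isnan(res.slope)

    def test_recovers_constructed_linear_relationship(self):
        pops = [f"p{i}" for i in range(6)]
        coords = {p: (40.0 + 3 * i, 5.0 + 2 * i) for i, p in enumerate(pops)}
        D = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if i != j:
                    lat1, lon1 = coords[pops[i]]
                    lat2, lon2 = coords[pops[j]]
                    D[i, j] = haversine_km(lat1, lon1, lat2, lon2)
        c = 2.5e-4
        G = pd.DataFrame(c * D, index=pops, columns=pops)
        res = ibd_regression(G, coords, n_permutations=999, seed=1)
        assert res.slope == pytest.approx(c, rel=1e-9)
        assert res.p_value <= 0.01
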