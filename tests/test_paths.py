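import math
from collections import Counter
from math import fsum

import numpy as np
import pytest

from pathdiv import (
    FitnessLandscape,
    count_monotone_paths,
    enumerate_monotone_paths,
    generate_additive,
    generate_uncorrelated,
    peak_accessibility,
    reach_probability,
    sample_sswm_walk,
    sswm_path_probability,
)
from pathdiv.landscape import GenotypeNotFoundError
from pathdiv.paths import (
    NonMonotonePathError,
    NotAPeakError,
    Path,
    PathOverflowError,
)


class TestEnumeration:
    def test_additive_l2_two_paths(self, additive_l2):
        (ens,) = enumerate_monotone_paths(additive_l2, "00")
        assert ens.peak.genotype == "11"
        assert [p.genotypes for p in ens.paths] == [
            ("00", "01", "11"),
            ("00", "10", "11"),
        ]
        assert ens.probabilities == [0.5, 0.5]

    def test_start_at_peak(self, additive_l2):
        (ens,) = enumerate_monotone_paths(additive_l2, "11")
        assert len(ens) == 1
        assert ens.paths[0].genotypes == ("11",)
        assert ens.probabilities == [1.0]

    def test_additive_l4_factorial_paths(self):
        ls = generate_additive(L=4, seed=0)
        (ens,) = enumerate_monotone_paths(ls, "0000")
        assert len(ens) == math.factorial(4)
        assert all(p.terminal == "1111" for p in ens.paths)

    def test_end_filter(self, two_peak_l2):
        ensembles = enumerate_monotone_paths(two_peak_l2, "01", end="00")
        assert len(ensembles) == 1
        assert ensembles[0].peak.genotype == "00"
        # 01 can only climb to 00 or 11; filtered to 00
        assert [p.genotypes for p in ensembles[0].paths] == [("01", "00")]

    def test_grouped_by_peak(self, two_peak_l2):
        ensembles = enumerate_monotone_paths(two_peak_l2, "01")
        assert [e.peak.genotype for e in ensembles] == ["00", "11"]

    def test_overflow_error_names_cap(self):
        ls = generate_additive(L=4, seed=0)
        with pytest.raises(PathOverflowError, match="5"):
            enumerate_monotone_paths(ls, "0000", max_paths=5)

    def test_absent_start_raises(self, additive_l2):
        with pytest.raises(GenotypeNotFoundError):
            enumerate_monotone_paths(additive_l2, "0000")

    def test_every_path_ends_at_a_peak(self):
        for seed in range(5):
            ls = generate_uncorrelated(5, seed=seed)
            for start in ls.genotypes():
                for ens in enumerate_monotone_paths(ls, start):
                    for p in ens.paths:
                        assert not ls.fitter_neighbors(p.terminal)


class TestPathProbability:
    def test_l2_paths_half(self, additive_l2):
        (ens,) = enumerate_monotone_paths(additive_l2, "00")
        for p in ens.paths:
            assert sswm_path_probability(p) == pytest.approx(0.5)

    def test_additive_l4_antipodal(self):
        ls = generate_additive(L=4, seed=0)
        (ens,) = enumerate_monotone_paths(ls, "0000")
        for p in ens.paths:
            assert sswm_path_probability(p) == pytest.approx(1 / 24)

    def test_length_one_path(self, additive_l2):
        assert sswm_path_probability(Path(("11",), additive_l2)) == 1.0

    def test_non_monotone_rejected(self, additive_l2):
        with pytest.raises(NonMonotonePathError):
            sswm_path_probability(Path(("11", "01"), additive_l2))
        with pytest.raises(NonMonotonePathError):  # non-unit Hamming step
            sswm_path_probability(Path(("00", "11"), additive_l2))

    def test_probability_conservation(self):
        """Sum over all maximal monotone paths from any start is 1."""
        for seed in range(8):
            ls = generate_uncorrelated(6, seed=seed)
            for start in ls.genotypes():
                ensembles = enumerate_monotone_paths(ls, start)
                total = fsum(p for e in ensembles for p in e.probabilities)
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_enumeration_probabilities_match_function(self):
        ls = generate_uncorrelated(5, seed=3)
        for start in ls.genotypes():
            for ens in enumerate_monotone_paths(ls, start):
                for p, prob in zip(ens.paths, ens.probabilities):
                    assert prob == pytest.approx(sswm_path_probability(p), rel=1e-12)


class TestCounting:
    def test_additive_l2(self, additive_l2):
        assert count_monotone_paths(additive_l2, "11") == {
            "00": 2,
            "01": 1,
            "10": 1,
            "11": 1,
        }

    def test_additive_l5_factorial(self):
        ls = generate_additive(L=5, seed=0)
        counts = count_monotone_paths(ls, "11111")
        assert counts["00000"] == 120

    def test_other_peak_unreachable(self, two_peak_l2):
        counts = count_monotone_paths(two_peak_l2, "00")
        assert counts["11"] == 0

    def test_not_a_peak_rejected(self, additive_l2):
        with pytest.raises(NotAPeakError):
            count_monotone_paths(additive_l2, "00")

    def test_dp_matches_enumeration(self):
        """Oracle: DP counts equal the enumerated ensemble sizes."""
        for seed in range(6):
            ls = generate_uncorrelated(5, seed=100 + seed)
            peaks = {p.genotype for p in ls.peaks()}
            for peak in peaks:
                counts = count_monotone_paths(ls, peak)
                for start in ls.genotypes():
                    ensembles = enumerate_monotone_paths(ls, start, end=peak)
                    n = len(ensembles[0].paths) if ensembles else 0
                    assert counts[start] == n

    def test_exact_integer_arithmetic(self):
        ls = generate_additive(L=10, seed=0)
        counts = count_monotone_paths(ls, "1" * 10)
        assert counts["0" * 10] == math.factorial(10)
        assert isinstance(counts["0" * 10], int)


class TestReachProbability:
    def test_single_peak_all_one(self):
        ls = generate_additive(L=4, seed=1)
        rho = reach_probability(ls, "1111")
        assert all(v == pytest.approx(1.0) for v in rho.values())

    def test_two_peak_hand_dp(self, two_peak_l2):
        # from 01 (or 10) both neighbors are fitter, so the walk splits
        # 50/50 between the two peaks; confirmed by 1e5 simulated walks
        rho = reach_probability(two_peak_l2, "00")
        assert rho == pytest.approx({"00": 1.0, "01": 0.5, "10": 0.5, "11": 0.0})

    def test_sums_to_one_over_peaks(self):
        for seed in range(6):
            ls = generate_uncorrelated(6, seed=seed)
            peaks = [p.genotype for p in ls.peaks()]
            rhos = [reach_probability(ls, p) for p in peaks]
            for g in ls.genotypes():
                assert fsum(r[g] for r in rhos) == pytest.approx(1.0, abs=1e-9)

    def test_walk_simulation_agrees(self, two_peak_l2):
        """Simulation oracle: terminal-peak frequencies match the DP."""
        rng = np.random.default_rng(0)
        n = 20_000
        hits = sum(
            sample_sswm_walk(two_peak_l2, "01", rng).terminal == "00"
            for _ in range(n)
        )
        p = reach_probability(two_peak_l2, "00")["01"]  # 1/2
        assert abs(hits / n - p) < 3 * math.sqrt(p * (1 - p) / n)
        ls = FitnessLandscape(
            {"000": 0.1, "001": 0.5, "010": 0.4, "100": 0.3,
             "011": 0.9, "110": 0.8}
        )
        rho = reach_probability(ls, "011")
        freq = (
            sum(
                sample_sswm_walk(ls, "000", rng).terminal == "011"
                for _ in range(n)
            )
            / n
        )
        sigma = math.sqrt(rho["000"] * (1 - rho["000"]) / n)
        assert abs(freq - rho["000"]) < 3 * sigma + 1e-12


class TestAccessibility:
    def test_additive_is_fully_accessible(self):
        ls = generate_additive(L=4, seed=2)
        report = peak_accessibility(ls)
        assert report.existence_accessibility == 1.0
        assert report.mean_reach_probability == pytest.approx(1.0)
        assert report.n_peaks == 1

    def test_two_peak(self, two_peak_l2):
        report = peak_accessibility(two_peak_l2)
        assert report.existence_accessibility == pytest.approx(3 / 4)
        # rho = (1, 1/2, 1/2, 0): the intermediate genotypes split 50/50
        assert report.mean_reach_probability == pytest.approx(1 / 2)
        assert report.n_peaks == 2
        assert report.n_global_peaks == 1

    def test_uncorrelated_strictly_between_0_and_1(self):
        report = peak_accessibility(generate_uncorrelated(6, seed=4))
        assert 0.0 < report.existence_accessibility < 1.0

    def test_tied_global_peaks_reported_per_peak(self):
        ls = FitnessLandscape({"00": 1.0, "01": 0.2, "10": 0.2, "11": 1.0})
        with pytest.warns(UserWarning, match="tie"):
            report = peak_accessibility(ls)
        assert report.existence_accessibility is None
        assert set(report.per_peak) == {"00", "11"}


class TestWalkSampler:
    def test_start_at_peak(self, additive_l2):
        walk = sample_sswm_walk(additive_l2, "11", rng=0)
        assert walk.genotypes == ("11",)

    def test_l2_path_frequencies(self, additive_l2):
        rng = np.random.default_rng(1)
        n = 20_000
        counts = Counter(
            sample_sswm_walk(additive_l2, "00", rng).genotypes for _ in range(n)
        )
        assert set(counts) == {("00", "01", "11"), ("00", "10", "11")}
        # 3 sigma for a fair binomial at n = 20000 is ~0.0106
        assert abs(counts[("00", "01", "11")] / n - 0.5) < 0.011

    def test_seed_reproducible(self, additive_l2):
        a = sample_sswm_walk(additive_l2, "00", rng=42)
        b = sample_sswm_walk(additive_l2, "00", rng=42)
        assert a.genotypes == b.genotypes

    def test_walks_are_monotone(self):
        ls = generate_uncorrelated(6, seed=5)
        rng = np.random.default_rng(2)
        for start in ls.genotypes()[:10]:
            assert sample_sswm_walk(ls, start, rng).is_monotone()
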