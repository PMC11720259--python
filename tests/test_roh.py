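import math

import numpy as np
import pytest

from rohscan.io import GT
from rohscan.roh import LFormulaInputs, ROHParams, detect_roh, min_snp_threshold

from conftest import make_gm
from oracles import brute_force_roh


class TestMinSnpThreshold:
    @pytest.mark.parametrize(
        "alpha,ns,ni,het,expected",
        [
            (0.05, 64_203, 506, 0.323, 52),  # 70k-array cohort value
            (0.05, 1000, 10, 0.5, 18),  # ln(5e-6)/ln(0.5) = 17.61 -> 18
        ],
    )
    def test_known_values(self, alpha, ns, ni, het, expected):
        assert min_snp_threshold(LFormulaInputs(alpha, ns, ni, het)) == expected

    def test_high_heterozygosity_small_positive(self):
        L = min_snp_threshold(LFormulaInputs(0.05, 10_000, 100, 0.999))
        assert 1 <= L <= 5

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            LFormulaInputs(het=0.0)
        with pytest.raises(ValueError):
            LFormulaInputs(het=1.0)
        with pytest.raises(ValueError):
            LFormulaInputs(alpha=1.5)


class TestDetectROH:
    def test_single_clean_run(self, hom_run_gm):
        segs = detect_roh(hom_run_gm)
        assert len(segs) == 1
        s = segs[0]
        assert (s.start_bp, s.end_bp, s.n_snps) == (20_000, 2_000_000, 100)
        assert s.length_bp == 1_980_000

    def test_single_het_kills_run(self, hom_run_gm):
        calls = hom_run_gm.calls.copy()
        calls[0, 49] = GT.HET
        gm = make_gm(calls, positions=list(hom_run_gm.positions))
        # both flanks carry < 52 SNPs: no run survives
        assert detect_roh(gm) == []

    def test_gap_splits_run(self):
        pos = [20_000 * (j + 1) for j in range(60)]
        pos += [pos[-1] + 1_500_000 + 20_000 * j for j in range(60)]
        gm = make_gm(np.zeros((1, 120)), positions=pos)
        segs = detect_roh(gm)
        assert len(segs) == 2
        assert all(s.n_snps == 60 for s in segs)
        assert segs[0].end_bp == 1_200_000
        assert segs[1].start_bp == 2_700_000

    def test_chromosome_shorter_than_window_skipped(self):
        gm = make_gm(np.zeros((1, 10)))
        assert detect_roh(gm) == []

    def test_missing_consumes_budget_not_het(self):
        p = ROHParams(window_snps=5, min_snps_in_run=5, min_length_bp=10,
                      max_het_per_window=0, max_missing_per_window=1,
                      window_support_threshold=0.05, min_density=0.0)
        calls = np.zeros((1, 20), dtype=np.int8)
        calls[0, 10] = GT.MISSING  # one missing per window: still homozygous
        segs = detect_roh(make_gm(calls), p)
        assert len(segs) == 1 and segs[0].n_snps == 20

    def test_allele_swap_invariance(self, rng):
        calls = rng.choice([GT.HOM_REF, GT.HOM_REF, GT.HOM_ALT, GT.HET, GT.MISSING],
                           size=(3, 150)).astype(np.int8)
        gm = make_gm(calls)
        swapped = calls.copy()
        swapped[calls == GT.HOM_REF] = GT.HOM_ALT
        swapped[calls == GT.HOM_ALT] = GT.HOM_REF
        p = ROHParams(window_snps=10, min_snps_in_run=10, min_length_bp=1000, min_density=0.0)
        assert detect_roh(gm, p) == detect_roh(make_gm(swapped), p)

    def test_monotonic_in_min_snps_and_min_length(self, rng):
        calls = rng.choice([0, 0, 0, 0, 1, -1], size=(4, 200)).astype(np.int8)
        gm = make_gm(calls)
        base = ROHParams(window_snps=8, min_snps_in_run=8, min_length_bp=1000,
                         min_density=0.0)
        n_base = len(detect_roh(gm, base))
        for min_snps in (12, 20, 40):
            p = ROHParams(window_snps=8, min_snps_in_run=min_snps, min_length_bp=1000,
                          min_density=0.0)
            n = len(detect_roh(gm, p))
            assert n <= n_base
            n_base_len = len(
                detect_roh(gm, ROHParams(window_snps=8, min_snps_in_run=min_snps,
                                         min_length_bp=500_000, min_density=0.0))
            )
            assert n_base_len <= n

    def test_segment_invariants_fuzz(self, rng):
        p = ROHParams(window_snps=6, min_snps_in_run=10, min_length_bp=50_000,
                      max_gap_bp=100_000, min_density=1 / 20_000)
        for _ in range(25):
            m = int(rng.integers(20, 180))
            pos = np.sort(rng.choice(np.arange(1, 3_000_000), size=m, replace=False))
            calls = rng.choice([0, 0, 0, 0, 0, 1, -1], size=(3, m)).astype(np.int8)
            gm = make_gm(calls, positions=pos)
            for s in detect_roh(gm, p):
                assert s.end_bp > s.start_bp
                assert s.n_snps >= p.min_snps_in_run
                assert s.length_bp >= p.min_length_bp
                assert s.n_snps / s.length_bp >= p.min_density
                inside = (gm.positions >= s.start_bp) & (gm.positions <= s.end_bp)
                gaps = np.diff(gm.positions[inside])
                assert (gaps <= p.max_gap_bp).all()


class TestOracleEquivalence:
    def _random_instance(self, rng):
        n = int(rng.integers(1, 6))
        m = int(rng.integers(10, 201))
        n_chrom = int(rng.integers(1, 4))
        chroms = np.sort(rng.integers(1, n_chrom + 1, size=m))
        pos = np.empty(m, dtype=np.int64)
        for c in np.unique(chroms):
            k = int((chroms == c).sum())
            pos[chroms == c] = np.sort(
                rng.choice(np.arange(1, 2_000_000), size=k, replace=False)
            )
        calls = rng.choice([0, 0, 0, 0, 0, 2, 1, -1], size=(n, m)).astype(np.int8)
        p = ROHParams(
            window_snps=int(rng.integers(2, 12)),
            min_snps_in_run=int(rng.integers(2, 15)),
            window_support_threshold=float(rng.choice([0.05, 0.2, 0.5])),
            max_gap_bp=int(rng.choice([50_000, 200_000, 1_000_000])),
            min_length_bp=int(rng.choice([1, 10_000, 100_000])),
            max_het_per_window=int(rng.integers(0, 2)),
            max_missing_per_window=int(rng.integers(0, 3)),
            min_density=float(rng.choice([0.0, 1 / 50_000, 1 / 10_000])),
        )
        return make_gm(calls, chromosomes=chroms, positions=pos), p

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            gm, p = self._random_instance(rng)
            fast = [
                (s.individual, s.chromosome, s.start_bp, s.end_bp, s.n_snps)
                for s in detect_roh(gm, p)
            ]
            slow = brute_force_roh(gm.calls, gm.positions, gm.chromosomes, gm.individuals, p)
            assert fast == slow
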