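import numpy as np
import pandas as pd
import pytest

from rohscan.islands import (
    IncidenceTrack,
    call_islands,
    incidence_pvalues,
    snp_incidence,
)
from rohscan.roh import ROHSegment

from conftest import make_gm
from oracles import interval_stab_counts


def track_from(counts, n, positions=None, chromosomes=None, freqs=None, pvals=None):
    m = len(counts)
    df = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chromosome": chromosomes if chromosomes is not None else [1] * m,
            "position_bp": positions if positions is not None else [1000 * (j + 1) for j in range(m)],
            "count": counts,
            "frequency": freqs if freqs is not None else np.asarray(counts) / n,
        }
    )
    if pvals is not None:
        df["p"] = pvals
    return IncidenceTrack(per_snp=df, n_individuals=n)


class TestSnpIncidence:
    def test_two_of_four_covered(self):
        gm = make_gm(np.zeros((4, 5), dtype=np.int8))
        segs = [ROHSegment("ind1", 1, 10_000, 30_000, 3), ROHSegment("ind2", 1, 20_000, 40_000, 3)]
        tr = snp_incidence(segs, gm)
        assert list(tr.per_snp["count"]) == [1, 2, 2, 1, 0]
        assert tr.per_snp["frequency"].iloc[1] == 0.5

    def test_no_segments_all_zero(self):
        gm = make_gm(np.zeros((3, 4), dtype=np.int8))
        tr = snp_incidence([], gm)
        assert (tr.per_snp["count"] == 0).all()
        assert tr.max_per_chromosome == {1: 0}

    def test_matches_interval_stabbing_oracle(self, rng):
        m = 60
        gm = make_gm(
            np.zeros((5, m), dtype=np.int8),
            chromosomes=np.sort(rng.integers(1, 3, size=m)),
            positions=None,
        )
        # rebuild positions per chromosome strictly increasing
        segs = []
        for ind in gm.individuals:
            for c, sl in gm.chromosome_slices().items():
                pos = gm.positions[sl]
                used = 0
                for _ in range(int(rng.integers(0, 3))):
                    a, b = sorted(rng.choice(pos, size=2, replace=False))
                    if a <= used:  # keep per-individual segments disjoint
                        continue
                    segs.append(ROHSegment(ind, c, int(a), int(b), 2))
                    used = int(b)
        tr = snp_incidence(segs, gm)
        expected = interval_stab_counts(segs, gm.positions, gm.chromosomes, gm.individuals)
        np.testing.assert_array_equal(tr.per_snp["count"].to_numpy(), expected)


class TestIncidencePvalues:
    def test_closed_form_examples(self):
        tr = track_from([99, 0, 50], n=100)
        out = incidence_pvalues(tr)  # M = 99
        p = out.per_snp["p"]
        assert p.iloc[0] == pytest.approx(0.01)
        assert p.iloc[1] == pytest.approx(1.0)
        assert p.iloc[2] == pytest.approx(50 / 100)

    def test_zero_max_all_p_one(self):
        tr = track_from([0, 0], n=10)
        assert (incidence_pvalues(tr).per_snp["p"] == 1.0).all()

    def test_monotone_nonincreasing_in_count(self):
        counts = list(range(0, 31))
        out = incidence_pvalues(track_from(counts, n=40))
        assert (np.diff(out.per_snp["p"]) <= 0).all()

    def test_monte_carlo_matches_closed_form_within_4sd(self):
        reps = 100_000
        for m_k in (5, 20, 99):
            counts = sorted({0, 1, m_k // 2, m_k - 1, m_k})
            cf = incidence_pvalues(track_from(counts, n=m_k + 1)).per_snp["p"].to_numpy()
            mc = incidence_pvalues(
                track_from(counts, n=m_k + 1), method="monte_carlo", reps=reps, seed=5
            ).per_snp["p"].to_numpy()
            tol = 4 * np.sqrt(cf * (1 - cf) / reps) + 1e-12
            assert (np.abs(mc - cf) <= tol).all()

    def test_literal_tail_is_complement_like(self):
        tr = track_from([10, 0], n=12)  # M = 10
        upper = incidence_pvalues(tr).per_snp["p"]
        literal = incidence_pvalues(tr, tail="literal").per_snp["p"]
        # literal reading gives large values for enriched SNPs
        assert upper.iloc[0] == pytest.approx(1 / 11)
        assert literal.iloc[0] == pytest.approx(10 / 11)

    def test_monte_carlo_requires_seed_and_reps(self):
        tr = track_from([1], n=2)
        with pytest.raises(ValueError):
            incidence_pvalues(tr, method="monte_carlo", seed=None)
        with pytest.raises(ValueError):
            incidence_pvalues(tr, method="monte_carlo", reps=0, seed=1)


class TestCallIslands:
    def test_basic_island(self):
        freqs = [0.2, 0.6, 0.6, 0.6, 0.6, 0.6, 0.2]
        pvals = [0.5, 0.004, 0.004, 0.004, 0.004, 0.004, 0.5]
        tr = track_from([0] * 7, n=10, freqs=freqs, pvals=pvals)
        islands = call_islands(tr)
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.start_bp, isl.end_bp, isl.n_snps) == (2000, 6000, 5)
        assert isl.mean_p == pytest.approx(0.004)
        assert isl.length_bp == 4000

    def test_two_significant_snps_insufficient(self):
        freqs = [0.6] * 5
        pvals = [0.004, 0.004, 0.5, 0.5, 0.5]
        tr = track_from([0] * 5, n=10, freqs=freqs, pvals=pvals)
        assert call_islands(tr) == []

    def test_frequency_below_half_never_island(self):
        tr = track_from([0] * 5, n=10, freqs=[0.49] * 5, pvals=[0.001] * 5)
        assert call_islands(tr) == []

    def test_requires_pvalues(self):
        tr = track_from([1, 2], n=4)
        with pytest.raises(ValueError, match="p-values"):
            call_islands(tr)

    def test_islands_sorted_and_non_overlapping(self):
        freqs = [0.6] * 4 + [0.1] + [0.7] * 4
        pvals = [0.001] * 4 + [0.9] + [0.001] * 4
        tr = track_from([0] * 9, n=10, freqs=freqs, pvals=pvals)
        islands = call_islands(tr)
        assert [i.island_id for i in islands] == [1, 2]
        assert islands[0].end_bp < islands[1].start_bp
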