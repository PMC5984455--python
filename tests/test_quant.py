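"""Peak quantification formulas, coverageBed-style counting, retention
filtering, the candidate caller and rank-sum comparison."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epitempo.quant import (AlignedRead, ReadIndex, quantify_peak,
                            count_reads_in_interval, filter_peaks,
                            call_candidate_peaks, region_enrichment_pvalues,
                            compare_enrichment_distributions)

HAVE_BEDTOOLS = shutil.which("bedtools") is not None


class TestFormulas:
    def test_matches_independent_evaluator_on_random_tuples(self, rng):
        evaluate = lambda A, D, C, B, E: (A * 1e9 / (B * C),
                                          D * 1e9 / (E * C),
                                          (A * 1e9 / (B * C)) / (D * 1e9 / (E * C)))
        n = 10_000
        A = rng.integers(0, 10_000, n).astype(float)
        D = rng.integers(1, 10_000, n).astype(float)
        C = rng.integers(50, 2_000, n).astype(float)
        B = rng.uniform(1e6, 1e8, n)
        E = rng.uniform(1e6, 1e8, n)
        for a, d, c, b, e in zip(A, D, C, B, E):
            q = quantify_peak(a, d, c, b, e)
            ra, rb, rc = evaluate(a, d, c, b, e)
            assert abs(q.ip_fpkm - ra) <= 1e-12 * max(1.0, abs(ra))
            assert abs(q.input_fpkm - rb) <= 1e-12 * max(1.0, abs(rb))
            if a > 0:
                assert abs(q.enrichment - rc) <= 1e-12 * abs(rc)

    def test_hand_example(self):
        assert quantify_peak(100, 50, 200, 1e7, 1e7).ip_fpkm == pytest.approx(50.0)

    def test_symmetry_gives_unit_enrichment(self):
        q = quantify_peak(123, 123, 150, 5e6, 5e6)
        assert q.enrichment == pytest.approx(1.0)

    def test_zero_ip_count(self):
        q = quantify_peak(0, 10, 100, 1e7, 1e7)
        assert q.ip_fpkm == 0.0 and q.enrichment == 0.0

    def test_zero_input_flagged_infinite(self):
        q = quantify_peak(5, 0, 100, 1e7, 1e7)
        assert not q.enrichment_defined
        assert np.isinf(q.enrichment)

    @pytest.mark.parametrize("kwargs", [
        dict(A=1, D=1, C=0, B=1e7, E=1e7),
        dict(A=1, D=1, C=100, B=0, E=1e7),
        dict(A=-1, D=1, C=100, B=1e7, E=1e7),
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            quantify_peak(**kwargs)

    def test_scale_invariance(self, rng):
        for _ in range(200):
            A, D = rng.integers(1, 1000, 2)
            C = int(rng.integers(50, 500))
            B, E = rng.uniform(1e6, 1e8, 2)
            k = rng.uniform(0.1, 10)
            q1 = quantify_peak(A, D, C, B, E)
            q2 = quantify_peak(k * A, k * D, C, k * B, k * E)
            assert q2.enrichment == pytest.approx(q1.enrichment, rel=1e-12)


class TestCounting:
    def _index(self, rows):
        return ReadIndex([AlignedRead(c, s, tuple(b)) for c, s, b in rows])

    def test_half_overlap_inclusive(self):
        # 100-nt read with exactly 50 nt inside the peak counts (-F 0.50)
        reads = self._index([("c", "+", [(50, 150)])])
        assert count_reads_in_interval("c", 100, 300, "+", reads) == 1
        # 49 nt inside does not
        reads = self._index([("c", "+", [(52, 152)])])
        assert count_reads_in_interval("c", 103, 300, "+", reads) == 0

    def test_opposite_strand_not_counted(self):
        reads = self._index([("c", "-", [(120, 180)])])
        assert count_reads_in_interval("c", 100, 300, "+", reads) == 0
        assert count_reads_in_interval("c", 100, 300, "+", reads,
                                       same_strand=False) == 1

    def test_no_overlap(self):
        reads = self._index([("c", "+", [(400, 500)])])
        assert count_reads_in_interval("c", 100, 300, "+", reads) == 0

    def test_split_read_blockwise_overlap(self):
        # blocks 60+40 nt; 60 of 100 overlap the peak -> counted
        reads = self._index([("c", "+", [(100, 160), (500, 540)])])
        assert count_reads_in_interval("c", 80, 200, "+", reads) == 1
        # only the 40-nt block overlaps -> 0.4 < 0.5 -> not counted
        assert count_reads_in_interval("c", 480, 600, "+", reads) == 0

    def test_strandless_read_errors(self):
        reads = self._index([("c", ".", [(100, 200)])])
        with pytest.raises(ValueError):
            count_reads_in_interval("c", 100, 300, "+", reads)

    @pytest.mark.skipif(not HAVE_BEDTOOLS, reason="bedtools not on PATH")
    def test_matches_bedtools_coverage_on_random_fixture(self, rng, tmp_path):
        peaks = []
        for i in range(20):
            s = int(rng.integers(0, 5000))
            peaks.append(("chr1", s, s + int(rng.integers(80, 400)),
                          f"p{i}", 0, "+" if rng.random() < 0.5 else "-"))
        reads = []
        for i in range(300):
            s = int(rng.integers(0, 5400))
            reads.append(("chr1", s, s + 100, f"r{i}", 0,
                          "+" if rng.random() < 0.5 else "-"))
        a = tmp_path / "peaks.bed"
        b = tmp_path / "reads.bed"
        a.write_text("".join("\t".join(map(str, p)) + "\n" for p in peaks))
        b.write_text("".join("\t".join(map(str, r)) + "\n" for r in reads))
        out = subprocess.run(
            ["bedtools", "coverage", "-a", str(a), "-b", str(b),
             "-s", "-counts", "-F", "0.50"],
            capture_output=True, text=True, check=True).stdout
        expected = [int(line.split("\t")[-1])
                    for line in out.strip().split("\n")]
        idx = ReadIndex([AlignedRead(c, st, ((s, e),))
                         for c, s, e, _, _, st in reads])
        ours = [count_reads_in_interval(c, s, e, st, idx)
                for c, s, e, _, _, st in peaks]
        assert ours == expected

    @pytest.mark.skipif(not HAVE_BEDTOOLS, reason="bedtools not on PATH")
    def test_split_reads_match_bedtools_bed12(self, tmp_path):
        # one spliced read: blocks 60 nt + 40 nt around an intron
        bed12 = ("chr1\t100\t540\tr0\t0\t+\t100\t540\t0,0,0\t2\t60,40\t0,400\n")
        peak = ("chr1\t80\t200\tp0\t0\t+\n")
        a = tmp_path / "p.bed"; a.write_text(peak)
        b = tmp_path / "r.bed"; b.write_text(bed12)
        out = subprocess.run(
            ["bedtools", "coverage", "-a", str(a), "-b", str(b),
             "-s", "-split", "-counts", "-F", "0.50"],
            capture_output=True, text=True, check=True).stdout
        expected = int(out.strip().split("\t")[-1])
        idx = ReadIndex([AlignedRead("chr1", "+", ((100, 160), (500, 540)))])
        assert count_reads_in_interval("chr1", 80, 200, "+", idx) == expected == 1


class TestFilter:
    def _frame(self, fdr, a, c):
        return pd.DataFrame({"fdr": [fdr], "ip_fpkm": [a], "enrichment": [c]})

    @pytest.mark.parametrize("fdr,a,c,kept", [
        (0.01, 2.0, 1.6, True),
        (0.049, 1.01, 100.0, True),
        (0.05, 2.0, 1.6, False),      # FDR strict
        (0.01, 1.0, 1.6, False),      # ip_fpkm strict
        (0.01, 2.0, 1.5, False),      # enrichment strict
        (np.nan, 2.0, 1.6, False),    # missing FDR
    ])
    def test_three_criteria_strict(self, fdr, a, c, kept):
        retained, tally = filter_peaks(self._frame(fdr, a, c))
        assert (len(retained) == 1) is kept
        assert tally["input"] == 1

    def test_tally_accounts_for_each_criterion(self):
        df = pd.DataFrame({"fdr": [0.2, 0.01, 0.01],
                           "ip_fpkm": [5.0, 0.5, 5.0],
                           "enrichment": [5.0, 5.0, 1.2]})
        _, tally = filter_peaks(df)
        assert tally["retained"] == 0
        assert tally["rejected_fdr"] == 1
        assert tally["rejected_ip_fpkm"] == 1
        assert tally["rejected_enrichment"] == 1


class TestCandidateCaller:
    def test_single_window_pvalue_matches_exact_binomial(self):
        # A=30, D=5 with equal library sizes: p0 = 0.5
        p = region_enrichment_pvalues(np.array([30]), np.array([5]),
                                      1e7, 1e7)[0]
        exact = sum(stats.binom.pmf(k, 35, 0.5) for k in range(30, 36))
        assert p == pytest.approx(exact, rel=1e-9)

    def test_null_yields_no_retained_peaks(self, rng):
        from epitempo.transcripts import TranscriptModel
        tx = TranscriptModel("g", "g.t", "c", "+", ((0, 5000),),
                             cds_start=300, cds_end=4500)
        mk = lambda: ReadIndex([
            AlignedRead("c", "+", ((s, s + 100),))
            for s in rng.integers(0, 4900, 2000)])
        peaks = call_candidate_peaks(mk(), mk(), [tx], 2000, 2000)
        assert len(peaks) == 0

    def test_planted_enrichment_recovered(self, rng):
        from epitempo.transcripts import TranscriptModel
        tx = TranscriptModel("g", "g.t", "c", "+", ((0, 5000),),
                             cds_start=300, cds_end=4500)
        t0, t1 = 2000, 2250
        bg = [AlignedRead("c", "+", ((int(s), int(s) + 100),))
              for s in rng.integers(0, 4900, 1500)]
        extra = [AlignedRead("c", "+", ((int(s), int(s) + 100),))
                 for s in rng.integers(t0, t1 - 100, 400)]
        ip = ReadIndex(bg + extra)
        inp = ReadIndex([AlignedRead("c", "+", ((int(s), int(s) + 100),))
                         for s in rng.integers(0, 4900, 1500)])
        peaks = call_candidate_peaks(ip, inp, [tx], 1900, 1500)
        assert len(peaks) >= 1
        best = max(peaks.itertuples(),
                   key=lambda p: min(p.end, t1) - max(p.start, t0))
        inter = min(best.end, t1) - max(best.start, t0)
        union = max(best.end, t1) - min(best.start, t0)
        assert inter / union >= 0.5

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            call_candidate_peaks(ReadIndex([]), ReadIndex([]), [], 0, 100)


class TestRankSum:
    def test_identical_multisets_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = compare_enrichment_distributions(x, list(x))
        assert p > 0.95

    def test_extreme_separation_matches_exact_enumeration(self):
        stat, p = compare_enrichment_distributions([1, 2, 3], [11, 12, 13])
        # U = 0; exact two-sided p over the 20 equally likely orderings
        assert stat == 0
        exact = stats.mannwhitneyu([1, 2, 3], [11, 12, 13],
                                   alternative="two-sided", method="exact")
        assert p == pytest.approx(exact.pvalue)
        assert p == pytest.approx(2 * 1 / 20)

    def test_symmetric_under_swap(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=25)
        _, pxy = compare_enrichment_distributions(x, y)
        _, pyx = compare_enrichment_distributions(y, x)
        assert pxy == pytest.approx(pyx)

    def test_too_small_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_enrichment_distributions([1.0], [1.0, 2.0])
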