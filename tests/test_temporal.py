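"""Merged peak atlas, ON/OFF switches, CMR/SMR classes and differential
methylation, checked against exhaustive-definition oracles and bedtools."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epitempo.temporal import (merge_peaks_across_samples, detect_switches,
                               classify_cmr_smr, detect_dmrs, rna_gain_loss)

STAGES = ["P7", "P14", "P21", "P60"]
HAVE_BEDTOOLS = shutil.which("bedtools") is not None


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "sample_id", "gene_id"])


def _merged_from_presence(vectors):
    """Build a presence-matrix frame as the switch/class functions expect."""
    df = pd.DataFrame({f"present_{s}": [bool(v[i]) for v in vectors]
                       for i, s in enumerate(STAGES)})
    df["gene_id"] = [f"g{k}" for k in range(len(vectors))]
    df.index = [f"m{k}" for k in range(len(vectors))]
    return df


def oracle_switches(vec):
    """Brute-force pairwise diff per the ON/OFF definitions."""
    events = []
    for j in range(len(vec) - 1):
        if not vec[j] and vec[j + 1]:
            events.append((f"{STAGES[j]}-{STAGES[j + 1]}", "ON"))
        if vec[j] and not vec[j + 1]:
            events.append((f"{STAGES[j]}-{STAGES[j + 1]}", "OFF"))
    return events


def oracle_class(vec):
    if all(vec):
        return "CMR"
    if not any(vec):
        return "unmethylated"
    if sum(vec) == 1:
        return f"SMR:{STAGES[vec.index(1)]}"
    return "other"


class TestMerge:
    def test_overlapping_same_strand_peaks_merge(self):
        merged = merge_peaks_across_samples(_peaks([
            ("c", 100, 200, "+", "P7", "g1"),
            ("c", 150, 250, "+", "P14", "g1")]), samples=STAGES)
        assert len(merged) == 1
        row = merged.iloc[0]
        assert (row["start"], row["end"]) == (100, 250)
        assert row["present_P7"] and row["present_P14"]
        assert not row["present_P21"] and not row["present_P60"]

    def test_opposite_strands_never_merge(self):
        merged = merge_peaks_across_samples(_peaks([
            ("c", 100, 200, "+", "P7", "g1"),
            ("c", 100, 200, "-", "P14", "g2")]), samples=STAGES)
        assert len(merged) == 2

    def test_singleton_peak(self):
        merged = merge_peaks_across_samples(_peaks([
            ("c", 10, 60, "+", "P21", "g1")]), samples=STAGES)
        assert len(merged) == 1
        assert merged.iloc[0]["present_P21"]

    def test_bookended_intervals_merge(self):
        merged = merge_peaks_across_samples(_peaks([
            ("c", 100, 200, "+", "P7", "g1"),
            ("c", 200, 300, "+", "P7", "g1")]), samples=STAGES)
        assert len(merged) == 1
        assert (merged.iloc[0]["start"], merged.iloc[0]["end"]) == (100, 300)

    @pytest.mark.skipif(not HAVE_BEDTOOLS, reason="bedtools not on PATH")
    def test_union_intervals_match_bedtools_merge(self, rng, tmp_path):
        rows = []
        for i in range(150):
            s = int(rng.integers(0, 4000))
            rows.append(("chr1", s, s + int(rng.integers(50, 300)),
                         "+" if rng.random() < 0.5 else "-",
                         STAGES[int(rng.integers(4))], f"g{i}"))
        merged = merge_peaks_across_samples(_peaks(rows), samples=STAGES)
        bed = tmp_path / "in.bed"
        bed.write_text("".join(
            f"{c}\t{s}\t{e}\tp{i}\t0\t{st}\n"
            for i, (c, s, e, st, _, _) in enumerate(rows)))
        out = subprocess.run(
            f"sort -k1,1 -k2,2n {bed} | bedtools merge -i - -s -c 6 -o distinct",
            shell=True, capture_output=True, text=True, check=True).stdout
        expected = set()
        for line in out.strip().split("\n"):
            c, s, e, st = line.split("\t")
            expected.add((c, int(s), int(e), st))
        ours = set(zip(merged["chrom"], merged["start"], merged["end"],
                       merged["strand"]))
        assert ours == expected


class TestSwitches:
    def test_on_at_first_transition_only(self):
        merged = _merged_from_presence([(0, 1, 1, 1)])
        events = detect_switches(merged, STAGES)
        assert len(events) == 1
        assert events.iloc[0]["transition"] == "P7-P14"
        assert events.iloc[0]["direction"] == "ON"

    def test_alternating_pattern_emits_three_events(self):
        events = detect_switches(_merged_from_presence([(1, 0, 1, 0)]), STAGES)
        got = list(zip(events["transition"], events["direction"]))
        assert sorted(got) == sorted([("P7-P14", "OFF"), ("P14-P21", "ON"),
                                      ("P21-P60", "OFF")])

    def test_matches_exhaustive_oracle_on_random_vectors(self, rng):
        vectors = [tuple(int(x) for x in rng.integers(0, 2, 4))
                   for _ in range(1000)]
        merged = _merged_from_presence(vectors)
        events = detect_switches(merged, STAGES)
        by_peak = {}
        for row in events.itertuples():
            by_peak.setdefault(row.merged_id, []).append(
                (row.transition, row.direction))
        for k, vec in enumerate(vectors):
            assert sorted(by_peak.get(f"m{k}", [])) == \
                sorted(oracle_switches(vec))

    def test_on_off_disjoint_per_transition(self, rng):
        vectors = [tuple(int(x) for x in rng.integers(0, 2, 4))
                   for _ in range(500)]
        events = detect_switches(_merged_from_presence(vectors), STAGES)
        for tr, grp in events.groupby("transition"):
            on = set(grp.loc[grp["direction"] == "ON", "merged_id"])
            off = set(grp.loc[grp["direction"] == "OFF", "merged_id"])
            assert not on & off

    def test_fewer_than_two_stages_rejected(self):
        with pytest.raises(ValueError):
            detect_switches(_merged_from_presence([(1, 0, 1, 0)]), ["P7"])


class TestClasses:
    @pytest.mark.parametrize("vec,label", [
        ((1, 1, 1, 1), "CMR"),
        ((0, 0, 0, 1), "SMR:P60"),
        ((1, 0, 0, 0), "SMR:P7"),
        ((1, 0, 1, 0), "other"),
        ((0, 0, 0, 0), "unmethylated"),
    ])
    def test_examples(self, vec, label):
        presence = pd.DataFrame([list(map(bool, vec))], columns=STAGES,
                                index=["r1"])
        out, _ = classify_cmr_smr(presence)
        assert out.loc["r1", "class_label"] == label

    def test_all_sixteen_patterns_match_oracle_and_are_exclusive(self):
        vectors = list(itertools.product([0, 1], repeat=4))
        presence = pd.DataFrame([list(map(bool, v)) for v in vectors],
                                columns=STAGES,
                                index=[f"r{k}" for k in range(16)])
        out, tally = classify_cmr_smr(presence)
        for k, vec in enumerate(vectors):
            assert out.loc[f"r{k}", "class_label"] == oracle_class(list(vec))
        class_sum = (tally["CMR"] + sum(tally[f"SMR:{s}"] for s in STAGES)
                     + tally["other"])
        assert class_sum == tally["methylated_total"]
        assert tally["methylated_total"] + tally["unmethylated"] == 16


class TestDmrs:
    def _frame(self, records):
        df = pd.DataFrame(records, columns=["peak_id", "gene_id", "A", "D",
                                            "C", "retained"])
        return df.set_index("peak_id")

    def test_identical_counts_unchanged(self):
        x = self._frame([("p1", "g1", 200, 50, 200, True)])
        out = detect_dmrs(x, x.copy(), (1e7, 1e7), (1e7, 1e7))
        assert out.loc["p1", "category"] == "unchanged"
        assert out.loc["p1", "log2fc"] == pytest.approx(0.0)

    def test_fourfold_increase_called_hyper_with_exact_fisher(self):
        x = self._frame([("p1", "g1", 1600, 100, 200, True)])
        y = self._frame([("p1", "g1", 400, 100, 200, True)])
        out = detect_dmrs(x, y, (1e7, 1e7), (1e7, 1e7))
        assert out.loc["p1", "category"] == "hyper"
        assert out.loc["p1", "log2fc"] == pytest.approx(2.0)
        exact = stats.fisher_exact([[1600, 100], [400, 100]])[1]
        assert out.loc["p1", "p"] == pytest.approx(exact)

    def test_fourfold_decrease_called_hypo(self):
        x = self._frame([("p1", "g1", 400, 100, 200, True)])
        y = self._frame([("p1", "g1", 1600, 100, 200, True)])
        out = detect_dmrs(x, y, (1e7, 1e7), (1e7, 1e7))
        assert out.loc["p1", "category"] == "hypo"

    def test_library_size_offset_rescales_input(self):
        # doubling the x-condition IP library halves its rates; with the
        # B/E offset the call stays unchanged
        x = self._frame([("p1", "g1", 400, 50, 200, True)])
        y = self._frame([("p1", "g1", 200, 50, 200, True)])
        out = detect_dmrs(x, y, (2e7, 1e7), (1e7, 1e7))
        assert out.loc["p1", "log2fc"] == pytest.approx(0.0)
        assert out.loc["p1", "category"] == "unchanged"

    def test_retained_only_in_one_condition_routes_to_gain_loss(self):
        x = self._frame([("p1", "g1", 300, 50, 200, True),
                         ("p2", "g2", 10, 50, 200, False)])
        y = self._frame([("p1", "g1", 10, 50, 200, False),
                         ("p2", "g2", 300, 50, 200, True)])
        out = detect_dmrs(x, y, (1e7, 1e7), (1e7, 1e7))
        assert out.loc["p1", "category"] == "gain"
        assert out.loc["p2", "category"] == "loss"

    def test_rna_level_gain_loss(self):
        out = rna_gain_loss({"a", "b"}, {"b", "c"})
        assert set(out.loc[out["category"] == "gain", "gene_id"]) == {"a"}
        assert set(out.loc[out["category"] == "loss", "gene_id"]) == {"c"}

    def test_significance_thresholds_strict(self):
        # log2fc exactly 1 must not qualify as hyper
        x = self._frame([("p1", "g1", 800, 100, 200, True)])
        y = self._frame([("p1", "g1", 400, 100, 200, True)])
        out = detect_dmrs(x, y, (1e7, 1e7), (1e7, 1e7))
        assert out.loc["p1", "log2fc"] == pytest.approx(1.0)
        assert out.loc["p1", "category"] == "unchanged"


class TestPresenceMonotonicity:
    def test_more_ip_reads_never_weaken_a_peak(self):
        from epitempo.quant import quantify_peak, region_enrichment_pvalues
        base = quantify_peak(100, 50, 200, 1e7, 1e7)
        more = quantify_peak(150, 50, 200, 1e7, 1e7)
        assert more.ip_fpkm > base.ip_fpkm
        assert more.enrichment > base.enrichment
        p_base = region_enrichment_pvalues(np.array([100]), np.array([50]),
                                           1e7, 1e7)[0]
        p_more = region_enrichment_pvalues(np.array([150]), np.array([50]),
                                           1e7, 1e7)[0]
        assert p_more <= p_base
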