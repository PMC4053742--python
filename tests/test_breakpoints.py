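"""GC peaks, enrichment nulls, homology scans, gene overlap, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from caninecnv.breakpoints import (
    GcPeakParams,
    annotation_enrichment,
    bootstrap_compare,
    breakpoint_windows,
    classify_gene_overlap,
    find_gc_peaks,
    gc_distance_profile,
    homology_scan_and_null,
    longest_perfect_match,
    repeat_excess_table,
    sd_overlap_stats,
)
from caninecnv.io import IntervalSet


def ivset(rows, extra_cols=()):
    cols = ["chrom", "start", "end", "name"] + list(extra_cols)
    return IntervalSet(pd.DataFrame(rows, columns=cols[: len(rows[0])] if rows else cols))


def make_seq(n, gc, rng):
    bases = np.array(list("ATGC"))
    p = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(rng.choice(bases, size=n, p=p))


def brute_force_gc_scan(seq, params):
    """Literal per-offset reimplementation of the dual-window scan."""
    marked = np.zeros(len(seq), dtype=bool)
    bw, pw = params.background_window, params.peak_window
    for off in range(0, len(seq) - bw + 1, params.step):
        bg = seq[off : off + bw]
        ps = off + (bw - pw) // 2
        pk = seq[ps : ps + pw]
        bgv = [c for c in bg if c != "N"]
        pkv = [c for c in pk if c != "N"]
        if not bgv or not pkv:
            continue
        bg_frac = sum(c in "GC" for c in bgv) / len(bgv)
        pk_frac = sum(c in "GC" for c in pkv) / len(pkv)
        if pk_frac == 0:
            continue
        if bg_frac == 0 or pk_frac / bg_frac >= params.fold:
            marked[ps : ps + pw] = True
    return marked


class TestGcPeaks:
    def test_uniform_sequence_no_peaks(self):
        rng = np.random.default_rng(0)
        seq = make_seq(30_000, 0.40, rng)
        assert len(find_gc_peaks(seq)) == 0

    def test_planted_peak_detected_and_matches_brute_force(self):
        rng = np.random.default_rng(1)
        seq = list(make_seq(40_000, 0.40, rng))
        seq[20_000:20_500] = list(make_seq(500, 0.68, rng))
        seq = "".join(seq)
        params = GcPeakParams()
        peaks = find_gc_peaks(seq, params)
        assert len(peaks) >= 1
        hit = peaks.table[(peaks.table["start"] <= 20_250) & (peaks.table["end"] > 20_250)]
        assert len(hit) == 1
        marked = brute_force_gc_scan(seq, params)
        ours = np.zeros(len(seq), dtype=bool)
        for _, r in peaks.table.iterrows():
            ours[r["start"] : r["end"]] = True
        np.testing.assert_array_equal(ours, marked)

    def test_all_n_sequence_empty(self):
        assert len(find_gc_peaks("N" * 20_000)) == 0

    def test_brute_force_agreement_on_random_planted_sequences(self):
        params = GcPeakParams(step=100)
        for seed in range(3):
            rng = np.random.default_rng(seed + 10)
            seq = list(make_seq(60_000, 0.38, rng))
            for _ in range(4):
                c = int(rng.integers(6_000, 54_000))
                w = int(rng.integers(300, 900))
                seq[c : c + w] = list(make_seq(w, rng.uniform(0.55, 0.75), rng))
            g = int(rng.integers(6_000, 54_000))
            seq[g : g + 400] = "N" * 400
            seq = "".join(seq)
            marked = brute_force_gc_scan(seq, params)
            ours = np.zeros(len(seq), dtype=bool)
            for _, r in find_gc_peaks(seq, params).table.iterrows():
                ours[r["start"] : r["end"]] = True
            np.testing.assert_array_equal(ours, marked)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_gc_peaks("ACGT" * 100)


class TestBreakpointWindows:
    def test_centered_window(self):
        loci = pd.DataFrame(
            [{"locus_id": "L1", "chrom": "chr1", "start": 50_000, "end": 80_000}]
        )
        w = breakpoint_windows(loci, {"chr1": 200_000})
        left = w[w["side"] == "left"].iloc[0]
        assert (left["start"], left["end"]) == (45_000, 55_000)

    def test_clipping_at_chromosome_start(self):
        loci = pd.DataFrame(
            [{"locus_id": "L1", "chrom": "chr1", "start": 2_000, "end": 50_000}]
        )
        w = breakpoint_windows(loci, {"chr1": 200_000})
        left = w[w["side"] == "left"].iloc[0]
        assert (left["start"], left["end"]) == (0, 7_000)

    def test_two_windows_per_locus(self):
        loci = pd.DataFrame(
            [
                {"locus_id": f"L{i}", "chrom": "chr1", "start": 20_000 * (i + 1), "end": 20_000 * (i + 1) + 5_000}
                for i in range(5)
            ]
        )
        assert len(breakpoint_windows(loci, {"chr1": 500_000})) == 10


class TestEnrichment:
    def _windows(self, n=20, width=1_000, chrom_len=500_000, rng=None):
        rng = rng or np.random.default_rng(0)
        starts = rng.integers(0, chrom_len - width, n)
        return pd.DataFrame(
            {
                "locus_id": [f"L{i}" for i in range(n)],
                "chrom": "chr1",
                "start": starts,
                "end": starts + width,
            }
        )

    def test_everything_covered_gives_oe_one_p_one(self):
        windows = self._windows()
        features = ivset([("chr1", 0, 500_000, "all")])
        res = annotation_enrichment(windows, features, {"chr1": 500_000}, reps=50, seed=1)
        assert res.oe == pytest.approx(1.0)
        assert res.p_upper == 1.0

    def test_features_only_inside_windows_hit_significance_floor(self):
        windows = self._windows(n=10)
        rows = [
            ("chr1", int(r["start"]) + 100, int(r["start"]) + 200, "f")
            for _, r in windows.iterrows()
        ]
        res = annotation_enrichment(
            pd.DataFrame(windows), ivset(rows), {"chr1": 500_000}, reps=1000, seed=2
        )
        assert res.p_upper == pytest.approx(1 / 1001)

    def test_double_density_near_windows_estimates_oe_two(self):
        rng = np.random.default_rng(3)
        chrom_len = 1_000_000
        windows = self._windows(n=30, width=2_000, chrom_len=chrom_len, rng=rng)
        rows = []
        # uniform background features
        for s in rng.integers(0, chrom_len - 50, 400):
            rows.append(("chr1", int(s), int(s) + 50, "bg"))
        # matched extra features inside windows to double the local density
        density = 400 / chrom_len
        per_window = int(density * 2_000 * 30)
        for _ in range(per_window):
            w = windows.iloc[int(rng.integers(len(windows)))]
            s = int(rng.integers(w["start"], w["end"] - 50))
            rows.append(("chr1", s, s + 50, "extra"))
        res = annotation_enrichment(
            windows, ivset(rows), {"chr1": chrom_len}, reps=300, seed=4, statistic="features"
        )
        assert res.oe == pytest.approx(2.0, rel=0.25)

    def test_reproducible_with_seed(self):
        windows = self._windows()
        features = ivset([("chr1", 1000, 1500, "f")])
        r1 = annotation_enrichment(windows, features, {"chr1": 500_000}, reps=50, seed=9)
        r2 = annotation_enrichment(windows, features, {"chr1": 500_000}, reps=50, seed=9)
        np.testing.assert_array_equal(r1.null, r2.null)
        assert r1.reps == 50 and r1.seed == 9


class TestRepeatExcess:
    def test_uniform_family_excess_near_one(self):
        rng = np.random.default_rng(5)
        chrom_len = 1_000_000
        rows = [
            ("chr1", int(s), int(s) + 200, "L1", 0.05)
            for s in range(0, chrom_len - 200, 2_000)
        ]
        rmsk = IntervalSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "divergence"])
        )
        starts = rng.integers(0, chrom_len - 10_000, 30)
        windows = pd.DataFrame(
            {"locus_id": range(30), "chrom": "chr1", "start": starts, "end": starts + 10_000}
        )
        out = repeat_excess_table(windows, rmsk, {"chr1": chrom_len})
        assert out.iloc[0]["excess"] == pytest.approx(1.0, rel=0.1)

    def test_family_only_inside_windows(self):
        windows = pd.DataFrame(
            [{"locus_id": "L1", "chrom": "chr1", "start": 10_000, "end": 20_000}]
        )
        rows = [("chr1", 12_000, 13_000, "L1", 0.02)]
        rmsk = IntervalSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "divergence"])
        )
        out = repeat_excess_table(windows, rmsk, {"chr1": 1_000_000})
        # all family bases in the windows: excess = genome / window length
        assert out.iloc[0]["excess"] == pytest.approx(1_000_000 / 10_000)

    def test_family_absent_from_windows(self):
        windows = pd.DataFrame(
            [{"locus_id": "L1", "chrom": "chr1", "start": 10_000, "end": 20_000}]
        )
        rows = [("chr1", 500_000, 501_000, "L1", 0.02)]
        rmsk = IntervalSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "divergence"])
        )
        out = repeat_excess_table(windows, rmsk, {"chr1": 1_000_000})
        assert out.iloc[0]["excess"] == 0.0
        assert out.iloc[0]["n_breakpoints_with"] == 0


class TestLongestPerfectMatch:
    def test_identical_sequences(self):
        s = "ACGT" * 2_500
        assert longest_perfect_match(s, s) == 10_000

    def test_known_overlap(self):
        assert longest_perfect_match("ACGTACGT", "TTACGTAA") == 5  # "ACGTA"

    def test_disjoint_alphabets_and_empty(self):
        assert longest_perfect_match("AAAA", "CCCC") == 0
        assert longest_perfect_match("", "ACGT") == 0

    def test_n_never_matches(self):
        assert longest_perfect_match("ANNNA", "ANNNA") == 1

    def test_strand_aware_reverse_complement(self):
        a = "AAAAAAACCCCCCC"
        b_rc = a[::-1].translate(str.maketrans("ACGT", "TGCA"))  # GGGGGGGTTTTTTT
        assert longest_perfect_match(a, b_rc) == 0
        assert longest_perfect_match(a, b_rc, strand_aware=True) == len(a)

    def dp_oracle(self, a, b):
        """O(nm) dynamic program over match diagonals."""
        a = a.replace("N", "#")
        b = b.replace("N", "$")
        best = 0
        prev = np.zeros(len(b) + 1, dtype=np.int32)
        arr_b = np.frombuffer(b.encode(), dtype="S1")
        for ch in a:
            match = arr_b == ch.encode()
            cur = np.zeros(len(b) + 1, dtype=np.int32)
            cur[1:][match] = prev[:-1][match] + 1
            best = max(best, int(cur.max()))
            prev = cur
        return best

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dp_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n, m = rng.integers(1, 301, size=2)
            a = make_seq(int(n), 0.5, rng)
            b = make_seq(int(m), 0.5, rng)
            assert longest_perfect_match(a, b) == self.dp_oracle(a, b)


class TestHomologyScan:
    def _genome_and_loci(self, rng, n_loci=6, chrom_len=120_000):
        genome = {"chr1": make_seq(chrom_len, 0.45, rng)}
        starts = rng.integers(10_000, chrom_len - 30_000, n_loci)
        loci = pd.DataFrame(
            {
                "locus_id": [f"L{i}" for i in range(n_loci)],
                "chrom": "chr1",
                "start": starts,
                "end": starts + 15_000,
            }
        )
        return genome, loci

    def test_planted_tracts_detected_with_floor_p(self):
        rng = np.random.default_rng(6)
        genome, loci = self._genome_and_loci(rng)
        seq = list(genome["chr1"])
        tract = make_seq(150, 0.45, rng)
        for _, r in loci.iterrows():
            for b in (int(r["start"]), int(r["end"])):
                seq[b - 75 : b + 75] = list(tract)
        genome["chr1"] = "".join(seq)
        res = homology_scan_and_null(loci, genome, width=2_000, reps=200, seed=7)
        assert (res.per_locus["match_len"] >= 150).all()
        assert res.n_gt_75 == len(loci)
        assert res.p == pytest.approx(1 / 201)

    def test_zero_reps_reports_observed_only(self):
        rng = np.random.default_rng(8)
        genome, loci = self._genome_and_loci(rng, n_loci=3)
        res = homology_scan_and_null(loci, genome, width=1_000, reps=0, seed=1)
        assert res.p is None
        assert len(res.per_locus) == 3

    def test_null_calibration_observed_near_null_mean(self):
        rng = np.random.default_rng(9)
        genome, loci = self._genome_and_loci(rng, n_loci=8)
        res = homology_scan_and_null(loci, genome, width=1_500, reps=100, seed=2)
        assert res.mean_length == pytest.approx(res.null_means.mean(), rel=0.35)
        assert 0.01 <= res.p <= 1.0


class TestGeneOverlap:
    def _genes(self):
        return pd.DataFrame(
            [
                {"chrom": "chr1", "start": 10_000, "end": 20_000, "name": "g1",
                 "strand": "+", "stop_start": 19_997, "stop_end": 20_000},
                {"chrom": "chr1", "start": 50_000, "end": 70_000, "name": "g2",
                 "strand": "+", "stop_start": 69_997, "stop_end": 70_000},
            ]
        )

    def _loci(self, ivs):
        return pd.DataFrame(
            [
                {"locus_id": f"L{i}", "chrom": "chr1", "start": s, "end": e, "class": c}
                for i, (s, e, c) in enumerate(ivs)
            ]
        )

    def test_three_overlap_classes(self):
        loci = self._loci(
            [
                (30_000, 40_000, "deletion"),   # intergenic
                (5_000, 25_000, "deletion"),    # whole gene
                (60_000, 80_000, "duplication"),  # partial incl. stop codon
                (45_000, 60_000, "duplication"),  # partial, 5' side only
            ]
        )
        per, counts = classify_gene_overlap(loci, self._genes())
        per = per.set_index("locus_id")
        assert per.loc["L0", "overlap_class"] == "intergenic"
        assert per.loc["L1", "overlap_class"] == "whole-gene"
        assert per.loc["L2", "overlap_class"] == "partial-gene"
        assert per.loc["L2", "stop_codon_removed"] == True  # noqa: E712
        assert per.loc["L3", "overlap_class"] == "partial-gene"
        assert per.loc["L3", "stop_codon_removed"] == False  # noqa: E712
        assert counts.loc["total", "intergenic"] == 1
        assert counts.loc["total", "whole_gene"] == 1
        assert counts.loc["total", "stop_codon"] == 1

    def test_deletion_duplication_ratio(self):
        loci = self._loci(
            [(30_000, 40_000, "deletion")] * 226 + [(30_000, 40_000, "duplication")] * 104
        )
        _, counts = classify_gene_overlap(loci, self._genes())
        assert counts.loc["del_dup_ratio", "total"] == pytest.approx(2.17, abs=0.005)


class TestBootstrap:
    def test_identical_groups(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 60)
        out = bootstrap_compare(a, a.copy(), reps=500, seed=2)
        assert out["p"] > 0.5
        assert out["ci_low"] <= 0 <= out["ci_high"]

    def test_strongly_shifted_groups_hit_floor(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 50)
        b = rng.normal(10, 1, 50)
        out = bootstrap_compare(a, b, reps=500, seed=4)
        assert out["p"] == pytest.approx(2 / 501)

    def test_median_of_identical_triples(self):
        out = bootstrap_compare([1, 2, 3], [1, 2, 3], statistic="median", reps=200, seed=5)
        assert out["difference"] == 0.0

    def test_few_reps_warns(self):
        with pytest.warns(UserWarning):
            bootstrap_compare([1.0, 2.0], [3.0, 4.0], reps=50, seed=6)


class TestSdOverlap:
    def _loci(self, rows):
        return pd.DataFrame(
            [
                {"locus_id": f"L{i}", "chrom": "chr1", "start": s, "end": e,
                 "class": "deletion", "complex_flag": cf}
                for i, (s, e, cf) in enumerate(rows)
            ]
        )

    def test_no_sds_all_non_sd(self):
        loci = self._loci([(10_000, 20_000, False), (40_000, 60_000, False)])
        sds = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "name"]))
        out = sd_overlap_stats(loci, sds, reps=100, seed=1)
        assert out.attrs["n_sd_loci"] == 0
        assert out.attrs["n_non_sd_loci"] == 2

    def test_abutting_half_open_is_non_sd(self):
        loci = self._loci([(10_000, 20_000, False)])
        sds = ivset([("chr1", 20_000, 25_000, "sd")])
        out = sd_overlap_stats(loci, sds, reps=100, seed=1)
        assert out.attrs["n_sd_loci"] == 0

    def test_longer_sd_stratum_significant(self):
        rng = np.random.default_rng(2)
        rows = []
        sd_rows = []
        pos = 10_000
        for i in range(40):
            if i < 20:  # SD stratum: long loci
                size = int(rng.integers(40_000, 60_000))
                sd_rows.append(("chr1", pos, pos + 1_000, "sd"))
            else:
                size = int(rng.integers(10_000, 15_000))
            rows.append((pos, pos + size, False))
            pos += size + 5_000
        loci = self._loci(rows)
        out = sd_overlap_stats(loci, ivset(sd_rows), reps=500, seed=3).set_index("property")
        assert out.loc["size", "p"] == pytest.approx(2 / 501)
        assert out.loc["size", "sd_value"] > out.loc["size", "non_sd_value"]


class TestGcDistanceProfile:
    def test_peaks_at_breakpoints_enrich_bin_zero(self):
        rng = np.random.default_rng(4)
        chrom_len = 2_000_000
        starts = rng.integers(100_000, chrom_len - 200_000, 15)
        loci = pd.DataFrame(
            {"locus_id": [f"L{i}" for i in range(15)], "chrom": "chr1",
             "start": starts, "end": starts + 60_000}
        )
        rows = []
        for _, r in loci.iterrows():
            for b in (int(r["start"]), int(r["end"])):
                rows.append(("chr1", b - 250, b + 250, "peak"))
        out = gc_distance_profile(
            loci, ivset(rows), {"chr1": chrom_len},
            max_dist=30_000, bin_width=5_000, reps=60, seed=5,
        )
        near = out[np.abs(out["distance"]) <= 5_000]["oe"].max()
        far = out[np.abs(out["distance"]) >= 20_000]["oe"].mean()
        assert near > 5 * max(far, 0.05)

    def test_empty_peaks_all_zero(self):
        loci = pd.DataFrame(
            [{"locus_id": "L1", "chrom": "chr1", "start": 200_000, "end": 300_000}]
        )
        empty = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "name"]))
        out = gc_distance_profile(loci, empty, {"chr1": 1_000_000}, reps=10, seed=6)
        assert (out["observed"] == 0).all()
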