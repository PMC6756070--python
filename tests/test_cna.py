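"""Gene-level CN calling, genome fractions, ploidy and amplification peaks."""

import numpy as np
import pandas as pd
import pytest

from incis import cna
from tests.conftest import make_allelic, make_genes, make_segments


def per_base_oracle(gene, segments):
    """Brute-force reference: give every base its segment value, then apply
    the breakpoint-conflict rules on the base multiset."""
    values = []
    for _, s in segments[segments["chrom"] == gene["chrom"]].iterrows():
        lo = max(s["start"], gene["start"])
        hi = min(s["end"], gene["end"])
        values.extend([s["value"]] * max(0, hi - lo))
    if not values:
        return float("nan"), cna.MISSING_NO_COVERAGE
    arr = np.array(values)
    states = np.where(arr >= 0.15, 1, np.where(arr <= -0.15, -1, 0))
    if (states == 1).any() and (states == -1).any():
        return float("nan"), cna.MISSING_CONFLICT
    if (states == 1).any():
        return float(arr.max()), cna.GAIN
    if (states == -1).any():
        return float(arr.min()), cna.LOSS
    return float(np.median(arr)), cna.NEUTRAL


class TestCallState:
    @pytest.mark.parametrize(
        "value,state",
        [(0.16, cna.GAIN), (0.15, cna.GAIN), (0.0, cna.NEUTRAL),
         (-0.15, cna.LOSS), (-0.149, cna.NEUTRAL)],
    )
    def test_thresholds_inclusive(self, value, state):
        assert cna.call_state(value) == state

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            cna.call_state(float("nan"))


class TestMedianCentering:
    def test_constant_profile_goes_to_zero(self):
        seg = make_segments([(1, 0, 100, 0.3), (1, 100, 400, 0.3)])
        out = cna.median_center_profile(seg)
        assert np.allclose(out["value"], 0.0)

    def test_length_weighted_center(self):
        seg = make_segments([(1, 0, 100, 0.2), (1, 100, 400, 0.4)])
        out = cna.median_center_profile(seg)
        assert np.allclose(out["value"], [-0.2, 0.0])

    def test_idempotent(self):
        seg = make_segments([(1, 0, 100, -0.2), (1, 100, 400, 0.0)])
        out = cna.median_center_profile(cna.median_center_profile(seg))
        assert np.allclose(out["value"], seg["value"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cna.median_center_profile(make_segments([]))


class TestGeneMapping:
    @pytest.mark.parametrize(
        "seg_rows,expected_value,expected_state",
        [
            # single covering segment
            ([(1, 0, 1000, 0.3)], 0.3, cna.GAIN),
            # rule i: both gain, keep most extreme
            ([(1, 0, 500, 0.3), (1, 500, 1000, 0.5)], 0.5, cna.GAIN),
            # rule ii: all neutral, median value
            ([(1, 0, 500, 0.05), (1, 500, 1000, -0.05)], 0.0, cna.NEUTRAL),
            # rule iii: neutral + gain, keep aberrant extreme
            ([(1, 0, 500, 0.3), (1, 500, 1000, 0.0)], 0.3, cna.GAIN),
        ],
    )
    def test_conflict_rules(self, seg_rows, expected_value, expected_state):
        gene = {"gene_id": "G1", "chrom": 1, "start": 100, "end": 900}
        call = cna.map_gene_copy_number(gene, make_segments(seg_rows))
        assert call.value == pytest.approx(expected_value)
        assert call.state == expected_state

    def test_rule_iv_gain_and_loss_is_missing(self):
        gene = {"gene_id": "G1", "chrom": 1, "start": 100, "end": 900}
        seg = make_segments([(1, 0, 500, 0.3), (1, 500, 1000, -0.2)])
        call = cna.map_gene_copy_number(gene, seg)
        assert call.state == cna.MISSING_CONFLICT
        assert np.isnan(call.value)

    def test_no_coverage_flagged(self):
        gene = {"gene_id": "G1", "chrom": 2, "start": 100, "end": 900}
        call = cna.map_gene_copy_number(gene, make_segments([(1, 0, 1000, 0.3)]))
        assert call.state == cna.MISSING_NO_COVERAGE
        assert call.no_coverage

    def test_matches_per_base_oracle_random(self, rng):
        for _ in range(200):
            cuts = np.sort(rng.choice(np.arange(1, 300), size=rng.integers(1, 6),
                                      replace=False))
            bounds = [0, *cuts.tolist(), 300]
            rows = [(1, bounds[i], bounds[i + 1], float(rng.normal(0, 0.25)))
                    for i in range(len(bounds) - 1)]
            seg = make_segments(rows)
            start = int(rng.integers(0, 290))
            gene = {"gene_id": "G", "chrom": 1, "start": start,
                    "end": int(rng.integers(start + 1, 301))}
            call = cna.map_gene_copy_number(gene, seg)
            v, s = per_base_oracle(gene, seg)
            assert call.state == s
            if not np.isnan(v):
                assert call.value == pytest.approx(v)

    def test_matrix_agrees_with_single_gene_calls(self, rng):
        seg = make_segments(
            [(1, 0, 400, 0.3), (1, 400, 1000, -0.2), (2, 0, 1000, 0.02)]
        )
        genes = make_genes(
            [("A", 1, 100, 300), ("B", 1, 300, 500), ("C", 2, 10, 60), ("D", 3, 0, 10)]
        )
        values, states = cna.gene_cn_matrix(seg, genes)
        for _, g in genes.iterrows():
            call = cna.map_gene_copy_number(g, seg)
            assert states.loc[g["gene_id"], "S1"] == call.state
            if not np.isnan(call.value):
                assert values.loc[g["gene_id"], "S1"] == pytest.approx(call.value)


class TestGenomeFractions:
    def test_fraction_aberrant(self):
        assert cna.fraction_genome_aberrant(
            make_segments([(1, 0, 100, 0.3), (1, 100, 400, 0.0)])
        ) == pytest.approx(0.25)

    def test_all_neutral_zero(self):
        assert cna.fraction_genome_aberrant(
            make_segments([(1, 0, 100, 0.05)])
        ) == 0.0

    def test_invariant_under_splitting(self, rng):
        seg = make_segments([(1, 0, 500, 0.3), (1, 500, 900, 0.0), (2, 0, 400, -0.4)])
        split = make_segments(
            [(1, 0, 250, 0.3), (1, 250, 500, 0.3), (1, 500, 900, 0.0),
             (2, 0, 100, -0.4), (2, 100, 400, -0.4)]
        )
        assert cna.fraction_genome_aberrant(seg) == pytest.approx(
            cna.fraction_genome_aberrant(split)
        )

    def test_loh_definition(self):
        seg = make_allelic([(1, 0, 100, 1, 0), (1, 100, 200, 0, 0), (1, 200, 400, 2, 1)])
        loh, frac = cna.call_loh(seg)
        assert list(loh["start"]) == [0]  # homozygous deletion is not LOH
        assert frac == pytest.approx(100 / 400)

    def test_ploidy_dichotomy(self):
        assert cna.estimate_ploidy(make_allelic([(1, 0, 100, 1, 1)])) == (2.0, "low")
        p, g = cna.estimate_ploidy(
            make_allelic([(1, 0, 100, 1, 1), (1, 100, 200, 2, 1)])
        )
        assert p == pytest.approx(2.5)
        assert g == "high"
        assert cna.estimate_ploidy(make_allelic([(1, 0, 100, 2, 2)])) == (4.0, "high")

    @pytest.mark.parametrize(
        "rows,expected",
        [
            ([(1, 0, 100, 1, 1)], 2),
            ([(1, 0, 60, 1, 1), (1, 60, 100, 2, 2)], 2),  # 60% at 2
            ([(1, 0, 40, 1, 1), (1, 40, 100, 2, 2)], 4),  # 60% at 4
        ],
    )
    def test_weighted_median_total_cn(self, rows, expected):
        assert cna.sample_median_total_cn(make_allelic(rows)) == expected


class TestAmpliconPeaks:
    genes = make_genes([(f"G{i}", 1, i * 100, i * 100 + 50) for i in range(60)])

    def test_diploid_focal_peak(self):
        seg = make_allelic([(1, 0, 150, 1, 1), (1, 150, 400, 7, 1), (1, 400, 6000, 1, 1)])
        peaks = cna.call_amplicon_peaks(seg, self.genes)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.max_additional_copies == 6
        assert p.focal and not p.high_level
        assert p.gene_count == 2  # G2 and G3 overlap [150, 400); G1 ends at 150

    def test_tetraploid_same_total_no_peak(self):
        seg = make_allelic([(1, 0, 150, 2, 2), (1, 150, 400, 6, 2), (1, 400, 6000, 2, 2)])
        assert cna.call_amplicon_peaks(seg, self.genes) == []

    def test_adjacent_runs_merge_to_broad_high_level(self):
        big = make_genes([(f"G{i}", 1, i * 100, i * 100 + 50) for i in range(100)])
        seg = make_allelic(
            [(1, 0, 1000, 1, 1), (1, 1000, 4000, 17, 1), (1, 4000, 7000, 21, 1),
             (1, 7000, 10000, 1, 1), (2, 0, 50000, 1, 1)]  # diploid bulk anchors the median
        )
        peaks = cna.call_amplicon_peaks(seg, big)
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start, p.end) == (1000, 7000)
        assert p.max_additional_copies == 20
        assert p.high_level and not p.focal
        assert p.gene_count == 60

    def test_peaks_maximal_no_adjacent_pair(self, default_sim):
        allelic = default_sim["allelic_segments"]
        peaks = cna.cohort_amplicon_peaks(allelic, default_sim["genes"])
        for sample_peaks in peaks.values():
            by_chrom = {}
            for p in sample_peaks:
                by_chrom.setdefault(p.chrom, []).append(p)
            for plist in by_chrom.values():
                plist.sort(key=lambda p: p.start)
                for a, b in zip(plist, plist[1:]):
                    assert a.end < b.start  # adjacent runs would have merged

    def test_high_level_threshold_monotone(self, default_sim):
        allelic = default_sim["allelic_segments"]
        genes = default_sim["genes"]
        p5 = cna.cohort_amplicon_peaks(allelic, genes, min_additional=5)
        p15 = cna.cohort_amplicon_peaks(allelic, genes, min_additional=15)
        for sid, plist in p15.items():
            for p in plist:
                covering = [
                    q for q in p5[sid]
                    if q.chrom == p.chrom and q.start <= p.start and q.end >= p.end
                ]
                assert covering, "every >=15 peak lies inside a >=5 peak"
                assert set(p.genes) <= set(covering[0].genes)


class TestRecurrence:
    def test_single_tumor_excluded_and_ci(self):
        genes = make_genes([("A", 1, 100, 200), ("B", 2, 100, 200)])
        peak = lambda sid, chrom, g: cna.AmpliconPeak(  # noqa: E731
            sid, chrom, 50, 250, 20, 1, (g,), True, True
        )
        peaks = {
            "S1": [peak("S1", 1, "A"), peak("S1", 2, "B")],
            "S2": [peak("S2", 1, "A")],
            "S3": [peak("S3", 1, "A")],
        }
        table = cna.recurrent_amplified_genes(peaks, 203, min_additional=5, min_tumors=2)
        assert list(table["gene_id"]) == ["A"]
        row = table.iloc[0]
        assert row["n_samples"] == 3
        assert round(100 * row["frequency"], 1) == 1.5
        assert round(100 * row["ci_lower"], 1) == 0.5
        assert round(100 * row["ci_upper"], 1) == 4.3
        # determinism on identical input
        again = cna.recurrent_amplified_genes(peaks, 203, min_additional=5, min_tumors=2)
        pd.testing.assert_frame_equal(table, again)
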