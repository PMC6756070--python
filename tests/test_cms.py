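"""Differential expression, overlap fractions, resampling and compartments."""

import math

import numpy as np
import pandas as pd
import pytest

from incis import cms, cna, integration
from incis.simulate import SimConfig, simulate_cohort, simulate_compartment_reference


def expr_frame(matrix, samples=None):
    samples = samples or [f"S{j}" for j in range(matrix.shape[1])]
    return pd.DataFrame(
        matrix, index=pd.Index([f"g{i}" for i in range(matrix.shape[0])], name="gene_id"),
        columns=samples,
    )


class TestDEUpregulated:
    def test_null_data_gives_empty_set(self, rng):
        expr = expr_frame(rng.normal(size=(200, 40)))
        labels = pd.Series(["CMS2"] * 10 + ["CMS4"] * 30, index=expr.columns)
        de = cms.de_upregulated(expr, labels, "CMS2")
        assert de["upregulated"].sum() == 0

    def test_shifted_genes_recovered(self, rng):
        expr = rng.normal(0, 0.3, size=(300, 80))
        expr[:50, :20] += 1.0  # 50 true genes shifted in the subtype
        frame = expr_frame(expr)
        labels = pd.Series(["CMS2"] * 20 + ["CMS4"] * 60, index=frame.columns)
        de = cms.de_upregulated(frame, labels, "CMS2")
        hits = de["upregulated"].iloc[:50].sum()
        assert hits >= 45
        assert de["upregulated"].iloc[50:].sum() <= 5

    def test_fold_change_strictly_above_threshold(self):
        # exact log2(1.2) shift with zero noise: fdr ~ 0 but the fold-change
        # test is strict, so the gene must not be called upregulated
        base = np.zeros((1, 20))
        base[0, :10] = math.log2(1.2)
        frame = expr_frame(base)
        labels = pd.Series(["CMS2"] * 10 + ["CMS4"] * 10, index=frame.columns)
        de = cms.de_upregulated(frame, labels, "CMS2")
        assert de["log_fc"].iloc[0] == pytest.approx(math.log2(1.2))
        assert not de["upregulated"].iloc[0]

    def test_unknown_subtype_rejected(self, rng):
        expr = expr_frame(rng.normal(size=(10, 8)))
        labels = pd.Series(["CMS2"] * 8, index=expr.columns)
        with pytest.raises(ValueError):
            cms.de_upregulated(expr, labels, "CMS9")


class TestOverlapFraction:
    @pytest.mark.parametrize(
        "up,ic,expected",
        [
            ({"a", "b"}, {"a", "b"}, 1.0),
            ({"a", "b"}, {"c"}, 0.0),
            (set("abcdefghij"), set("abcde"), 0.5),
        ],
    )
    def test_fractions(self, up, ic, expected):
        assert cms.overlap_fraction(up, ic).overlap_fraction == pytest.approx(expected)

    def test_empty_set_flagged_as_nan(self):
        assert math.isnan(cms.overlap_fraction(set(), {"a"}).overlap_fraction)

    def test_relabeling_invariance(self):
        up, ic = {"a", "b", "c"}, {"b", "c", "d"}
        ren = {"a": "x1", "b": "x2", "c": "x3", "d": "x4"}
        f1 = cms.overlap_fraction(up, ic).overlap_fraction
        f2 = cms.overlap_fraction({ren[g] for g in up}, {ren[g] for g in ic})
        assert f1 == f2.overlap_fraction


class TestGeneListResampling:
    def test_superset_always_one(self):
        up = [f"g{i}" for i in range(300)]
        dist = cms.resample_gene_lists(up, up, size=250, n_iter=20, seed=3)
        # drawing 250 of 300 from both lists cannot reach fraction 1 unless
        # the draws coincide; a true superset does:
        full = cms.resample_gene_lists(up, up + ["extra"] * 0, size=300, n_iter=5, seed=3)
        assert np.allclose(full.fractions_a, 1.0)
        assert np.all(dist.fractions_a <= 1.0)

    def test_disjoint_always_zero(self):
        a = [f"a{i}" for i in range(260)]
        b = [f"b{i}" for i in range(260)]
        dist = cms.resample_gene_lists(a, b, size=250, n_iter=10, seed=0)
        assert np.allclose(dist.fractions_a, 0.0)

    def test_seed_determinism(self):
        a = [f"g{i}" for i in range(400)]
        b = [f"g{i}" for i in range(200, 600)]
        d1 = cms.resample_gene_lists(a, b, 250, 15, seed=9)
        d2 = cms.resample_gene_lists(a, b, 250, 15, seed=9)
        assert np.array_equal(d1.fractions_a, d2.fractions_a)

    def test_short_list_rejected(self):
        with pytest.raises(ValueError):
            cms.resample_gene_lists(["a"], ["b"] * 300, size=250, n_iter=2, seed=0)


@pytest.fixture(scope="module")
def tiny_cohort():
    """A small cohort with a strong dosage-driven subtype for resampling tests."""
    config = SimConfig(seed=21, n_samples=90, n_genes=400, program_size=60,
                       stromal_program_size=40, amp_width_genes=(2, 8))
    sim = simulate_cohort(config)
    rel = sim["relative_segments"]
    centered = pd.concat(
        [cna.median_center_profile(s) for _, s in rel.groupby("sample")],
        ignore_index=True,
    )
    values, states = cna.gene_cn_matrix(centered, sim["genes"])
    keep = integration.filter_low_variance(sim["expression"], 0.1)
    expr = sim["expression"].loc[keep]
    labels = sim["metadata"]["cms"].where(
        sim["metadata"]["cms"].isin(["CMS1", "CMS2", "CMS3", "CMS4"])
    )
    mss = sim["metadata"].index[sim["metadata"]["msi"] == "MSS"]
    expr = expr[[s for s in expr.columns if s in set(mss)]]
    upreg = {}
    for s in ("CMS2", "CMS4"):
        de = cms.de_upregulated(expr, labels, s)
        upreg[s] = list(de.index[de["upregulated"]])
    return {"expr": expr, "states": states, "values": values, "labels": labels,
            "upregulated": upreg, "sim": sim}


class TestResampleEnrichment:
    def test_seed_determinism(self, tiny_cohort):
        kwargs = dict(
            labels=tiny_cohort["labels"], pair=("CMS2", "CMS4"), variant="ii",
            n_iter=4, per_group=10, seed=5,
            original_upregulated=tiny_cohort["upregulated"],
        )
        d1 = cms.resample_enrichment(
            tiny_cohort["expr"], tiny_cohort["states"], tiny_cohort["values"], **kwargs)
        d2 = cms.resample_enrichment(
            tiny_cohort["expr"], tiny_cohort["states"], tiny_cohort["values"], **kwargs)
        assert np.array_equal(d1.fractions_a, d2.fractions_a, equal_nan=True)
        assert d1.prop_a_greater == d2.prop_a_greater

    def test_variant_iii_equals_ii_when_subsample_covers_list(self, tiny_cohort):
        common = dict(
            labels=tiny_cohort["labels"], pair=("CMS2", "CMS4"),
            n_iter=4, per_group=10, seed=5,
            original_upregulated=tiny_cohort["upregulated"],
        )
        d2 = cms.resample_enrichment(
            tiny_cohort["expr"], tiny_cohort["states"], tiny_cohort["values"],
            variant="ii", **common)
        d3 = cms.resample_enrichment(
            tiny_cohort["expr"], tiny_cohort["states"], tiny_cohort["values"],
            variant="iii", gene_subsample=10_000, **common)
        assert np.array_equal(d2.fractions_a, d3.fractions_a, equal_nan=True)

    def test_variant_i_runs_and_separates_driven_subtype(self, tiny_cohort):
        dist = cms.resample_enrichment(
            tiny_cohort["expr"], tiny_cohort["states"], tiny_cohort["values"],
            tiny_cohort["labels"], ("CMS2", "CMS4"), variant="i",
            n_iter=6, per_group=10, seed=2,
        )
        assert dist.prop_a_greater >= 0.5

    def test_small_subtype_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            cms.resample_enrichment(
                tiny_cohort["expr"], tiny_cohort["states"], tiny_cohort["values"],
                tiny_cohort["labels"], ("CMS2", "CMS4"), variant="ii",
                n_iter=2, per_group=500,
                original_upregulated=tiny_cohort["upregulated"],
            )

    def test_null_cohort_prop_centers_at_half(self):
        config = SimConfig(
            seed=33, n_samples=80, n_genes=300, dosage_effect=0.0,
            amp_width_genes=(2, 8),
            stromal_program_size=0, program_size=40, amp_rate=0.0,
            msi_fraction=0.0,
            cms_proportions={"CMS1": 0.0, "CMS2": 0.5, "CMS3": 0.0, "CMS4": 0.5},
            purity_mean_by_cms={"CMS2": 0.6, "CMS4": 0.6, "NA": 0.6},
        )
        sim = simulate_cohort(config)
        centered = pd.concat(
            [cna.median_center_profile(s)
             for _, s in sim["relative_segments"].groupby("sample")],
            ignore_index=True,
        )
        values, states = cna.gene_cn_matrix(centered, sim["genes"])
        labels = sim["metadata"]["cms"]
        expr = sim["expression"]
        upreg = {}
        for s in ("CMS2", "CMS4"):
            de = cms.de_upregulated(expr, labels, s)
            upreg[s] = list(de.index[de["upregulated"]])
        dist = cms.resample_enrichment(
            expr, states, values, labels, ("CMS2", "CMS4"), variant="ii",
            n_iter=500, per_group=20, seed=1, original_upregulated=upreg,
        )
        assert dist.prop_a_greater == pytest.approx(0.5, abs=0.05)


class TestCompartments:
    def test_marker_recovery_and_determinism(self):
        config = SimConfig(seed=13, n_genes=600, stromal_program_size=90,
                           program_size=80, amp_width_genes=(2, 8))
        expr, labels = simulate_compartment_reference(config)
        expr2, _ = simulate_compartment_reference(config)
        pd.testing.assert_frame_equal(expr, expr2)
        sets = cms.compartment_specific_genes(expr, labels)
        truth = simulate_cohort(config)["truth"].gene_truth
        for comp in cms.MICROENVIRONMENT:
            markers = set(truth.index[truth["compartment"] == comp])
            assert markers, "generator must assign markers"
            recovered = len(markers & sets[comp]) / len(markers)
            assert recovered >= 0.9

    def test_zero_effect_yields_no_markers(self):
        config = SimConfig(seed=13, n_genes=300, compartment_effect=0.0,
                           program_size=40, stromal_program_size=30,
                           amp_width_genes=(2, 8))
        expr, labels = simulate_compartment_reference(config)
        sets = cms.compartment_specific_genes(expr, labels)
        assert all(len(s) == 0 for s in sets.values())

    def test_missing_compartment_rejected(self, rng):
        expr = expr_frame(rng.normal(size=(20, 6)))
        labels = pd.Series(["epithelial"] * 3 + ["fibroblast"] * 3, index=expr.columns)
        with pytest.raises(ValueError):
            cms.compartment_specific_genes(expr, labels)

    def test_depletion_rules(self):
        sets = {"fibroblast": {"f1"}, "endothelial": {"e1"}, "leukocyte": {"l1"},
                "epithelial": {"p1"}}
        assert cms.deplete_microenvironment({"x", "p1"}, sets) == {"x", "p1"}
        assert cms.deplete_microenvironment({"f1", "e1", "l1"}, sets) == set()
        # never removes genes absent from the microenvironment sets
        survivors = cms.deplete_microenvironment({"x", "f1"}, sets)
        assert "x" in survivors and "f1" not in survivors

    def test_compartment_enrichment_directions(self, rng):
        universe = [f"g{i}" for i in range(500)]
        sets = {"epithelial": set(universe[:100]), "fibroblast": set(universe[100:150]),
                "endothelial": set(universe[150:200]), "leukocyte": set(universe[200:250])}
        in_cis = set(universe[:50])  # subset of the epithelial program
        table = cms.compartment_enrichment(in_cis, sets, universe)
        assert table.loc["epithelial", "p"] < 1e-6
        assert table.loc["fibroblast", "odds_ratio"] < 1.0 or \
            table.loc["fibroblast", "p"] > 0.05
        # independent random sets: odds ratio near 1 on average
        ors = []
        for _ in range(20):
            rand = set(rng.choice(universe, size=50, replace=False))
            t = cms.compartment_enrichment(rand, sets, universe)
            ors.append(t.loc["epithelial", "odds_ratio"])
        assert 0.5 < float(np.median(ors)) < 2.0

    def test_empty_in_cis_not_evaluable(self):
        table = cms.compartment_enrichment(
            set(), {c: set() for c in cms.COMPARTMENTS}, ["g1", "g2"])
        assert not table["evaluable"].any()


class TestArmAndCorrelation:
    def test_arm_fraction(self):
        ann = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "arm": ["20q", "20q", "13q"]})
        assert cms.arm_fraction({"a", "b"}, "20q", ann) == 1.0
        assert cms.arm_fraction({"c"}, "20q", ann) == 0.0
        assert cms.arm_fraction({"a", "c"}, "20q", ann) == 0.5
        assert cms.arm_fraction({"a", "zz"}, "20q", ann) == 1.0  # unannotated dropped

    def test_median_correlation_pure_dosage(self):
        samples = [f"S{i}" for i in range(10)]
        cnv = np.tile(np.linspace(-0.5, 0.5, 10), (5, 1))
        expr = expr_frame(2.0 * cnv, samples)
        cn = pd.DataFrame(cnv, index=expr.index, columns=samples)
        assert cms.median_cn_expr_correlation(expr, cn, samples) == pytest.approx(1.0)

    def test_median_correlation_null_near_zero(self, rng):
        samples = [f"S{i}" for i in range(30)]
        expr = expr_frame(rng.normal(size=(100, 30)), samples)
        cn = pd.DataFrame(rng.normal(0, 0.2, size=(100, 30)), index=expr.index,
                          columns=samples)
        assert abs(cms.median_cn_expr_correlation(expr, cn, samples)) < 0.15

    def test_ks_compare_delegates(self):
        res = cms.ks_compare([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.statistic == pytest.approx(0.0)
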