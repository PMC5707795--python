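import dataclasses

import numpy as np
import pandas as pd
import pytest

import neuromark as nm
from neuromark.markers import GeneProvenance, select_from_pass_rates
from neuromark.preprocess import CellTypeSummary

from conftest import make_matrix


def brute_force_silhouette(x, labels):
    """Independent O(n^2) silhouette: a(i), b(i), s=(b-a)/max(a,b).

    ``labels`` assigns each sample to one of two clusters; singleton
    clusters contribute width 0.  Returns per-sample widths.
    """
    n = len(x)
    widths = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        other = [j for j in range(n) if labels[j] != labels[i]]
        if not own:
            widths.append(0.0)
            continue
        a = float(np.mean([abs(x[i] - x[j]) for j in own]))
        b = float(np.mean([abs(x[i] - x[j]) for j in other]))
        m = max(a, b)
        widths.append((b - a) / m if m > 0 else 0.0)
    return widths


def brute_force_scores(values, target_samples, other_by_type):
    order = list(target_samples) + [s for t in other_by_type for s in other_by_type[t]]
    x = [values[s] for s in order]
    labels = [0] * len(target_samples) + [1] * (len(order) - len(target_samples))
    mean_sil = float(np.mean(brute_force_silhouette(x, labels)))
    per_type = []
    for t, members in other_by_type.items():
        if not members:
            continue
        sub = list(target_samples) + list(members)
        xs = [values[s] for s in sub]
        ls = [0] * len(target_samples) + [1] * len(members)
        widths = brute_force_silhouette(xs, ls)
        per_type.append(float(np.mean(widths[: len(target_samples)])))
    return mean_sil, min(per_type)


class TestSilhouette:
    def test_perfect_separation(self):
        r = nm.silhouette_scores(
            {"a": 0, "b": 0, "c": 10, "d": 10}, ["a", "b"], {"X": ["c", "d"]}
        )
        assert r.mean_sil == 1.0 and r.min_sil == 1.0

    def test_hand_computed_example(self):
        r = nm.silhouette_scores(
            {"t1": 8, "t2": 10, "o1": 6, "o2": 7}, ["t1", "t2"], {"X": ["o1", "o2"]}
        )
        # s values: -0.25, 0.428571, 0.666667, 0.5
        assert r.mean_sil == pytest.approx(0.336310, abs=1e-6)

    def test_min_sil_is_worst_pairwise(self):
        values = {"t1": 8, "t2": 10, "a1": 6, "a2": 7, "b1": 9, "b2": 9}
        r = nm.silhouette_scores(
            values, ["t1", "t2"], {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        )
        _, expected_min = brute_force_scores(
            values, ["t1", "t2"], {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        )
        assert r.min_sil == pytest.approx(expected_min, abs=1e-12)

    def test_degenerate_identical_values(self):
        r = nm.silhouette_scores(
            {"a": 5, "b": 5, "c": 5}, ["a"], {"X": ["b", "c"]}
        )
        assert r.mean_sil == 0.0 and r.min_sil == 0.0 and r.degenerate

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_types = rng.integers(3, 7)
        groups = {
            f"T{k}": [f"T{k}_s{i}" for i in range(rng.integers(2, 9))]
            for k in range(n_types)
        }
        values = {
            s: float(rng.normal(k * rng.uniform(0, 3), 1))
            for k, (t, members) in enumerate(groups.items())
            for s in members
        }
        target = "T0"
        others = {t: m for t, m in groups.items() if t != target}
        r = nm.silhouette_scores(values, groups[target], others)
        exp_mean, exp_min = brute_force_scores(values, groups[target], others)
        assert r.mean_sil == pytest.approx(exp_mean, abs=1e-12)
        assert r.min_sil == pytest.approx(exp_min, abs=1e-12)


def make_summary(genes, columns, values, scale=nm.LOG2_INTENSITY):
    return CellTypeSummary(
        values=pd.DataFrame(values, index=genes, columns=columns),
        scale=scale,
        provenance={},
    )


GOOD_SIL = nm.SilhouetteResult("g", "T", 0.9, 0.2)


class TestEvaluateGene:
    def test_strong_marker_qualifies_by_fold(self):
        summary = make_summary(["g"], ["T", "A", "B", "C"], [[12.0, 7.0, 6.5, 5.0]])
        v = nm.evaluate_gene(
            "g", "T", summary, GOOD_SIL, [12.0, 12.0, 12.1],
            nm.MarkerSelectionConfig(),
        )
        # 12.0 > 6 + log2(10) and 12.0 - 6.5 = 5.5 >= log2(10)
        assert v.qualifies and v.c1_expression and v.c2_fold and v.c3_silhouette

    def test_low_summary_uses_strict_max_branch(self):
        config = nm.MarkerSelectionConfig()
        ok = make_summary(["g"], ["T", "A", "B"], [[8.5, 8.0, 6.0]])
        v = nm.evaluate_gene("g", "T", ok, GOOD_SIL, [8.5, 8.6], config)
        assert v.c2_fold  # 8.5 < 9.32 -> strict max rule, 8.5 > 8.0
        bad = make_summary(["g"], ["T", "A", "B"], [[8.5, 8.6, 6.0]])
        v = nm.evaluate_gene("g", "T", bad, GOOD_SIL, [8.5, 8.6], config)
        assert not v.c2_fold

    def test_median_below_threshold_fails_c1(self):
        summary = make_summary(["g"], ["T", "A"], [[12.0, 5.0]])
        v = nm.evaluate_gene(
            "g", "T", summary, GOOD_SIL, [7.9, 7.9, 12.0],
            nm.MarkerSelectionConfig(),
        )
        assert not v.c1_expression and not v.qualifies

    def test_silhouette_thresholds_strict(self):
        summary = make_summary(["g"], ["T", "A"], [[12.0, 6.0]])
        at_bound = nm.SilhouetteResult("g", "T", 0.5, 0.0)
        v = nm.evaluate_gene(
            "g", "T", summary, at_bound, [12.0] * 3, nm.MarkerSelectionConfig()
        )
        assert not v.c3_silhouette

    def test_rpkm_scale_constants(self):
        # RPKM values compared after log2(x + 0.1); threshold 2.5 RPKM
        summary = make_summary(["g"], ["T", "A"], [[100.0, 0.05]], scale=nm.RPKM)
        v = nm.evaluate_gene(
            "g", "T", summary, GOOD_SIL, [3.0, 4.0], nm.MarkerSelectionConfig()
        )
        assert v.qualifies
        v = nm.evaluate_gene(
            "g", "T", summary, GOOD_SIL, [2.0, 2.0], nm.MarkerSelectionConfig()
        )
        assert not v.c1_expression


class TestSelectMarkers:
    def test_recovers_planted_markers(self, small_atlas):
        config, atlas, annotations, truth = small_atlas
        sel = nm.MarkerSelectionConfig(n_permutations=100, seed=1)
        sets = nm.select_markers(
            atlas, annotations, nm.default_region_hierarchy(), "cortex", sel
        )
        by_type = {m.cell_type: set(m.genes) for m in sets}
        for ct, planted in truth.planted_markers.items():
            assert by_type[ct] == set(planted)

    def test_deterministic_under_seed(self, small_atlas):
        _, atlas, annotations, _ = small_atlas
        h = nm.default_region_hierarchy()
        sel = nm.MarkerSelectionConfig(n_permutations=25, seed=11)
        a = nm.select_markers(atlas, annotations, h, "cortex", sel)
        b = nm.select_markers(atlas, annotations, h, "cortex", dataclasses.replace(sel))
        assert [(m.cell_type, m.genes) for m in a] == [
            (m.cell_type, m.genes) for m in b
        ]

    def test_single_pass_equals_direct_evaluation(self, small_atlas):
        _, atlas, annotations, _ = small_atlas
        h = nm.default_region_hierarchy()
        sel = nm.MarkerSelectionConfig(
            n_permutations=1, drop_fraction=0.0, seed=0
        )
        sets = nm.select_markers(atlas, annotations, h, "cortex", sel)
        summary = nm.summarize_celltype_expression(
            atlas, annotations, atlas.sample_ids
        )
        ann = {a.sample_id: a for a in annotations}
        by_type = {}
        for a in annotations:
            by_type.setdefault(a.cell_type, []).append(a.sample_id)
        for mgs in sets:
            expected = []
            others = {t: s for t, s in by_type.items() if t != mgs.cell_type}
            for g in atlas.gene_ids:
                values = atlas.data.loc[g]
                sil = nm.silhouette_scores(values, by_type[mgs.cell_type], others)
                v = nm.evaluate_gene(
                    g, mgs.cell_type, summary, sil,
                    values[by_type[mgs.cell_type]].to_numpy(),
                    nm.MarkerSelectionConfig(),
                )
                if v.qualifies:
                    expected.append(g)
            # uniqueness (criterion 4) can only shrink the direct list
            assert set(mgs.genes) <= set(expected)
            missing = set(expected) - set(mgs.genes)
            for g in missing:  # every discrepancy must be a uniqueness drop
                hits = 0
                for ct2 in by_type:
                    others2 = {t: s for t, s in by_type.items() if t != ct2}
                    sil2 = nm.silhouette_scores(
                        atlas.data.loc[g], by_type[ct2], others2
                    )
                    v2 = nm.evaluate_gene(
                        g, ct2, summary, sil2,
                        atlas.data.loc[g, by_type[ct2]].to_numpy(),
                        nm.MarkerSelectionConfig(),
                    )
                    hits += v2.qualifies
                assert hits >= 2

    def test_monotone_in_fold_and_threshold(self, small_atlas):
        _, atlas, annotations, _ = small_atlas
        h = nm.default_region_hierarchy()
        base = nm.MarkerSelectionConfig(n_permutations=20, seed=5)
        loose = nm.select_markers(atlas, annotations, h, "cortex", base)
        strict_cfg = nm.MarkerSelectionConfig(
            n_permutations=20, seed=5, fold=20.0,
            expr_threshold={nm.LOG2_INTENSITY: 9.0, nm.RPKM: 5.0},
        )
        strict = nm.select_markers(atlas, annotations, h, "cortex", strict_cfg)
        for a, b in zip(loose, strict):
            assert set(b.genes) <= set(a.genes)

    def test_fewer_than_two_cell_types_rejected(self, small_atlas):
        _, atlas, annotations, _ = small_atlas
        one_type = [a for a in annotations if a.cell_type == "t1"]
        with pytest.raises(ValueError, match="2 cell types"):
            nm.select_markers(
                atlas, one_type, nm.default_region_hierarchy(), "cortex",
                nm.MarkerSelectionConfig(n_permutations=2, seed=0),
            )

    def test_pass_rate_is_strict(self):
        rates = pd.DataFrame(
            {"T": [475 / 500, 476 / 500, 1.0], "U": [0.0, 0.0, 0.0]},
            index=["g_at_bound", "g_above", "g_perfect"],
        )
        sel = select_from_pass_rates(rates, 0.95)
        assert not sel.loc["g_at_bound", "T"]  # exactly 95% is not "more than"
        assert sel.loc["g_above", "T"] and sel.loc["g_perfect", "T"]

    def test_uniqueness_drops_shared_genes(self):
        rates = pd.DataFrame({"T": [1.0, 1.0], "U": [1.0, 0.0]}, index=["g1", "g2"])
        sel = select_from_pass_rates(rates, 0.95)
        assert not sel.loc["g1"].any()
        assert sel.loc["g2", "T"]


class TestSoftIntersect:
    def _sets(self):
        mgs_a = nm.MarkerGeneSet(
            "T", "cortex", ["both", "a_top_in_b", "a_low_in_b", "a_unmeasured"],
            {g: GeneProvenance(platforms=["microarray"]) for g in
             ["both", "a_top_in_b", "a_low_in_b", "a_unmeasured"]},
        )
        mgs_b = nm.MarkerGeneSet(
            "T", "cortex", ["both", "b_top_in_a"],
            {g: GeneProvenance(platforms=["rnaseq"]) for g in ["both", "b_top_in_a"]},
        )
        summary_b = make_summary(
            ["both", "a_top_in_b", "a_low_in_b", "b_top_in_a"],
            ["T", "U", "V"],
            [[9, 1, 1], [8, 2, 3], [4, 9, 1], [7, 1, 2]],
            scale=nm.RPKM,
        )
        summary_a = make_summary(
            ["both", "a_top_in_b", "a_low_in_b", "b_top_in_a"],
            ["T", "U", "V"],
            [[12, 6, 6], [11, 6, 6], [11, 5, 5], [10, 6, 7]],
        )
        return mgs_a, summary_b, mgs_b, summary_a

    def test_admission_rules(self):
        mgs_a, summary_b, mgs_b, summary_a = self._sets()
        out = nm.soft_intersect(mgs_a, summary_b, mgs_b, summary_a)
        assert "both" in out.genes  # selected on both platforms
        assert "a_top_in_b" in out.genes  # one platform + top on the other
        assert out.provenance["a_top_in_b"].soft_intersection
        assert "a_low_in_b" not in out.genes  # higher elsewhere on platform B
        assert "a_unmeasured" in out.genes  # only measured on platform A
        assert "b_top_in_a" in out.genes

    def test_bounds_between_intersection_and_union(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            genes = [f"g{i}" for i in range(12)]
            cols = ["T", "U", "V"]
            sa = make_summary(genes, cols, rng.normal(8, 2, size=(12, 3)))
            sb = make_summary(genes, cols, rng.normal(8, 2, size=(12, 3)))
            pick = lambda: sorted(
                rng.choice(genes, size=rng.integers(1, 8), replace=False)
            )
            mgs_a = nm.MarkerGeneSet("T", "cortex", pick())
            mgs_b = nm.MarkerGeneSet("T", "cortex", pick())
            out = set(nm.soft_intersect(mgs_a, sb, mgs_b, sa).genes)
            assert set(mgs_a.genes) & set(mgs_b.genes) <= out
            assert out <= set(mgs_a.genes) | set(mgs_b.genes)


class TestRefinementFilters:
    def test_exclusion_counts(self):
        genes = [f"g{i:04d}" for i in range(720)]
        mgs = nm.MarkerGeneSet("Microglia", "cortex", genes)
        out = nm.apply_exclusion_filter(mgs, genes[:408], "Microglia_activation")
        assert len(out.genes) == 312
        assert len(out.removed["Microglia_activation"]) == 408

    def test_exclusion_empty_list_identity(self):
        mgs = nm.MarkerGeneSet("T", "cortex", ["a", "b"])
        assert nm.apply_exclusion_filter(mgs, [], "x").genes == ["a", "b"]

    def test_inclusion_set_algebra(self):
        mgs = nm.MarkerGeneSet("T", "cortex", ["a", "b", "c"])
        out = nm.apply_inclusion_filter(mgs, ["a", "b"], ["b"])
        assert out.genes == ["a"]

    def test_inclusion_counts(self):
        genes = [f"g{i}" for i in range(47)]
        mgs = nm.MarkerGeneSet("PyramidalS100a10", "cortex", genes)
        out = nm.apply_inclusion_filter(mgs, genes[:11])
        assert len(out.genes) == 11

    def test_inclusion_disjoint_warns_and_empties(self):
        mgs = nm.MarkerGeneSet("T", "cortex", ["a", "b"])
        with pytest.warns(UserWarning):
            out = nm.apply_inclusion_filter(mgs, ["zzz"])
        assert out.genes == []

    def test_external_ranking_counts(self):
        genes = [f"g{i}" for i in range(39)]
        # 15 genes rank below another column, 24 survive
        values = np.full((39, 3), 5.0)
        values[:, 0] = 6.0
        values[:15, 0] = 4.0
        ext = make_summary(genes, ["granule_dorsal", "granule_ventral", "other"],
                           np.column_stack([values[:, 0], values[:, 0], values[:, 2]]))
        mgs = nm.MarkerGeneSet("DentateGranule", "hippocampus", genes)
        out = nm.refine_by_external_ranking(
            mgs, ext, ["granule_dorsal", "granule_ventral"]
        )
        assert len(out.genes) == 24
        assert len(out.removed["external_ranking"]) == 15

    def test_external_ranking_tie_retained(self):
        ext = make_summary(["g"], ["target", "other"], [[5.0, 5.0]])
        mgs = nm.MarkerGeneSet("T", "cortex", ["g"])
        assert nm.refine_by_external_ranking(mgs, ext, ["target"]).genes == ["g"]

    def test_external_ranking_single_column_identity(self):
        ext = make_summary(["g"], ["target"], [[5.0]])
        mgs = nm.MarkerGeneSet("T", "cortex", ["g"])
        assert nm.refine_by_external_ranking(mgs, ext, ["target"]).genes == ["g"]


class TestMarkerSetIO:
    def test_round_trip(self, tmp_path):
        mgs = nm.MarkerGeneSet(
            "T", "cortex", ["a", "b"],
            {
                "a": GeneProvenance(platforms=["microarray"], soft_intersection=True),
                "b": GeneProvenance(platforms=["microarray", "rnaseq"]),
            },
        )
        path = tmp_path / "markers.tsv"
        nm.write_marker_sets([mgs], path)
        (back,) = nm.read_marker_sets(path)
        assert back.genes == ["a", "b"]
        assert back.provenance["a"].soft_intersection
        assert back.provenance["b"].platforms == ["microarray", "rnaseq"]
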