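"""Thresholds, hierarchical/multilabel/learned classification, analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mplexpheno import panels, phenotyping
from mplexpheno.errors import ConfigurationError
from mplexpheno.phenotyping import (
    UNCLASSIFIED,
    MarkerThreshold,
    classify_hierarchical,
    classify_multilabel,
    classify_singleplex,
    compare_scripts,
    default_orders,
    derive_threshold,
    label_implies_positive,
    mp1_tree,
    mp2_tree,
    order_sweep,
)


def _cells(**columns) -> pd.DataFrame:
    return pd.DataFrame(columns)


def _th(marker: str, value: float) -> MarkerThreshold:
    return MarkerThreshold(marker, panels.MARKER_COMPARTMENT[marker], value)


def _mp1_cells_from_sets(marker_sets, level=20.0):
    """Cell table where each row is positive exactly for its marker set."""
    markers = [m for m in panels.panel_markers("MP1") if m != "DAPI"]
    cols = {}
    for m in markers:
        col = phenotyping.measurement_column(m)
        cols[col] = [level if m in s else 0.1 for s in marker_sets]
    return pd.DataFrame(cols)


MP1_THRESHOLDS = {m: _th(m, 10.0) for m in ["CK", "CD3", "CD4", "CD8", "CD20"]}
FINAL_ORDER = ["CK", "CD4", "CD3", "CD20", "CD8"]


class TestDeriveThreshold:
    def test_manual_threshold_below_constant_column_calls_all_positive(self):
        cells = _cells(CD3_membrane_mean=[5.0] * 10)
        th = derive_threshold(cells, "CD3", "manual", manual_value=2.0)
        assert classify_singleplex(cells, "CD3", th).mean() == 1.0

    @pytest.mark.parametrize("q", [0.1, 0.25, 0.5, 0.9])
    def test_quantile_match_reproduces_reference_fraction(self, q):
        # order-statistic argument: on a continuous column the called
        # fraction can always be matched to within one cell
        rng = np.random.default_rng(17)
        n = 137
        cells = _cells(CD20_membrane_mean=rng.uniform(0.5, 30.0, n))
        th = derive_threshold(
            cells, "CD20", "quantile-match", reference_positive_fraction=q
        )
        called = classify_singleplex(cells, "CD20", th).mean()
        assert abs(called - q) <= 1.0 / n

    def test_quantile_match_recovers_truth_fraction_on_scene(
        self, sparse_mp1_truth, sparse_mp1_cells
    ):
        q = float((sparse_mp1_truth.abundance("CD20") > 0).mean())
        th = derive_threshold(
            sparse_mp1_cells, "CD20", "quantile-match", reference_positive_fraction=q
        )
        called = classify_singleplex(sparse_mp1_cells, "CD20", th).mean()
        assert abs(called - q) <= 1.0 / len(sparse_mp1_cells)

    def test_otsu_lands_between_well_separated_modes(self):
        rng = np.random.default_rng(1)
        lo = rng.normal(2.0, 0.5, 300)
        hi = rng.normal(22.0, 0.5, 100)  # modes far beyond 5 sigma apart
        cells = _cells(CD8_membrane_mean=np.abs(np.concatenate([lo, hi])))
        th = derive_threshold(cells, "CD8", "otsu")
        assert 2.0 < th.value < 22.0

    def test_quantile_match_requires_reference(self):
        with pytest.raises(ConfigurationError, match="reference"):
            derive_threshold(_cells(CD3_membrane_mean=[1.0]), "CD3", "quantile-match")


class TestSingleplex:
    def test_threshold_above_max_gives_no_positives(self):
        cells = _cells(CD3_membrane_mean=[1.0, 5.0, 9.0])
        assert classify_singleplex(cells, "CD3", _th("CD3", 9.5)).sum() == 0

    def test_quantile_matched_singleplex_recovers_true_positives(
        self, sparse_mp1_truth, sparse_mp1_cells, sparse_mp1_thresholds
    ):
        from mplexpheno import segmentation

        matches = segmentation.match_to_truth(sparse_mp1_truth.cells, sparse_mp1_cells)
        truth = sparse_mp1_truth.cells.set_index("id").loc[matches["truth_id"]]
        truth_pos = truth["ab_CD20"].to_numpy() > 0
        pos = classify_singleplex(sparse_mp1_cells, "CD20", sparse_mp1_thresholds["CD20"])
        order = [
            sparse_mp1_cells.index[sparse_mp1_cells["cell_id"] == c][0]
            for c in matches["cell_id"]
        ]
        np.testing.assert_array_equal(pos.loc[order].to_numpy(), truth_pos)

    def test_calls_are_deterministic(self, sparse_mp1_cells, sparse_mp1_thresholds):
        a = classify_singleplex(sparse_mp1_cells, "CD3", sparse_mp1_thresholds["CD3"])
        b = classify_singleplex(sparse_mp1_cells, "CD3", sparse_mp1_thresholds["CD3"])
        pd.testing.assert_series_equal(a, b)


class TestHierarchical:
    def test_cd20_claim_shields_spillover_cd8(self):
        # CD20+CD8 double-threshold cell, CD20 ordered before CD8, no rule:
        # B cell stays CD20+ instead of becoming a CD8 T cell
        cells = _mp1_cells_from_sets([{"CD20", "CD8"}])
        call = classify_hierarchical(cells, MP1_THRESHOLDS, FINAL_ORDER, mp1_tree())
        assert call.labels.iloc[0] == "CD20+"

    def test_single_marker_cell_is_order_independent(self):
        cells = _mp1_cells_from_sets([{"CK"}])
        for order in default_orders("MP1").values():
            call = classify_hierarchical(cells, MP1_THRESHOLDS, order, mp1_tree())
            assert call.labels.iloc[0] == "CK+"

    def test_unexpected_rule_resolves_cd4_cd8_double_positive(self):
        cells = _mp1_cells_from_sets([{"CD3", "CD4", "CD8"}])
        tree = mp1_tree()
        s1 = classify_hierarchical(cells, MP1_THRESHOLDS, FINAL_ORDER, tree.without_unexpected())
        s2 = classify_hierarchical(cells, MP1_THRESHOLDS, FINAL_ORDER, tree)
        assert s1.labels.iloc[0] == "CD3+/CD4+"  # CD4 branch wins in script 1
        assert s2.labels.iloc[0] == "CD4+/CD8+"

    def test_every_cell_gets_exactly_one_label(self, sparse_mp1_cells, sparse_mp1_thresholds):
        call = classify_hierarchical(
            sparse_mp1_cells, sparse_mp1_thresholds, FINAL_ORDER, mp1_tree()
        )
        assert len(call.labels) == len(sparse_mp1_cells)
        fr = call.fractions(of_classified=True)
        assert fr.sum() == pytest.approx(1.0)

    def test_order_tree_mismatch_raises_before_classifying(self):
        cells = _mp1_cells_from_sets([{"CK"}])
        with pytest.raises(ConfigurationError, match="permutation"):
            classify_hierarchical(cells, MP1_THRESHOLDS, ["CK", "CD4"], mp1_tree())

    def test_audit_trail_records_each_decision(self):
        cells = _mp1_cells_from_sets([{"CD3", "CD4"}])
        call = classify_hierarchical(cells, MP1_THRESHOLDS, FINAL_ORDER, mp1_tree())
        steps = call.audit[0]
        assert any("base" in s for s in steps)
        assert any("CD3+/CD4+" in s for s in steps)


class TestMultilabel:
    def test_mapped_set_uses_vocabulary_label(self):
        cells = _mp1_cells_from_sets([{"CD3", "CD4"}])
        call = classify_multilabel(
            cells, MP1_THRESHOLDS, {frozenset({"CD3", "CD4"}): "CD3+/CD4+"}
        )
        assert call.labels.iloc[0] == "CD3+/CD4+"

    def test_unmapped_set_keeps_raw_marker_label(self):
        # contrast with hierarchy: the CD20/CD8 dual stays a dual here
        cells = _mp1_cells_from_sets([{"CD20", "CD8"}])
        ml = classify_multilabel(cells, MP1_THRESHOLDS)
        hier = classify_hierarchical(cells, MP1_THRESHOLDS, FINAL_ORDER, mp1_tree())
        assert label_implies_positive(ml.labels.iloc[0], "CD20")
        assert label_implies_positive(ml.labels.iloc[0], "CD8")
        assert hier.labels.iloc[0] == "CD20+"

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.permutations(["CK", "CD3", "CD4", "CD8", "CD20"]), st.integers(0, 2**16))
    def test_marker_evaluation_order_is_irrelevant(self, order, seed):
        rng = np.random.default_rng(seed)
        sets = [
            {m for m in order if rng.random() < 0.4} for _ in range(20)
        ]
        cells = _mp1_cells_from_sets(sets)
        base = classify_multilabel(cells, MP1_THRESHOLDS)
        permuted = classify_multilabel(cells, {m: MP1_THRESHOLDS[m] for m in order})
        assert (base.labels == permuted.labels).all() or (
            # raw labels order markers by threshold-dict order; compare sets
            [frozenset(t[:-1] for t in l.split("/")) for l in base.labels]
            == [frozenset(t[:-1] for t in l.split("/")) for l in permuted.labels]
        )


class TestLearned:
    def test_resubstitution_accuracy_on_clean_scene(
        self, sparse_mp1_cells, sparse_mp1_truth
    ):
        from mplexpheno import segmentation

        matches = segmentation.match_to_truth(sparse_mp1_truth.cells, sparse_mp1_cells)
        truth_labels = sparse_mp1_truth.cells.set_index("id").loc[
            matches["truth_id"], "phenotype"
        ]
        order = [
            sparse_mp1_cells.index[sparse_mp1_cells["cell_id"] == c][0]
            for c in matches["cell_id"]
        ]
        painted = pd.Series(truth_labels.to_numpy(), index=order)
        call = phenotyping.classify_learned(sparse_mp1_cells, painted, seed=0)
        acc = (call.labels.loc[order].to_numpy() == painted.to_numpy()).mean()
        assert acc >= 0.99

    def test_same_seed_reproduces_calls(self, sparse_mp1_cells):
        painted = pd.Series(
            ["A"] * 20 + ["B"] * 20, index=sparse_mp1_cells.index[:40]
        )
        a = phenotyping.classify_learned(sparse_mp1_cells, painted, seed=3)
        b = phenotyping.classify_learned(sparse_mp1_cells, painted, seed=3)
        assert (a.labels == b.labels).all()

    def test_single_class_training_set_rejected(self, sparse_mp1_cells):
        painted = pd.Series(["A"] * 10, index=sparse_mp1_cells.index[:10])
        with pytest.raises(ConfigurationError, match="two classes"):
            phenotyping.classify_learned(sparse_mp1_cells, painted)


class TestOrderSweep:
    def test_sparse_scene_is_order_free(self, sparse_mp1_cells, sparse_mp1_thresholds):
        sw = order_sweep(
            sparse_mp1_cells, sparse_mp1_thresholds, mp1_tree(), default_orders("MP1")
        )
        frames = sw.class_fractions
        for name in frames.index[1:]:
            pd.testing.assert_series_equal(
                frames.loc[name], frames.loc[frames.index[0]], check_names=False
            )

    def test_dense_scene_cd8_fraction_depends_on_order(self, hotspot_mp1_cells):
        sw = order_sweep(
            hotspot_mp1_cells,
            phenotyping.default_thresholds("MP1"),
            mp1_tree(),
            default_orders("MP1"),
        )
        cd8 = [
            c for c in sw.class_fractions.columns if label_implies_positive(c, "CD8")
        ]
        frac = sw.class_fractions[cd8].sum(axis=1)
        assert frac.max() - frac.min() > 0

    def test_final_order_tracks_singleplex_best(self, hotspot_mp1_cells):
        sw = order_sweep(
            hotspot_mp1_cells,
            phenotyping.default_thresholds("MP1"),
            mp1_tree(),
            default_orders("MP1"),
        )
        final_dev = sw.deviations["final"]
        assert final_dev <= sw.deviations["order1-cd20-first"]
        assert final_dev <= sw.deviations.min() + 1e-12


class TestCompareScripts:
    def test_hotspot_reclassification_is_dense_context_only(
        self, hotspot_mp1_cells, hotspot_mp1_contexts
    ):
        cmp_ = compare_scripts(
            hotspot_mp1_cells,
            phenotyping.default_thresholds("MP1"),
            FINAL_ORDER,
            mp1_tree(),
            hotspot_mp1_contexts,
        )
        re = cmp_.reassigned
        assert len(re) > 0
        assert (re["to_class"] == "CD4+/CD8+").all()
        assert (re["from_class"].map(lambda l: label_implies_positive(l, "CD4"))).all()
        assert (re["context"] == "hotspot").all()

    def test_script2_only_relabels_classified_cells(
        self, hotspot_mp1_cells, hotspot_mp1_contexts
    ):
        cmp_ = compare_scripts(
            hotspot_mp1_cells,
            phenotyping.default_thresholds("MP1"),
            FINAL_ORDER,
            mp1_tree(),
            hotspot_mp1_contexts,
        )
        s1_unclassified = cmp_.script1.labels == UNCLASSIFIED
        s2_unclassified = cmp_.script2.labels == UNCLASSIFIED
        assert (s1_unclassified == s2_unclassified).all()

    def test_mp2_scene_shows_no_script_differences(self, mp2_cells):
        cmp_ = compare_scripts(
            mp2_cells,
            phenotyping.default_thresholds("MP2"),
            default_orders("MP2")["default"],
            mp2_tree(),
        )
        assert cmp_.empty

    def test_tree_without_unexpected_rules_compares_to_itself_empty(
        self, sparse_mp1_cells, sparse_mp1_thresholds
    ):
        stripped = mp1_tree().without_unexpected()
        cmp_ = compare_scripts(
            sparse_mp1_cells, sparse_mp1_thresholds, FINAL_ORDER, stripped
        )
        assert cmp_.empty
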