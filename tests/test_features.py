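"""Gene-load collapsing and the two-layer feature reduction."""

import numpy as np
import pytest

from bdvp.discovery import SelectedVariant, SelectionResult, select_variants, annotate_selection
from bdvp.features import (
    FeatureMatrix,
    build_feature_matrix,
    forward_select,
    importance_filter,
    read_feature_matrix,
    reduce_features,
    reduction_summary,
    write_feature_matrix,
)
from bdvp.genome_model import GeneIndex, RegionClass
from bdvp.variant_store import VariantKey
from tests.conftest import make_cohort


def _selection(entries):
    return SelectionResult(
        selected=[
            SelectedVariant(
                key=VariantKey("chr1", pos, "A", "T"),
                case_carrier_count=cc,
                region=region,
                genes=tuple(genes),
            )
            for pos, cc, region, genes in entries
        ]
    )


class TestBuildFeatureMatrix:
    def test_hand_counted_loads_with_multi_gene_variant(self):
        # variants at pos 100..102; 102 is intergenic tied to two genes
        sel = _selection(
            [
                (100, 3, RegionClass.CODING, ["G1"]),
                (101, 3, RegionClass.CODING, ["G1"]),
                (102, 3, RegionClass.INTERGENIC, ["G1", "G2"]),
            ]
        )
        carrier = np.array(
            [[1, 1, 0], [0, 0, 1], [0, 0, 0], [0, 0, 0]], dtype=np.uint8
        )
        matrix, sheet = make_cohort(carrier, ["BD_CANCER"] * 3 + ["BD_ONLY"])
        fm = build_feature_matrix(sel, matrix, sheet, "coding")
        assert fm.genes == ["G1"]
        np.testing.assert_array_equal(fm.load[:, 0], [2, 0, 0, 0])
        fmi = build_feature_matrix(sel, matrix, sheet, "intergenic")
        assert fmi.genes == ["G1", "G2"]
        np.testing.assert_array_equal(fmi.load[1], [1, 1])  # both columns +1
        np.testing.assert_array_equal(fm.labels, [1, 1, 1, 0])

    def test_empty_stratum_gives_empty_matrix(self):
        sel = _selection([(100, 3, RegionClass.CODING, ["G1"])])
        matrix, sheet = make_cohort(np.ones((3, 1), np.uint8), ["BD_CANCER"] * 3)
        fm = build_feature_matrix(sel, matrix, sheet, "noncoding")
        assert fm.is_empty and fm.load.shape == (3, 0)

    def test_explicit_gene_order_zero_fills_missing(self):
        sel = _selection([(100, 3, RegionClass.CODING, ["G1"])])
        matrix, sheet = make_cohort(np.ones((3, 1), np.uint8), ["BD_CANCER"] * 3)
        fm = build_feature_matrix(sel, matrix, sheet, "coding", gene_order=["G0", "G1"])
        assert fm.genes == ["G0", "G1"]
        np.testing.assert_array_equal(fm.load.sum(axis=0), [0, 3])

    def test_column_sums_match_brute_force(self, tiny_cohort):
        sim = tiny_cohort
        sel = annotate_selection(select_variants(sim.matrix, sim.sheet), GeneIndex(sim.genes))
        for stratum in ("coding", "noncoding", "intergenic"):
            fm = build_feature_matrix(sel, sim.matrix, sim.sheet, stratum)
            probands = {s.sample_id: i for i, s in enumerate(sim.sheet)
                        if s.role == "proband" and s.group in ("BD_CANCER", "BD_ONLY")}
            for gj, gene in enumerate(fm.genes):
                expect = np.zeros(len(fm.samples), dtype=int)
                for v in sel.selected:
                    if v.stratum == stratum and gene in v.genes:
                        col = sim.matrix.column(v.key)
                        for si, sid in enumerate(fm.samples):
                            expect[si] += col[probands[sid]]
                np.testing.assert_array_equal(fm.load[:, gj], expect)

    def test_disease_only_probands_have_zero_load_on_discovery_data(self, tiny_cohort):
        sim = tiny_cohort
        sel = annotate_selection(select_variants(sim.matrix, sim.sheet), GeneIndex(sim.genes))
        for stratum in ("coding", "noncoding", "intergenic"):
            fm = build_feature_matrix(sel, sim.matrix, sim.sheet, stratum)
            assert fm.load[fm.labels == 0].sum() == 0


def _signal_noise_fm(n=200, n_noise=50, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array([1] * (n // 2) + [0] * (n // 2))
    signal = np.where(labels == 1, rng.integers(1, 4, n), 0)
    noise = rng.integers(0, 3, (n, n_noise))
    load = np.column_stack([signal, noise])
    return FeatureMatrix(
        stratum="coding",
        genes=["SIG"] + [f"N{i}" for i in range(n_noise)],
        samples=[f"S{i}" for i in range(n)],
        load=load,
        labels=labels,
    )


class TestImportanceFilter:
    def test_importances_sum_to_one_and_zero_threshold_keeps_all(self):
        fm = _signal_noise_fm()
        kept, dropped, imp = importance_filter(fm, threshold=0.0, n_trees=100, seed=1)
        assert dropped == []
        assert np.isclose(sum(imp.values()), 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_separating_gene_retained_across_seeds(self, seed):
        fm = _signal_noise_fm(seed=seed)
        kept, _, _ = importance_filter(fm, threshold=1e-5, n_trees=100, seed=seed)
        assert "SIG" in kept

    def test_single_class_labels_rejected(self):
        fm = _signal_noise_fm()
        fm.labels[:] = 1
        with pytest.raises(ValueError):
            importance_filter(fm)

    def test_seed_stability(self):
        fm = _signal_noise_fm()
        a = importance_filter(fm, seed=7)
        b = importance_filter(fm, seed=7)
        assert a == b


class TestForwardSelect:
    def test_informative_gene_picked_first(self):
        wins = 0
        for seed in range(10):
            fm = _signal_noise_fm(n=120, n_noise=8, seed=seed)
            selected, _ = forward_select(fm, cv_folds=3, seed=seed)
            wins += selected[0] == "SIG"
        assert wins > 5  # majority of seeds

    def test_zero_patience_stops_after_best_single_gene(self):
        # one perfect gene among constant (uninformative) columns: nothing
        # can improve on round 2, so only the best single gene is returned
        labels = np.array([1] * 20 + [0] * 20)
        load = np.column_stack([labels * 2, np.zeros(40), np.zeros(40)]).astype(int)
        fm = FeatureMatrix("coding", ["SIG", "Z1", "Z2"], [f"S{i}" for i in range(40)], load, labels)
        selected, dropped = forward_select(fm, cv_folds=2, seed=0, patience=0)
        assert selected == ["SIG"]
        assert set(dropped) == {"Z1", "Z2"}

    def test_selection_is_subset_of_importance_survivors(self):
        fm = _signal_noise_fm(n=100, n_noise=10)
        red, report = reduce_features(fm, cv_folds=3, n_trees=50, seed=3)
        surviving = set(fm.genes) - set(report.dropped_by_importance)
        assert set(report.kept_genes) <= surviving
        assert set(red.genes) == set(report.kept_genes)

    def test_too_many_folds_rejected(self):
        fm = _signal_noise_fm(n=20)
        with pytest.raises(ValueError, match="cv_folds"):
            forward_select(fm, cv_folds=15)


class TestReductionSummary:
    def test_boundary_cases_and_brute_force_recount(self):
        sel = _selection(
            [
                (100, 3, RegionClass.CODING, ["G1"]),
                (101, 3, RegionClass.CODING, ["G1", "G2"]),
                (102, 3, RegionClass.CODING, ["G2"]),
                (103, 3, RegionClass.CODING, ["G3"]),
                (104, 3, RegionClass.INTERGENIC, ["G3", "G4"]),
            ]
        )
        all_genes = {"G1", "G2", "G3", "G4"}
        assert reduction_summary(sel, all_genes)["variants_after"] == 5
        assert reduction_summary(sel, set())["variants_after"] == 0
        # drop G1 and G3: brute-force recount over the incidence list
        kept = {"G2", "G4"}
        expect = sum(1 for v in sel.selected if set(v.genes) & kept)
        got = reduction_summary(sel, kept)
        assert got["variants_after"] == expect == 3
        assert got["percent_reduction"] == pytest.approx(40.0)


def test_feature_matrix_serialization_round_trip(tmp_path):
    fm = _signal_noise_fm(n=10, n_noise=3)
    tsv, js = str(tmp_path / "f.tsv"), str(tmp_path / "f.json")
    write_feature_matrix(fm, tsv, js)
    back = read_feature_matrix(tsv, js)
    assert back.genes == fm.genes and back.samples == fm.samples
    np.testing.assert_array_equal(back.load, fm.load)
    np.testing.assert_array_equal(back.labels, fm.labels)
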