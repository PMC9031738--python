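"""Metric definitions against independent brute-force tallies, plus the
bespoke patch-level scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tilepurify.datatypes import CLASSES
from tilepurify.errors import DataError
from tilepurify.evaluation import (
    classification_score_vector,
    confusion_and_metrics,
    f1_from_precision_recall,
    four_score,
    image_label,
    jaccard_from_f1,
    jaccard_from_precision_recall,
    three_score,
    GROUP_SCORED_CLASS,
)

from oracles import (
    brute_accuracy,
    brute_class_metrics,
    brute_confusion,
    brute_four_score,
    brute_score_vector,
    brute_three_score,
)

THREE = ("HLN", "HP", "PDAC")


class TestConfusionMetrics:
    def test_perfect_predictions_score_one(self):
        y = ["HLN", "HP", "PDAC", "HP"]
        rep = confusion_and_metrics(y, y, THREE)
        assert np.array_equal(rep.confusion, np.diag([1, 2, 1]))
        assert rep.accuracy == 1.0
        assert (rep.per_class[["precision", "recall", "f1", "jaccard"]] == 1.0).all().all()

    def test_published_f1_and_jaccard_relation(self):
        # a class with precision 0.89 and recall 0.91 rounds to F1 0.90 and
        # Jaccard 0.82
        assert round(f1_from_precision_recall(0.89, 0.91), 2) == 0.90
        assert round(jaccard_from_precision_recall(0.89, 0.91), 2) == 0.82

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_tally(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        y_true = [str(c) for c in rng.choice(THREE, n)]
        y_pred = [str(c) for c in rng.choice(THREE, n)]
        rep = confusion_and_metrics(y_true, y_pred, THREE)
        assert np.array_equal(rep.confusion, brute_confusion(y_true, y_pred, THREE))
        assert rep.accuracy == pytest.approx(brute_accuracy(y_true, y_pred), abs=1e-12)
        for cls in THREE:
            p, r, f, j, s = brute_class_metrics(y_true, y_pred, cls)
            row = rep.per_class.loc[cls]
            assert row.precision == pytest.approx(p, abs=1e-12)
            assert row.recall == pytest.approx(r, abs=1e-12)
            assert row.f1 == pytest.approx(f, abs=1e-12)
            assert row.jaccard == pytest.approx(j, abs=1e-12)
            assert row.support == s

    def test_micro_accuracy_equals_trace_over_total(self, rng):
        y_true = [str(c) for c in rng.choice(THREE, 40)]
        y_pred = [str(c) for c in rng.choice(THREE, 40)]
        rep = confusion_and_metrics(y_true, y_pred, THREE)
        assert rep.accuracy == pytest.approx(
            rep.confusion.trace() / rep.confusion.sum()
        )

    def test_f1_jaccard_identity_on_counts(self, rng):
        y_true = [str(c) for c in rng.choice(THREE, 80)]
        y_pred = [str(c) for c in rng.choice(THREE, 80)]
        rep = confusion_and_metrics(y_true, y_pred, THREE)
        for cls in THREE:
            f1 = rep.per_class.loc[cls, "f1"]
            assert rep.per_class.loc[cls, "jaccard"] == pytest.approx(
                jaccard_from_f1(f1), abs=1e-9
            )

    def test_zero_division_flagged(self):
        rep = confusion_and_metrics(["HP", "HP"], ["HP", "HP"], THREE)
        assert "HLN" in rep.zero_division_classes
        assert rep.per_class.loc["HLN", "precision"] == 0.0

    def test_empty_input_is_error(self):
        with pytest.raises(DataError):
            confusion_and_metrics([], [], THREE)


class TestScoreVector:
    def test_counts_fractions(self):
        c = classification_score_vector(["a", "a", "b", "c"], ("a", "b", "c"))
        assert np.allclose(c, [0.5, 0.25, 0.25])

    def test_one_hot_for_uniform_labels(self):
        c = classification_score_vector(["HP"] * 7, THREE)
        assert np.allclose(c, [0.0, 1.0, 0.0])

    def test_zero_patches_is_error(self):
        with pytest.raises(DataError):
            classification_score_vector([], THREE)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.sampled_from(THREE), min_size=1, max_size=50))
    def test_sums_to_one_and_matches_oracle(self, labels):
        c = classification_score_vector(labels, THREE)
        assert c.sum() == pytest.approx(1.0)
        assert np.allclose(c, brute_score_vector(labels, THREE))

    def test_image_label_tie_breaks_to_lowest_index(self):
        assert image_label(np.array([0.5, 0.5, 0.0]), THREE) == "HLN"

    def test_image_label_ignores_zero_padding(self):
        c = np.array([0.25, 0.75, 0.0])
        assert image_label(c, THREE) == image_label(np.append(c, 0.0), THREE + ("ADI",))


class TestThreeScore:
    def test_perfect_patches_score_one(self):
        vectors = {"a": np.array([1.0, 0, 0]), "b": np.array([0, 1.0, 0]),
                   "c": np.array([0, 0, 1.0])}
        comps, agg = three_score({"a": "HLN", "b": "HP", "c": "PDAC"}, vectors, THREE)
        assert agg == 1.0 and set(comps) == set(THREE)

    def test_single_image_component(self):
        comps, agg = three_score(
            {"img": "HP"}, {"img": np.array([0.4, 0.6, 0.0])}, THREE
        )
        assert comps == {"HP": pytest.approx(0.6)}
        assert agg == pytest.approx(0.6)

    def test_matches_oracle_on_random_batch(self, rng):
        ids = [f"i{k}" for k in range(12)]
        classes = {i: str(rng.choice(THREE)) for i in ids}
        vectors = {}
        for i in ids:
            v = rng.dirichlet(np.ones(3))
            vectors[i] = v
        comps, agg = three_score(classes, vectors, THREE)
        b_comps, b_agg = brute_three_score(classes, vectors, THREE)
        assert agg == pytest.approx(b_agg, abs=1e-12)
        assert comps == pytest.approx(b_comps, abs=1e-12)


class TestFourScore:
    def _inputs(self, rng):
        groups, vectors, expert = {}, {}, {}
        for g, n in [("HLN", 3), ("HP", 2), ("PDAC", 4), ("LNPM", 3)]:
            for j in range(n):
                i = f"{g}{j}"
                groups[i] = g
                vectors[i] = rng.dirichlet(np.ones(len(CLASSES)))
                expert[i] = rng.dirichlet(np.ones(len(CLASSES)))
        return groups, vectors, expert

    def test_exact_agreement_scores_one(self, rng):
        groups, vectors, _ = self._inputs(rng)
        rep = four_score(groups, vectors, vectors, CLASSES)
        assert rep.fourscore == pytest.approx(1.0)
        assert all(v == pytest.approx(0.0) for v in rep.m.values())

    def test_single_gap_formula(self):
        groups = {"h": "HLN", "p": "HP", "d": "PDAC", "l": "LNPM"}
        vectors = {
            "h": np.array([1.0, 0, 0, 0, 0]),
            "p": np.array([0, 0.7, 0, 0, 0.3]),
            "d": np.array([0, 0, 1.0, 0, 0]),
            "l": np.array([0, 0, 1.0, 0, 0]),
        }
        expert = {k: v.copy() for k, v in vectors.items()}
        expert["p"] = np.array([0, 0.9, 0, 0, 0.1])  # model 0.7 vs expert 0.9
        rep = four_score(groups, vectors, expert, CLASSES)
        assert rep.m["HP"] == pytest.approx(0.2)
        assert rep.fourscore == pytest.approx(1 - 0.2 / 4)

    def test_lnpm_scored_on_pdac_fraction(self):
        assert GROUP_SCORED_CLASS["LNPM"] == "PDAC"

    def test_missing_group_error_lists_it(self, rng):
        groups, vectors, expert = self._inputs(rng)
        groups = {i: g for i, g in groups.items() if g != "LNPM"}
        with pytest.raises(DataError, match="LNPM"):
            four_score(groups, vectors, expert, CLASSES)

    def test_exclusion_list_honored(self, rng):
        groups, vectors, expert = self._inputs(rng)
        rep_all = four_score(groups, vectors, expert, CLASSES)
        rep_ex = four_score(groups, vectors, expert, CLASSES, exclude=("PDAC0",))
        assert rep_ex.n_images["PDAC"] == rep_all.n_images["PDAC"] - 1

    def test_matches_oracle(self, rng):
        groups, vectors, expert = self._inputs(rng)
        rep = four_score(groups, vectors, expert, CLASSES)
        assert rep.fourscore == pytest.approx(
            brute_four_score(groups, vectors, expert, list(CLASSES), GROUP_SCORED_CLASS),
            abs=1e-12,
        )
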