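"""Communicator loop: subset selection, argmax filtering, cycle
bookkeeping, the final threshold sweep, and oracle equivalence."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from tilepurify.communicator import (
    CommunicatorState,
    ReferenceDataset,
    cleanup_cycle,
    conservation_check,
    filter_tiles,
    final_sweep,
    run_cleanup,
    select_image_subsets,
    sweep_summary,
    train_communicator,
)
from tilepurify.datatypes import (
    CLASSES,
    CONTAMINANT_CLASSES,
    PARENCHYMAL_CLASSES,
    STATUS_KEPT,
    Tile,
    TileDataset,
)
from tilepurify.errors import ConfigError, DataError
from tilepurify.synthetic import (
    SyntheticCohortConfig,
    cohort_to_dataset,
    generate_cohort,
)
from tilepurify.training import DESK_CONFIG


class StubModel:
    """Fixed-prediction classifier handle for bookkeeping tests."""

    def __init__(self, classes, chooser):
        self.classes = tuple(classes)
        self._choose = chooser

    def predict(self, tiles):
        probs = np.zeros((len(tiles), len(self.classes)))
        labels = []
        for i, t in enumerate(tiles):
            lab = self._choose(t)
            probs[i, self.classes.index(lab)] = 1.0
            labels.append(lab)
        return probs, labels


def oracle_model(target):
    """Perfect oracle: predicts each tile's hidden true class (certainty 1)."""
    classes = (target, "ADI", "BG")

    def choose(t):
        return t.true_class if t.true_class in classes else target

    return StubModel(classes, choose)


@pytest.fixture(scope="module")
def contaminated():
    cfg = SyntheticCohortConfig(
        n_images_per_class=6, image_size=128, tile_size=32, contamination_rate=0.25,
        seed=21,
    )
    images, truth = generate_cohort(cfg)
    return cohort_to_dataset(images, truth, cfg.tile_size)


@pytest.fixture(scope="module")
def fast_config():
    return replace(DESK_CONFIG, max_epochs=25)


class TestSubsetSelection:
    def test_disjoint_full_size(self):
        ids = [f"im{i}" for i in range(40)]
        a, b = select_image_subsets(ids, k=20, seed=1)
        assert len(a) == len(b) == 20 and not set(a) & set(b)

    def test_fallback_halves_with_warning(self):
        with pytest.warns(UserWarning, match="k=5"):
            a, b = select_image_subsets([f"im{i}" for i in range(10)], k=20, seed=1)
        assert len(a) == len(b) == 5

    def test_too_few_images_is_error(self):
        with pytest.raises(DataError):
            select_image_subsets(["only"], k=20, seed=1)

    def test_seed_reproducible(self):
        ids = [f"im{i}" for i in range(30)]
        assert select_image_subsets(ids, 10, seed=3) == select_image_subsets(
            ids, 10, seed=3
        )


class TestFilterTiles:
    def _tiles(self, n):
        return [Tile(f"i{k}", 0, 0, np.zeros((8, 8, 3), np.uint8), "HP") for k in range(n)]

    def test_always_target_removes_nothing(self):
        model = StubModel(("HP", "ADI", "BG"), lambda t: "HP")
        kept, removed = filter_tiles(model, self._tiles(5), "HP")
        assert len(kept) == 5 and removed == []

    def test_never_target_keeps_nothing(self):
        model = StubModel(("HP", "ADI", "BG"), lambda t: "ADI")
        kept, removed = filter_tiles(model, self._tiles(5), "HP")
        assert kept == [] and all(lab == "ADI" for _, lab in removed)

    def test_target_must_be_known_to_model(self):
        model = StubModel(("ADI", "BG"), lambda t: "ADI")
        with pytest.raises(DataError):
            filter_tiles(model, self._tiles(2), "HP")


class TestTrainCommunicator:
    def test_reference_must_contain_adi(self, contaminated, fast_config):
        bad = ReferenceDataset([t for t in contaminated.tiles if t.label == "BG"])
        hp = [t for t in contaminated.tiles if t.label == "HP"][:20]
        with pytest.raises(DataError, match="ADI"):
            train_communicator(bad, hp, "HP", fast_config)

    def test_reference_cannot_overlap_target(self, contaminated, fast_config):
        ref = ReferenceDataset(
            [t for t in contaminated.tiles if t.label in ("ADI", "HP")]
        )
        hp = [t for t in contaminated.tiles if t.label == "HP"][:20]
        with pytest.raises(DataError, match="overlap"):
            train_communicator(ref, hp, "HP", fast_config)

    def test_learns_to_separate_planted_contaminants(self, contaminated, fast_config):
        ref = ReferenceDataset(
            [t for t in contaminated.tiles if t.label in CONTAMINANT_CLASSES]
        )
        hp_tiles = [t for t in contaminated.tiles if t.label == "HP"]
        model = train_communicator(ref, hp_tiles, "HP", fast_config)
        assert set(model.classes) == {"HP", "ADI", "BG"}
        kept, removed = filter_tiles(model, hp_tiles, "HP")
        planted = [t for t in hp_tiles if t.true_class in CONTAMINANT_CLASSES]
        removed_tiles = {id(t) for t, _ in removed}
        contaminant_recall = sum(id(t) in removed_tiles for t in planted) / len(planted)
        true_hp = [t for t in hp_tiles if t.true_class == "HP"]
        false_removal = sum(id(t) in removed_tiles for t in true_hp) / len(true_hp)
        assert contaminant_recall >= 0.9
        assert false_removal <= 0.1


class TestCleanupCycle:
    def test_monotone_and_logged(self, contaminated, fast_config):
        ref = ReferenceDataset(
            [t for t in contaminated.tiles if t.label in CONTAMINANT_CLASSES]
        )
        by_image = contaminated.by_image()
        hp_images = sorted({t.image_id for t in contaminated.tiles if t.label == "HP"})
        state = CommunicatorState(
            target_class="HP",
            a_images=hp_images[:3],
            a_set=[t for im in hp_images[:3] for t in by_image[im]],
        )
        b_tiles = [t for im in hp_images[3:] for t in by_image[im]]
        n0 = len(state.a_set)
        cleanup_cycle(state, ref, fast_config, b_tiles)
        assert len(state.a_set) <= n0
        assert state.cycle_index == 1 and len(state.discard_log) == 1

    def test_clean_data_loses_under_15pct(self, fast_config):
        cfg = SyntheticCohortConfig(
            n_images_per_class=6, image_size=128, tile_size=32,
            contamination_rate=0.0, seed=33,
        )
        images, truth = generate_cohort(cfg)
        ds = cohort_to_dataset(images, truth, cfg.tile_size)
        ref = ReferenceDataset([t for t in ds.tiles if t.label in CONTAMINANT_CLASSES])
        by_image = ds.by_image()
        hp_images = sorted({t.image_id for t in ds.tiles if t.label == "HP"})
        state = CommunicatorState(
            target_class="HP",
            a_images=hp_images[:3],
            a_set=[t for im in hp_images[:3] for t in by_image[im]],
        )
        n0 = len(state.a_set)
        cleanup_cycle(
            state, ref, fast_config, [t for im in hp_images[3:] for t in by_image[im]]
        )
        assert (n0 - len(state.a_set)) / n0 < 0.15

    def test_empty_a_set_is_error(self, fast_config):
        state = CommunicatorState(target_class="HP")
        with pytest.raises(DataError):
            cleanup_cycle(state, ReferenceDataset([]), fast_config, [])


class TestRunCleanup:
    def test_discard_log_has_one_entry_per_cycle(self, contaminated, fast_config):
        ref = ReferenceDataset(
            [t for t in contaminated.tiles if t.label in CONTAMINANT_CLASSES]
        )
        paren = TileDataset(
            [t for t in contaminated.tiles if t.label in PARENCHYMAL_CLASSES]
        )
        result = run_cleanup(paren, ref, n_cycles=2, config=fast_config, seed=5)
        for cls in PARENCHYMAL_CLASSES:
            assert len(result.states[cls].discard_log) == 2
            assert result.models[cls] is result.states[cls].model_2

    def test_zero_cycles_rejected(self, contaminated, fast_config):
        ref = ReferenceDataset(
            [t for t in contaminated.tiles if t.label in CONTAMINANT_CLASSES]
        )
        with pytest.raises(ConfigError):
            run_cleanup(contaminated, ref, n_cycles=0, config=fast_config)


class TestFinalSweep:
    def test_threshold_bounds(self, contaminated):
        with pytest.raises(ConfigError):
            final_sweep({}, contaminated, threshold=1.0)
        with pytest.raises(ConfigError):
            final_sweep({}, contaminated, threshold=0.0)

    def test_confident_adi_prediction_moves_tile(self):
        tiles = [Tile("i", 0, 0, np.zeros((8, 8, 3), np.uint8), "HP")]
        ds = TileDataset(tiles)
        model = StubModel(("HP", "ADI", "BG"), lambda t: "ADI")
        out = final_sweep({"HP": model}, ds)
        assert out.tiles[0].status == "moved_to_ADI"
        assert out.tiles[0].label == "ADI"

    def test_low_confidence_discards(self):
        class Unsure:
            classes = ("HP", "ADI", "BG")

            def predict(self, tiles):
                probs = np.full((len(tiles), 3), 1 / 3)
                return probs, ["HP"] * len(tiles)

        ds = TileDataset([Tile("i", 0, 0, np.zeros((8, 8, 3), np.uint8), "HP")])
        out = final_sweep({"HP": Unsure()}, ds)
        assert out.tiles[0].status == "discarded_unclassifiable"

    def test_oracle_models_recover_truth_exactly(self, contaminated):
        models = {cls: oracle_model(cls) for cls in PARENCHYMAL_CLASSES}
        out = final_sweep(models, contaminated)
        for t in out.tiles:
            assert t.label == t.true_class
            if t.true_class in CONTAMINANT_CLASSES and t.image_id.split("_")[0] in PARENCHYMAL_CLASSES:
                assert t.status == f"moved_to_{t.true_class}"
            else:
                assert t.status == STATUS_KEPT

    def test_counts_conserved_per_image(self, contaminated):
        models = {cls: oracle_model(cls) for cls in PARENCHYMAL_CLASSES}
        out = final_sweep(models, contaminated)
        assert all(conservation_check(contaminated, out).values())
        summary = sweep_summary(out)
        assert sum(summary.values()) == len(contaminated.tiles)
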