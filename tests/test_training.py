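"""Training harness: splits, balancing, LR schedule, early stopping, frozen
layers, determinism, and the grid runner."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from tilepurify.datatypes import CLASSES, Tile, TileDataset
from tilepurify.errors import ConfigError, DataError
from tilepurify.models import filter_bank, get_backbone
from tilepurify.synthetic import (
    DEFAULT_SPECS,
    generate_validation_cohort,
    ValidationCohortConfig,
)
from tilepurify.preprocessing import tile_image
from tilepurify.training import (
    DESK_CONFIG,
    TrainConfig,
    balance_by_doubling,
    fit,
    learning_rate_at,
    make_splits,
    predict,
    run_grid,
)


def _tiles(label, n, subject_prefix="s"):
    return [
        Tile(f"{label}_{i}", 0, 0, np.zeros((8, 8, 3), np.uint8), label,
             subject_id=f"{subject_prefix}_{label}_{i}")
        for i in range(n)
    ]


def _train_val(n_per_class=24, n_val=6, size=32, seed0=5000):
    from tilepurify.synthetic import render_tile

    train, val = [], []
    for cls, spec in DEFAULT_SPECS.items():
        for i in range(n_per_class):
            (val if i < n_val else train).append(render_tile(spec, seed0 + i, size=size))
    return train, val


class TestSplits:
    def test_ten_subjects_split_8_1_1(self):
        ds = TileDataset(_tiles("HP", 10))
        plan = make_splits(ds, seed=1)
        assert plan.counts() == {"train": 8, "val": 1, "test": 1}

    def test_subjects_are_disjoint_and_reproducible(self):
        ds = TileDataset(_tiles("HP", 12) + _tiles("PDAC", 12))
        p1, p2 = make_splits(ds, seed=7), make_splits(ds, seed=7)
        assert p1.assignment == p2.assignment
        assert set(p1.assignment) == {t.subject_id for t in ds.tiles}

    def test_single_subject_class_goes_to_train_with_warning(self):
        ds = TileDataset(_tiles("HP", 10) + _tiles("ADI", 1))
        with pytest.warns(UserWarning, match="ADI"):
            plan = make_splits(ds, seed=0)
        assert plan.assignment["s_ADI_0"] == "train"


class TestBalancing:
    def test_upsamples_to_majority_sharing_objects(self):
        a, b = _tiles("A", 10), _tiles("B", 4)
        out = balance_by_doubling(a + b, seed=3)
        labels = [t.label for t in out]
        assert labels.count("A") == labels.count("B") == 10
        extras = [t for t in out[14:]]
        assert all(any(t is orig for orig in b) for t in extras)  # no pixel copies

    def test_balanced_input_unchanged(self):
        tiles = _tiles("A", 5) + _tiles("B", 5)
        assert balance_by_doubling(tiles, seed=0) == tiles

    def test_strict_double_mode(self):
        out = balance_by_doubling(_tiles("A", 10) + _tiles("B", 4), mode="strict_double")
        assert [t.label for t in out].count("B") == 8


class TestConfig:
    def test_lr_schedule_decays_5pct_every_5_epochs(self):
        cfg = TrainConfig(lr=1e-4)
        assert learning_rate_at(cfg, 1) == pytest.approx(1e-4)
        assert learning_rate_at(cfg, 5) == pytest.approx(0.95e-4)
        assert learning_rate_at(cfg, 10) == pytest.approx(0.95**2 * 1e-4)

    def test_input_size_must_match_backbone_family(self):
        with pytest.raises(ConfigError):
            TrainConfig(backbone="inception_small", input_size=224)
        with pytest.raises(ConfigError):
            TrainConfig(backbone="small_cnn", input_size=299)
        TrainConfig(backbone="inception_small", input_size=299)

    def test_unknown_backbone_lists_available(self):
        with pytest.raises(ConfigError, match="small_cnn"):
            TrainConfig(backbone="resnet999")


class TestFit:
    def test_reaches_85pct_val_accuracy_in_10_epochs(self):
        train, val = _train_val(n_per_class=40, n_val=8)
        model, log = fit(train, val, replace(DESK_CONFIG, max_epochs=10, seed=0))
        _, labels = predict(model, val)
        acc = np.mean([l == t.true_class for l, t in zip(labels, val)])
        assert acc > 0.85 and len(log) <= 10

    def test_constant_loss_stops_after_patience_plus_one(self):
        train, val = _train_val(n_per_class=6, n_val=2)
        cfg = replace(DESK_CONFIG, lr=1e-300, max_epochs=50, early_stop_patience=5)
        _, log = fit(train, val, cfg)
        assert len(log) == 6  # first epoch sets the best loss, then patience

    def test_deterministic_given_seed(self):
        train, val = _train_val(n_per_class=8, n_val=2)
        cfg = replace(DESK_CONFIG, max_epochs=5, seed=9)
        m1, log1 = fit(train, val, cfg)
        m2, log2 = fit(train, val, cfg)
        assert log1.equals(log2)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_frozen_blocks_survive_fitting(self):
        train, val = _train_val(n_per_class=8, n_val=2)
        spec = get_backbone("small_cnn")
        bank_before = filter_bank(spec)
        cfg = replace(DESK_CONFIG, max_epochs=3, seed=4, layers_to_retrain=1)
        m3, _ = fit(train, val, cfg)
        m8, _ = fit(train, val, replace(cfg, max_epochs=8))
        assert np.array_equal(filter_bank(spec), bank_before)
        # untouched blocks identical across runs of different length;
        # the retrained output block differs
        assert np.array_equal(m3.params["W0"], m8.params["W0"])
        assert np.array_equal(m3.params["W1"], m8.params["W1"])
        assert not np.array_equal(m3.params["W2"], m8.params["W2"])

    def test_softmax_rows_sum_to_one(self):
        train, val = _train_val(n_per_class=8, n_val=2)
        model, _ = fit(train, val, replace(DESK_CONFIG, max_epochs=3, seed=1))
        probs, _ = predict(model, val)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_size_mismatch_error_names_expected_size(self):
        train, val = _train_val(n_per_class=8, n_val=2, size=32)
        model, _ = fit(train, val, replace(DESK_CONFIG, max_epochs=2, seed=1))
        other = [Tile("x", 0, 0, np.zeros((16, 16, 3), np.uint8), "HP")]
        with pytest.raises(DataError, match="32"):
            model.predict(other)

    def test_empty_sets_rejected(self):
        train, val = _train_val(n_per_class=8, n_val=2)
        with pytest.raises(DataError):
            fit([], val, DESK_CONFIG)
        with pytest.raises(DataError):
            fit(train, [], DESK_CONFIG)


@pytest.fixture(scope="module")
def grid_inputs():
    train, val = _train_val(n_per_class=14, n_val=3)
    test, _ = _train_val(n_per_class=4, n_val=0, seed0=7000)
    vc = ValidationCohortConfig(
        n_per_group={"HP": 1, "PDAC": 1, "HLN": 1, "LNPM": 1}, seed=2
    )
    images, _, expert = generate_validation_cohort(vc)
    vmap = {
        im.image_id: (im.class_label, tile_image(im, vc.tile_size))
        for im in images
    }
    return train, val, test, vmap, expert


class TestGrid:
    def test_ranked_table_with_failures_last(self, grid_inputs):
        train, val, test, vmap, expert = grid_inputs
        base = replace(DESK_CONFIG, max_epochs=6)
        configs = [
            replace(base, optimizer=o, seed=s)
            for o in ("adam", "sgd")
            for s in (0, 1)
        ] + [replace(base, input_size=224)]  # fails: 32 px tiles
        table = run_grid(configs, train, val, test, vmap, expert)
        assert len(table) == 5
        assert list(table["rank"]) == [1, 2, 3, 4, 5]
        assert table.iloc[0]["four_score"] == table["four_score"].max()
        assert table.iloc[-1]["error"] != ""

    def test_identical_configs_rank_identically(self, grid_inputs):
        train, val, test, vmap, expert = grid_inputs
        cfg = replace(DESK_CONFIG, max_epochs=4, seed=3)
        table = run_grid([cfg, cfg], train, val, test, vmap, expert)
        assert table.iloc[0]["four_score"] == table.iloc[1]["four_score"]
        assert table.iloc[0]["weighted_f1"] == table.iloc[1]["weighted_f1"]
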